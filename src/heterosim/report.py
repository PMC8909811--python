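"""Pipeline orchestration and paper-shaped summary tables.

``run_pipeline`` chains the stages — simulate/load -> TPM -> differential
tests (three pairwise contrasts + hybrid-vs-mid-parent, genes and miRNAs) ->
12-class pattern assignment -> negative miRNA-mRNA network -> pathway
enrichment of the non-additive gene set -> growth metrics — and writes every
stage's TSV plus a ``manifest.json`` run record (config snapshot, seed, input
digests, per-stage counts, version). All randomness flows from one seed, so a
rerun with the same manifest reproduces the outputs byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from ._util import pct
from .classify import classify_patterns, summarize_categories, summary_frame
from .diffexp import ThresholdPolicy, run_contrasts, write_calls
from .enrichment import hypergeom_enrich, write_enrichment
from .io import read_annotation, read_counts, read_phenotypes, read_targets
from .network import build_network, network_stats, write_network
from .phenotype import records_from_table, stock_summary
from .quantify import tpm, write_tpm
from .simulate import SimulationConfig, simulate_annotation, simulate_counts, \
    simulate_phenotypes, simulate_targets

PAIRWISE = ("NL_vs_AR", "HY_vs_NL", "HY_vs_AR")


def venn_counts(calls: Mapping[str, pd.DataFrame | set]) -> dict:
    """Seven-region overlap of the three pairwise DE sets.

    Region keys join contrast names with ``&``; pairwise overlap percentages
    are directional: ``pct_overlap[a][b]`` is the share of a's DE features
    also DE in b (1 decimal).
    """
    sets = {}
    for c in PAIRWISE:
        v = calls[c]
        sets[c] = set(v.index[v["significant"]]) if isinstance(v, pd.DataFrame) else set(v)
    a, b, c = (sets[k] for k in PAIRWISE)
    regions = {
        PAIRWISE[0]: len(a - b - c),
        PAIRWISE[1]: len(b - a - c),
        PAIRWISE[2]: len(c - a - b),
        f"{PAIRWISE[0]}&{PAIRWISE[1]}": len((a & b) - c),
        f"{PAIRWISE[0]}&{PAIRWISE[2]}": len((a & c) - b),
        f"{PAIRWISE[1]}&{PAIRWISE[2]}": len((b & c) - a),
        "&".join(PAIRWISE): len(a & b & c),
    }
    overlaps = {
        ca: {cb: pct(len(sets[ca] & sets[cb]), len(sets[ca])) if sets[ca] else 0.0
             for cb in PAIRWISE if cb != ca}
        for ca in PAIRWISE
    }
    return {"regions": regions, "totals": {k: len(sets[k]) for k in PAIRWISE},
            "pct_overlap": overlaps}


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(outdir: str | Path,
                 sim_config: SimulationConfig | None = None,
                 input_paths: Mapping[str, str | Path] | None = None,
                 policy: ThresholdPolicy | None = None,
                 de_input: str = "counts",
                 targets_per_mirna: int = 10,
                 negative_fraction: float = 0.5,
                 n_fish: int = 50,
                 growth_days: tuple[int, int] = (0, 45)) -> dict:
    """Run every stage; returns the summary dict also written to results.json.

    Provide ``sim_config`` to simulate inputs, or ``input_paths`` with keys
    gene_counts, mirna_counts, design, gene_lengths, targets, annotation and
    (optionally) phenotypes.
    """
    if (sim_config is None) == (input_paths is None):
        raise ValueError("provide exactly one of sim_config or input_paths")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    policy = policy or ThresholdPolicy()
    stage_counts: dict[str, int] = {}

    # --- stage: inputs -------------------------------------------------
    if sim_config is not None:
        genes, mirnas, truth = simulate_counts(sim_config)
        targets = simulate_targets(truth, targets_per_mirna, negative_fraction,
                                   seed=sim_config.seed)
        annotation = simulate_annotation(truth, seed=sim_config.seed)
        pheno = simulate_phenotypes(n_fish, seed=sim_config.seed)
        truth.genes.to_csv(outdir / "gene_truth.tsv", sep="\t")
        truth.mirnas.to_csv(outdir / "mirna_truth.tsv", sep="\t")
        input_digests = {}
        config_snapshot = asdict(sim_config)
        seed = sim_config.seed
    else:
        paths = {k: Path(v) for k, v in input_paths.items()}
        genes = read_counts(paths["gene_counts"], paths["design"],
                            paths.get("gene_lengths"), feature_type="gene")
        mirnas = read_counts(paths["mirna_counts"], paths["design"],
                             feature_type="mirna")
        targets = read_targets(paths["targets"])
        annotation = read_annotation(paths["annotation"])
        pheno = read_phenotypes(paths["phenotypes"]) if "phenotypes" in paths else None
        input_digests = {k: _digest(p) for k, p in paths.items() if p.exists()}
        config_snapshot = {"input_paths": {k: str(v) for k, v in paths.items()}}
        seed = None
    stage_counts["genes"] = len(genes.feature_ids)
    stage_counts["mirnas"] = len(mirnas.feature_ids)

    # --- stage: quantify -----------------------------------------------
    write_tpm(tpm(genes), outdir / "gene_tpm.tsv")
    write_tpm(tpm(mirnas), outdir / "mirna_tpm.tsv")

    # --- stage: differential expression --------------------------------
    gene_calls = run_contrasts(genes, policy, de_input)
    mirna_calls = run_contrasts(mirnas, policy, de_input)
    for name, calls in (("gene", gene_calls), ("mirna", mirna_calls)):
        for contrast, df in calls.items():
            write_calls(df, outdir / f"{name}_de_{contrast}.tsv")
            stage_counts[f"{name}_DE_{contrast}"] = int(df["significant"].sum())

    # --- stage: classification -----------------------------------------
    gene_patterns = classify_patterns(gene_calls)
    mirna_patterns = classify_patterns(mirna_calls)
    gene_patterns.to_csv(outdir / "gene_patterns.tsv", sep="\t")
    mirna_patterns.to_csv(outdir / "mirna_patterns.tsv", sep="\t")
    gene_summary = summarize_categories(gene_patterns)
    mirna_summary = summarize_categories(mirna_patterns)
    summary_frame(gene_summary).to_csv(outdir / "gene_category_summary.tsv",
                                       sep="\t", index=False)
    summary_frame(mirna_summary).to_csv(outdir / "mirna_category_summary.tsv",
                                        sep="\t", index=False)
    stage_counts["NEG"] = int(gene_summary["non_additive_total"])
    stage_counts["NEM"] = int(mirna_summary["non_additive_total"])

    # --- stage: network -------------------------------------------------
    pairs = build_network(mirna_calls, gene_calls, gene_patterns, targets)
    write_network(pairs, outdir / "network_edges.tsv", outdir / "network_nodes.tsv")
    net_summary = network_stats(pairs)
    stage_counts["interaction_pairs"] = net_summary["n_pairs"]

    # --- stage: enrichment ----------------------------------------------
    expressed = set(genes.counts.index[(genes.counts.sum(axis=1) > 0)])
    neg_set = set(gene_patterns.index[gene_patterns["group"].isin(
        ("ELD_NL", "ELD_AR", "ELOD_up", "ELOD_down"))])
    enr = hypergeom_enrich(neg_set, annotation, background=expressed)
    write_enrichment(enr, outdir / "neg_enrichment.tsv",
                     background_note="annotated genes with nonzero counts")
    stage_counts["enriched_pathways_p05"] = int((enr["p_value"] < 0.05).sum()) if len(enr) else 0

    # --- stage: phenotype -----------------------------------------------
    growth = None
    if pheno is not None:
        records = records_from_table(pheno, *growth_days)
        growth = stock_summary(records)

    # --- summaries -------------------------------------------------------
    summary = {
        "gene_venn": venn_counts(gene_calls),
        "mirna_venn": venn_counts(mirna_calls),
        "gene_categories": gene_summary,
        "mirna_categories": mirna_summary,
        "network": net_summary,
        "growth": growth,
        "stage_counts": stage_counts,
    }
    (outdir / "results.json").write_text(json.dumps(summary, indent=2, default=float))
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config_snapshot,
        "policy": asdict(policy),
        "de_input": de_input,
        "input_digests": input_digests,
        "stage_counts": stage_counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return summary
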