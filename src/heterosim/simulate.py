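"""Seeded synthetic worlds emulating a three-stock hybrid RNA design.

The generator produces gene and miRNA count matrices for two parental stocks
(NL, AR) and their hybrid (HY), three replicates each, with every feature
carrying a known inheritance pattern:

* ``conserved``          — all three stock means equal
* ``additive_*``         — parents differ by ``effect_size``, hybrid at the
                           mid-parent value
* ``ELD_NL_* / ELD_AR_*``— hybrid mean equals one parent, parents differ
* ``ELOD_up_* / ELOD_down_*`` — hybrid above (x effect) or below (/ effect)
                           both parents, with the stated parental relation

Counts are negative-binomial with variance mu + phi mu^2; expected library
size varies +/-20% across samples so normalization is actually exercised. A
deterministic "mean injection" mode (counts = rounded expected counts, equal
library sizes) exists solely for exact regression tests.

Default proportions mirror a liver transcriptome in which roughly a fifth of
genes respond to hybridisation, with additive > ELD-NL > ELD-AR >> ELOD — the
mix reported for hybrid tilapia. Defaults for replicate number (3), effect
size (4) and dispersion (0.05) likewise follow that study design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import spawn_rng
from .io import CountMatrix

LABELS = (
    "conserved",
    "additive_I", "additive_II",
    "ELD_NL_III", "ELD_NL_IV",
    "ELD_AR_V", "ELD_AR_VI",
    "ELOD_up_parents_differ_NLhigh", "ELOD_up_parents_equal",
    "ELOD_up_parents_differ_ARhigh",
    "ELOD_down_parents_differ_NLhigh", "ELOD_down_parents_equal",
    "ELOD_down_parents_differ_ARhigh",
)

LABEL_CATEGORY = {
    "conserved": "conserved",
    "additive_I": "I", "additive_II": "II",
    "ELD_NL_III": "III", "ELD_NL_IV": "IV",
    "ELD_AR_V": "V", "ELD_AR_VI": "VI",
    "ELOD_up_parents_differ_NLhigh": "VII",
    "ELOD_up_parents_equal": "VIII",
    "ELOD_up_parents_differ_ARhigh": "IX",
    "ELOD_down_parents_differ_NLhigh": "X",
    "ELOD_down_parents_equal": "XI",
    "ELOD_down_parents_differ_ARhigh": "XII",
}

LABEL_GROUP = {
    "conserved": "none",
    "additive_I": "additive", "additive_II": "additive",
    "ELD_NL_III": "ELD_NL", "ELD_NL_IV": "ELD_NL",
    "ELD_AR_V": "ELD_AR", "ELD_AR_VI": "ELD_AR",
    "ELOD_up_parents_differ_NLhigh": "ELOD_up",
    "ELOD_up_parents_equal": "ELOD_up",
    "ELOD_up_parents_differ_ARhigh": "ELOD_up",
    "ELOD_down_parents_differ_NLhigh": "ELOD_down",
    "ELOD_down_parents_equal": "ELOD_down",
    "ELOD_down_parents_differ_ARhigh": "ELOD_down",
}

#: study-shaped default mix: ~78% conserved, additive 10.7%, ELD-NL 6.1%
#: (III ~2x IV), ELD-AR 4.5% (V ~1.2x VI), ELOD up 0.55% / down 0.28%
DEFAULT_PROPORTIONS = {
    "conserved": 0.7788,
    "additive_I": 0.0535, "additive_II": 0.0535,
    "ELD_NL_III": 0.0407, "ELD_NL_IV": 0.0204,
    "ELD_AR_V": 0.0243, "ELD_AR_VI": 0.0205,
    "ELOD_up_parents_differ_NLhigh": 0.0014,
    "ELOD_up_parents_equal": 0.0027,
    "ELOD_up_parents_differ_ARhigh": 0.0014,
    "ELOD_down_parents_differ_NLhigh": 0.0007,
    "ELOD_down_parents_equal": 0.0014,
    "ELOD_down_parents_differ_ARhigh": 0.0007,
}


@dataclass
class SimulationConfig:
    n_genes: int = 13000
    n_mirnas: int = 300
    n_replicates: int = 3
    dispersion: float = 0.05
    #: expected total counts per sample; None keeps feature means unscaled
    library_size: float | None = None
    pattern_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    #: optional separate mix for miRNAs (defaults to pattern_proportions)
    mirna_pattern_proportions: dict[str, float] | None = None
    effect_size: float = 4.0
    #: baseline (low-parent) means drawn log-uniform from this range
    mean_low: float = 200.0
    mean_high: float = 2000.0
    #: gamma CV of optional per-feature dispersion jitter (0 = global phi)
    dispersion_jitter: float = 0.0
    #: deterministic mode: counts = rounded expected counts, equal libraries
    mean_injection: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_mirnas < 0:
            raise ValueError("feature counts must be positive")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per stock")
        if self.dispersion < 0 or not np.isfinite(self.dispersion):
            raise ValueError("dispersion must be finite and >= 0")
        if self.effect_size <= 1 or not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite and > 1")
        for props in (self.pattern_proportions, self.mirna_pattern_proportions):
            if props is None:
                continue
            unknown = set(props) - set(LABELS)
            if unknown:
                raise ValueError(f"unknown pattern labels: {sorted(unknown)}")
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"pattern proportions sum to {total}, expected 1")
        if not (0 < self.mean_low <= self.mean_high) or not np.isfinite(self.mean_high):
            raise ValueError("mean range must be finite and positive")


@dataclass
class GroundTruth:
    """True pattern labels and stock means for every simulated feature."""

    genes: pd.DataFrame
    mirnas: pd.DataFrame
    effect_size: float

    def frame(self, feature_type: str) -> pd.DataFrame:
        return self.genes if feature_type == "gene" else self.mirnas


def apportion(proportions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of ``n`` features across labels.

    Exact shares get their floor first; leftover units go to the largest
    fractional remainders, ties broken by label order.
    """
    labels = [lab for lab in LABELS if lab in proportions]
    quota = {lab: proportions[lab] * n for lab in labels}
    counts = {lab: int(np.floor(quota[lab])) for lab in labels}
    leftover = n - sum(counts.values())
    by_remainder = sorted(labels, key=lambda lab: (-(quota[lab] - counts[lab]), labels.index(lab)))
    for lab in by_remainder[:leftover]:
        counts[lab] += 1
    return counts


def _stock_means(label: str, base: float, e: float) -> tuple[float, float, float]:
    """(mu_NL, mu_AR, mu_HY) for one feature."""
    a = base
    table = {
        "conserved": (a, a, a),
        "additive_I": (e * a, a, (e + 1) / 2 * a),
        "additive_II": (a, e * a, (e + 1) / 2 * a),
        "ELD_NL_III": (e * a, a, e * a),
        "ELD_NL_IV": (a, e * a, a),
        "ELD_AR_V": (a, e * a, e * a),
        "ELD_AR_VI": (e * a, a, a),
        "ELOD_up_parents_differ_NLhigh": (e * a, a, e * e * a),
        "ELOD_up_parents_equal": (a, a, e * a),
        "ELOD_up_parents_differ_ARhigh": (a, e * a, e * e * a),
        "ELOD_down_parents_differ_NLhigh": (e * a, a, a / e),
        "ELOD_down_parents_equal": (a, a, a / e),
        "ELOD_down_parents_differ_ARhigh": (a, e * a, a / e),
    }
    return table[label]


def _truth_frame(prefix: str, n: int, config: SimulationConfig,
                 rng: np.random.Generator,
                 proportions: dict[str, float] | None = None) -> pd.DataFrame:
    counts = apportion(proportions or config.pattern_proportions, n)
    labels = np.array([lab for lab in LABELS for _ in range(counts.get(lab, 0))], dtype=object)
    rng.shuffle(labels)
    base = np.exp(rng.uniform(np.log(config.mean_low), np.log(config.mean_high), size=n))
    mus = np.array([_stock_means(lab, b, config.effect_size)
                    for lab, b in zip(labels, base)])
    ids = [f"{prefix}{i:05d}" for i in range(n)]
    return pd.DataFrame(
        {
            "label": labels,
            "true_category": [LABEL_CATEGORY[lab] for lab in labels],
            "true_group": [LABEL_GROUP[lab] for lab in labels],
            "mu_NL": mus[:, 0],
            "mu_AR": mus[:, 1],
            "mu_HY": mus[:, 2],
        },
        index=pd.Index(ids, name="feature_id"),
    )


def _draw_counts(truth: pd.DataFrame, config: SimulationConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    mu = truth[["mu_NL", "mu_AR", "mu_HY"]].to_numpy()
    n_rep = config.n_replicates
    samples = [f"{stock}{r + 1}" for stock in ("NL", "AR", "HY") for r in range(n_rep)]
    stock_idx = np.repeat([0, 1, 2], n_rep)
    expected = mu[:, stock_idx]  # features x samples
    if config.library_size is not None:
        expected = expected * (config.library_size / expected.sum(axis=0, keepdims=True))
    if config.mean_injection:
        counts = np.round(expected)
    else:
        lib = rng.uniform(0.8, 1.2, size=len(samples))
        expected = expected * lib[None, :]
        phi = np.full(mu.shape[0], config.dispersion)
        if config.dispersion_jitter > 0 and config.dispersion > 0:
            shape = 1.0 / config.dispersion_jitter ** 2
            phi = phi * rng.gamma(shape, 1.0 / shape, size=phi.shape)
        if config.dispersion == 0:
            counts = rng.poisson(expected)
        else:
            r = 1.0 / phi[:, None]
            p = r / (r + expected)
            counts = rng.negative_binomial(np.broadcast_to(r, expected.shape), p)
    return pd.DataFrame(counts.astype(np.int64), index=truth.index, columns=samples)


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, CountMatrix, GroundTruth]:
    """Gene and miRNA count matrices plus the ground truth behind them."""
    rng = spawn_rng(config.seed, stream=0)
    gene_truth = _truth_frame("gene", config.n_genes, config, rng)
    mirna_truth = _truth_frame("mir", config.n_mirnas, config, rng,
                               config.mirna_pattern_proportions)
    gene_counts = _draw_counts(gene_truth, config, rng)
    mirna_counts = _draw_counts(mirna_truth, config, rng)
    design = pd.DataFrame(
        {
            "stock": np.repeat(["NL", "AR", "HY"], config.n_replicates),
            "replicate": np.tile(np.arange(1, config.n_replicates + 1), 3),
        },
        index=pd.Index(gene_counts.columns, name="sample_id"),
    )
    gene_lengths = pd.Series(
        np.exp(rng.uniform(np.log(300), np.log(8000), size=config.n_genes)).round().astype(int),
        index=gene_truth.index, name="length_nt",
    )
    genes = CountMatrix(gene_counts, design, lengths=gene_lengths, feature_type="gene")
    mirnas = CountMatrix(mirna_counts, design.copy(), lengths=None, feature_type="mirna")
    return genes, mirnas, GroundTruth(gene_truth, mirna_truth, config.effect_size)


def truth_directions(frame: pd.DataFrame, min_fold: float) -> pd.DataFrame:
    """Per-contrast ground-truth hybrid direction: ``up``/``down``/``none``.

    A feature has a direction in a hybrid-vs-parent contrast when its true
    fold against that parent reaches ``min_fold``.
    """
    out = {}
    for contrast, parent in (("HY_vs_NL", "mu_NL"), ("HY_vs_AR", "mu_AR")):
        ratio = frame["mu_HY"] / frame[parent]
        out[contrast] = np.where(ratio >= min_fold, "up",
                                 np.where(ratio <= 1.0 / min_fold, "down", "none"))
    return pd.DataFrame(out, index=frame.index)


def simulate_targets(truth: GroundTruth, targets_per_mirna: int = 10,
                     negative_fraction: float = 0.5,
                     seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """miRNA -> target-gene table with a controlled negatively-regulated share.

    For ``negative_fraction`` of each miRNA's rows the partner gene is chosen
    so that, in some hybrid-vs-parent contrast where the miRNA truly departs
    at full effect size, the gene truly departs in the opposite direction —
    i.e. the pair is negatively regulated by construction. Remaining rows pair
    uniformly random genes. miRNAs with no strong hybrid direction contribute
    only random rows. Duplicate (mirna, gene) rows are dropped.
    """
    if not 0.0 <= negative_fraction <= 1.0:
        raise ValueError("negative_fraction must lie in [0, 1]")
    if targets_per_mirna > len(truth.genes):
        raise ValueError("targets_per_mirna exceeds number of genes")
    rng = spawn_rng(seed, stream=1)
    gene_dirs = truth_directions(truth.genes, truth.effect_size)
    mirna_dirs = truth_directions(truth.mirnas, truth.effect_size)
    pools = {
        (contrast, d): truth.genes.index[gene_dirs[contrast] == d].to_numpy()
        for contrast in gene_dirs.columns for d in ("up", "down")
    }
    opposite = {"up": "down", "down": "up"}
    rows = []
    all_genes = truth.genes.index.to_numpy()
    for mirna in truth.mirnas.index:
        options = [(c, d) for c in mirna_dirs.columns
                   if (d := mirna_dirs.loc[mirna, c]) in opposite]
        n_neg = int(round(negative_fraction * targets_per_mirna)) if options else 0
        chosen: list[tuple[str, bool]] = []
        if n_neg:
            contrast, d = options[rng.integers(len(options))]
            pool = pools[(contrast, opposite[d])]
            take = rng.choice(pool, size=min(n_neg, len(pool)), replace=False)
            chosen += [(g, True) for g in take]
        n_rand = targets_per_mirna - len(chosen)
        if n_rand > 0:
            take = rng.choice(all_genes, size=n_rand, replace=False)
            chosen += [(g, False) for g in take]
        for gene, is_neg in chosen:
            rows.append((mirna, gene, float(rng.uniform(-25.0, -8.0)), is_neg))
    df = pd.DataFrame(rows, columns=["mirna_id", "gene_id", "score", "is_negative"])
    return df.drop_duplicates(subset=["mirna_id", "gene_id"]).reset_index(drop=True)


def simulate_annotation(truth: GroundTruth, n_pathways: int = 30,
                        genes_per_pathway: int = 40,
                        seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Random pathway membership; the first few pathways are biased toward
    truly non-additive genes so enrichment has signal to find."""
    rng = spawn_rng(seed, stream=2)
    genes = truth.genes.index.to_numpy()
    nonadd = truth.genes.index[truth.genes["true_group"].isin(
        ["ELD_NL", "ELD_AR", "ELOD_up", "ELOD_down"])].to_numpy()
    rows = []
    for k in range(n_pathways):
        pid = f"path{k:03d}"
        name = f"synthetic pathway {k}"
        if k < 5 and len(nonadd) >= genes_per_pathway // 2:
            members = np.concatenate([
                rng.choice(nonadd, size=genes_per_pathway // 2, replace=False),
                rng.choice(genes, size=genes_per_pathway - genes_per_pathway // 2,
                           replace=False),
            ])
        else:
            members = rng.choice(genes, size=min(genes_per_pathway, len(genes)),
                                 replace=False)
        for g in np.unique(members):
            rows.append((g, pid, name))
    return pd.DataFrame(rows, columns=["gene_id", "pathway_id", "pathway_name"])


#: specific growth rates (%/day) chosen so the hybrid outgrows both parents
#: at the study's reported day-45 ratios (HY/AR = 1.46, HY/NL = 1.27)
DEFAULT_GROWTH_PARAMS = {
    "NL": {"w0": 10.0, "sgr": 2.18, "l0": 8.0, "lgr_day": 0.0070, "d0": 3.0, "dgr_day": 0.0072},
    "AR": {"w0": 10.0, "sgr": 1.90, "l0": 8.0, "lgr_day": 0.0062, "d0": 3.0, "dgr_day": 0.0064},
    "HY": {"w0": 10.0, "sgr": 2.77, "l0": 8.0, "lgr_day": 0.0089, "d0": 3.0, "dgr_day": 0.0091},
}


def simulate_phenotypes(n_fish: int = 50,
                        stock_growth_params: dict | None = None,
                        days: tuple[int, ...] = (0, 45, 90),
                        noise_sd: float = 0.08,
                        seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Per-fish weight/length/depth at each measurement day.

    Weight grows exponentially at the stock SGR; length and depth grow
    linearly at the stock daily rate. Measurements carry multiplicative
    lognormal noise with log-sd ``noise_sd``.
    """
    if n_fish < 0:
        raise ValueError("n_fish must be >= 0")
    params = stock_growth_params or DEFAULT_GROWTH_PARAMS
    for stock, p in params.items():
        if min(p["w0"], p["l0"], p["d0"]) <= 0:
            raise ValueError(f"non-positive initial size for stock {stock}")
    rng = spawn_rng(seed, stream=3)
    rows = []
    for stock, p in params.items():
        for i in range(n_fish):
            fish = f"{stock}_f{i:03d}"
            for day in days:
                w = p["w0"] * np.exp(p["sgr"] / 100.0 * day)
                ln = p["l0"] * (1.0 + p["lgr_day"] * day)
                d = p["d0"] * (1.0 + p["dgr_day"] * day)
                if noise_sd > 0:
                    w, ln, d = (v * np.exp(rng.normal(0.0, noise_sd)) for v in (w, ln, d))
                rows.append((fish, stock, day, w, ln, d))
    return pd.DataFrame(rows, columns=["fish_id", "stock", "day",
                                       "weight_g", "length_cm", "depth_cm"])


def write_dataset(outdir: str | Path, config: SimulationConfig,
                  targets_per_mirna: int = 10, negative_fraction: float = 0.5,
                  n_fish: int = 50) -> dict[str, Path]:
    """Simulate one full dataset and write every TSV the pipeline consumes."""
    from .io import write_counts

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, mirnas, truth = simulate_counts(config)
    paths = {
        "gene_counts": outdir / "gene_counts.tsv",
        "mirna_counts": outdir / "mirna_counts.tsv",
        "design": outdir / "design.tsv",
        "gene_lengths": outdir / "gene_lengths.tsv",
        "targets": outdir / "targets.tsv",
        "annotation": outdir / "annotation.tsv",
        "gene_truth": outdir / "gene_truth.tsv",
        "mirna_truth": outdir / "mirna_truth.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
    }
    write_counts(genes, paths["gene_counts"], paths["design"], paths["gene_lengths"])
    write_counts(mirnas, paths["mirna_counts"])
    simulate_targets(truth, targets_per_mirna, negative_fraction,
                     seed=config.seed).to_csv(paths["targets"], sep="\t", index=False)
    simulate_annotation(truth, seed=config.seed).to_csv(
        paths["annotation"], sep="\t", index=False)
    truth.genes.to_csv(paths["gene_truth"], sep="\t")
    truth.mirnas.to_csv(paths["mirna_truth"], sep="\t")
    simulate_phenotypes(n_fish, seed=config.seed).to_csv(
        paths["phenotypes"], sep="\t", index=False)
    return paths
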