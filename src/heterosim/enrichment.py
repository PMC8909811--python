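"""Hypergeometric pathway over-representation.

For a gene set of size n drawn from a background of N genes, a pathway with K
background members and k set members is scored with the upper-tail
hypergeometric probability P[X >= k], X ~ Hypergeometric(N, K, n) — the
classic over-representation test of KOBAS-style KEGG analysis.
Benjamini-Hochberg values are reported alongside, but the default
significance filter is on raw p < 0.05, matching the study's convention.

The background is the annotated universe: genes present in the annotation
table, optionally intersected with an expressed-gene list supplied by the
caller (the pipeline passes every feature with a nonzero count).
"""

from __future__ import annotations

from collections.abc import Collection

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def hypergeom_enrich(gene_set: Collection[str], annotation: pd.DataFrame,
                     background: Collection[str] | None = None) -> pd.DataFrame:
    """Per-pathway enrichment table, sorted by p.

    ``annotation`` has columns gene_id, pathway_id, pathway_name. If
    ``background`` is given, the universe is its intersection with the
    annotated genes and the gene set is clipped to the universe; otherwise
    all annotated genes form the universe.
    """
    ann = annotation.drop_duplicates(subset=["gene_id", "pathway_id"])
    universe = set(ann["gene_id"])
    if background is not None:
        universe &= set(background)
        ann = ann[ann["gene_id"].isin(universe)]
    gene_set = set(gene_set)
    outside = gene_set - universe
    gene_set &= universe
    N, n = len(universe), len(gene_set)
    if N == 0 or N < n:
        raise ValueError("background smaller than gene set (or empty)")
    rows = []
    for (pid, name), members in ann.groupby(["pathway_id", "pathway_name"])["gene_id"]:
        K = members.nunique()
        if K == 0:
            continue
        k = len(gene_set & set(members))
        # P[X >= k]; sf(k-1) is the exact upper tail
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"pathway_id": pid, "pathway_name": name,
                     "k": k, "n": n, "K": K, "N": N, "p_value": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["pathway_id", "pathway_name",
                                      "k", "n", "K", "N", "p_value"])
    if len(out):
        out["adj_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out = out.sort_values(["p_value", "pathway_id"]).reset_index(drop=True)
    else:
        out["adj_p"] = []
    out.attrs["n_outside_background"] = len(outside)
    return out


def write_enrichment(result: pd.DataFrame, path, background_note: str = "") -> None:
    with open(path, "w") as fh:
        if background_note:
            fh.write(f"# background: {background_note}\n")
        result.to_csv(fh, sep="\t", index=False, float_format="%.6g")
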