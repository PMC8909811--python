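"""Negative miRNA-mRNA interaction network.

A candidate (miRNA, gene) edge from the target-prediction table is kept when
both members are differentially expressed in at least one shared
hybrid-vs-parent contrast with opposite directions (miRNA up, gene down, or
vice versa) — the direction-based reading of negative post-transcriptional
regulation. Correlation across replicates is deliberately not used: with
three replicates per stock it is too unstable to rank edges.

Edge directions are reported from the first supporting contrast in the fixed
order (HY_vs_NL, HY_vs_AR); all supporting contrasts are listed so the
ambiguity of "up-regulated relative to which parent" stays visible per edge.
"""

from __future__ import annotations

from typing import Mapping

import networkx as nx
import pandas as pd

from ._util import pct
from .io import warn

HYBRID_CONTRASTS = ("HY_vs_NL", "HY_vs_AR")


def build_network(dem_calls: Mapping[str, pd.DataFrame],
                  deg_calls: Mapping[str, pd.DataFrame],
                  assignments: pd.DataFrame,
                  targets: pd.DataFrame) -> pd.DataFrame:
    """Retain negatively-interacting DEM-DEG pairs from the target table.

    ``dem_calls`` / ``deg_calls`` map contrast -> called test table;
    ``assignments`` is the gene pattern table (for the edge's category group).
    Rows referencing unknown ids are skipped (counted in a warning).
    """
    known_m = set(dem_calls[HYBRID_CONTRASTS[0]].index)
    known_g = set(deg_calls[HYBRID_CONTRASTS[0]].index)
    cand = targets.drop_duplicates(subset=["mirna_id", "gene_id"])
    unknown = (~cand["mirna_id"].isin(known_m)) | (~cand["gene_id"].isin(known_g))
    if unknown.any():
        warn(f"skipping {int(unknown.sum())} target rows with unknown ids")
        cand = cand[~unknown]

    rows = []
    for _, row in cand.iterrows():
        supports = []
        for contrast in HYBRID_CONTRASTS:
            m = dem_calls[contrast].loc[row["mirna_id"]]
            g = deg_calls[contrast].loc[row["gene_id"]]
            if (m["significant"] and g["significant"]
                    and m["direction"] != g["direction"]):
                supports.append((contrast, m["direction"], g["direction"]))
        if not supports:
            continue
        contrast, mdir, gdir = supports[0]
        rows.append({
            "mirna_id": row["mirna_id"],
            "gene_id": row["gene_id"],
            "mirna_direction": mdir,
            "gene_direction": gdir,
            "contrasts": ";".join(s[0] for s in supports),
            "pair_category": (assignments.loc[row["gene_id"], "group"]
                              if row["gene_id"] in assignments.index else "none"),
            "score": row.get("score", float("nan")),
        })
    cols = ["mirna_id", "gene_id", "mirna_direction", "gene_direction",
            "contrasts", "pair_category", "score"]
    return pd.DataFrame(rows, columns=cols)


def network_stats(pairs: pd.DataFrame) -> dict:
    """Edge/node counts, up-regulated-gene share and per-group percentages."""
    n = len(pairs)
    per_group = pairs["pair_category"].value_counts().to_dict() if n else {}
    return {
        "n_pairs": n,
        "n_mirnas": pairs["mirna_id"].nunique() if n else 0,
        "n_genes": pairs["gene_id"].nunique() if n else 0,
        "pct_gene_up": pct((pairs["gene_direction"] == "up").sum(), n) if n else 0.0,
        "per_group": {g: {"count": int(c), "pct": pct(c, n)}
                      for g, c in sorted(per_group.items())},
    }


def to_graph(pairs: pd.DataFrame) -> nx.Graph:
    """Bipartite graph view for export to standard viewers."""
    g = nx.Graph()
    for _, row in pairs.iterrows():
        g.add_node(row["mirna_id"], kind="mirna")
        g.add_node(row["gene_id"], kind="gene", group=row["pair_category"])
        g.add_edge(row["mirna_id"], row["gene_id"],
                   contrasts=row["contrasts"], score=row["score"])
    return g


def write_network(pairs: pd.DataFrame, edges_tsv, nodes_tsv) -> None:
    pairs.to_csv(edges_tsv, sep="\t", index=False)
    g = to_graph(pairs)
    nodes = pd.DataFrame(
        [{"node_id": n, **attrs} for n, attrs in g.nodes(data=True)]
    )
    nodes.to_csv(nodes_tsv, sep="\t", index=False)
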