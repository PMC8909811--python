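"""Twelve-class inheritance-pattern classification and its summary tables.

Every feature with all four contrasts available is assigned one category:

========  ==========  =====================================================
category  group       meaning (HY = hybrid, NL/AR = parents, MPV = parental
                      average)
========  ==========  =====================================================
I, II     additive    parents differ; HY consistent with the MPV
                      (I: NL > AR, II: NL < AR)
III, IV   ELD_NL      HY statistically matches NL, differs from AR
                      (III: NL > AR, IV: NL < AR)
V, VI     ELD_AR      HY matches AR, differs from NL (V: AR > NL, VI: AR < NL)
VII-IX    ELOD_up     HY significantly above BOTH parents
                      (VII: NL > AR, VIII: parents equal, IX: NL < AR)
X-XII     ELOD_down   HY significantly below both parents, same sub-order
========  ==========  =====================================================

plus ``conserved`` (no contrast significant) and ``ambiguous`` (every other
signature). Rules are evaluated top-down (ELOD, ELD, additive, conserved) and
the first match wins.

Dominance (ELD) additionally requires mid-parent evidence: the HY-vs-MPV test
significant, or at least a smaller p than the HY-vs-matched-parent contrast.
Without that condition an additive feature whose fold against the nearer
parent happens to fall below the detection threshold is indistinguishable
from dominance and the additive class bleeds into ELD; requiring only a
significant MPV test instead caps dominance recovery at the MPV test's power.
Comparing the two p-values resolves the ambiguous cell toward whichever
departure (from the matched parent, or from the mid-parent) the data support
more strongly.

``non_additive`` marks the NEG/NEM set: any ELD/ELOD feature, or any feature
whose HY-vs-MPV test is significant regardless of category.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from ._util import pct, round_half_up

CATEGORIES = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII",
              "conserved", "ambiguous"]

CATEGORY_GROUP: dict[str, str] = {
    "I": "additive", "II": "additive",
    "III": "ELD_NL", "IV": "ELD_NL",
    "V": "ELD_AR", "VI": "ELD_AR",
    "VII": "ELOD_up", "VIII": "ELOD_up", "IX": "ELOD_up",
    "X": "ELOD_down", "XI": "ELOD_down", "XII": "ELOD_down",
    "conserved": "none", "ambiguous": "none",
}

GROUPS = ("additive", "ELD_NL", "ELD_AR", "ELOD_up", "ELOD_down")
NON_ADDITIVE_GROUPS = ("ELD_NL", "ELD_AR", "ELOD_up", "ELOD_down")


def classify_patterns(calls: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Assign categories from the four called contrasts.

    ``calls`` maps contrast name -> DataFrame with ``significant``,
    ``direction``, ``log2fc`` and ``p_value`` columns (as produced by
    :func:`heterosim.diffexp.run_contrasts`), indexed by feature.
    """
    needed = {"NL_vs_AR", "HY_vs_NL", "HY_vs_AR", "HY_vs_MPV"}
    missing = needed - set(calls)
    if missing:
        raise ValueError(f"missing contrasts: {sorted(missing)}")
    P, HN, HA, M = (calls[c] for c in ("NL_vs_AR", "HY_vs_NL", "HY_vs_AR", "HY_vs_MPV"))
    idx = P.index
    for df in (HN, HA, M):
        if not df.index.equals(idx):
            raise ValueError("contrast tables must share one feature index")

    p_sig = P["significant"].to_numpy(bool)
    hn_sig = HN["significant"].to_numpy(bool)
    ha_sig = HA["significant"].to_numpy(bool)
    m_sig = M["significant"].to_numpy(bool)
    hn_up = HN["log2fc"].to_numpy() > 0
    ha_up = HA["log2fc"].to_numpy() > 0
    nl_gt_ar = P["log2fc"].to_numpy() > 0

    # parental relation index: 0 = NL>AR, 1 = statistically equal, 2 = NL<AR
    rel = np.where(~p_sig, 1, np.where(nl_gt_ar, 0, 2))

    # mid-parent evidence backing a dominance call against the matched parent
    eld_nl_ev = m_sig | (M["p_value"].to_numpy() < HN["p_value"].to_numpy())
    eld_ar_ev = m_sig | (M["p_value"].to_numpy() < HA["p_value"].to_numpy())

    category = np.full(len(idx), "ambiguous", dtype=object)
    unassigned = np.ones(len(idx), dtype=bool)

    def assign(mask: np.ndarray, labels: np.ndarray | str) -> None:
        nonlocal unassigned
        take = mask & unassigned
        category[take] = labels[take] if isinstance(labels, np.ndarray) else labels
        unassigned &= ~take

    up_bins = np.array(["VII", "VIII", "IX"], dtype=object)[rel]
    down_bins = np.array(["X", "XI", "XII"], dtype=object)[rel]
    assign(hn_sig & ha_sig & hn_up & ha_up, up_bins)
    assign(hn_sig & ha_sig & ~hn_up & ~ha_up, down_bins)
    assign(p_sig & ~hn_sig & ha_sig & eld_nl_ev, np.where(nl_gt_ar, "III", "IV").astype(object))
    assign(p_sig & ~ha_sig & hn_sig & eld_ar_ev, np.where(nl_gt_ar, "VI", "V").astype(object))
    assign(p_sig & ~m_sig, np.where(nl_gt_ar, "I", "II").astype(object))
    assign(~p_sig & ~hn_sig & ~ha_sig & ~m_sig, "conserved")

    group = np.array([CATEGORY_GROUP[c] for c in category], dtype=object)
    non_additive = np.isin(group, NON_ADDITIVE_GROUPS) | m_sig
    return pd.DataFrame(
        {"category": category, "group": group, "non_additive": non_additive},
        index=idx.rename("feature_id"),
    )


def tally(assignments: pd.DataFrame) -> dict[str, int]:
    """Category -> count over an assignment table."""
    vc = assignments["category"].value_counts()
    return {c: int(vc.get(c, 0)) for c in CATEGORIES}


def _within(counts: Mapping[str, float], a: str, b: str) -> dict:
    """Larger-vs-smaller statistics inside a two-bin group."""
    ca, cb = counts.get(a, 0), counts.get(b, 0)
    total = ca + cb
    larger, lc, sc = (a, ca, cb) if ca >= cb else (b, cb, ca)
    return {
        "larger": larger,
        "ratio": round_half_up(lc / sc, 2) if sc > 0 else (float("inf") if lc > 0 else 0.0),
        "pct_larger": pct(lc, total),
    }


def summarize_categories(data: pd.DataFrame | Mapping[str, float]) -> dict:
    """Counts, percentages and within-group ratios over categories I-XII.

    ``data`` is either an assignment table from :func:`classify_patterns` or
    a mapping category -> count. Percentages use the categorized total
    (sum over I-XII) as denominator and are rounded half-up to 1 decimal;
    ratios to 2 decimals. The non-additive total sums the ELD and ELOD
    groups (the NEG/NEM count of the study design).
    """
    counts = dict(tally(data)) if isinstance(data, pd.DataFrame) else {
        c: float(data.get(c, 0)) for c in CATEGORIES
    }
    group_counts = {g: 0.0 for g in GROUPS}
    for c, g in CATEGORY_GROUP.items():
        if g != "none":
            group_counts[g] += counts.get(c, 0)
    total = sum(group_counts.values())
    groups = {
        g: {"count": group_counts[g], "pct": pct(group_counts[g], total)} for g in GROUPS
    }
    elod_total = group_counts["ELOD_up"] + group_counts["ELOD_down"]
    within = {
        "additive": _within(counts, "I", "II"),
        "ELD_NL": _within(counts, "III", "IV"),
        "ELD_AR": _within(counts, "V", "VI"),
        "ELOD": _within(group_counts, "ELOD_up", "ELOD_down"),
    }
    return {
        "total": total,
        "categories": counts,
        "groups": groups,
        "elod_pct": pct(elod_total, total),
        "within": within,
        "non_additive_total": sum(group_counts[g] for g in NON_ADDITIVE_GROUPS),
        "conserved": counts.get("conserved", 0),
        "ambiguous": counts.get("ambiguous", 0),
    }


def summary_frame(summary: dict) -> pd.DataFrame:
    """Flat one-row-per-group table for TSV export."""
    rows = []
    for g in GROUPS:
        rows.append({"group": g, "count": summary["groups"][g]["count"],
                     "pct": summary["groups"][g]["pct"]})
    rows.append({"group": "non_additive_total", "count": summary["non_additive_total"],
                 "pct": pct(summary["non_additive_total"], summary["total"])})
    return pd.DataFrame(rows)
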