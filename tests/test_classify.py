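import numpy as np
import pandas as pd
import pytest

from heterosim.classify import (
    CATEGORY_GROUP,
    classify_patterns,
    summarize_categories,
    tally,
)


def make_calls(features):
    """Build the four-contrast call dict from per-feature tuples.

    Each feature maps to {contrast: (log2fc, p, significant)}.
    """
    idx = pd.Index(list(features), name="feature_id")
    calls = {}
    for contrast in ("NL_vs_AR", "HY_vs_NL", "HY_vs_AR", "HY_vs_MPV"):
        rows = [features[f][contrast] for f in features]
        df = pd.DataFrame(rows, columns=["log2fc", "p_value", "significant"], index=idx)
        df["contrast"] = contrast
        df["direction"] = np.where(~df["significant"], "ns",
                                   np.where(df["log2fc"] > 0, "up", "down"))
        calls[contrast] = df
    return calls


SIG_UP = (2.0, 1e-6, True)
SIG_DOWN = (-2.0, 1e-6, True)
NS = (0.1, 0.8, False)
NS_LOWP = (0.3, 0.02, False)   # not significant but small p


@pytest.mark.parametrize(
    "contrasts,expected_cat,expected_group,expected_na",
    [
        # dominance by NL, parents NL>AR: HY==NL, differs from AR, MPV sig
        ({"NL_vs_AR": SIG_UP, "HY_vs_NL": NS, "HY_vs_AR": SIG_UP, "HY_vs_MPV": SIG_UP},
         "III", "ELD_NL", True),
        ({"NL_vs_AR": SIG_DOWN, "HY_vs_NL": NS, "HY_vs_AR": SIG_DOWN, "HY_vs_MPV": SIG_DOWN},
         "IV", "ELD_NL", True),
        ({"NL_vs_AR": SIG_DOWN, "HY_vs_NL": SIG_UP, "HY_vs_AR": NS, "HY_vs_MPV": SIG_UP},
         "V", "ELD_AR", True),
        ({"NL_vs_AR": SIG_UP, "HY_vs_NL": SIG_DOWN, "HY_vs_AR": NS, "HY_vs_MPV": SIG_DOWN},
         "VI", "ELD_AR", True),
        # overdominance beats dominance in the rule order
        ({"NL_vs_AR": SIG_UP, "HY_vs_NL": SIG_UP, "HY_vs_AR": SIG_UP, "HY_vs_MPV": SIG_UP},
         "VII", "ELOD_up", True),
        ({"NL_vs_AR": NS, "HY_vs_NL": SIG_UP, "HY_vs_AR": SIG_UP, "HY_vs_MPV": SIG_UP},
         "VIII", "ELOD_up", True),
        ({"NL_vs_AR": SIG_DOWN, "HY_vs_NL": SIG_UP, "HY_vs_AR": SIG_UP, "HY_vs_MPV": SIG_UP},
         "IX", "ELOD_up", True),
        ({"NL_vs_AR": SIG_UP, "HY_vs_NL": SIG_DOWN, "HY_vs_AR": SIG_DOWN, "HY_vs_MPV": SIG_DOWN},
         "X", "ELOD_down", True),
        ({"NL_vs_AR": NS, "HY_vs_NL": SIG_DOWN, "HY_vs_AR": SIG_DOWN, "HY_vs_MPV": SIG_DOWN},
         "XI", "ELOD_down", True),
        ({"NL_vs_AR": SIG_DOWN, "HY_vs_NL": SIG_DOWN, "HY_vs_AR": SIG_DOWN, "HY_vs_MPV": SIG_DOWN},
         "XII", "ELOD_down", True),
        # additivity: parents differ, hybrid consistent with mid-parent;
        # the hybrid differing from both parents does not matter
        ({"NL_vs_AR": SIG_UP, "HY_vs_NL": SIG_DOWN, "HY_vs_AR": SIG_UP, "HY_vs_MPV": NS},
         "I", "additive", False),
        ({"NL_vs_AR": SIG_DOWN, "HY_vs_NL": SIG_UP, "HY_vs_AR": SIG_DOWN, "HY_vs_MPV": NS},
         "II", "additive", False),
        # nothing significant
        ({"NL_vs_AR": NS, "HY_vs_NL": NS, "HY_vs_AR": NS, "HY_vs_MPV": NS},
         "conserved", "none", False),
        # only the mid-parent test fires: category stays out of the 12 but
        # the feature is still non-additive
        ({"NL_vs_AR": NS, "HY_vs_NL": NS, "HY_vs_AR": NS, "HY_vs_MPV": SIG_UP},
         "ambiguous", "none", True),
        # dominance signature without any mid-parent evidence collapses to
        # additivity (HY-vs-matched-parent p is smaller than the MPV p)
        ({"NL_vs_AR": SIG_UP, "HY_vs_NL": (0.0, 1e-8, False), "HY_vs_AR": SIG_UP,
          "HY_vs_MPV": NS}, "I", "additive", False),
        # dominance signature where MPV is non-significant but carries more
        # evidence than the matched-parent contrast -> still dominance
        ({"NL_vs_AR": SIG_UP, "HY_vs_NL": (0.1, 0.9, False), "HY_vs_AR": SIG_UP,
          "HY_vs_MPV": NS_LOWP}, "III", "ELD_NL", True),
    ],
)
def test_decision_table(contrasts, expected_cat, expected_group, expected_na):
    calls = make_calls({"f0": contrasts})
    out = classify_patterns(calls)
    assert out.loc["f0", "category"] == expected_cat
    assert out.loc["f0", "group"] == expected_group
    assert bool(out.loc["f0", "non_additive"]) is expected_na


def test_missing_contrast_raises():
    calls = make_calls({"f0": {"NL_vs_AR": NS, "HY_vs_NL": NS, "HY_vs_AR": NS,
                               "HY_vs_MPV": NS}})
    del calls["HY_vs_MPV"]
    with pytest.raises(ValueError, match="missing contrasts"):
        classify_patterns(calls)


def _swap_stocks(calls):
    """Relabel NL<->AR: negate the parental contrast, swap the hybrid ones."""
    swapped = {
        "NL_vs_AR": calls["NL_vs_AR"].copy(),
        "HY_vs_NL": calls["HY_vs_AR"].copy(),
        "HY_vs_AR": calls["HY_vs_NL"].copy(),
        "HY_vs_MPV": calls["HY_vs_MPV"].copy(),
    }
    swapped["NL_vs_AR"]["log2fc"] *= -1
    for name, df in swapped.items():
        df["contrast"] = name
    return swapped


SWAP_MAP = {"I": "II", "II": "I", "III": "V", "V": "III", "IV": "VI", "VI": "IV",
            "VII": "IX", "IX": "VII", "VIII": "VIII", "X": "XII", "XII": "X",
            "XI": "XI", "conserved": "conserved", "ambiguous": "ambiguous"}


def test_stock_relabelling_symmetry(default_gene_calls):
    """Swapping the parental labels permutes categories but preserves the
    overdominance groups and the non-additive set."""
    base = classify_patterns(default_gene_calls)
    flipped = classify_patterns(_swap_stocks(default_gene_calls))
    assert (flipped["category"] == base["category"].map(SWAP_MAP)).all()
    elod = base["group"].isin(["ELOD_up", "ELOD_down"])
    assert (flipped.loc[elod.values, "group"] == base.loc[elod.values, "group"]).all()
    assert (flipped["non_additive"] == base["non_additive"]).all()


def test_partition_and_percentages(default_gene_calls):
    """Every feature gets exactly one category; group shares sum to ~100."""
    out = classify_patterns(default_gene_calls)
    assert out["category"].isin(list(CATEGORY_GROUP)).all()
    summary = summarize_categories(out)
    total_pct = sum(summary["groups"][g]["pct"] for g in summary["groups"])
    assert total_pct == pytest.approx(100.0, abs=0.2)
    assert summary["total"] == sum(
        v for c, v in tally(out).items() if CATEGORY_GROUP[c] != "none")
    # group membership implies non-additivity for ELD/ELOD
    eld = out["group"].isin(["ELD_NL", "ELD_AR", "ELOD_up", "ELOD_down"])
    assert out.loc[eld.values, "non_additive"].all()


def test_summary_single_category_and_empty():
    s = summarize_categories({"III": 10})
    assert s["groups"]["ELD_NL"]["pct"] == 100.0
    assert s["groups"]["additive"]["pct"] == 0.0
    assert s["non_additive_total"] == 10
    empty = summarize_categories({})
    assert empty["total"] == 0
    assert all(empty["groups"][g]["count"] == 0 for g in empty["groups"])
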