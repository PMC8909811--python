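"""Pairwise negative-binomial Wald tests and the mid-parent non-additivity test.

The test is a deliberately transparent stand-in for heavyweight DE packages:

* counts are divided by median-of-ratios size factors;
* a per-feature dispersion phi (variance = mu + phi mu^2) is estimated by
  method of moments from the pooled within-group variance,
  ``phi_raw = max(0, (s^2 - mu) / mu^2)``, and shrunk toward the median raw
  estimate across features with weight n/(n+4), n = samples in the contrast
  (n=6 for 3 vs 3) — a cheap analogue of dispersion-trend shrinkage that
  stabilises the noisy 3-replicate estimates;
* the Wald statistic is the log mean ratio over its delta-method standard
  error, ``var(ln mean_g) ~= (1/mean_g + phi)/n_g``, with a two-sided normal
  reference; group means carry a pseudo-count of 0.5 normalized counts.

Differential calls apply the study thresholds: genes need p < 0.01 and fold
change > 2 or < 0.5; miRNAs need p < 0.05 only. The mid-parent test compares
hybrid replicates against per-replicate pseudo mid-parent samples
``m_r = (x_NL,r + x_AR,r)/2`` (paired by replicate index) and flags a feature
non-additive at p < 0.05. Raw p-values gate significance by default, matching
the study; Benjamini-Hochberg values are always reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, warn
from .quantify import normalized_counts, tpm

CONTRASTS = ("NL_vs_AR", "HY_vs_NL", "HY_vs_AR", "HY_vs_MPV")
PSEUDOCOUNT = 0.5


@dataclass
class ThresholdPolicy:
    """Significance thresholds defining DEGs, DEMs and non-additive features."""

    gene_p: float = 0.01
    gene_fc: float = 2.0
    mirna_p: float = 0.05
    mirna_fc: float | None = None  # the DEM call has no fold-change gate
    mpv_p: float = 0.05
    use_bh: bool = False

    def __post_init__(self) -> None:
        for p in (self.gene_p, self.mirna_p, self.mpv_p):
            if not 0 < p < 1:
                raise ValueError("p thresholds must lie in (0, 1)")
        for fc in (self.gene_fc, self.mirna_fc):
            if fc is not None and fc <= 1:
                raise ValueError("fold-change thresholds must exceed 1")

    def p_threshold(self, feature_type: str) -> float:
        return self.gene_p if feature_type == "gene" else self.mirna_p

    def fc_threshold(self, feature_type: str) -> float | None:
        return self.gene_fc if feature_type == "gene" else self.mirna_fc


def _moment_dispersion(groups: list[np.ndarray]) -> np.ndarray:
    """Shrunken method-of-moments dispersion per feature (rows)."""
    n_total = sum(g.shape[1] for g in groups)
    df = n_total - len(groups)
    ss = sum(((g - g.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for g in groups)
    s2 = ss / df
    mu = np.concatenate(groups, axis=1).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_raw = np.where(mu > 0, np.maximum(0.0, (s2 - mu) / np.maximum(mu, 1e-12) ** 2), 0.0)
    expressed = mu > 0
    trend = float(np.median(phi_raw[expressed])) if expressed.any() else 0.0
    # n = replicates per group; stronger shrinkage than total-n keeps the
    # Wald test calibrated at three replicates
    n_group = n_total / len(groups)
    w = n_group / (n_group + 4)
    return w * phi_raw + (1 - w) * trend


def _wald(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised NB Wald test of rows of ``a`` vs rows of ``b``.

    Returns (log2 fold change a/b, two-sided p). All-zero features get
    log2fc 0, p 1.
    """
    phi = _moment_dispersion([a, b])
    na, nb = a.shape[1], b.shape[1]
    ma = a.mean(axis=1) + PSEUDOCOUNT
    mb = b.mean(axis=1) + PSEUDOCOUNT
    log2fc = np.log2(ma / mb)
    var_ln = (1.0 / ma + phi) / na + (1.0 / mb + phi) / nb
    z = np.log(ma / mb) / np.sqrt(var_ln)
    p = 2.0 * stats.norm.sf(np.abs(z))
    empty = (a.sum(axis=1) + b.sum(axis=1)) == 0
    log2fc[empty] = 0.0
    p[empty] = 1.0
    return log2fc, np.clip(p, 0.0, 1.0)


def _expression(cm: CountMatrix, de_input: str) -> pd.DataFrame:
    if de_input == "counts":
        return normalized_counts(cm)
    if de_input == "tpm":
        # literal reading of running the test on TPM units
        return tpm(cm)
    raise ValueError("de_input must be 'counts' or 'tpm'")


def _frame(cm: CountMatrix, contrast: str, log2fc: np.ndarray, p: np.ndarray,
           mean_a: np.ndarray, mean_b: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contrast": contrast,
            "log2fc": log2fc,
            "p_value": p,
            "adj_p": multipletests(p, method="fdr_bh")[1] if len(p) else p,
            "mean_a": mean_a,
            "mean_b": mean_b,
        },
        index=pd.Index(cm.feature_ids, name="feature_id"),
    )


def nb_test(cm: CountMatrix, group_a: str, group_b: str, de_input: str = "counts") -> pd.DataFrame:
    """Test ``group_a`` vs ``group_b`` (log2fc is first over second)."""
    for g in (group_a, group_b):
        if not cm.samples_of(g):
            raise ValueError(f"stock {g!r} absent from design")
        if len(cm.samples_of(g)) < 2:
            raise ValueError(f"stock {g!r} has fewer than 2 replicates")
    expr = _expression(cm, de_input)
    a = expr[cm.samples_of(group_a)].to_numpy()
    b = expr[cm.samples_of(group_b)].to_numpy()
    log2fc, p = _wald(a, b)
    return _frame(cm, f"{group_a}_vs_{group_b}", log2fc, p, a.mean(axis=1), b.mean(axis=1))


def mpv_test(cm: CountMatrix, de_input: str = "counts") -> pd.DataFrame:
    """Hybrid vs pseudo-mid-parent test (contrast ``HY_vs_MPV``).

    Parent replicates are paired by replicate index; unequal parental
    replicate numbers are truncated to the shorter with a warning.
    """
    for g in ("NL", "AR", "HY"):
        if not cm.samples_of(g):
            raise ValueError(f"stock {g!r} absent from design")
    expr = _expression(cm, de_input)
    nl = expr[cm.samples_of("NL")].to_numpy()
    ar = expr[cm.samples_of("AR")].to_numpy()
    hy = expr[cm.samples_of("HY")].to_numpy()
    k = min(nl.shape[1], ar.shape[1])
    if nl.shape[1] != ar.shape[1]:
        warn(f"unequal parental replicates; pairing first {k} of each")
    mpv = (nl[:, :k] + ar[:, :k]) / 2.0
    log2fc, p = _wald(hy, mpv)
    return _frame(cm, "HY_vs_MPV", log2fc, p, hy.mean(axis=1), mpv.mean(axis=1))


def call_de(res: pd.DataFrame, policy: ThresholdPolicy, feature_type: str = "gene") -> pd.DataFrame:
    """Apply the threshold policy: adds ``significant`` and ``direction``."""
    out = res.copy()
    p = out["adj_p"] if policy.use_bh else out["p_value"]
    contrast = out["contrast"].iloc[0] if len(out) else ""
    if contrast == "HY_vs_MPV":
        sig = p < policy.mpv_p
    else:
        sig = p < policy.p_threshold(feature_type)
        fc_thr = policy.fc_threshold(feature_type)
        if fc_thr is not None:
            fc = 2.0 ** out["log2fc"]
            sig &= (fc > fc_thr) | (fc < 1.0 / fc_thr)
    out["significant"] = sig
    out["direction"] = np.where(~sig, "ns", np.where(out["log2fc"] > 0, "up", "down"))
    return out


def run_contrasts(cm: CountMatrix, policy: ThresholdPolicy | None = None,
                  de_input: str = "counts") -> dict[str, pd.DataFrame]:
    """All three pairwise contrasts plus HY_vs_MPV, with calls applied."""
    policy = policy or ThresholdPolicy()
    out = {}
    for a, b in (("NL", "AR"), ("HY", "NL"), ("HY", "AR")):
        out[f"{a}_vs_{b}"] = call_de(nb_test(cm, a, b, de_input), policy, cm.feature_type)
    out["HY_vs_MPV"] = call_de(mpv_test(cm, de_input), policy, cm.feature_type)
    return out


def write_calls(res: pd.DataFrame, path) -> None:
    cols = ["contrast", "log2fc", "p_value", "adj_p", "significant", "direction"]
    res[cols].to_csv(path, sep="\t", float_format="%.6g")
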