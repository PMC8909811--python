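"""Expression normalization: TPM for reporting, median-of-ratios size factors
for the count-based differential test.

TPM divides each count by the feature length, then rescales every sample so
the column sums to 1e6; it is the descriptive unit used throughout the summary
tables. The negative-binomial test instead consumes counts divided by
per-sample size factors, computed by the median-of-ratios scheme standard in
count-based differential expression: a pseudo-reference sample is built from
per-feature geometric means over features observed in every sample, and each
sample's factor is the median ratio to that reference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CountMatrix, warn

TPM_SCALE = 1e6


def tpm(cm: CountMatrix) -> pd.DataFrame:
    """Transcripts-per-million matrix, same shape as the input counts.

    An all-zero sample yields an all-zero TPM column (with a warning) rather
    than a division error.
    """
    lengths = cm.effective_lengths().to_numpy()[:, None]
    rate = cm.counts.to_numpy(dtype=float) / lengths
    colsum = rate.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        warn(f"{int(zero.sum())} sample(s) with zero total counts; TPM set to 0")
    colsum[zero] = 1.0
    out = rate / colsum[None, :] * TPM_SCALE
    return pd.DataFrame(out, index=cm.counts.index, columns=cm.counts.columns)


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factor per sample, rescaled to geometric mean 1.

    Falls back to column-total scaling (with a warning) when no feature is
    observed in every sample.
    """
    mat = cm.counts.to_numpy(dtype=float)
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        warn("no feature nonzero in all samples; falling back to column-total scaling")
        totals = mat.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("cannot compute size factors: a sample has zero total counts")
        factors = totals
    else:
        sub = mat[allpos]
        log_ref = np.mean(np.log(sub), axis=1)
        factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.counts.columns, name="size_factor")


def normalized_counts(cm: CountMatrix) -> pd.DataFrame:
    """Counts divided by their sample size factor."""
    sf = size_factors(cm)
    return cm.counts.astype(float).div(sf, axis=1)


def write_tpm(tpm_df: pd.DataFrame, path) -> None:
    tpm_df.rename_axis("feature_id").to_csv(path, sep="\t", float_format="%.4f")
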