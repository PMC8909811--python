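"""Tabular containers and the TSV dialects shared by every stage.

All on-disk formats are plain tab-separated text:

* counts:      ``feature_id`` + one integer column per sample
* lengths:     ``feature_id``, ``length_nt``
* design:      ``sample_id``, ``stock`` (NL/AR/HY), ``replicate``
* targets:     ``mirna_id``, ``gene_id``, ``score``
* annotation:  ``gene_id``, ``pathway_id``, ``pathway_name``
* phenotypes:  ``fish_id``, ``stock``, ``day``, ``weight_g``, ``length_cm``, ``depth_cm``
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

STOCKS = ("NL", "AR", "HY")


@dataclass
class CountMatrix:
    """Feature x sample integer counts with the three-stock design attached.

    ``lengths`` (nt) are required for gene TPM; miRNA matrices may omit them,
    in which case every feature gets length 1 (mature miRNA lengths are nearly
    constant, so counts are TPM up to a scale factor).
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    lengths: pd.Series | None = None
    feature_type: str = "gene"

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        self.design = self.design.loc[list(self.counts.columns)]
        bad = set(self.design["stock"]) - set(STOCKS)
        if bad:
            raise ValueError(f"unknown stocks in design: {sorted(bad)}")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("negative counts")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integral")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.counts.index)
            if self.lengths.isna().any():
                missing = self.lengths.index[self.lengths.isna()][:5].tolist()
                raise ValueError(f"missing feature lengths, e.g. {missing}")
            if (self.lengths <= 0).any():
                raise ValueError("feature lengths must be positive")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_of(self, stock: str) -> list[str]:
        """Sample ids of one stock, ordered by replicate label."""
        sub = self.design[self.design["stock"] == stock]
        return list(sub.sort_values("replicate").index)

    def effective_lengths(self) -> pd.Series:
        if self.lengths is None:
            return pd.Series(1.0, index=self.counts.index)
        return self.lengths.astype(float)


def read_counts(
    counts_tsv: str | Path,
    design_tsv: str | Path,
    lengths_tsv: str | Path | None = None,
    feature_type: str = "gene",
) -> CountMatrix:
    counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
    design = pd.read_csv(design_tsv, sep="\t", index_col=0)
    lengths = None
    if lengths_tsv is not None:
        lengths = pd.read_csv(lengths_tsv, sep="\t", index_col=0).iloc[:, 0]
    return CountMatrix(counts=counts, design=design, lengths=lengths, feature_type=feature_type)


def write_counts(cm: CountMatrix, counts_tsv: str | Path, design_tsv: str | Path | None = None,
                 lengths_tsv: str | Path | None = None) -> None:
    cm.counts.rename_axis("feature_id").to_csv(counts_tsv, sep="\t")
    if design_tsv is not None:
        cm.design.rename_axis("sample_id").to_csv(design_tsv, sep="\t")
    if lengths_tsv is not None and cm.lengths is not None:
        cm.lengths.rename("length_nt").rename_axis("feature_id").to_csv(lengths_tsv, sep="\t")


def read_targets(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"mirna_id", "gene_id"}
    if not need <= set(df.columns):
        raise ValueError(f"target table needs columns {sorted(need)}")
    return df


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"gene_id", "pathway_id"}
    if not need <= set(df.columns):
        raise ValueError(f"annotation table needs columns {sorted(need)}")
    if "pathway_name" not in df.columns:
        df["pathway_name"] = df["pathway_id"]
    return df


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"fish_id", "stock", "day", "weight_g", "length_cm", "depth_cm"}
    if not need <= set(df.columns):
        raise ValueError(f"phenotype table needs columns {sorted(need)}")
    return df


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
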