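"""Growth-trait metrics over per-fish longitudinal measurements.

Standard aquaculture growth descriptors between an initial (0) and final (t)
measurement, t experimental days apart:

* weight gain rate        WGR  (%)     = (Wt - W0) / W0 x 100
* body length gain rate   BLGR (%)     = (Lt - L0) / L0 x 100
* body depth gain rate    BDGR (%)     = (Dt - D0) / D0 x 100
* specific growth rate    SGR  (%/day) = (ln Wt - ln W0) / t x 100
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


@dataclass
class GrowthRecord:
    fish_id: str
    stock: str
    w0: float
    wt: float
    l0: float
    lt: float
    d0: float
    dt: float
    t: float

    def __post_init__(self) -> None:
        if min(self.w0, self.wt, self.l0, self.lt, self.d0, self.dt) <= 0:
            raise ValueError("all measurements must be positive")
        if self.t <= 0:
            raise ValueError("experimental days must be positive")


def growth_metrics(rec: GrowthRecord) -> dict[str, float]:
    return {
        "WGR": (rec.wt - rec.w0) / rec.w0 * 100.0,
        "BLGR": (rec.lt - rec.l0) / rec.l0 * 100.0,
        "BDGR": (rec.dt - rec.d0) / rec.d0 * 100.0,
        "SGR": (math.log(rec.wt) - math.log(rec.w0)) / rec.t * 100.0,
    }


METRICS = ("WGR", "BLGR", "BDGR", "SGR")


def records_from_table(pheno: pd.DataFrame, from_day: int = 0,
                       to_day: int = 45) -> list[GrowthRecord]:
    """Pair each fish's measurements at two days into growth records.

    Fish missing either time point are dropped.
    """
    t = to_day - from_day
    if t <= 0:
        raise ValueError("to_day must exceed from_day")
    wide = pheno[pheno["day"].isin([from_day, to_day])].pivot_table(
        index=["fish_id", "stock"], columns="day",
        values=["weight_g", "length_cm", "depth_cm"])
    wide = wide.dropna()
    recs = []
    for (fish, stock), row in wide.iterrows():
        recs.append(GrowthRecord(
            fish_id=fish, stock=stock,
            w0=row[("weight_g", from_day)], wt=row[("weight_g", to_day)],
            l0=row[("length_cm", from_day)], lt=row[("length_cm", to_day)],
            d0=row[("depth_cm", from_day)], dt=row[("depth_cm", to_day)],
            t=t,
        ))
    return recs


def metrics_table(records: list[GrowthRecord]) -> pd.DataFrame:
    rows = [{"fish_id": r.fish_id, "stock": r.stock, **growth_metrics(r)}
            for r in records]
    return pd.DataFrame(rows, columns=["fish_id", "stock", *METRICS])


def stock_summary(records: list[GrowthRecord]) -> dict:
    """Per-stock mean +/- SD of each metric, and hybrid/parent mean ratios.

    SD is the sample standard deviation (ddof=1; 0.0 for a single fish).
    """
    tab = metrics_table(records)
    if tab.empty:
        raise ValueError("no growth records")
    out: dict = {"stocks": {}, "hybrid_ratios": {}}
    grouped = tab.groupby("stock")
    for stock, sub in grouped:
        out["stocks"][stock] = {
            m: {"mean": float(sub[m].mean()),
                "sd": float(sub[m].std(ddof=1)) if len(sub) > 1 else 0.0}
            for m in METRICS
        }
    if "HY" in out["stocks"]:
        for parent in ("NL", "AR"):
            if parent in out["stocks"]:
                out["hybrid_ratios"][f"HY_vs_{parent}"] = {
                    m: float(out["stocks"]["HY"][m]["mean"]
                             / out["stocks"][parent][m]["mean"])
                    if out["stocks"][parent][m]["mean"] != 0 else float("nan")
                    for m in METRICS
                }
    return out


def welch_comparison(records: list[GrowthRecord], metric: str = "SGR") -> pd.DataFrame:
    """Descriptive pairwise Welch t-tests between stocks (convenience only)."""
    from scipy import stats as sps

    tab = metrics_table(records)
    stocks = sorted(tab["stock"].unique())
    rows = []
    for i, a in enumerate(stocks):
        for b in stocks[i + 1:]:
            xa, xb = tab.loc[tab["stock"] == a, metric], tab.loc[tab["stock"] == b, metric]
            t, p = sps.ttest_ind(xa, xb, equal_var=False)
            rows.append({"stock_a": a, "stock_b": b, "metric": metric,
                         "t": float(t), "p_value": float(p)})
    return pd.DataFrame(rows)


def summary_frame(summary: dict) -> pd.DataFrame:
    rows = []
    for stock, metrics in summary["stocks"].items():
        row = {"stock": stock}
        for m in METRICS:
            row[f"{m}_mean"] = metrics[m]["mean"]
            row[f"{m}_sd"] = metrics[m]["sd"]
        rows.append(row)
    return pd.DataFrame(rows)
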