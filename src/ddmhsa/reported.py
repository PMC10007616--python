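"""Published per-subject detection counts and their recomputed metrics.

The package ships the per-subject TP/TN/FP/FN counts reported for the three
model variants (S1 and S2 separately, 20 subjects each, 120 rows) as a CSV
data file. The underlying clinical recordings are not publicly available,
so these counts are the anchor for verifying the metric arithmetic and the
model-level summary statistics.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .evaluation import ConfusionCounts, MetricsReport, aggregate, compute_metrics

__all__ = ["load_reported_counts", "recompute_metrics", "model_summary"]


def load_reported_counts() -> pd.DataFrame:
    """Published counts table: model, sound, subject, mean HR, TP/TN/FP/FN
    and the printed SEN/PRE/SPE/ACC columns."""
    with resources.files("ddmhsa.data").joinpath("reported_counts.csv").open() as fh:
        return pd.read_csv(fh)


def recompute_metrics(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute SEN/PRE/SPE/ACC from the counts of every row.

    Adds ``sen_calc``/``pre_calc``/``spe_calc``/``acc_calc`` columns next to
    the printed values.
    """
    if df is None:
        df = load_reported_counts()
    df = df.copy()
    calc = {k: [] for k in ("sen_calc", "pre_calc", "spe_calc", "acc_calc")}
    for row in df.itertuples():
        rep = compute_metrics(
            ConfusionCounts(tp=row.tp, tn=row.tn, fp=row.fp, fn=row.fn)
        )
        calc["sen_calc"].append(rep.sen)
        calc["pre_calc"].append(rep.pre)
        calc["spe_calc"].append(rep.spe)
        calc["acc_calc"].append(rep.acc)
    for k, v in calc.items():
        df[k] = v
    return df


def model_summary(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Mean and sample SD of the recomputed per-subject metrics, per
    (model, sound) group - the summary-row arithmetic of the published
    tables."""
    df = recompute_metrics(df)
    rows = []
    for (model, sound), grp in df.groupby(["model", "sound"], sort=False):
        reports = [
            MetricsReport(r.sen_calc, r.pre_calc, r.spe_calc, r.acc_calc)
            for r in grp.itertuples()
        ]
        mean, sd = aggregate(reports)
        rows.append(
            dict(
                model=model,
                sound=sound,
                n=len(reports),
                sen_mean=mean.sen, pre_mean=mean.pre, spe_mean=mean.spe, acc_mean=mean.acc,
                sen_sd=sd.sen, pre_sd=sd.pre, spe_sd=sd.spe, acc_sd=sd.acc,
            )
        )
    return pd.DataFrame(rows)
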