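"""Relative expression by the Livak 2^-ddCt method with replicate aggregation
and temporal trend classification over developmental stages (days after full
bloom).  Amplification efficiency is fixed at 2 (the Livak assumption)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "delta_ct",
    "ddct_fold",
    "trend_call",
    "trends_by_gene",
]

REQUIRED_COLUMNS = ("gene", "cultivar", "stage_DAFB", "replicate", "Ct")


class DataError(ValueError):
    pass


def _check_columns(records: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise DataError(f"Ct table is missing columns {missing}")
    ct = records["Ct"]
    if not np.all(np.isfinite(ct)):
        raise DataError("non-finite Ct values present")
    odd = records[(ct < 10) | (ct > 40)]
    if len(odd):
        import warnings
        warnings.warn(f"{len(odd)} Ct value(s) outside the typical 10-40 range")


def delta_ct(records: pd.DataFrame, reference_gene: str) -> pd.DataFrame:
    """dCt = Ct_target - Ct_reference, paired within each replicate.

    Returns a frame with columns gene, cultivar, stage_DAFB, replicate, dCt.
    A replicate of any (cultivar, stage) lacking the reference measurement is
    a data error naming the condition.
    """
    _check_columns(records)
    ref = records[records["gene"] == reference_gene]
    if ref.empty:
        raise DataError(f"reference gene {reference_gene!r} absent from table")
    ref_map = ref.set_index(["cultivar", "stage_DAFB", "replicate"])["Ct"]
    if ref_map.index.has_duplicates:
        ref_map = ref_map.groupby(level=[0, 1, 2]).mean()
    targets = records[records["gene"] != reference_gene].copy()
    keys = list(zip(targets["cultivar"], targets["stage_DAFB"],
                    targets["replicate"]))
    missing = sorted({k for k in keys if k not in ref_map.index})
    if missing:
        raise DataError(f"missing reference Ct for (cultivar, stage, replicate)"
                        f" conditions: {missing}")
    targets["dCt"] = targets["Ct"].to_numpy() - ref_map.loc[keys].to_numpy()
    return targets[["gene", "cultivar", "stage_DAFB", "replicate", "dCt"]]


def ddct_fold(dct: pd.DataFrame,
              calibrator_stage: Optional[int] = None) -> pd.DataFrame:
    """Fold change 2^-ddCt per (gene, cultivar, stage) vs the calibrator.

    The calibrator is the first (smallest) stage within each (gene, cultivar)
    unless ``calibrator_stage`` is given.  The standard error of the fold is
    obtained by the delta method from the replicate SD of dCt; a fold range
    [2^-(ddCt+SE), 2^-(ddCt-SE)] is reported alongside.
    """
    rows: List[dict] = []
    for (gene, cultivar), sub in dct.groupby(["gene", "cultivar"], sort=True):
        stages = sorted(sub["stage_DAFB"].unique())
        cal = calibrator_stage if calibrator_stage is not None else stages[0]
        cal_vals = sub.loc[sub["stage_DAFB"] == cal, "dCt"].to_numpy()
        if cal_vals.size == 0:
            raise DataError(f"calibrator stage {cal} absent for "
                            f"({gene}, {cultivar})")
        cal_mean = cal_vals.mean()
        cal_se2 = (cal_vals.var(ddof=1) / cal_vals.size
                   if cal_vals.size > 1 else 0.0)
        for stage in stages:
            vals = sub.loc[sub["stage_DAFB"] == stage, "dCt"].to_numpy()
            mean = vals.mean()
            se2 = vals.var(ddof=1) / vals.size if vals.size > 1 else 0.0
            if stage == cal:
                ddct, se = 0.0, float(np.sqrt(2 * cal_se2))
            else:
                ddct = float(mean - cal_mean)
                se = float(np.sqrt(se2 + cal_se2))
            fold = float(2.0 ** (-ddct))
            rows.append({
                "gene": gene, "cultivar": cultivar, "stage_DAFB": int(stage),
                "dCt_mean": float(mean), "ddCt": ddct, "fold": fold,
                "fold_se": float(np.log(2.0) * fold * se),
                "fold_lo": float(2.0 ** (-(ddct + se))),
                "fold_hi": float(2.0 ** (-(ddct - se))),
            })
    return pd.DataFrame(rows)


def trend_call(folds: Sequence[float], tolerance: float = 0.05) -> str:
    """Classify a fold series over >= 3 stages as decreasing / increasing /
    none.  Decreasing: every successive ratio <= 1+tolerance and last/first
    < 1; increasing symmetrically; anything else is "none"."""
    folds = [float(f) for f in folds]
    if len(folds) < 3:
        raise ValueError("need >= 3 stages for a trend call")
    ratios = [b / a for a, b in zip(folds, folds[1:])]
    if all(r <= 1.0 + tolerance for r in ratios) and folds[-1] / folds[0] < 1:
        return "decreasing"
    if all(r >= 1.0 / (1.0 + tolerance) for r in ratios) and folds[-1] / folds[0] > 1:
        return "increasing"
    return "none"


def trends_by_gene(results: pd.DataFrame,
                   tolerance: float = 0.05) -> pd.DataFrame:
    """Per (gene, cultivar) trend call from the stage-ordered fold series."""
    rows = []
    for (gene, cultivar), sub in results.groupby(["gene", "cultivar"],
                                                 sort=True):
        sub = sub.sort_values("stage_DAFB")
        rows.append({"gene": gene, "cultivar": cultivar,
                     "trend": trend_call(sub["fold"].tolist(), tolerance)})
    return pd.DataFrame(rows)
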