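"""Percentile scoring, quartile binning and binary state flags.

A sample's ratio is placed on its LH day's fitted reference CDF; the
percentile rank is 100 x F(ratio).  Quartile bins are [0,25) -> Q1,
[25,50) -> Q2, [50,75) -> Q3, [75,100] -> Q4.  The binary states follow the
printed strict inequalities: *stalled* decidual reaction means a stromal
percentile strictly below 25, *heightened* strictly above 75, and likewise
*suboptimal* / *strong* uNK expansion for the uNK percentile.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .calibrate import CalibrationError, ReferenceModel, compute_ratios
from .io import HORMONES, RATIOS

logger = logging.getLogger("endoscore")

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")

SCORE_COLUMNS = [
    "sample_id", "subject_id", "cycle_index", "lh_day",
    "stromal_percentile", "unk_percentile",
    "stromal_quartile", "unk_quartile",
    "stalled", "heightened", "suboptimal_unk", "strong_unk",
]


class ScoringError(ValueError):
    pass


def ratio_percentile(ratio: float | np.ndarray, lh_day: int,
                     model: ReferenceModel, ratio_name: str) -> float | np.ndarray:
    """Percentile rank of a ratio on its day's selected reference CDF."""
    lo, hi = model.day_range
    if not lo <= lh_day <= hi:
        raise CalibrationError(f"LH+{lh_day} outside calibrated range {lo}..{hi}")
    arr = np.asarray(ratio, dtype=float)
    if (arr <= 0).any():
        raise ScoringError("ratio must be strictly positive")
    pct = 100.0 * model.ratio_fit(ratio_name, lh_day).cdf(arr)
    return float(pct) if arr.ndim == 0 else pct


def analyte_percentile(value: float | np.ndarray, lh_day: int,
                       model: ReferenceModel, analyte: str) -> float | np.ndarray:
    """Percentile of an analyte level: 100 x Phi((log10 v − mu)/sigma)."""
    lo, hi = model.day_range
    if not lo <= lh_day <= hi:
        raise CalibrationError(f"LH+{lh_day} outside calibrated range {lo}..{hi}")
    arr = np.asarray(value, dtype=float)
    if (arr <= 0).any():
        raise ScoringError("analyte value must be strictly positive")
    fit = model.analyte_fit(analyte, lh_day)
    z = (np.log10(arr) - fit.log_mean) / fit.log_sd
    pct = 100.0 * stats.norm.cdf(z)
    return float(pct) if arr.ndim == 0 else pct


def assign_quartile(percentile: float | np.ndarray) -> tuple:
    """Quartile label plus (lower-tail, upper-tail) strict-inequality flags.

    Returns ``(quartile, below_25, above_75)``; vectorized over arrays.
    """
    arr = np.asarray(percentile, dtype=float)
    if ((arr < 0) | (arr > 100)).any() or np.isnan(arr).any():
        raise ScoringError("percentile must lie in [0, 100]")
    idx = np.minimum((arr // 25).astype(int), 3)
    below = arr < 25.0
    above = arr > 75.0
    if arr.ndim == 0:
        return QUARTILE_LABELS[int(idx)], bool(below), bool(above)
    return np.asarray(QUARTILE_LABELS, dtype=object)[idx], below, above


def score_cohort(cohort: pd.DataFrame, model: ReferenceModel,
                 include_analytes: bool = False
                 ) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Score every usable sample of a cohort against a reference model.

    Returns ``(scores, skip_log)``: one row per usable sample, and
    ``(sample_id, reason)`` entries for samples skipped because of
    zero/missing copy numbers or an LH day outside the calibrated range.
    Duplicate sample identifiers are a hard error.
    """
    if cohort["sample_id"].duplicated().any():
        dupes = cohort["sample_id"][cohort["sample_id"].duplicated()].unique()
        raise ScoringError(f"duplicate sample_id values: {list(dupes)[:5]}")

    lo, hi = model.day_range
    lh_day = pd.to_numeric(cohort["lh_day"], errors="coerce")
    ratios = compute_ratios(cohort)
    skip_log: list[tuple[str, str]] = []

    in_range = lh_day.between(lo, hi)
    usable = in_range & ratios["stromal"].notna() & ratios["unk"].notna()
    for i in cohort.index[~usable]:
        if not in_range.loc[i]:
            reason = f"lh_day {cohort.loc[i, 'lh_day']} outside calibrated range"
        else:
            bad = [name for name in RATIOS if pd.isna(ratios.loc[i, name])]
            reason = f"zero/missing copies for ratio(s): {', '.join(bad)}"
        skip_log.append((str(cohort.loc[i, "sample_id"]), reason))
    if skip_log:
        logger.warning("score_cohort: %d samples skipped", len(skip_log))

    sub = cohort[usable]
    day = lh_day[usable].astype(int).to_numpy()
    out = sub[["sample_id", "subject_id", "cycle_index", "lh_day"]].copy()
    pct = {}
    for name in RATIOS:
        vals = ratios.loc[usable, name].to_numpy()
        col = np.empty(len(sub))
        for d in range(lo, hi + 1):
            mask = day == d
            if mask.any():
                col[mask] = ratio_percentile(vals[mask], d, model, name)
        pct[name] = col
    out["stromal_percentile"] = pct["stromal"]
    out["unk_percentile"] = pct["unk"]
    q_s, stalled, heightened = assign_quartile(pct["stromal"])
    q_u, subopt, strong = assign_quartile(pct["unk"])
    out["stromal_quartile"] = q_s
    out["unk_quartile"] = q_u
    out["stalled"] = stalled
    out["heightened"] = heightened
    out["suboptimal_unk"] = subopt
    out["strong_unk"] = strong

    if include_analytes:
        for h in HORMONES:
            if h not in sub.columns:
                continue
            vals = pd.to_numeric(sub[h], errors="coerce").to_numpy()
            col = np.full(len(sub), np.nan)
            for d in range(lo, hi + 1):
                mask = (day == d) & np.isfinite(vals) & (vals > 0)
                if mask.any() and (h, d) in model.analyte_fits:
                    col[mask] = analyte_percentile(vals[mask], d, model, h)
            out[f"{h}_percentile"] = col

    # clinical covariates ride along for downstream association analyses
    for col in ("prior_losses", "outcome", "karyotype"):
        if col in sub.columns:
            out[col] = sub[col]
    return out.reset_index(drop=True), skip_log
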