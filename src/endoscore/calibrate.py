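"""Day-indexed reference model for marker ratios and analyte levels.

For every LH day the two marker ratios are fitted by maximum likelihood to a
gamma and to a log-normal distribution, and the family with the smaller
Cramér–von Mises W² statistic is retained; gene copy numbers and hormone
levels are fitted as normal distributions of their log10 values.  Percentile
scoring downstream evaluates the selected family's CDF only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .io import HORMONES, MARKER_GENES, RATIOS, provenance

logger = logging.getLogger("endoscore")

MODEL_SCHEMA_VERSION = "1"


class CalibrationError(ValueError):
    pass


class DegenerateDataError(CalibrationError):
    """All-equal (zero-variance) input where a spread is required."""


def log_transform_copies(copies: float | np.ndarray) -> float | np.ndarray:
    """log10 of ddPCR copy numbers; zero or negative input is rejected."""
    arr = np.asarray(copies, dtype=float)
    if (arr <= 0).any():
        raise CalibrationError("copy numbers must be strictly positive for log10")
    out = np.log10(arr)
    return float(out) if np.isscalar(copies) or arr.ndim == 0 else out


def cvm_statistic(values: np.ndarray, cdf: Callable[[np.ndarray], np.ndarray]) -> float:
    """Cramér–von Mises W² of ``values`` against a candidate CDF.

    W² = 1/(12n) + sum_i (F(x_(i)) − (2i−1)/(2n))², the minimum 1/(12n) being
    attained exactly when F hits the plotting positions.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n == 0:
        raise CalibrationError("cvm_statistic requires at least one value")
    f = np.asarray(cdf(x), dtype=float)
    plotting = (2 * np.arange(1, n + 1) - 1) / (2 * n)
    return float(1.0 / (12 * n) + np.sum((f - plotting) ** 2))


@dataclasses.dataclass
class RatioFit:
    """Fitted reference distribution of one ratio on one LH day."""

    lh_day: int
    family: str  # "gamma" | "lognormal"
    params: dict[str, float]
    cvm_gamma: float
    cvm_lognormal: float
    n: int

    def frozen(self) -> stats.rv_continuous:
        if self.family == "gamma":
            return stats.gamma(a=self.params["shape"], scale=self.params["scale"])
        return stats.lognorm(s=self.params["log_sd"],
                             scale=np.exp(self.params["log_mean"]))

    def cdf(self, x: np.ndarray) -> np.ndarray:
        return self.frozen().cdf(x)


@dataclasses.dataclass
class AnalyteFit:
    """Normal fit of log10 analyte levels (gene copies or hormones) per day."""

    lh_day: int
    analyte: str
    log_mean: float
    log_sd: float
    n: int


def fit_ratio_reference(ratios: np.ndarray, lh_day: int,
                        min_n: int = 20) -> RatioFit:
    """Fit gamma and log-normal by ML and keep the smaller-W² family.

    Both candidate CDFs are evaluated on the raw ratio scale so the two W²
    values are directly comparable; ties break toward log-normal (the ratio
    of two log-scaled quantities).
    """
    x = np.asarray(ratios, dtype=float)
    if len(x) < min_n:
        raise CalibrationError(
            f"LH+{lh_day}: {len(x)} ratios < required minimum {min_n}"
        )
    if (x <= 0).any():
        raise CalibrationError(f"LH+{lh_day}: non-positive ratio in calibration data")
    logs = np.log(x)
    log_mean, log_sd = float(logs.mean()), float(logs.std(ddof=0))
    if log_sd < 1e-6:
        raise DegenerateDataError(f"LH+{lh_day}: ratios have no spread")
    shape, _, scale = stats.gamma.fit(x, floc=0)
    gamma_frozen = stats.gamma(a=shape, scale=scale)
    lognorm_frozen = stats.lognorm(s=log_sd, scale=np.exp(log_mean))
    w2_gamma = cvm_statistic(x, gamma_frozen.cdf)
    w2_lognorm = cvm_statistic(x, lognorm_frozen.cdf)
    if w2_lognorm <= w2_gamma:
        family, params = "lognormal", {"log_mean": log_mean, "log_sd": log_sd}
    else:
        family, params = "gamma", {"shape": float(shape), "scale": float(scale)}
    return RatioFit(lh_day=lh_day, family=family, params=params,
                    cvm_gamma=w2_gamma, cvm_lognormal=w2_lognorm, n=len(x))


def fit_analyte_reference(values: np.ndarray, analyte: str, lh_day: int,
                          min_n: int = 20) -> AnalyteFit:
    """ML normal fit (1/n variance) of log10 values."""
    x = np.asarray(values, dtype=float)
    if len(x) < min_n:
        raise CalibrationError(
            f"{analyte} LH+{lh_day}: {len(x)} values < required minimum {min_n}"
        )
    logs = log_transform_copies(x)
    log_mean, log_sd = float(np.mean(logs)), float(np.std(logs, ddof=0))
    if log_sd < 1e-6:
        raise DegenerateDataError(f"{analyte} LH+{lh_day}: values have no spread")
    return AnalyteFit(lh_day=lh_day, analyte=analyte, log_mean=log_mean,
                      log_sd=log_sd, n=len(x))


@dataclasses.dataclass
class ReferenceModel:
    """Per-LH-day reference distributions; the unit downstream scoring uses.

    ``ratio_fits`` maps (ratio_name, lh_day) to a :class:`RatioFit`;
    ``analyte_fits`` maps (analyte, lh_day) to an :class:`AnalyteFit`.
    Serialization round-trips to full float precision.
    """

    day_range: tuple[int, int]
    ratio_fits: dict[tuple[str, int], RatioFit]
    analyte_fits: dict[tuple[str, int], AnalyteFit]
    version: str = MODEL_SCHEMA_VERSION
    quartile_edges: tuple[float, float, float] = (25.0, 50.0, 75.0)

    def days(self) -> range:
        return range(self.day_range[0], self.day_range[1] + 1)

    def ratio_fit(self, ratio: str, lh_day: int) -> RatioFit:
        try:
            return self.ratio_fits[(ratio, int(lh_day))]
        except KeyError:
            raise CalibrationError(
                f"no reference fit for ratio {ratio!r} at LH+{lh_day}"
            ) from None

    def analyte_fit(self, analyte: str, lh_day: int) -> AnalyteFit:
        try:
            return self.analyte_fits[(analyte, int(lh_day))]
        except KeyError:
            raise CalibrationError(
                f"no reference fit for analyte {analyte!r} at LH+{lh_day}"
            ) from None

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            **provenance(),
            "schema_version": self.version,
            "day_range": list(self.day_range),
            "quartile_edges": list(self.quartile_edges),
            "ratio_fits": {
                f"{name}@{day}": dataclasses.asdict(fit)
                for (name, day), fit in sorted(self.ratio_fits.items())
            },
            "analyte_fits": {
                f"{name}@{day}": dataclasses.asdict(fit)
                for (name, day), fit in sorted(self.analyte_fits.items())
            },
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, raw: dict) -> "ReferenceModel":
        if raw.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise CalibrationError(
                f"unsupported model schema version: {raw.get('schema_version')!r}"
            )
        ratio_fits = {}
        for key, fit in raw["ratio_fits"].items():
            name, day = key.rsplit("@", 1)
            ratio_fits[(name, int(day))] = RatioFit(**fit)
        analyte_fits = {}
        for key, fit in raw["analyte_fits"].items():
            name, day = key.rsplit("@", 1)
            analyte_fits[(name, int(day))] = AnalyteFit(**fit)
        return cls(
            day_range=tuple(raw["day_range"]),
            ratio_fits=ratio_fits,
            analyte_fits=analyte_fits,
            quartile_edges=tuple(raw["quartile_edges"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def compute_ratios(cohort: pd.DataFrame) -> pd.DataFrame:
    """Raw marker ratios per sample; zero/missing copies give NaN."""
    out = pd.DataFrame(index=cohort.index)
    for name, (num, den) in RATIOS.items():
        numer = pd.to_numeric(cohort[f"copies_{num}"], errors="coerce")
        denom = pd.to_numeric(cohort[f"copies_{den}"], errors="coerce")
        ratio = numer / denom
        ratio[(numer <= 0) | (denom <= 0)] = np.nan
        out[name] = ratio
    return out


def build_reference_model(cohort: pd.DataFrame, day_range: tuple[int, int] = (6, 10),
                          min_n: int = 20, pool_adjacent: bool = False,
                          fit_hormones: bool = True) -> ReferenceModel:
    """Calibrate the full per-day reference model from a cohort table.

    Samples with a zero or missing copy number are excluded from that ratio's
    calibration with a logged warning.  A day with fewer than ``min_n``
    usable samples is an error unless ``pool_adjacent`` merges it with its
    nearest day that has data.
    """
    days = list(range(day_range[0], day_range[1] + 1))
    lh_day = pd.to_numeric(cohort["lh_day"], errors="coerce")
    ratios = compute_ratios(cohort)

    missing_days = [d for d in days if (lh_day == d).sum() == 0]
    if missing_days:
        raise CalibrationError(
            f"cohort has no samples for LH days {missing_days} "
            f"within configured day_range {list(day_range)}"
        )

    def pooled_values(series: pd.Series, day: int) -> tuple[np.ndarray, int]:
        vals = series[(lh_day == day) & series.notna() & (series > 0)].to_numpy()
        if len(vals) >= min_n or not pool_adjacent:
            return vals, day
        for offset in (1, -1, 2, -2, 3, -3, 4, -4):
            nb = day + offset
            if nb in days:
                extra = series[(lh_day == nb) & series.notna() & (series > 0)]
                merged = np.concatenate([vals, extra.to_numpy()])
                if len(merged) >= min_n:
                    logger.warning(
                        "LH+%d sparse (n=%d); pooled with LH+%d", day, len(vals), nb
                    )
                    return merged, day
        return vals, day

    ratio_fits: dict[tuple[str, int], RatioFit] = {}
    for name in RATIOS:
        n_excluded = int(((lh_day.isin(days)) & ratios[name].isna()).sum())
        if n_excluded:
            logger.warning(
                "ratio %s: %d samples excluded (zero/missing copies)",
                name, n_excluded,
            )
        for day in days:
            vals, _ = pooled_values(ratios[name], day)
            ratio_fits[(name, day)] = fit_ratio_reference(vals, day, min_n=min_n)
            logger.info(
                "LH+%d %s: n=%d family=%s", day, name, len(vals),
                ratio_fits[(name, day)].family,
            )

    analyte_fits: dict[tuple[str, int], AnalyteFit] = {}
    analytes = [f"copies_{g}" for g in MARKER_GENES]
    if fit_hormones:
        analytes += [h for h in HORMONES if h in cohort.columns]
    for col in analytes:
        name = col.removeprefix("copies_")
        series = pd.to_numeric(cohort[col], errors="coerce")
        for day in days:
            vals, _ = pooled_values(series, day)
            if len(vals) < min_n:
                logger.warning("analyte %s LH+%d: n=%d < %d, fit skipped",
                               name, day, len(vals), min_n)
                continue
            analyte_fits[(name, day)] = fit_analyte_reference(
                vals, name, day, min_n=min_n
            )

    return ReferenceModel(day_range=tuple(day_range), ratio_fits=ratio_fits,
                          analyte_fits=analyte_fits)
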