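"""Synthetic endometrial cohort generator.

Emulates the statistical structure the downstream analytics assume: per-LH-day
gamma or log-normal marker-ratio distributions, Gaussian-copula dependence
between the stromal and uNK traits within a sample (latent correlation 0.377,
giving a rank correlation of ~0.36), Gaussian-copula persistence of the
stromal trait between a subject's two cycles (latent correlation 0.62, giving
a ~55% recurrence of the lowest-quartile state), and pregnancy outcomes drawn
conditionally on a quartile exposure flag with a configurable fraction of
aneuploid losses.

The latent construction: a sample's pair (z_s, z_u) is bivariate standard
normal with correlation ``rho_cross``; u = Phi(z) is uniform, and the ratio is
the inverse CDF of that LH day's configured family at u.  Denominator-gene
copies are drawn log-normally and the numerator is defined as ratio x
denominator, so the ratio is exact by construction.  In paired cohorts the two
cycle-specific stromal latents are bivariate normal with correlation
``rho_cycle`` while the uNK latents are redrawn independently each cycle
(the first biopsy's uNK state carries no information about the second's).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .io import COHORT_COLUMNS, HORMONES

DAY_RANGE = (6, 10)
DAYS = tuple(range(DAY_RANGE[0], DAY_RANGE[1] + 1))

FLAG_NAMES = ("stalled", "heightened", "suboptimal_unk", "strong_unk")
#: (which latent trait, lower-tail flag?) for each exposure flag
_FLAG_DEF = {
    "stalled": ("stromal", True),
    "heightened": ("stromal", False),
    "suboptimal_unk": ("unk", True),
    "strong_unk": ("unk", False),
}


class SimulationError(ValueError):
    pass


@dataclasses.dataclass
class RatioSpec:
    """Distribution of one marker ratio on one LH day.

    ``family`` is ``gamma`` (shape/scale) or ``lognormal`` (natural-log
    mean / sd of the ratio).
    """

    family: Literal["gamma", "lognormal"]
    shape: float | None = None
    scale: float | None = None
    log_mean: float | None = None
    log_sd: float | None = None

    def validate(self) -> None:
        if self.family == "gamma":
            if self.shape is None or self.scale is None:
                raise SimulationError("gamma spec needs shape and scale")
            if self.shape <= 0 or self.scale <= 0:
                raise SimulationError("gamma shape and scale must be positive")
        elif self.family == "lognormal":
            if self.log_mean is None or self.log_sd is None:
                raise SimulationError("lognormal spec needs log_mean and log_sd")
            if self.log_sd <= 0:
                raise SimulationError("lognormal log_sd must be positive")
        else:
            raise SimulationError(f"unknown ratio family: {self.family!r}")

    def frozen(self) -> stats.rv_continuous:
        if self.family == "gamma":
            return stats.gamma(a=self.shape, scale=self.scale)
        return stats.lognorm(s=self.log_sd, scale=np.exp(self.log_mean))


@dataclasses.dataclass
class GeneSpec:
    """log10-copy-number distribution of a denominator gene on one LH day."""

    log10_mean: float
    log10_sd: float

    def validate(self) -> None:
        if self.log10_sd <= 0:
            raise SimulationError("gene log10_sd must be positive")


@dataclasses.dataclass
class OutcomeModel:
    """Flag-conditional pregnancy outcome probabilities.

    ``exposure_flag`` names the quartile state that defines the exposed arm;
    live-birth probabilities are per arm, and among miscarriages a fraction is
    karyotyped aneuploid (the rest split between euploid and unknown).
    """

    exposure_flag: str = "stalled"
    p_live_exposed: float = 0.438
    p_live_unexposed: float = 0.600
    aneuploid_fraction: float = 0.30
    karyotyped_euploid_fraction: float = 0.25

    def validate(self) -> None:
        if self.exposure_flag not in _FLAG_DEF:
            raise SimulationError(f"unknown exposure flag: {self.exposure_flag!r}")
        probs = (
            self.p_live_exposed,
            self.p_live_unexposed,
            self.aneuploid_fraction,
            self.karyotyped_euploid_fraction,
        )
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise SimulationError("outcome probabilities must lie in [0, 1]")
        if self.aneuploid_fraction + self.karyotyped_euploid_fraction > 1.0:
            raise SimulationError("karyotype fractions exceed 1")


def _default_ratio_specs() -> dict[int, dict[str, RatioSpec]]:
    # The decidual reaction strengthens across the implantation window, so the
    # stromal ratio drifts upward with LH day; uNK expansion likewise.  Both
    # families appear so calibration exercises the model selection.
    return {
        6: {
            "stromal": RatioSpec("lognormal", log_mean=-0.50, log_sd=0.80),
            "unk": RatioSpec("gamma", shape=1.5, scale=0.50),
        },
        7: {
            "stromal": RatioSpec("lognormal", log_mean=0.00, log_sd=0.80),
            "unk": RatioSpec("lognormal", log_mean=-0.20, log_sd=0.70),
        },
        8: {
            "stromal": RatioSpec("gamma", shape=2.5, scale=0.80),
            "unk": RatioSpec("gamma", shape=2.2, scale=0.60),
        },
        9: {
            "stromal": RatioSpec("gamma", shape=3.0, scale=1.00),
            "unk": RatioSpec("lognormal", log_mean=0.50, log_sd=0.60),
        },
        10: {
            "stromal": RatioSpec("lognormal", log_mean=1.00, log_sd=0.70),
            "unk": RatioSpec("gamma", shape=3.5, scale=0.50),
        },
    }


def _default_gene_specs() -> dict[int, dict[str, GeneSpec]]:
    # ddPCR copies of the denominator genes; DIO2 falls as the window
    # progresses (progesterone represses it), CD160 is roughly stable.
    out: dict[int, dict[str, GeneSpec]] = {}
    for day in DAYS:
        out[day] = {
            "stromal": GeneSpec(log10_mean=3.2 - 0.1 * (day - 6), log10_sd=0.35),
            "unk": GeneSpec(log10_mean=2.5, log10_sd=0.35),
        }
    return out


def _default_hormone_specs() -> dict[int, dict[str, GeneSpec]]:
    # Circulating levels on a log10 scale: progesterone peaks midluteally,
    # estradiol shows a shallow secondary rise, TSH is day-independent.
    out: dict[int, dict[str, GeneSpec]] = {}
    for day in DAYS:
        out[day] = {
            "progesterone": GeneSpec(
                log10_mean=1.55 + 0.03 * (8 - abs(day - 8)), log10_sd=0.15
            ),
            "estradiol": GeneSpec(log10_mean=2.65 + 0.01 * (day - 6), log10_sd=0.12),
            "tsh": GeneSpec(log10_mean=0.20, log10_sd=0.18),
        }
    return out


@dataclasses.dataclass
class SimulationParams:
    """Full generator configuration; defaults are the study conditions."""

    n_samples: int = 779
    lh_day_weights: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    ratio_specs: dict[int, dict[str, RatioSpec]] = dataclasses.field(
        default_factory=_default_ratio_specs
    )
    gene_specs: dict[int, dict[str, GeneSpec]] = dataclasses.field(
        default_factory=_default_gene_specs
    )
    hormone_specs: dict[int, dict[str, GeneSpec]] = dataclasses.field(
        default_factory=_default_hormone_specs
    )
    rho_cross: float = 0.377
    rho_cycle: float = 0.62
    #: P(0, 1, 2, 3, >=4 prior losses) — a recurrent-miscarriage-clinic mix
    prior_loss_probs: tuple[float, ...] = (0.15, 0.20, 0.25, 0.20, 0.20)
    #: optional logistic link: log-odds shift of being in a higher loss
    #: category per unit decrease of the latent stromal trait (0 = independent)
    prior_loss_beta: float = 0.0
    outcome_model: OutcomeModel = dataclasses.field(default_factory=OutcomeModel)
    #: optional user-supplied 4x4 row-stochastic quartile transition matrix for
    #: asymmetric intercycle dependence (rows: first-cycle stromal quartile).
    quartile_transition: np.ndarray | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise SimulationError("n_samples must be positive")
        for name, vec in (
            ("lh_day_weights", self.lh_day_weights),
            ("prior_loss_probs", self.prior_loss_probs),
        ):
            arr = np.asarray(vec, dtype=float)
            if (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-12:
                raise SimulationError(f"{name} must be non-negative and sum to 1")
        if len(self.lh_day_weights) != len(DAYS):
            raise SimulationError("lh_day_weights must cover days 6..10")
        for rho in (self.rho_cross, self.rho_cycle):
            if not -1.0 <= rho <= 1.0:
                raise SimulationError("correlations must lie in [-1, 1]")
        for day in DAYS:
            for spec in self.ratio_specs[day].values():
                spec.validate()
            for spec in self.gene_specs[day].values():
                spec.validate()
            for spec in self.hormone_specs.get(day, {}).values():
                spec.validate()
        self.outcome_model.validate()
        if self.quartile_transition is not None:
            qt = np.asarray(self.quartile_transition, dtype=float)
            if qt.shape != (4, 4) or (qt < 0).any():
                raise SimulationError("quartile_transition must be 4x4 non-negative")
            if not np.allclose(qt.sum(axis=1), 1.0, atol=1e-12):
                raise SimulationError("quartile_transition rows must sum to 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationParams":
        with open(path) as fh:
            raw = json.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationParams":
        params = cls()
        for key in ("n_samples", "rho_cross", "rho_cycle", "prior_loss_beta", "seed"):
            if key in raw:
                setattr(params, key, raw[key])
        for key in ("lh_day_weights", "prior_loss_probs"):
            if key in raw:
                setattr(params, key, tuple(raw[key]))
        if "ratio_specs" in raw:
            params.ratio_specs = {
                int(day): {name: RatioSpec(**spec) for name, spec in specs.items()}
                for day, specs in raw["ratio_specs"].items()
            }
        if "outcome_model" in raw:
            params.outcome_model = OutcomeModel(**raw["outcome_model"])
        if raw.get("quartile_transition") is not None:
            params.quartile_transition = np.asarray(raw["quartile_transition"], float)
        params.validate()
        return params


# --------------------------------------------------------------------------
# Latent-to-observed conversion


def _ratio_from_latent(z: np.ndarray, days: np.ndarray, ratio: str,
                       params: SimulationParams) -> np.ndarray:
    """Map standard-normal latents to ratios via each day's inverse CDF."""
    u = stats.norm.cdf(z)
    out = np.empty_like(u)
    for day in DAYS:
        mask = days == day
        if mask.any():
            out[mask] = params.ratio_specs[day][ratio].frozen().ppf(u[mask])
    return out


def _assemble(params: SimulationParams, rng: np.random.Generator,
              subject_ids: np.ndarray, cycle_index: np.ndarray, days: np.ndarray,
              z_stromal: np.ndarray, z_unk: np.ndarray,
              prior_losses: np.ndarray) -> pd.DataFrame:
    """Build the cohort frame from latent traits (ratio exact by construction)."""
    n = len(days)
    stromal = _ratio_from_latent(z_stromal, days, "stromal", params)
    unk = _ratio_from_latent(z_unk, days, "unk", params)
    denom_s = np.empty(n)
    denom_u = np.empty(n)
    hormones = {h: np.empty(n) for h in HORMONES}
    for day in DAYS:
        mask = days == day
        if not mask.any():
            continue
        m = int(mask.sum())
        gs = params.gene_specs[day]
        denom_s[mask] = 10 ** rng.normal(gs["stromal"].log10_mean,
                                         gs["stromal"].log10_sd, m)
        denom_u[mask] = 10 ** rng.normal(gs["unk"].log10_mean,
                                         gs["unk"].log10_sd, m)
        hs = params.hormone_specs.get(day, {})
        for h in HORMONES:
            if h in hs:
                hormones[h][mask] = 10 ** rng.normal(hs[h].log10_mean,
                                                     hs[h].log10_sd, m)
            else:
                hormones[h][mask] = np.nan
    df = pd.DataFrame(
        {
            "sample_id": [f"{s}-c{c}" for s, c in zip(subject_ids, cycle_index)],
            "subject_id": subject_ids,
            "cycle_index": cycle_index,
            "lh_day": days,
            "copies_pla2g2a": stromal * denom_s,
            "copies_dio2": denom_s,
            "copies_itgad": unk * denom_u,
            "copies_cd160": denom_u,
            "prior_losses": prior_losses,
            "outcome": "none",
            "karyotype": "unknown",
        }
    )
    for h in HORMONES:
        df[h] = hormones[h]
    return df[COHORT_COLUMNS]


def _draw_days(params: SimulationParams, rng: np.random.Generator,
               n: int) -> np.ndarray:
    return rng.choice(DAYS, size=n, p=np.asarray(params.lh_day_weights, float))


def _draw_prior_losses(params: SimulationParams, rng: np.random.Generator,
                       z_stromal: np.ndarray) -> np.ndarray:
    """Prior-loss category 0..4 (4 = four or more losses).

    With ``prior_loss_beta`` > 0 a proportional-odds tilt makes low latent
    stromal traits more likely in higher loss categories.
    """
    n = len(z_stromal)
    base = np.asarray(params.prior_loss_probs, float)
    if params.prior_loss_beta == 0.0:
        return rng.choice(len(base), size=n, p=base)
    # proportional-odds tilt of the categorical distribution per sample
    k = np.arange(len(base))
    logits = np.log(base)[None, :] + params.prior_loss_beta * (
        -z_stromal[:, None]
    ) * k[None, :]
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(n)
    return (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)


def _bivariate_normal(rng: np.random.Generator, rho: float,
                      n: int) -> tuple[np.ndarray, np.ndarray]:
    z1 = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * eps
    return z1, z2


# --------------------------------------------------------------------------
# Public generators


def simulate_reference_cohort(params: SimulationParams,
                              n: int | None = None) -> pd.DataFrame:
    """One biopsy per subject: the calibration cohort.

    Deterministic given ``params.seed``.
    """
    params.validate()
    n = params.n_samples if n is None else int(n)
    rng = np.random.default_rng(params.seed)
    days = _draw_days(params, rng, n)
    z_s, z_u = _bivariate_normal(rng, params.rho_cross, n)
    losses = _draw_prior_losses(params, rng, z_s)
    subjects = np.array([f"S{i:06d}" for i in range(n)])
    cycles = np.ones(n, dtype=int)
    return _assemble(params, rng, subjects, cycles, days, z_s, z_u, losses)


def simulate_paired_cohort(params: SimulationParams, n_pairs: int) -> pd.DataFrame:
    """Two biopsies per subject in different cycles.

    The two cycle-specific stromal latents share correlation ``rho_cycle``
    (or, if ``quartile_transition`` is set, the second cycle's stromal
    quartile is drawn from the supplied transition matrix and the latent is
    resampled uniformly within that quartile).  uNK latents are drawn
    independently for every cycle.
    """
    params.validate()
    if n_pairs < 1:
        raise SimulationError("n_pairs must be at least 1")
    rng = np.random.default_rng(params.seed)
    z_s1 = rng.standard_normal(n_pairs)
    if params.quartile_transition is not None:
        q1 = np.clip((stats.norm.cdf(z_s1) * 4).astype(int), 0, 3)
        rows = np.asarray(params.quartile_transition, float)[q1]
        u = rng.random(n_pairs)
        q2 = (rows.cumsum(axis=1) < u[:, None]).sum(axis=1)
        # resample the latent uniformly within the drawn quartile
        u2 = (q2 + rng.random(n_pairs)) / 4.0
        z_s2 = stats.norm.ppf(u2)
    else:
        eps = rng.standard_normal(n_pairs)
        rho = params.rho_cycle
        z_s2 = rho * z_s1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * eps
    # uNK latents are fully independent per cycle: coupling them to the
    # persistent stromal trait would induce an indirect intercycle uNK
    # correlation, contradicting the observed lack of uNK persistence
    z_u1 = rng.standard_normal(n_pairs)
    z_u2 = rng.standard_normal(n_pairs)
    losses = _draw_prior_losses(params, rng, z_s1)

    subjects = np.array([f"P{i:06d}" for i in range(n_pairs)])
    frames = []
    for cycle, (zs, zu) in enumerate(((z_s1, z_u1), (z_s2, z_u2)), start=1):
        days = _draw_days(params, rng, n_pairs)
        cycles = np.full(n_pairs, cycle, dtype=int)
        frames.append(
            _assemble(params, rng, subjects, cycles, days, zs, zu, losses)
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["subject_id", "cycle_index"]).reset_index(drop=True)


def simulate_outcome_cohort(params: SimulationParams, n: int) -> pd.DataFrame:
    """Prospective cohort: one prepregnancy biopsy plus a pregnancy outcome.

    The exposure arm is defined by the configured quartile flag of the
    *latent* trait (e.g. ``stalled`` = latent stromal below its 25th
    percentile), so the arm's prevalence is exactly 25%.  Live birth is
    Bernoulli with the arm's probability; the remaining pregnancies are
    miscarriages, a configured fraction of which are karyotyped aneuploid.
    """
    params.validate()
    if n < 1:
        raise SimulationError("n must be at least 1")
    om = params.outcome_model
    rng = np.random.default_rng(params.seed)
    days = _draw_days(params, rng, n)
    z_s, z_u = _bivariate_normal(rng, params.rho_cross, n)
    losses = _draw_prior_losses(params, rng, z_s)
    subjects = np.array([f"O{i:06d}" for i in range(n)])
    df = _assemble(params, rng, subjects, np.ones(n, dtype=int), days, z_s, z_u,
                   losses)

    trait, lower = _FLAG_DEF[om.exposure_flag]
    z = z_s if trait == "stromal" else z_u
    cut = stats.norm.ppf(0.25)
    exposed = z < cut if lower else z > -cut
    p_live = np.where(exposed, om.p_live_exposed, om.p_live_unexposed)
    live = rng.random(n) < p_live
    df["outcome"] = np.where(live, "live_birth", "miscarriage")
    karyo = np.full(n, "unknown", dtype=object)
    u = rng.random(n)
    karyo[~live & (u < om.aneuploid_fraction)] = "aneuploid"
    karyo[~live & (u >= om.aneuploid_fraction)
          & (u < om.aneuploid_fraction + om.karyotyped_euploid_fraction)] = "euploid"
    df["karyotype"] = karyo
    # the generator's own exposure assignment, free of scoring-side
    # misclassification; preserved as an extra passthrough column
    df["exposed"] = exposed
    return df
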