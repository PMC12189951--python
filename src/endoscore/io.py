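"""Cohort CSV schema, readers/writers, and pipeline configuration.

The on-disk exchange format for all stages is a flat CSV with one biopsy per
row.  Mandatory columns identify the sample, its timing relative to the LH
surge, and the ddPCR copy numbers of the four marker genes; clinical
covariates, hormone levels and pregnancy outcome are optional.  Missing
optional values are empty strings on disk and NaN / empty in memory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("endoscore")

MARKER_GENES = ("pla2g2a", "dio2", "itgad", "cd160")
HORMONES = ("progesterone", "estradiol", "tsh")

#: (ratio name, numerator gene, denominator gene).  The stromal ratio proxies
#: the strength of the decidual reaction, the uNK ratio the expansion of
#: immunotolerant (KIR+) uNK subsets.
RATIOS = {
    "stromal": ("pla2g2a", "dio2"),
    "unk": ("itgad", "cd160"),
}

MANDATORY_COLUMNS = [
    "sample_id",
    "subject_id",
    "cycle_index",
    "lh_day",
    "copies_pla2g2a",
    "copies_dio2",
    "copies_itgad",
    "copies_cd160",
]
OPTIONAL_COLUMNS = [
    "prior_losses",
    "outcome",
    "karyotype",
    "progesterone",
    "estradiol",
    "tsh",
]
COHORT_COLUMNS = MANDATORY_COLUMNS + OPTIONAL_COLUMNS

OUTCOME_VALUES = {"live_birth", "miscarriage", "none", ""}
KARYOTYPE_VALUES = {"euploid", "aneuploid", "unknown", ""}


class CohortSchemaError(ValueError):
    """Raised when a cohort table violates the mandatory schema."""


@dataclasses.dataclass
class RowErrorReport:
    """Malformed rows collected during reading, with reasons."""

    rows: list[tuple[int, str]] = dataclasses.field(default_factory=list)

    def add(self, index: int, reason: str) -> None:
        self.rows.append((index, reason))

    def __len__(self) -> int:
        return len(self.rows)


def validate_cohort(df: pd.DataFrame) -> None:
    """Validate mandatory schema and per-row domain invariants.

    Raises :class:`CohortSchemaError` listing every missing mandatory column;
    domain violations (negative copies, outcome/karyotype inconsistency) also
    raise, since in-memory frames are expected to be clean — the tolerant
    path is :func:`read_cohort_csv`.
    """
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing mandatory columns: {missing}")
    for gene in MARKER_GENES:
        col = df[f"copies_{gene}"]
        if (pd.to_numeric(col, errors="coerce") < 0).any():
            raise CohortSchemaError(f"negative copy numbers in copies_{gene}")
    if "karyotype" in df.columns and "outcome" in df.columns:
        karyo = df["karyotype"].fillna("").astype(str)
        outc = df["outcome"].fillna("").astype(str)
        bad = karyo.isin({"euploid", "aneuploid"}) & (outc != "miscarriage")
        if bad.any():
            raise CohortSchemaError(
                "karyotype set on rows whose outcome is not miscarriage"
            )


def read_cohort_csv(path: str | Path) -> tuple[pd.DataFrame, RowErrorReport]:
    """Read a cohort CSV into a typed DataFrame.

    Malformed rows (negative copy numbers, unparseable numerics, invalid
    outcome codes) are dropped into the returned :class:`RowErrorReport`
    rather than failing the read.  Unknown extra columns are preserved.
    A missing mandatory column is a hard error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(
            f"{path}: missing mandatory columns: {missing}; "
            f"expected at least {MANDATORY_COLUMNS}"
        )
    report = RowErrorReport()
    numeric_cols = [f"copies_{g}" for g in MARKER_GENES] + list(HORMONES)
    out = df.copy()
    for col in ("cycle_index", "lh_day"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    for col in numeric_cols:
        if col in out.columns:
            out[col] = pd.to_numeric(out[col].replace("", np.nan), errors="coerce")
    if "prior_losses" in out.columns:
        out["prior_losses"] = pd.to_numeric(
            out["prior_losses"].replace("", np.nan), errors="coerce"
        )

    bad = pd.Series(False, index=out.index)
    for col in ("cycle_index", "lh_day"):
        mask = out[col].isna()
        for i in out.index[mask]:
            report.add(int(i), f"unparseable {col}: {df.loc[i, col]!r}")
        bad |= mask
    for gene in MARKER_GENES:
        col = f"copies_{gene}"
        mask = out[col] < 0
        for i in out.index[mask.fillna(False)]:
            report.add(int(i), f"negative copy number in {col}")
        bad |= mask.fillna(False)
    if "outcome" in out.columns:
        mask = ~out["outcome"].isin(OUTCOME_VALUES)
        for i in out.index[mask]:
            report.add(int(i), f"invalid outcome code: {df.loc[i, 'outcome']!r}")
        bad |= mask
    if "karyotype" in out.columns:
        mask = ~out["karyotype"].isin(KARYOTYPE_VALUES)
        for i in out.index[mask]:
            report.add(int(i), f"invalid karyotype code: {df.loc[i, 'karyotype']!r}")
        bad |= mask

    out = out[~bad].reset_index(drop=True)
    if len(report):
        logger.warning("read_cohort_csv: %d malformed rows rejected", len(report))
    return out, report


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort DataFrame; missing optional values become empty strings."""
    out = df.copy()
    cols = [c for c in COHORT_COLUMNS if c in out.columns]
    cols += [c for c in out.columns if c not in cols]
    out[cols].to_csv(path, index=False, na_rep="")


# --------------------------------------------------------------------------
# Pipeline configuration


@dataclasses.dataclass
class PipelineConfig:
    """End-to-end pipeline settings; every stage draws from these fields.

    All randomness flows from ``seed``; Bonferroni family size for the paired
    4x4 table defaults to the 16 cells of one table.
    """

    day_range: tuple[int, int] = (6, 10)
    min_n: int = 20
    pool_adjacent: bool = False
    alpha: float = 0.05
    bonferroni_m: int = 16
    seed: int = 0
    n_reference: int = 2000
    n_pairs: int = 316
    n_outcomes: int = 2000
    out_dir: str = "endoscore_out"
    cohort_csv: str | None = None  # external cohort; None -> simulate

    def validate(self) -> None:
        lo, hi = self.day_range
        if lo > hi:
            raise ValueError(f"day_range reversed: {self.day_range}")
        if self.min_n < 2:
            raise ValueError("min_n must be at least 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.bonferroni_m not in (4, 16):
            raise ValueError("bonferroni_m must be 4 (per column) or 16 (per table)")
        if min(self.n_reference, self.n_pairs, self.n_outcomes) < 1:
            raise ValueError("cohort sizes must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "day_range" in raw:
            raw["day_range"] = tuple(raw["day_range"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def provenance(config: PipelineConfig | None = None) -> dict[str, Any]:
    """Version/config stamp embedded in every output file."""
    from . import __version__

    stamp: dict[str, Any] = {"package": "endoscore", "version": __version__}
    if config is not None:
        stamp["config_hash"] = config.config_hash()
        stamp["seed"] = config.seed
    return stamp
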