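"""Intercycle analysis of paired biopsies.

Paired first/second-cycle quartile states are cross-tabulated in a 4x4
contingency table.  Each cell is tested one-versus-all: a 2x2 chi-square of
independence (Yates-corrected, with a Fisher fallback when an expected count
drops below 5) and a two-sided Fisher exact test with Bonferroni correction
over the 16 cells for enrichment/depletion.  Row-wise chi-square
goodness-of-fit tests check whether second-biopsy quartiles are uniform given
the first biopsy's bin, and the recurrence rate of a state is the diagonal
cell's share of its row.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .score import QUARTILE_LABELS

logger = logging.getLogger("endoscore")


class PairedAnalysisError(ValueError):
    pass


def _bin_index(bin_label: str | int) -> int:
    if isinstance(bin_label, str):
        if bin_label not in QUARTILE_LABELS:
            raise PairedAnalysisError(f"unknown quartile label: {bin_label!r}")
        return QUARTILE_LABELS.index(bin_label)
    if not 0 <= int(bin_label) <= 3:
        raise PairedAnalysisError(f"quartile index out of range: {bin_label}")
    return int(bin_label)


@dataclasses.dataclass
class QuartileTable:
    """4x4 paired-cycle contingency counts (rows: first biopsy quartile)."""

    counts: np.ndarray
    n_pairs: int

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def row_conditional_pct(self) -> np.ndarray:
        """Row-wise percentages; rows with no pairs are NaN."""
        totals = self.row_totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / totals[:, None]
        pct[totals == 0] = np.nan
        return pct

    def expected(self) -> np.ndarray:
        """Cell expectations under row/column independence."""
        return np.outer(self.row_totals, self.col_totals) / self.n_pairs


def build_quartile_table(first: np.ndarray, second: np.ndarray) -> QuartileTable:
    """Cross-tabulate aligned first/second-cycle quartile vectors."""
    a = np.asarray([_bin_index(q) for q in np.asarray(first, dtype=object)])
    b = np.asarray([_bin_index(q) for q in np.asarray(second, dtype=object)])
    if len(a) != len(b):
        raise PairedAnalysisError(
            f"unpaired input: {len(a)} first vs {len(b)} second biopsies"
        )
    counts = np.zeros((4, 4), dtype=int)
    np.add.at(counts, (a, b), 1)
    return QuartileTable(counts=counts, n_pairs=len(a))


def pair_scores(scores: pd.DataFrame, pair_on: str = "subject_id") -> pd.DataFrame:
    """Align each subject's cycle-1 and cycle-2 scores into one row per pair."""
    c1 = scores[scores["cycle_index"] == 1].set_index(pair_on)
    c2 = scores[scores["cycle_index"] == 2].set_index(pair_on)
    common = c1.index.intersection(c2.index)
    dropped = len(set(c1.index).symmetric_difference(c2.index))
    if dropped:
        logger.warning("pair_scores: %d subjects lack a complete pair", dropped)
    out = pd.DataFrame(index=common)
    for col in ("stromal_quartile", "unk_quartile", "stromal_percentile",
                "unk_percentile"):
        out[f"{col}_first"] = c1.loc[common, col]
        out[f"{col}_second"] = c2.loc[common, col]
    if "prior_losses" in c1.columns:
        out["prior_losses"] = c1.loc[common, "prior_losses"]
    return out.reset_index()


def _collapse_cell(table: QuartileTable, a_bin: int, b_bin: int) -> np.ndarray:
    """One-versus-all 2x2: (A in bin vs not) x (B in bin vs not)."""
    c = table.counts
    in_in = c[a_bin, b_bin]
    in_out = c[a_bin].sum() - in_in
    out_in = c[:, b_bin].sum() - in_in
    out_out = table.n_pairs - in_in - in_out - out_in
    return np.array([[in_in, in_out], [out_in, out_out]], dtype=int)


def one_vs_all_chi2(table: QuartileTable, bin: tuple[str | int, str | int]
                    ) -> tuple[float, float]:
    """Chi-square test of independence on a cell's one-versus-all 2x2.

    Yates continuity correction is applied; when any expected count is below
    5 the p-value comes from the two-sided Fisher exact test instead (the
    statistic is still the Yates chi-square).
    """
    a_bin, b_bin = (_bin_index(bin[0]), _bin_index(bin[1]))
    grid = _collapse_cell(table, a_bin, b_bin)
    if (grid.sum(axis=0) == 0).any() or (grid.sum(axis=1) == 0).any():
        raise PairedAnalysisError(
            f"one_vs_all_chi2: zero margin for bins ({a_bin}, {b_bin})"
        )
    res = stats.chi2_contingency(grid, correction=True)
    expected = res.expected_freq
    if (expected < 5).any():
        p = float(stats.fisher_exact(grid).pvalue)
    else:
        p = float(res.pvalue)
    return float(res.statistic), p


@dataclasses.dataclass
class CellEnrichment:
    a_bin: str
    b_bin: str
    observed: int
    expected: float
    direction: str  # "enriched" | "depleted" | "none"
    raw_p: float
    adjusted_p: float
    significant: bool


@dataclasses.dataclass
class EnrichmentResult:
    """Per-cell Fisher enrichment/depletion with Bonferroni correction."""

    cells: list[CellEnrichment]
    family_size: int
    alpha: float

    def any_significant(self) -> bool:
        return any(c.significant for c in self.cells)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(c) for c in self.cells])


def fisher_cell_enrichment(table: QuartileTable, alpha: float = 0.05,
                           family_size: int = 16) -> EnrichmentResult:
    """Two-sided Fisher exact test on every cell's one-versus-all 2x2.

    Bonferroni adjusts over ``family_size`` tests (16 = all cells of the
    table; 4 restricts the family to one column of interest).  A cell whose
    observed count equals its independence expectation gets direction
    ``none`` and is never significant.
    """
    if table.n_pairs <= 0:
        raise PairedAnalysisError("empty table")
    expected = table.expected()
    cells = []
    for i in range(4):
        for j in range(4):
            grid = _collapse_cell(table, i, j)
            raw_p = float(stats.fisher_exact(grid).pvalue)
            obs, exp = int(table.counts[i, j]), float(expected[i, j])
            if obs > exp:
                direction = "enriched"
            elif obs < exp:
                direction = "depleted"
            else:
                direction = "none"
            adj_p = min(1.0, family_size * raw_p)
            cells.append(CellEnrichment(
                a_bin=QUARTILE_LABELS[i], b_bin=QUARTILE_LABELS[j],
                observed=obs, expected=exp, direction=direction,
                raw_p=raw_p, adjusted_p=adj_p,
                significant=bool(adj_p < alpha and direction != "none"),
            ))
    return EnrichmentResult(cells=cells, family_size=family_size, alpha=alpha)


def column_uniformity(table: QuartileTable, a_bin: str | int
                      ) -> tuple[float, float]:
    """Chi-square goodness-of-fit of one row against uniform (df = 3)."""
    i = _bin_index(a_bin)
    row = table.counts[i].astype(float)
    if row.sum() == 0:
        raise PairedAnalysisError(f"row {QUARTILE_LABELS[i]} is empty")
    res = stats.chisquare(row)
    return float(res.statistic), float(res.pvalue)


def recurrence_rate(table: QuartileTable, bin: str | int) -> float:
    """P(second biopsy in the same quartile | first biopsy in that quartile).

    NaN for an empty row (undefined conditional).
    """
    i = _bin_index(bin)
    total = table.row_totals[i]
    if total == 0:
        logger.warning("recurrence_rate: no pairs with first biopsy in %s",
                       QUARTILE_LABELS[i])
        return float("nan")
    return float(table.counts[i, i] / total)


def analyze_pairs(pairs: pd.DataFrame, ratio: str = "stromal",
                  alpha: float = 0.05, family_size: int = 16) -> dict:
    """Full paired analysis for one ratio: table, tests, recurrence rates."""
    table = build_quartile_table(
        pairs[f"{ratio}_quartile_first"], pairs[f"{ratio}_quartile_second"]
    )
    enrichment = fisher_cell_enrichment(table, alpha=alpha,
                                        family_size=family_size)
    uniformity = {}
    for q in QUARTILE_LABELS:
        if table.row_totals[_bin_index(q)] > 0:
            chi2, p = column_uniformity(table, q)
            uniformity[q] = {"chi2": chi2, "p": p}
    recurrence = {
        q: recurrence_rate(table, q)
        for q in QUARTILE_LABELS
    }
    return {
        "ratio": ratio,
        "table": table,
        "enrichment": enrichment,
        "uniformity": uniformity,
        "recurrence": recurrence,
    }


def stratified_recurrence(pairs: pd.DataFrame, strata: pd.Series | str =
                          "prior_losses", ratio: str = "stromal",
                          alpha: float = 0.05, family_size: int = 16
                          ) -> dict[object, dict]:
    """Paired analysis per prior-loss stratum.

    The Bonferroni family stays within each stratum's table.  Empty strata
    are skipped with a warning; a stratum with no first-biopsy pairs in a
    quartile reports that quartile's recurrence as NaN.
    """
    labels = pairs[strata] if isinstance(strata, str) else strata
    out: dict[object, dict] = {}
    for level in pd.unique(labels.dropna()):
        sub = pairs[labels == level]
        if len(sub) == 0:
            logger.warning("stratum %r empty, skipped", level)
            continue
        out[level] = analyze_pairs(sub, ratio=ratio, alpha=alpha,
                                   family_size=family_size)
    return out
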