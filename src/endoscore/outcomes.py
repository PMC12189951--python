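"""Association of percentile scores with prior losses and pregnancy outcome.

Covers the cohort-level association machinery: quartile-bin frequencies
stratified by the number of prior pregnancy losses (pairwise chi-square with
Bonferroni correction and compact-letter grouping), unadjusted odds ratios
with Woolf (log-OR) 95% confidence intervals for future-pregnancy outcomes —
optionally excluding karyotyped aneuploid losses — Spearman rank correlation
between the stromal and uNK percentile scores, and Kruskal–Wallis with Dunn's
post hoc comparisons across quartile bins.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .score import QUARTILE_LABELS

logger = logging.getLogger("endoscore")


class AssociationError(ValueError):
    pass


# --------------------------------------------------------------------------
# Compact letter display


def compact_letters(groups: list, nonsig_pairs: set[tuple]) -> dict:
    """Assign shared letters to groups not significantly different.

    Insert-and-absorb algorithm: each letter names a maximal clique-ish set
    in which every pair is non-significant; groups sharing no letter differ
    significantly.  Groups are processed in the order given (ties keep the
    first letter assigned).
    """
    nonsig = {frozenset(p) for p in nonsig_pairs}

    def compatible(g, letter_set):
        return all(frozenset((g, h)) in nonsig for h in letter_set)

    letter_sets: list[list] = []
    for g in groups:
        placed = False
        for ls in letter_sets:
            if compatible(g, ls):
                ls.append(g)
                placed = True
        if not placed:
            # split off the compatible part of each incompatible set
            new_sets = []
            for ls in letter_sets:
                sub = [h for h in ls if frozenset((g, h)) in nonsig]
                if sub + [g] not in new_sets:
                    new_sets.append(sub + [g])
            letter_sets.extend(new_sets or [[g]])
    # absorb redundant subsets
    letter_sets = [
        ls for i, ls in enumerate(letter_sets)
        if not any(set(ls) < set(other) for j, other in enumerate(letter_sets)
                   if i != j)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict = {g: "" for g in groups}
    for letter, ls in zip(alphabet, letter_sets):
        for g in ls:
            out[g] += letter
    return out


# --------------------------------------------------------------------------
# Quartile-bin frequencies by prior losses


def _loss_category(losses: pd.Series, top: int = 4) -> pd.Series:
    """0, 1, 2, 3 and '4+' prior-loss categories."""
    vals = pd.to_numeric(losses, errors="coerce")
    cat = vals.where(vals < top, top)
    labels = {i: str(i) for i in range(top)} | {top: f"{top}+"}
    return cat.map(labels)


def frequency_by_losses(scores: pd.DataFrame, flag: str = "stalled",
                        alpha: float = 0.05) -> dict:
    """Flag frequency per prior-loss group with pairwise chi-square tests.

    Returns per-group n and in-flag percentage, pairwise Yates chi-square
    p-values Bonferroni-corrected over the number of pairwise comparisons,
    and compact letters (groups sharing a letter do not differ at ``alpha``).
    Groups with no samples are excluded with a warning; with fewer than two
    usable groups only frequencies are reported.
    """
    if flag not in scores.columns:
        raise AssociationError(f"unknown flag column: {flag!r}")
    cats = _loss_category(scores["prior_losses"])
    usable = scores[cats.notna()].copy()
    usable["loss_group"] = cats[cats.notna()]
    order = [g for g in ("0", "1", "2", "3", "4+")
             if g in set(usable["loss_group"])]
    freq = {}
    for g in order:
        sub = usable[usable["loss_group"] == g]
        if len(sub) == 0:
            logger.warning("loss group %s empty, excluded", g)
            continue
        freq[g] = {
            "n": int(len(sub)),
            "in_flag": int(sub[flag].sum()),
            "pct": 100.0 * float(sub[flag].mean()),
        }
    groups = list(freq)
    result = {"flag": flag, "groups": freq, "pairwise": {}, "letters": {}}
    if len(groups) < 2:
        return result

    pairs = list(itertools.combinations(groups, 2))
    m = len(pairs)
    nonsig = set()
    for g1, g2 in pairs:
        a, n1 = freq[g1]["in_flag"], freq[g1]["n"]
        b, n2 = freq[g2]["in_flag"], freq[g2]["n"]
        grid = np.array([[a, n1 - a], [b, n2 - b]])
        if (grid.sum(axis=0) == 0).any():
            raw_p = 1.0
        elif grid[0].tolist() == grid[1].tolist() or (
            n1 > 0 and n2 > 0 and a / n1 == b / n2
        ):
            raw_p = 1.0  # identical proportions: no evidence by construction
        else:
            res = stats.chi2_contingency(grid, correction=True)
            raw_p = float(res.pvalue)
            if (res.expected_freq < 5).any():
                raw_p = float(stats.fisher_exact(grid).pvalue)
        adj_p = min(1.0, m * raw_p)
        significant = adj_p < alpha
        result["pairwise"][(g1, g2)] = {
            "raw_p": raw_p, "adjusted_p": adj_p, "significant": significant,
        }
        if not significant:
            nonsig.add((g1, g2))
    result["letters"] = compact_letters(groups, nonsig)
    return result


# --------------------------------------------------------------------------
# Odds ratios


@dataclasses.dataclass
class OddsRatioResult:
    """Unadjusted OR with Woolf 95% CI for a binary exposure and outcome.

    ``table`` rows are exposure (exposed first), columns outcome (event
    first); OR = ad/bc.  ``haldane`` records whether the +0.5 zero-cell
    correction was applied.
    """

    table: np.ndarray
    or_estimate: float
    ci_low: float
    ci_high: float
    p: float
    exclusion_applied: bool
    haldane: bool = False

    def inverted(self) -> "OddsRatioResult":
        """Same data with the exposure rows swapped (OR -> 1/OR)."""
        return odds_ratio_from_table(self.table[::-1].copy(),
                                     exclusion_applied=self.exclusion_applied)


def odds_ratio_from_table(table: np.ndarray,
                          exclusion_applied: bool = False) -> OddsRatioResult:
    """Woolf log-OR estimate, 95% CI and two-sided z-test p from a 2x2."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise AssociationError("odds ratio requires a non-negative 2x2 table")
    haldane = bool((t == 0).any())
    if haldane:
        logger.warning("zero cell: Haldane–Anscombe +0.5 correction applied")
        t = t + 0.5
    a, b = t[0]
    c, d = t[1]
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = 1.959963984540054  # Phi^-1(0.975)
    p = 2.0 * stats.norm.sf(abs(log_or) / se)
    return OddsRatioResult(
        table=np.asarray(table, dtype=float),
        or_estimate=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        p=float(p),
        exclusion_applied=exclusion_applied,
        haldane=haldane,
    )


def odds_ratio_ci(scores: pd.DataFrame, flag: str = "stalled",
                  event: str = "live_birth",
                  exclude_aneuploid: bool = False) -> OddsRatioResult:
    """OR for ``event`` comparing flagged vs unflagged subjects.

    Subjects with no recorded pregnancy outcome are excluded.  With
    ``exclude_aneuploid`` subjects whose miscarriage is karyotyped aneuploid
    are removed before tabulation (chromosomally abnormal losses are not
    informative about the endometrial contribution to risk).
    """
    if flag not in scores.columns:
        raise AssociationError(f"unknown flag column: {flag!r}")
    if event not in ("live_birth", "miscarriage"):
        raise AssociationError(f"unknown event: {event!r}")
    sub = scores[scores["outcome"].isin(["live_birth", "miscarriage"])]
    if exclude_aneuploid:
        sub = sub[~((sub["outcome"] == "miscarriage")
                    & (sub["karyotype"] == "aneuploid"))]
    exposed = sub[flag].astype(bool)
    is_event = sub["outcome"] == event
    table = np.array([
        [int((exposed & is_event).sum()), int((exposed & ~is_event).sum())],
        [int((~exposed & is_event).sum()), int((~exposed & ~is_event).sum())],
    ])
    return odds_ratio_from_table(table, exclusion_applied=exclude_aneuploid)


def outcome_forest(scores: pd.DataFrame,
                   exclude_aneuploid: bool = False) -> pd.DataFrame:
    """Quartile-bin ORs for both outcome codings and both ratios.

    One row per (ratio, quartile, event): the bin-vs-all-others OR with its
    CI — the two forest panels (miscarriage risk and live birth rate) are
    two codings of the same tabulation.
    """
    rows = []
    for ratio in ("stromal", "unk"):
        qcol = f"{ratio}_quartile"
        for q in QUARTILE_LABELS:
            flag_col = f"_in_{qcol}_{q}"
            tagged = scores.copy()
            tagged[flag_col] = tagged[qcol] == q
            for event in ("miscarriage", "live_birth"):
                res = odds_ratio_ci(tagged, flag=flag_col, event=event,
                                    exclude_aneuploid=exclude_aneuploid)
                rows.append({
                    "ratio": ratio, "quartile": q, "event": event,
                    "or": res.or_estimate, "ci_low": res.ci_low,
                    "ci_high": res.ci_high, "p": res.p,
                    "exclusion_applied": res.exclusion_applied,
                })
    return pd.DataFrame(rows)


def miscarriage_rate(scores: pd.DataFrame) -> float:
    """Percentage of subjects with a recorded pregnancy who miscarried."""
    sub = scores[scores["outcome"].isin(["live_birth", "miscarriage"])]
    if len(sub) == 0:
        raise AssociationError("no subjects with a recorded pregnancy outcome")
    return 100.0 * float((sub["outcome"] == "miscarriage").mean())


# --------------------------------------------------------------------------
# Rank statistics


def spearman_percentiles(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with t-test p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise AssociationError("aligned vectors required")
    if len(x) < 3:
        raise AssociationError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AssociationError("constant vector: correlation undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclasses.dataclass
class DunnComparison:
    group1: object
    group2: object
    z: float
    raw_p: float
    adjusted_p: float
    significant: bool


def kruskal_dunn(values: np.ndarray, groups: np.ndarray, alpha: float = 0.05,
                 adjust: str = "bonferroni") -> dict:
    """Kruskal–Wallis omnibus test plus Dunn's pairwise z comparisons.

    Dunn's test uses the pooled mid-ranks with the standard tie correction
    of the rank variance; pairwise p-values are Bonferroni-adjusted by
    default (``adjust='holm'`` for the step-down alternative).  All-identical
    observations return H = 0, p = 1 with every comparison non-significant.
    Compact letters summarize the pairwise pattern.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    uniq = list(pd.unique(labels))
    if len(uniq) < 2:
        raise AssociationError("need at least 2 groups")
    if any((labels == g).sum() < 1 for g in uniq):
        raise AssociationError("every group needs at least one observation")
    samples = [values[labels == g] for g in uniq]

    if np.ptp(values) == 0:
        pairwise = [
            DunnComparison(g1, g2, 0.0, 1.0, 1.0, False)
            for g1, g2 in itertools.combinations(uniq, 2)
        ]
        return {"H": 0.0, "p": 1.0, "pairwise": pairwise,
                "letters": {g: "a" for g in uniq}}

    hres = stats.kruskal(*samples)

    n = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    mean_ranks = {g: float(ranks[labels == g].mean()) for g in uniq}
    sizes = {g: int((labels == g).sum()) for g in uniq}

    pairs = list(itertools.combinations(uniq, 2))
    m = len(pairs)
    raw = []
    for g1, g2 in pairs:
        se = np.sqrt(var_base * (1 / sizes[g1] + 1 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        raw.append((g1, g2, float(z), float(2.0 * stats.norm.sf(abs(z)))))

    if adjust == "bonferroni":
        adj = [min(1.0, m * p) for *_, p in raw]
    elif adjust == "holm":
        order = np.argsort([p for *_, p in raw])
        adj = [0.0] * m
        running = 0.0
        for rank_i, idx in enumerate(order):
            running = max(running, min(1.0, (m - rank_i) * raw[idx][3]))
            adj[idx] = running
    else:
        raise AssociationError(f"unknown adjustment: {adjust!r}")

    pairwise = [
        DunnComparison(g1, g2, z, p, ap, bool(ap < alpha))
        for (g1, g2, z, p), ap in zip(raw, adj)
    ]
    nonsig = {(c.group1, c.group2) for c in pairwise if not c.significant}
    return {
        "H": float(hres.statistic),
        "p": float(hres.pvalue),
        "pairwise": pairwise,
        "letters": compact_letters(uniq, nonsig),
    }


def percentiles_by_quartile(scores: pd.DataFrame, of: str = "unk",
                            by: str = "stromal", alpha: float = 0.05) -> dict:
    """Kruskal–Wallis/Dunn of one score's percentiles across the other's bins."""
    return kruskal_dunn(
        scores[f"{of}_percentile"].to_numpy(),
        scores[f"{by}_quartile"].to_numpy(),
        alpha=alpha,
    )
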