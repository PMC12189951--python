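"""Outcome association: odds ratios, Spearman, Kruskal-Wallis/Dunn, frequencies."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from endoscore import (AssociationError, compact_letters, frequency_by_losses,
                       kruskal_dunn, miscarriage_rate, odds_ratio_ci,
                       odds_ratio_from_table, outcome_forest,
                       percentiles_by_quartile, spearman_percentiles)


def outcome_frame(a, b, c, d, aneuploid=0):
    """2x2 (exposure x live-birth) as a scores-like frame; a,b exposed."""
    rows = (
        [("live_birth", True)] * a + [("miscarriage", True)] * b
        + [("live_birth", False)] * c + [("miscarriage", False)] * d
    )
    df = pd.DataFrame(rows, columns=["outcome", "flag"])
    df["karyotype"] = "unknown"
    mis = df.index[df["outcome"] == "miscarriage"][:aneuploid]
    df.loc[mis, "karyotype"] = "aneuploid"
    return df


class TestOddsRatio:
    def test_hand_arithmetic_with_woolf_ci(self):
        res = odds_ratio_from_table([[10, 40], [25, 25]])
        assert res.or_estimate == pytest.approx(0.25)
        assert res.ci_low == pytest.approx(0.103, abs=1e-3)
        assert res.ci_high == pytest.approx(0.607, abs=1e-3)

    def test_null_table_symmetric_on_log_scale(self):
        res = odds_ratio_from_table([[20, 20], [20, 20]])
        assert res.or_estimate == pytest.approx(1.0)
        assert res.ci_low * res.ci_high == pytest.approx(1.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    @given(st.tuples(*[st.integers(1, 80)] * 4))
    def test_inversion_symmetry(self, cells):
        """Swapping exposure rows inverts the OR and mirrors the CI."""
        a, b, c, d = cells
        res = odds_ratio_from_table([[a, b], [c, d]])
        inv = res.inverted()
        assert res.or_estimate * inv.or_estimate == pytest.approx(1, abs=1e-9)
        assert res.ci_low * inv.ci_high == pytest.approx(1.0, abs=1e-9)

    def test_haldane_correction_on_zero_cell(self):
        res = odds_ratio_from_table([[0, 10], [5, 5]])
        assert res.haldane
        assert np.isfinite(res.or_estimate) and res.or_estimate > 0

    def test_exclusion_noop_without_aneuploid_losses(self):
        df = outcome_frame(10, 40, 25, 25, aneuploid=0)
        a = odds_ratio_ci(df, flag="flag", exclude_aneuploid=False)
        b = odds_ratio_ci(df, flag="flag", exclude_aneuploid=True)
        assert np.array_equal(a.table, b.table)
        assert b.exclusion_applied and not a.exclusion_applied

    def test_exclusion_removes_only_aneuploid_losses(self):
        df = outcome_frame(10, 40, 25, 25, aneuploid=12)
        res = odds_ratio_ci(df, flag="flag", exclude_aneuploid=True)
        assert res.table.sum() == 100 - 12

    def test_forest_covers_both_codings(self, scores):
        rng = np.random.default_rng(0)
        tagged = scores.copy()
        tagged["outcome"] = rng.choice(["live_birth", "miscarriage"],
                                       len(tagged))
        tagged["karyotype"] = "unknown"
        forest = outcome_forest(tagged)
        assert len(forest) == 2 * 4 * 2
        sub = forest[(forest["ratio"] == "stromal")
                     & (forest["quartile"] == "Q1")]
        mis = sub[sub["event"] == "miscarriage"].iloc[0]
        live = sub[sub["event"] == "live_birth"].iloc[0]
        assert mis["or"] * live["or"] == pytest.approx(1.0, abs=1e-9)

    def test_miscarriage_rate_arithmetic(self):
        df = outcome_frame(10, 40, 25, 25)
        assert miscarriage_rate(df) == pytest.approx(65.0)


class TestSpearman:
    def test_perfect_concordance_and_discordance(self):
        x = np.arange(10.0)
        assert spearman_percentiles(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert spearman_percentiles(x, -x)[0] == pytest.approx(-1.0)

    def test_gaussian_copula_closed_form(self):
        """rho_latent=0.377 gives Spearman (6/pi) asin(0.377/2) = 0.362."""
        rng = np.random.default_rng(31)
        z1 = rng.standard_normal(10_000)
        z2 = 0.377 * z1 + np.sqrt(1 - 0.377**2) * rng.standard_normal(10_000)
        rho, p = spearman_percentiles(z1, z2)
        assert rho == pytest.approx(0.3622, abs=0.03)
        assert p < 1e-10

    def test_constant_vector_rejected(self):
        with pytest.raises(AssociationError, match="constant"):
            spearman_percentiles(np.ones(10), np.arange(10.0))


class TestKruskalDunn:
    def test_fully_separated_groups_brute_force_h(self):
        values = np.array([1, 2, 3, 4, 5, 6, 7, 8], dtype=float)
        groups = np.repeat(["a", "b", "c", "d"], 2)
        res = kruskal_dunn(values, groups)
        # brute-force H from the rank definition (no ties)
        ranks = stats.rankdata(values)
        n = len(values)
        h = 12 / (n * (n + 1)) * sum(
            2 * (ranks[groups == g].mean() - (n + 1) / 2) ** 2
            for g in "abcd")
        assert res["H"] == pytest.approx(h)
        assert h == pytest.approx(20 / 3)

    def test_identical_groups_adjusted_p_is_one(self):
        values = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        groups = np.repeat(["a", "b"], 3)
        res = kruskal_dunn(values, groups)
        assert res["pairwise"][0].adjusted_p == 1.0
        assert res["letters"]["a"] == res["letters"]["b"]

    def test_all_values_identical(self):
        res = kruskal_dunn(np.ones(12), np.repeat(["a", "b", "c"], 4))
        assert res["H"] == 0.0 and res["p"] == 1.0

    def test_null_omnibus_p_is_uniform(self):
        """Across 500 null simulations the omnibus p is uniform (KS < 0.08)."""
        rng = np.random.default_rng(37)
        pvals = []
        for _ in range(500):
            values = rng.standard_normal(40)
            groups = np.repeat(["a", "b", "c", "d"], 10)
            pvals.append(kruskal_dunn(values, groups)["p"])
        assert stats.kstest(pvals, "uniform").statistic < 0.08

    def test_holm_never_exceeds_bonferroni(self):
        rng = np.random.default_rng(41)
        values = rng.standard_normal(60)
        groups = np.repeat(["a", "b", "c", "d"], 15)
        bon = kruskal_dunn(values, groups, adjust="bonferroni")["pairwise"]
        holm = kruskal_dunn(values, groups, adjust="holm")["pairwise"]
        for cb, ch in zip(bon, holm):
            assert ch.adjusted_p <= cb.adjusted_p + 1e-12

    def test_separated_quartile_bins_differ(self, scores):
        res = percentiles_by_quartile(scores, of="stromal", by="stromal")
        assert res["p"] < 1e-10
        letters = set(res["letters"].values())
        assert len(letters) == 4  # every bin separated from every other


class TestFrequencyByLosses:
    @staticmethod
    def null_frame(rng, n=600):
        return pd.DataFrame({
            "prior_losses": rng.integers(0, 5, n),
            "stalled": rng.random(n) < 0.25,
        })

    def test_null_generator_controls_type_i_error(self):
        """No significant pairs in >=95 of 100 null cohorts."""
        rng = np.random.default_rng(43)
        clean = 0
        for _ in range(100):
            res = frequency_by_losses(self.null_frame(rng))
            clean += not any(p["significant"]
                             for p in res["pairwise"].values())
        assert clean >= 95

    def test_identical_proportions_give_p_one(self):
        df = pd.DataFrame({
            "prior_losses": [0] * 40 + [1] * 40,
            "stalled": ([True] * 10 + [False] * 30) * 2,
        })
        res = frequency_by_losses(df)
        assert res["pairwise"][("0", "1")]["raw_p"] == 1.0
        assert res["letters"]["0"] == res["letters"]["1"]

    def test_groups_absent_from_data_excluded(self):
        df = pd.DataFrame({"prior_losses": [0] * 30 + [2] * 30,
                           "stalled": [True, False] * 30})
        res = frequency_by_losses(df)
        assert set(res["groups"]) == {"0", "2"}

    def test_single_group_reports_frequencies_only(self):
        df = pd.DataFrame({"prior_losses": [1] * 30,
                           "stalled": [True] * 6 + [False] * 24})
        res = frequency_by_losses(df)
        assert res["groups"]["1"]["pct"] == pytest.approx(20.0)
        assert res["pairwise"] == {}

    def test_strong_shift_detected_with_letters(self):
        rng = np.random.default_rng(47)
        df = pd.DataFrame({
            "prior_losses": np.repeat([0, 4], 300),
            "stalled": np.concatenate([rng.random(300) < 0.10,
                                       rng.random(300) < 0.45]),
        })
        res = frequency_by_losses(df)
        assert res["pairwise"][("0", "4+")]["significant"]
        assert not set(res["letters"]["0"]) & set(res["letters"]["4+"])


class TestCompactLetters:
    def test_all_equivalent_share_one_letter(self):
        groups = ["a", "b", "c"]
        nonsig = set(itertools.combinations(groups, 2))
        letters = compact_letters(groups, nonsig)
        assert len(set(letters.values())) == 1

    def test_all_different_get_distinct_letters(self):
        letters = compact_letters(["a", "b", "c"], set())
        assert letters == {"a": "a", "b": "b", "c": "c"}

    def test_chain_structure(self):
        # a~b, b~c, but a != c: b shares a letter with each
        letters = compact_letters(["a", "b", "c"], {("a", "b"), ("b", "c")})
        assert set(letters["a"]) & set(letters["b"])
        assert set(letters["b"]) & set(letters["c"])
        assert not set(letters["a"]) & set(letters["c"])
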