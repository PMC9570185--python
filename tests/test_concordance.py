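import itertools

import numpy as np
import pandas as pd
import pytest

from oxysig.concordance import (
    direction_concordance,
    fisher_categorical,
    paired_wilcoxon_bh,
    published_candidate_sets,
    spearman_consistency,
    venn,
    volcano_table,
)
from tests_support import tiny_paired_study as tiny_study


def exhaustive_signrank_p(diffs: np.ndarray) -> float:
    """Exact two-sided signed-rank p by enumerating all sign patterns."""
    from scipy.stats import rankdata

    d = diffs[diffs != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    stat_obs = min(w_obs, total - w_obs)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if min(w, total - w) <= stat_obs + 1e-9:
            count += 1
    return count / 2**n


class TestPairedWilcoxon:
    def test_identical_pairs_give_p_one(self):
        vals = np.abs(np.random.default_rng(0).standard_normal((8, 2))) + 1
        study = tiny_study(vals, vals.copy())
        out = paired_wilcoxon_bh(study)
        assert (out["p_raw"] == 1.0).all()
        assert out["degenerate"].all()
        assert (out["statistic"] == 0.0).all()

    def test_constant_shift_exact_p(self):
        """A uniform positive shift over 10 pairs has the extreme-most
        statistic: exact two-sided p = 2/2^10."""
        rng = np.random.default_rng(1)
        ctrl = np.abs(rng.standard_normal((10, 1))) + 1
        case = ctrl + 1.0
        out = paired_wilcoxon_bh(tiny_study(case, ctrl))
        assert out["p_raw"].iloc[0] == pytest.approx(2 / 2**10)

    def test_exact_matches_sign_enumeration(self):
        rng = np.random.default_rng(2)
        for n in (6, 9, 12):
            ctrl = np.abs(rng.standard_normal((n, 1))) + 2
            case = ctrl * np.exp(rng.standard_normal((n, 1)) * 0.4 + 0.3)
            out = paired_wilcoxon_bh(tiny_study(case, ctrl))
            expected = exhaustive_signrank_p((case - ctrl).ravel())
            assert out["p_raw"].iloc[0] == pytest.approx(expected)

    def test_direction_sign_flips_with_roles(self):
        rng = np.random.default_rng(3)
        ctrl = np.abs(rng.standard_normal((12, 1))) + 1
        case = ctrl + 0.5
        up = paired_wilcoxon_bh(tiny_study(case, ctrl))
        down = paired_wilcoxon_bh(tiny_study(ctrl, case))
        assert up["direction"].iloc[0] == 1
        assert down["direction"].iloc[0] == -1
        assert up["std_difference"].iloc[0] == pytest.approx(
            -down["std_difference"].iloc[0]
        )


class TestBH:
    def test_step_up_closed_form(self):
        from statsmodels.stats.multitest import multipletests

        adjusted = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert adjusted == pytest.approx([0.03, 0.03, 0.03])

    def test_bh_applied_across_analyte_family(self):
        rng = np.random.default_rng(4)
        ctrl = np.abs(rng.standard_normal((15, 4))) + 1
        case = ctrl * np.exp(rng.standard_normal((15, 4)) * 0.3)
        out = paired_wilcoxon_bh(tiny_study(case, ctrl))
        assert (out["p_adj"] >= out["p_raw"] - 1e-15).all()
        assert (out["p_adj"] <= 1.0).all()
        # step-up preserves the raw ordering
        ranked = out.sort_values("p_raw")
        assert ranked["p_adj"].is_monotonic_increasing


class TestVolcano:
    def test_equal_means_give_zero_x(self):
        vals = np.abs(np.random.default_rng(5).standard_normal((10, 1))) + 1
        out = paired_wilcoxon_bh(tiny_study(vals, vals[::-1].copy()))
        assert out["std_difference"].iloc[0] == pytest.approx(0.0)

    def test_threshold_line_value(self):
        records = pd.DataFrame(
            {"std_difference": [0.1], "p_adj": [0.0005]}, index=["a"]
        )
        out = volcano_table(records)
        assert out["y"].iloc[0] == pytest.approx(-np.log10(0.0005))
        assert out["y"].iloc[0] == pytest.approx(3.3010, abs=1e-4)
        assert bool(out["significant"].iloc[0]) is True


class TestSpearman:
    def test_monotone_gives_strong(self):
        x = pd.DataFrame({"score": np.arange(20.0)})
        y = pd.DataFrame({"crit": np.arange(20.0) ** 3})
        out = spearman_consistency(x, y)
        assert out["rho"].iloc[0] == pytest.approx(1.0)
        assert out["label"].iloc[0] == "strong"

    def test_brute_force_rank_formula(self):
        x = pd.DataFrame({"score": [1.0, 2.0, 3.0]})
        y = pd.DataFrame({"crit": [2.0, 1.0, 3.0]})
        out = spearman_consistency(x, y)
        # rank-transform Pearson on ranks (1,2,3) vs (2,1,3)
        rx, ry = np.array([1, 2, 3]), np.array([2, 1, 3])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert out["rho"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_anti_monotone_is_none(self):
        x = pd.DataFrame({"score": np.arange(20.0)})
        y = pd.DataFrame({"crit": -np.arange(20.0)})
        out = spearman_consistency(x, y)
        assert out["rho"].iloc[0] == pytest.approx(-1.0)
        assert out["label"].iloc[0] == "none"  # cutoffs are one-sided

    def test_matches_rank_pearson_on_tie_free_data(self):
        rng = np.random.default_rng(6)
        from scipy.stats import rankdata

        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        out = spearman_consistency(
            pd.DataFrame({"s": x}), pd.DataFrame({"c": y})
        )
        expected = np.corrcoef(rankdata(x), rankdata(y))[0, 1]
        assert out["rho"].iloc[0] == pytest.approx(expected, abs=1e-12)


class TestVenn:
    def test_published_lists_arithmetic(self):
        sets = published_candidate_sets()
        summary = venn(sets["discovery"], sets["replication"])
        assert summary.counts() == {"n_a": 23, "n_b": 17, "n_common": 11, "n_union": 29}

    def test_identical_sets(self):
        s = venn(["a", "b"], ["b", "a"])
        assert s.common == s.union == ["a", "b"]

    def test_disjoint_sets(self):
        s = venn(["a", "b"], ["c", "d", "e"])
        assert s.counts() == {"n_a": 2, "n_b": 3, "n_common": 0, "n_union": 5}

    def test_inclusion_exclusion_on_random_sets(self):
        rng = np.random.default_rng(7)
        universe = [f"x{i}" for i in range(30)]
        for _ in range(25):
            a = list(rng.choice(universe, rng.integers(0, 20), replace=False))
            b = list(rng.choice(universe, rng.integers(1, 20), replace=False))
            s = venn(a, b)
            c = s.counts()
            assert c["n_union"] == c["n_a"] + c["n_b"] - c["n_common"]
            assert set(s.common) == set(a) & set(b)


class TestDirectionConcordance:
    def frame(self, signs):
        return pd.DataFrame(
            {"std_difference": signs}, index=[f"a{i}" for i in range(len(signs))]
        )

    def test_identical_tables(self):
        f = self.frame([0.5, -0.2, 1.0])
        assert direction_concordance(f, f) == 1.0

    def test_all_flipped(self):
        f = self.frame([0.5, -0.2, 1.0])
        g = self.frame([-0.5, 0.2, -1.0])
        assert direction_concordance(f, g) == 0.0

    def test_nineteen_of_twentynine(self):
        from oxysig.io import round_percent

        signs_a = [1.0] * 29
        signs_b = [1.0] * 19 + [-1.0] * 10
        frac = direction_concordance(self.frame(signs_a), self.frame(signs_b))
        assert frac == pytest.approx(19 / 29)
        assert round_percent(19, 29) == 65.5
        assert round(frac, 2) == 0.66


class TestFisher:
    def test_2x2_matches_scipy(self):
        from scipy.stats import fisher_exact

        table = [[10, 3], [4, 9]]
        assert fisher_categorical(table) == pytest.approx(fisher_exact(table)[1])

    def test_2x3_permutation_sane(self):
        balanced = [[10, 10, 10], [10, 10, 10]]
        p = fisher_categorical(balanced, n_permutations=2000, seed=0)
        assert p > 0.5
        skewed = [[20, 1, 1], [1, 20, 20]]
        p = fisher_categorical(skewed, n_permutations=2000, seed=0)
        assert p < 0.01
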