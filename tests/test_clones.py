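import itertools
import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import comb

from mklandscape import clones
from mklandscape.clones import (
    CloneRecord, ContingencyTable, Observation, SummaryStats,
    chi_square_test, classify_clone, consolidate, first_mk_day, fisher_exact,
    mann_whitney_u, min_divisions, overlap_score, percent_depletion,
    student_t_from_summary, welch_t_from_summary,
)


def record(obs, well="w1", pop="pMKP", geno="WT"):
    return CloneRecord(well, pop, geno, [Observation(*o) for o in obs])


class TestClassifyClone:
    @pytest.mark.parametrize(
        "n_large, n_small, expected",
        [
            (1, 0, "1 MK"),
            (3, 0, ">1 MK"),
            (2, 4, "mixed"),
            (1, 1, "mixed"),
            (0, 6, "proliferation only"),
        ],
    )
    def test_category_rules(self, n_large, n_small, expected):
        r = record([(4, n_large, n_small, True)])
        assert classify_clone(r, 4) == expected

    def test_dead_well(self):
        r = record([(2, 1, 1, True), (4, 0, 0, False)])
        assert classify_clone(r, 4) == "dead"

    def test_missing_day_is_error(self):
        r = record([(4, 1, 0, True)])
        with pytest.raises(KeyError, match="day 2"):
            classify_clone(r, 2)

    def test_record_invariants(self):
        with pytest.raises(ValueError, match="increase"):
            record([(2, 1, 0, True), (1, 1, 0, True)])
        with pytest.raises(ValueError, match="after death"):
            record([(1, 0, 0, False), (2, 1, 0, True)])
        with pytest.raises(ValueError, match="negative"):
            record([(1, -1, 0, True)])


class TestConsolidate:
    def _four_cat(self, col):
        return ContingencyTable(
            np.array(col).reshape(4, 1),
            ("1 MK", ">1 MK", "mixed", "proliferation only"), ("WT",),
        )

    def test_mk_no_mk(self):
        out = consolidate(self._four_cat([5, 3, 2, 10]), "MK/noMK")
        assert out.counts.ravel().tolist() == [10, 10]
        assert out.row_labels == ("MK", "no MK")

    def test_threeway(self):
        out = consolidate(self._four_cat([5, 3, 2, 10]), "threeway")
        assert out.counts.ravel().tolist() == [5, 3, 12]

    def test_column_totals_conserved(self):
        rng = np.random.default_rng(0)
        t = ContingencyTable(
            rng.integers(0, 20, size=(4, 3)),
            ("1 MK", ">1 MK", "mixed", "proliferation only"), ("a", "b", "c"),
        )
        for scheme in ("MK/noMK", "threeway"):
            out = consolidate(t, scheme)
            np.testing.assert_array_equal(out.counts.sum(axis=0),
                                          t.counts.sum(axis=0))

    def test_unknown_scheme(self):
        with pytest.raises(ValueError, match="scheme"):
            consolidate(self._four_cat([1, 1, 1, 1]), "five-way")


class TestFirstMkDay:
    def test_first_appearance(self):
        r = record([(1, 0, 1, True), (2, 1, 2, True), (3, 2, 1, True)])
        assert first_mk_day(r) == 2

    def test_never_returns_none(self):
        r = record([(1, 0, 1, True), (2, 0, 4, True)])
        assert first_mk_day(r) is None

    def test_appending_later_observations_never_decreases(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            days = sorted(rng.choice(range(1, 8), size=4, replace=False))
            obs = [(int(d), int(rng.integers(0, 3)), int(rng.integers(0, 3)), True)
                   for d in days]
            r_full = record(obs)
            r_prefix = record(obs[:2])
            full, pre = first_mk_day(r_full), first_mk_day(r_prefix)
            if pre is not None:
                assert full == pre
            elif full is not None:
                assert full > obs[1][0]


class TestMinDivisions:
    @pytest.mark.parametrize("n, expected", [(1, 0), (2, 1), (5, 3), (8, 3), (9, 4)])
    def test_values(self, n, expected):
        assert min_divisions(n) == expected

    def test_five_cells_need_three_divisions(self):
        # two divisions can yield at most 4 cells
        assert 2 ** 2 < 5 <= 2 ** 3
        assert min_divisions(5) == 3

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            min_divisions(0)


class TestSummaryTTests:
    def test_welch_matches_scipy_from_stats(self):
        a = SummaryStats("a", 10.0, 2.0, 8)
        b = SummaryStats("b", 12.5, 3.0, 10)
        t, df, p = welch_t_from_summary(a, b)
        t_s, p_s = stats.ttest_ind_from_stats(12.5, 3.0, 10, 10.0, 2.0, 8,
                                              equal_var=False)
        assert t == pytest.approx(float(t_s))
        assert p == pytest.approx(float(p_s))

    def test_identical_groups_null(self):
        a = SummaryStats("a", 5.0, 1.0, 6)
        t, df, p = welch_t_from_summary(a, a)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_student_variant_pooled_df(self):
        a = SummaryStats("a", 1.0, 0.5, 4)
        b = SummaryStats("b", 2.0, 0.7, 6)
        t, df, p = student_t_from_summary(a, b)
        assert df == 8

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n"):
            SummaryStats("a", 1.0, 0.1, 1)


class TestPercentDepletion:
    @pytest.mark.parametrize("ctrl, dep, expected",
                             [(17.1, 4.3, 74.85), (13.0, 4.1, 68.46),
                              (5.0, 5.0, 0.0)])
    def test_values(self, ctrl, dep, expected):
        assert percent_depletion(ctrl, dep) == pytest.approx(expected, abs=0.01)

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            percent_depletion(0.0, 1.0)


class TestChiSquare:
    def test_perfect_independence(self):
        t = ContingencyTable(np.full((2, 2), 10), ("r1", "r2"), ("c1", "c2"))
        stat, df, p = chi_square_test(t)
        assert stat == 0.0 and df == 1 and p == 1.0

    def test_matches_monte_carlo_multinomial_oracle(self):
        obs = np.array([[30, 10], [15, 25]])
        t = ContingencyTable(obs, ("r1", "r2"), ("c1", "c2"))
        stat, df, p = chi_square_test(t)
        # resampling oracle under independence with the observed margins
        rng = np.random.default_rng(2)
        n = obs.sum()
        pr = np.outer(obs.sum(axis=1), obs.sum(axis=0)).astype(float) / n ** 2
        draws = rng.multinomial(n, pr.ravel(), size=100_000).reshape(-1, 2, 2)
        # each draw's Pearson statistic uses its own margins
        r = draws.sum(axis=2, keepdims=True).astype(float)
        c = draws.sum(axis=1, keepdims=True).astype(float)
        exp = r * c / n
        with np.errstate(divide="ignore", invalid="ignore"):
            cells = np.where(exp > 0, (draws - exp) ** 2 / exp, 0.0)
        sim = cells.sum(axis=(1, 2))
        p_mc = (sim >= stat - 1e-9).mean()
        assert p == pytest.approx(p_mc, abs=3 * math.sqrt(p_mc * (1 - p_mc) / 1e5) + 1e-4)

    def test_four_by_two_supported(self):
        rng = np.random.default_rng(3)
        t = ContingencyTable(rng.integers(5, 40, size=(4, 2)),
                             ("1 MK", ">1 MK", "mixed", "prolif"), ("WT", "HOM"))
        stat, df, p = chi_square_test(t)
        assert df == 3 and 0 <= p <= 1

    def test_low_expected_warns(self):
        t = ContingencyTable(np.array([[1, 2], [2, 1]]), ("a", "b"), ("x", "y"))
        with pytest.warns(UserWarning, match="expected"):
            chi_square_test(t)

    def test_degenerate_margins_rejected(self):
        t = ContingencyTable(np.array([[0, 0], [3, 4]]), ("a", "b"), ("x", "y"))
        with pytest.raises(ValueError, match="margins"):
            chi_square_test(t)


def enumeration_fisher_p(table):
    """Oracle: enumerate all 2x2 tables with the observed margins."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(a_):
        return (comb(r1, a_, exact=True) * comb(r2, c1 - a_, exact=True)
                / comb(n, c1, exact=True))

    p_obs = prob(a)
    total = 0.0
    for a_ in range(max(0, c1 - r2), min(r1, c1) + 1):
        pr = prob(a_)
        if pr <= p_obs * (1 + 1e-12):
            total += pr
    return min(total, 1.0)


class TestFisherExact:
    def test_modal_table_p_one(self):
        t = ContingencyTable(np.array([[5, 5], [5, 5]]), ("a", "b"), ("x", "y"))
        assert fisher_exact(t) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_oracle_small_tables(self, seed):
        rng = np.random.default_rng(seed)
        c = rng.integers(0, 9, size=(2, 2))
        if c.sum() == 0:
            c[0, 0] = 1
        t = ContingencyTable(c, ("a", "b"), ("x", "y"))
        assert fisher_exact(t) == pytest.approx(enumeration_fisher_p(c), abs=1e-10)

    def test_strengthening_diagonal_never_increases_p(self):
        p_prev = 1.1
        for k in range(6):
            c = np.array([[5 + k, 5 - min(k, 5)], [5 - min(k, 5), 5 + k]])
            t = ContingencyTable(c, ("a", "b"), ("x", "y"))
            p = fisher_exact(t)
            assert p <= p_prev + 1e-12
            p_prev = p

    def test_non_integer_rejected(self):
        t = ContingencyTable(np.array([[1.5, 2.0], [2.0, 1.0]]), ("a", "b"), ("x", "y"))
        with pytest.raises(ValueError, match="integer"):
            fisher_exact(t)


class TestMannWhitney:
    def test_separated_triples_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0 and p == pytest.approx(0.1)

    def test_identical_samples_near_one(self):
        _, p = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert p >= 0.99

    def test_exact_equals_itertools_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.integers(0, 5, size=5).astype(float)
            y = rng.integers(0, 5, size=6).astype(float)
            _, p = mann_whitney_u(x, y)
            pooled = np.concatenate([x, y])
            ranks = stats.rankdata(pooled)
            mu = len(x) * len(y) / 2
            u_obs = ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2
            total = extreme = 0
            for comb_ in itertools.combinations(range(11), 5):
                u = ranks[list(comb_)].sum() - len(x) * (len(x) + 1) / 2
                total += 1
                extreme += abs(u - mu) >= abs(u_obs - mu) - 1e-9
            assert p == pytest.approx(extreme / total)

    def test_approximation_close_to_exact_at_n6(self):
        rng = np.random.default_rng(5)
        errs = []
        for _ in range(100):
            x = rng.normal(size=6)
            y = rng.normal(loc=rng.normal(scale=0.5), size=6)
            _, p_exact = mann_whitney_u(x, y)
            p_approx = stats.mannwhitneyu(x, y, alternative="two-sided",
                                          method="asymptotic")[1]
            errs.append(abs(p_exact - p_approx))
        assert np.mean(errs) < 0.01 and max(errs) < 0.03


class TestOverlapScore:
    @pytest.mark.parametrize(
        "flags, expected", [((True, True, True), 1.0),
                            ((True, False, False), 1 / 3),
                            ((True, True, False), 2 / 3)],
    )
    def test_scores(self, flags, expected):
        score, in_domain = overlap_score(*flags)
        assert score == pytest.approx(expected) and in_domain

    def test_zero_overlap_flagged_out_of_domain(self):
        score, in_domain = overlap_score(False, False, False)
        assert score == 0.0 and not in_domain


def test_clone_records_tsv_round_trip(tmp_path):
    import pandas as pd

    rows = []
    for well, cat in [("w1", (1, 0)), ("w2", (0, 3)), ("w3", (2, 2))]:
        for day in (1, 2):
            rows.append({"well": well, "population": "pMKP", "genotype": "WT",
                         "day": day, "n_large": cat[0] if day == 2 else 0,
                         "n_small": cat[1], "alive": True})
    pd.DataFrame(rows).to_csv(tmp_path / "clones.tsv", sep="\t", index=False)
    records = clones.read_clone_records(str(tmp_path / "clones.tsv"))
    assert len(records) == 3
    cats = {r.well: classify_clone(r, 2) for r in records}
    assert cats == {"w1": "1 MK", "w2": "proliferation only", "w3": "mixed"}
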