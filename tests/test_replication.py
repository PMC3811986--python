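import numpy as np
import pytest
from scipy import stats
from statsmodels.stats import meta_analysis as sm_meta

import tgscan as tg
from tgscan.genotype_io import Marker
from tgscan.replication import run_trio_test, woolf_se


def _trio_gm(fathers, mothers, children, n_markers=1):
    """Build a trio dataset from per-trio dosage lists."""
    n = len(fathers)
    calls = np.vstack(
        [
            np.asarray(fathers, dtype=np.int8).reshape(n, -1),
            np.asarray(mothers, dtype=np.int8).reshape(n, -1),
            np.asarray(children, dtype=np.int8).reshape(n, -1),
        ]
    )
    m = calls.shape[1]
    markers = [Marker(f"rs{j + 1}", "1", j + 1, "A", "G") for j in range(m)]
    ids = (
        [f"F{i}" for i in range(n)]
        + [f"M{i}" for i in range(n)]
        + [f"C{i}" for i in range(n)]
    )
    gm = tg.GenotypeMatrix(ids, markers, calls)
    trios = tg.TrioSet(
        [tg.Trio(f"F{i}", f"M{i}", f"C{i}", True, "rep1") for i in range(n)]
    )
    return gm, trios


def pearson_oracle(table):
    a, b, c, d = (float(x) for x in np.asarray(table).ravel())
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


class TestTdt:
    def test_balanced_transmissions_null(self):
        # father het; child het or hom-ref in equal numbers -> b = c
        gm, trios = _trio_gm([1] * 4, [0] * 4, [1, 1, 0, 0])
        res = tg.tdt(gm, trios, 0)
        assert res.chi_square == 0.0

    def test_closed_form_b10_c5(self):
        # 15 trios, one het father each; 10 transmit a1, 5 transmit a2
        gm, trios = _trio_gm([1] * 15, [0] * 15, [1] * 10 + [0] * 5)
        res = tg.tdt(gm, trios, 0)
        assert res.chi_square == pytest.approx(25 / 15)
        assert res.odds_ratio == pytest.approx(2.0)
        assert res.informative_n == 15

    def test_untestable_without_het_parents(self):
        gm, trios = _trio_gm([0, 2], [0, 2], [0, 2])
        assert not tg.tdt(gm, trios, 0).testable

    def test_null_type_one_error(self):
        cfg = tg.SimConfig(
            n_trios=200, n_markers=1500, seed=41, freq_range=(0.2, 0.5)
        )
        gm, trios, _ = tg.sim_trios(cfg)
        p = np.array(
            [tg.tdt(gm, trios, j).p_value for j in range(gm.n_markers)]
        )
        rej = (p[np.isfinite(p)] < 0.05).mean()
        half = 3.29 * np.sqrt(0.05 * 0.95 / np.isfinite(p).sum())
        assert 0.05 - half <= rej <= 0.05 + half


class TestParentFreq:
    def test_identical_frequencies_null(self):
        gm, trios = _trio_gm([0, 1, 2], [0, 1, 2], [0, 1, 2])
        res = tg.parent_freq_test(gm, trios, 0)
        assert res.chi_square == 0.0
        assert res.odds_ratio == pytest.approx(1.0)

    def test_fully_separated_parents(self):
        # 5 mothers dosage 2, 5 fathers dosage 0 -> table [[10,0],[0,10]]
        gm, trios = _trio_gm([0] * 5, [2] * 5, [1] * 5)
        res = tg.parent_freq_test(gm, trios, 0)
        assert res.chi_square == pytest.approx(20.0)

    def test_matches_tally_oracle(self, rng):
        for _ in range(30):
            n = 40
            f = rng.integers(0, 3, n)
            m = rng.integers(0, 3, n)
            c = np.minimum(rng.integers(0, 2, n) + rng.integers(0, 2, n), 2)
            gm, trios = _trio_gm(f, m, c)
            res = tg.parent_freq_test(gm, trios, 0)
            table = np.array(
                [
                    [m.sum(), 2 * n - m.sum()],
                    [f.sum(), 2 * n - f.sum()],
                ]
            )
            if not res.testable:
                continue
            assert res.chi_square == pytest.approx(
                pearson_oracle(table), rel=1e-10
            )


class TestTrioTe:
    def test_symmetric_parents_null_unmatched(self):
        # child het everywhere; mothers and fathers 8 hom / 2 het each
        mothers = [0] * 4 + [2] * 4 + [1] * 2
        fathers = [2] * 4 + [0] * 4 + [1] * 2
        gm, trios = _trio_gm(fathers, mothers, [1] * 10)
        res = tg.trio_te_test("offhet_rep", gm, trios, 0, matched=False)
        assert res.chi_square == pytest.approx(0.0)

    def test_hand_pearson_example_unmatched(self):
        # offhet table [[6,4],[2,8]] -> chi2 = 10/3, OR = 6
        mothers = [0, 0, 0, 2, 2, 2, 1, 1, 1, 1]
        fathers = [1, 1, 1, 1, 1, 1, 0, 2, 1, 1]
        gm, trios = _trio_gm(fathers, mothers, [1] * 10)
        res = tg.trio_te_test("offhet_rep", gm, trios, 0, matched=False)
        assert res.chi_square == pytest.approx(10 / 3)
        assert res.odds_ratio == pytest.approx(6.0)

    def test_matched_counts_discordant_pairs(self):
        # offhet, child het everywhere: discordant pairs only
        mothers = [0, 2, 1, 1, 0, 1]
        fathers = [1, 1, 0, 2, 2, 1]
        # indicator = parent homozygous: pairs (hom,het)x2, (het,hom)x2,
        # (hom,hom), (het,het) -> b = 2, c = 2
        gm, trios = _trio_gm(fathers, mothers, [1] * 6)
        res = tg.trio_te_test("offhet_rep", gm, trios, 0)
        assert res.kind == "pairs"
        assert res.table[0].tolist() == [2, 2]
        assert res.chi_square == pytest.approx(0.0)
        assert res.informative_n == 4

    def test_matched_closed_form(self):
        # diff analog: b = 6 mother-opposite, c = 2 father-opposite
        mothers = [0] * 6 + [1] * 2 + [1, 1]
        fathers = [1] * 6 + [0] * 2 + [1, 1]
        gm, trios = _trio_gm(fathers, mothers, [1] * 10)
        res = tg.trio_te_test("diff_rep", gm, trios, 0)
        assert res.chi_square == pytest.approx((6 - 2) ** 2 / 8)
        assert res.odds_ratio == pytest.approx(3.0)

    def test_diff_rep_opposite_genotype_meaning(self):
        # child het, mother het (same), father hom (opposite)
        gm, trios = _trio_gm([0, 0], [1, 2], [1, 1])
        res = tg.trio_te_test("diff_rep", gm, trios, 0, matched=False)
        # mothers: 1 same + 1 opposite; fathers: 2 opposite
        assert res.table.tolist() == [[1, 1], [2, 0]]

    @pytest.mark.parametrize(
        "test", ["offhet_rep", "mathet_rep", "diff_rep"]
    )
    def test_matches_tally_pearson_oracle(self, test, rng):
        for _ in range(40):
            n = 60
            f = rng.integers(0, 3, n)
            m = rng.integers(0, 3, n)
            c = rng.integers(0, 3, n)
            gm, trios = _trio_gm(f, m, c)
            res = run_trio_test(test, gm, trios, 0, matched=False)
            if test == "offhet_rep":
                keep = c == 1
                mcol, fcol = m[keep] != 1, f[keep] != 1
            elif test == "mathet_rep":
                keep = c != 1
                mcol, fcol = m[keep] == 1, f[keep] == 1
            else:
                mcol, fcol = m != c, f != c
            table = np.array(
                [
                    [mcol.sum(), mcol.size - mcol.sum()],
                    [fcol.sum(), fcol.size - fcol.sum()],
                ]
            )
            if min(table.sum(0).min(), table.sum(1).min()) == 0:
                assert not res.testable
                continue
            assert res.chi_square == pytest.approx(
                pearson_oracle(table), rel=1e-10
            )

    def test_null_trio_type_one_error_all_tests(self):
        cfg = tg.SimConfig(
            n_trios=200, n_markers=1500, seed=43, freq_range=(0.2, 0.5)
        )
        gm, trios, _ = tg.sim_trios(cfg)
        for test in ("parent_freq", "offhet_rep", "mathet_rep", "diff_rep"):
            p = np.array(
                [
                    run_trio_test(test, gm, trios, j).p_value
                    for j in range(gm.n_markers)
                ]
            )
            ok = np.isfinite(p)
            rej = (p[ok] < 0.05).mean()
            half = 3.29 * np.sqrt(0.05 * 0.95 / ok.sum())
            assert 0.05 - half <= rej <= 0.05 + half, (test, rej)

    def test_maternal_effect_favors_parent_freq_over_tdt(self, trio_data):
        gm, trios, truth = trio_data
        # planted maternal main effect at marker 0: the mother-vs-father
        # frequency test sees it, transmission to the child does not
        pf = tg.parent_freq_test(gm, trios, 0)
        td = tg.tdt(gm, trios, 0)
        assert pf.p_value < td.p_value
        assert pf.p_value < 0.01


class TestMeta:
    def test_two_identical_studies(self):
        res = tg.dl_meta([(0.5, 0.1), (0.5, 0.1)])
        assert res.tau_squared == 0.0
        assert res.pooled_log_or == pytest.approx(0.5)
        assert res.se == pytest.approx(0.1 / np.sqrt(2))

    def test_null_effects(self):
        res = tg.dl_meta([(0.0, 0.2), (0.0, 0.1), (0.0, 0.15)])
        assert res.pooled_log_or == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_heterogeneous_three_studies(self):
        ests = [(0.8, 0.1), (0.1, 0.1), (0.4, 0.2)]
        res = tg.dl_meta(ests)
        assert res.tau_squared > 0
        assert 0.1 < res.pooled_log_or < 0.8

    def test_matches_statsmodels_dl(self, rng):
        # statsmodels leaves tau2 untruncated; the conventional DL estimator
        # floors it at 0, so only positive-tau2 draws are comparable
        checked = 0
        while checked < 20:
            k = rng.integers(2, 6)
            eff = rng.normal(0.3, 0.6, k)
            se = rng.uniform(0.05, 0.3, k)
            sm = sm_meta.combine_effects(eff, se**2, method_re="dl")
            if float(sm.tau2) <= 0:
                continue
            res = tg.dl_meta(list(zip(eff, se)))
            assert res.tau_squared == pytest.approx(
                float(sm.tau2), abs=1e-10
            )
            want = float(sm.mean_effect_re)
            assert res.pooled_log_or == pytest.approx(want, rel=1e-9)
            checked += 1

    def test_single_dataset_pass_through(self):
        res = tg.dl_meta([(0.3, 0.1)])
        assert res.pooled_log_or == 0.3 and res.tau_squared == 0.0

    def test_fixed_effect_limit(self):
        # with tau2 = 0 the DL pooled estimate is inverse-variance weighting
        ests = [(0.2, 0.1), (0.2, 0.2)]
        res = tg.dl_meta(ests)
        w = np.array([100.0, 25.0])
        assert res.pooled_log_or == pytest.approx(0.2)
        assert res.se == pytest.approx(w.sum() ** -0.5)


class TestMergedTest:
    def test_merging_identical_tables_preserves_or(self):
        t = np.array([[6, 4], [2, 8]])
        single = tg.merged_test("diff_rep", [t], "rs1")
        double = tg.merged_test("diff_rep", [t, t], "rs1")
        assert double.odds_ratio == pytest.approx(single.odds_ratio)
        assert np.array_equal(double.table, 2 * t)

    def test_zero_cell_dataset_still_testable_after_merge(self):
        t_zero = np.array([[5, 0], [3, 2]])
        t_full = np.array([[4, 6], [7, 3]])
        res = tg.merged_test("offhet_rep", [t_zero, t_full], "rs1")
        assert res.testable
        assert res.chi_square == pytest.approx(
            pearson_oracle(t_zero + t_full)
        )


class TestWoolfSe:
    def test_no_zero_cells(self):
        t = np.array([[10, 20], [30, 40]])
        assert woolf_se(t) == pytest.approx(
            np.sqrt(1 / 10 + 1 / 20 + 1 / 30 + 1 / 40)
        )

    def test_haldane_correction_on_zero(self):
        t = np.array([[10, 0], [30, 40]])
        assert np.isfinite(woolf_se(t))


class TestBonferroniGate:
    def test_replicated(self):
        assert tg.bonferroni_gate(0.001, 0.4, 0.6, 40) == "replicated"

    def test_nominal_only(self):
        assert tg.bonferroni_gate(0.031, 0.4, 0.6, 40) == "nominal"

    def test_opposite_direction_never_replicates(self):
        assert tg.bonferroni_gate(1e-6, -0.4, 0.6, 40) == "no"

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            tg.bonferroni_gate(0.01, 0.1, 0.1, 0)
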