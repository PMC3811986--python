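from fractions import Fraction
from math import comb

import numpy as np
import pytest

import tgscan as tg
from tgscan.genotype_io import Marker
from tgscan.qc import (
    allele_freqs,
    apply_qc,
    call_rates,
    duo_mendel_errors,
    duo_relatedness,
    genotype_counts,
    hwe_exact_p,
    inbreeding_f,
)


def _gm(calls, prefix="s"):
    calls = np.asarray(calls, dtype=np.int8)
    markers = [
        Marker(f"rs{j}", "1", j + 1, "A", "G")
        for j in range(calls.shape[1])
    ]
    return tg.GenotypeMatrix(
        [f"{prefix}{i}" for i in range(calls.shape[0])], markers, calls
    )


def hwe_oracle(n_aa, n_ab, n_bb):
    """Exact-arithmetic enumeration of the HWE exact test."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    if n_a == 0 or n_a == 2 * n:
        return Fraction(1)
    weights = {}
    for k in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2):
        naa = (n_a - k) // 2
        nbb = n - naa - k
        w = Fraction(2**k)
        # multinomial n! / (naa! k! nbb!)
        w *= comb(n, naa) * comb(n - naa, k)
        weights[k] = w
    total = sum(weights.values())
    obs = weights[n_ab]
    return sum(w for w in weights.values() if w <= obs) / total


class TestCallRates:
    def test_no_missing_all_pass(self):
        gm = _gm(np.ones((4, 5)))
        sr, mr = call_rates(gm)
        assert (sr == 1.0).all() and (mr == 1.0).all()

    def test_boundary_semantics_at_97_percent(self):
        # 3 of 100 missing -> rate exactly 0.97: passes the marker rule
        # (>= 0.97) but fails the strict sample rule (> 0.97)
        calls = np.ones((1, 100), dtype=np.int8)
        calls[0, :3] = -1
        sr, _ = call_rates(_gm(calls))
        assert sr[0] == pytest.approx(0.97)
        assert not sr[0] > 0.97
        assert sr[0] >= 0.97

    def test_fully_missing_marker(self):
        calls = np.ones((3, 2), dtype=np.int8)
        calls[:, 1] = -1
        _, mr = call_rates(_gm(calls))
        assert mr[1] == 0.0


class TestMendelErrors:
    def test_opposite_homozygotes_flagged(self):
        gm_m = _gm([[0]], prefix="m")
        gm_c = _gm([[2]], prefix="c")
        duos = tg.DuoSet([tg.Duo("m0", "c0", "case")])
        per_marker, per_duo = duo_mendel_errors(gm_m, gm_c, duos)
        assert per_marker[0] == 1 and per_duo[0] == 1

    @pytest.mark.parametrize("c", [0, 1, 2])
    def test_het_mother_compatible_with_all(self, c):
        gm_m = _gm([[1]], prefix="m")
        gm_c = _gm([[c]], prefix="c")
        duos = tg.DuoSet([tg.Duo("m0", "c0", "case")])
        per_marker, _ = duo_mendel_errors(gm_m, gm_c, duos)
        assert per_marker[0] == 0

    def test_never_fires_on_simulated_transmissions(self):
        # generator guarantees Mendelian consistency; > 1e5 duo-markers
        cfg = tg.SimConfig(
            n_case_duos=100, n_control_duos=100, n_markers=600, seed=3
        )
        gm_m, gm_c, duos, _ = tg.sim_duos(cfg)
        per_marker, _ = duo_mendel_errors(gm_m, gm_c, duos)
        assert per_marker.sum() == 0


class TestHweExact:
    def test_monomorphic(self):
        assert hwe_exact_p(50, 0, 0) == 1.0

    def test_two_sample_case(self):
        # (1,0,1): weights 2 (k=0) and 4 (k=2) -> P = 2/6
        assert hwe_exact_p(1, 0, 1) == pytest.approx(1 / 3)

    def test_matches_exact_enumeration_small_totals(self):
        for n in range(1, 31):
            for naa in range(n + 1):
                for nab in range(n - naa + 1):
                    nbb = n - naa - nab
                    got = hwe_exact_p(naa, nab, nbb)
                    want = float(hwe_oracle(naa, nab, nbb))
                    assert got == pytest.approx(want, abs=1e-10), (
                        naa, nab, nbb,
                    )

    def test_conservative_under_null(self, rng):
        # exact test rejects at most ~alpha under HWE simulation
        n, alpha, reps = 100, 0.05, 2000
        q = 0.3
        g = rng.multinomial(
            n, [(1 - q) ** 2, 2 * q * (1 - q), q**2], size=reps
        )
        rej = sum(
            hwe_exact_p(aa, ab, bb) < alpha for bb, ab, aa in g
        )
        # binomial 99.9% upper bound around alpha
        bound = alpha + 3.29 * np.sqrt(alpha * (1 - alpha) / reps)
        assert rej / reps <= bound


class TestInbreedingF:
    def test_all_het_at_half_frequency(self):
        gm = _gm(np.ones((1, 10)))
        f = inbreeding_f(gm, "s0", np.full(10, 0.5))
        assert f == pytest.approx(-1.0)

    def test_all_homozygous(self):
        gm = _gm(np.full((1, 10), 2))
        f = inbreeding_f(gm, "s0", np.full(10, 0.5))
        assert f == pytest.approx(1.0)

    def test_mean_near_zero_under_hwe(self, rng):
        q = rng.uniform(0.1, 0.5, 2000)
        u = rng.random((50, 2000))
        p0 = (1 - q) ** 2
        calls = (
            (u >= p0).astype(np.int8)
            + (u >= p0 + 2 * q * (1 - q)).astype(np.int8)
        )
        gm = _gm(calls)
        fs = [inbreeding_f(gm, s, q) for s in gm.samples]
        assert abs(np.mean(fs)) < 0.02


class TestDuoRelatedness:
    def test_parent_offspring(self):
        cfg = tg.SimConfig(
            n_case_duos=5, n_control_duos=5, n_markers=2000, seed=5,
            freq_range=(0.2, 0.5),
        )
        gm_m, gm_c, duos, _ = tg.sim_duos(cfg)
        freqs = allele_freqs(gm_m)
        d = duos.records[0]
        ibs0, pihat = duo_relatedness(
            gm_m, gm_c, d.mother_id, d.child_id, freqs
        )
        assert ibs0 == 0.0  # Mendelian transmission forbids IBS0
        assert pihat == pytest.approx(0.5, abs=0.1)

    def test_unrelated_pair_ibs0_rate(self, rng):
        # opposite homozygotes between unrelated samples at q = 0.5:
        # 2 * q^2 * (1-q)^2 = 0.125
        n = 20000
        calls = rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25], size=(2, n))
        gm_m = _gm(calls[:1], prefix="m")
        gm_c = _gm(calls[1:], prefix="c")
        ibs0, pihat = duo_relatedness(
            gm_m, gm_c, "m0", "c0", np.full(n, 0.5)
        )
        assert ibs0 == pytest.approx(0.125, abs=0.01)
        assert pihat == pytest.approx(0.0, abs=0.05)

    def test_too_few_markers(self):
        gm_m = _gm([[1] * 50], prefix="m")
        gm_c = _gm([[1] * 50], prefix="c")
        with pytest.raises(ValueError, match="jointly typed"):
            duo_relatedness(gm_m, gm_c, "m0", "c0", np.full(50, 0.5))


class TestApplyQC:
    def test_clean_fixture_untouched(self, small_duo_data):
        gm_m, gm_c, duos, _ = small_duo_data
        m2, c2, d2, report = apply_qc(gm_m, gm_c, duos)
        assert m2.n_markers == gm_m.n_markers
        assert len(d2) == len(duos)
        assert report.excluded.empty

    def test_planted_mendel_marker_removed(self, small_duo_data):
        gm_m, gm_c, duos, _ = small_duo_data
        calls_c = gm_c.calls.copy()
        m_col = gm_m.calls[gm_m.sample_indices(duos.mothers), 5]
        c_rows = gm_c.sample_indices(duos.children)
        hom0 = np.flatnonzero(m_col == 0)[:11]
        calls_c[c_rows[hom0], 5] = 2  # 11 opposite-homozygote errors
        gm_c2 = tg.GenotypeMatrix(gm_c.samples, gm_c.markers, calls_c)
        _, _, _, report = apply_qc(gm_m, gm_c2, duos)
        removed = report.excluded.query("kind == 'marker'")
        assert list(removed.id) == ["rs6"]
        assert list(removed.reason) == ["mendel"]

    def test_boundary_ten_errors_retained(self, small_duo_data):
        gm_m, gm_c, duos, _ = small_duo_data
        calls_c = gm_c.calls.copy()
        m_col = gm_m.calls[gm_m.sample_indices(duos.mothers), 5]
        c_rows = gm_c.sample_indices(duos.children)
        hom0 = np.flatnonzero(m_col == 0)[:10]
        calls_c[c_rows[hom0], 5] = 2  # exactly 10: retained
        gm_c2 = tg.GenotypeMatrix(gm_c.samples, gm_c.markers, calls_c)
        m2, _, _, report = apply_qc(gm_m, gm_c2, duos)
        assert m2.n_markers == gm_m.n_markers

    def test_marker_failing_in_one_set_removed_from_both(
        self, small_duo_data
    ):
        gm_m, gm_c, duos, _ = small_duo_data
        calls_c = gm_c.calls.copy()
        calls_c[:, 7] = -1  # child-set call rate 0 at rs8
        gm_c2 = tg.GenotypeMatrix(gm_c.samples, gm_c.markers, calls_c)
        m2, c2, _, report = apply_qc(gm_m, gm_c2, duos)
        kept = {m.id for m in m2.markers}
        assert "rs8" not in kept
        assert {m.id for m in c2.markers} == kept

    def test_idempotent(self, small_duo_data):
        gm_m, gm_c, duos, _ = small_duo_data
        m1, c1, d1, _ = apply_qc(gm_m, gm_c, duos)
        m2, c2, d2, _ = apply_qc(m1, c1, d1)
        assert np.array_equal(m1.calls, m2.calls)
        assert np.array_equal(c1.calls, c2.calls)
        assert len(d1) == len(d2)
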