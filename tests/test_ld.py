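"""Composite LD: hand counts, exact dosage-moment identities, matrix
geometry, distances, and decay on synthetic admixed data."""

import warnings

import numpy as np
import pytest
from scipy import stats

from hzscan.errors import HzscanError, MonomorphicSiteError, UndefinedStatisticError
from hzscan.ld import (
    LDPair,
    composite_delta,
    composite_r2,
    ld_matrix,
    pair_distance,
    sliding_window_decay,
    square_matrix,
)
from hzscan.variants import call_sites, classify_and_condense
from hzscan.io import LocusAlignment, LocusAnnotation

from conftest import make_matrix, random_genotype_table


class TestCompositeDelta:
    def test_hand_counted_example(self):
        # A: AA, Aa, Aa, aa -> dosages 2,1,1,0 ; B: BB, Bb, bb, bb -> 2,1,0,0
        x = np.array([2.0, 1.0, 1.0, 0.0])
        y = np.array([2.0, 1.0, 0.0, 0.0])
        delta, pA, pB, DA, DB, n = composite_delta(x, y, min_pairs=4)
        assert delta == pytest.approx(0.25)
        assert (pA, pB) == (0.5, 0.375)
        assert n == 4
        # identity: half the (divisor-N) dosage covariance
        assert delta == pytest.approx(np.cov(x, y, bias=True)[0, 1] / 2, abs=1e-15)

    def test_independent_sites_in_hwe_population(self, rng):
        N = 500
        x = rng.binomial(2, 0.3, N).astype(float)
        y = rng.binomial(2, 0.6, N).astype(float)
        delta, pA, pB, *_ = composite_delta(x, y, min_pairs=10)
        se = np.sqrt(pA * (1 - pA) * pB * (1 - pB) / N)
        assert abs(delta) < 3 * se

    def test_self_pairing_is_half_variance(self, rng):
        x = rng.binomial(2, 0.4, 50).astype(float)
        delta, *_ = composite_delta(x, x, min_pairs=10)
        assert delta == pytest.approx(np.var(x) / 2, abs=1e-14)

    def test_monomorphic_site_raises(self):
        with pytest.raises(MonomorphicSiteError):
            composite_delta(np.zeros(20), np.ones(20), min_pairs=10)

    def test_min_pairs_enforced(self):
        with pytest.raises(HzscanError):
            composite_delta(np.array([1.0, 0.0]), np.array([0.0, 1.0]), min_pairs=10)


class TestCompositeR2:
    def test_hand_example_equals_squared_pearson(self):
        x = np.array([2.0, 1.0, 1.0, 0.0])
        y = np.array([2.0, 1.0, 0.0, 0.0])
        r2 = composite_r2(*composite_delta(x, y, min_pairs=4)[:5])
        assert r2 == pytest.approx(8 / 11, abs=1e-12)       # 0.72727...
        assert r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-12)

    def test_self_pair_unit(self, rng):
        x = rng.binomial(2, 0.5, 40).astype(float)
        r2 = composite_r2(*composite_delta(x, x, min_pairs=10)[:5])
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_complementary_dosages(self, rng):
        x = rng.binomial(2, 0.5, 40).astype(float)
        y = 2.0 - x
        delta, *rest = composite_delta(x, y, min_pairs=10)
        assert delta < 0
        assert composite_r2(delta, *rest[:4]) == pytest.approx(1.0, abs=1e-12)

    def test_zero_denominator_signalled(self):
        # all heterozygotes: pq + D_HW = 0
        x = np.ones(20)
        y = np.array([0.0, 2.0] * 10)
        with pytest.raises(UndefinedStatisticError):
            composite_r2(*composite_delta(x, y, min_pairs=10)[:5])

    def test_exact_identities_on_random_tables(self, rng):
        """Delta = cov/2 and r^2 = Pearson^2, with missing data, 200 tables."""
        for _ in range(200):
            dos = random_genotype_table(rng, int(rng.integers(12, 40)), 2,
                                        missing_rate=0.1)
            x, y = dos[:, 0], dos[:, 1]
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 10:
                continue
            try:
                delta, pA, pB, DA, DB, n = composite_delta(x, y, min_pairs=10)
            except (MonomorphicSiteError, HzscanError):
                continue
            xo, yo = x[ok], y[ok]
            assert delta == pytest.approx(np.cov(xo, yo, bias=True)[0, 1] / 2,
                                          abs=1e-12)
            try:
                r2 = composite_r2(delta, pA, pB, DA, DB)
            except UndefinedStatisticError:
                continue
            assert r2 == pytest.approx(np.corrcoef(xo, yo)[0, 1] ** 2, abs=1e-12)


class TestLdMatrix:
    def _two_locus_gm(self):
        # two D-interval loci at the Dna-J / Kinesin positions
        seqs1 = {f"i{k}": s for k, s in enumerate(
            ["AA", "AT", "TA", "TT", "AA", "AT", "TA", "TT", "AA", "TT", "WA", "AW"])}
        a1 = LocusAlignment("Dna-J", seqs1)
        g1 = call_sites(a1, LocusAnnotation("Dna-J", "D", 165_009, 2), min_alleles=2)
        seqs2 = {f"i{k}": s for k, s in enumerate(
            ["A", "T", "A", "T", "A", "T", "A", "T", "W", "W", "A", "T"])}
        a2 = LocusAlignment("Kinesin", seqs2)
        g2 = call_sites(a2, LocusAnnotation("Kinesin", "D", 299_335, 1), min_alleles=2)
        from hzscan.variants import concat_matrices
        gm = concat_matrices([g1, g2])
        classify_and_condense(gm.sites)
        return gm

    def test_pairs_and_symmetry(self):
        gm = self._two_locus_gm()
        pairs, omitted = ld_matrix(gm, min_pairs=5)
        assert len(pairs) + omitted == 3
        mat = square_matrix(gm, pairs, list(range(3)))
        arr = mat.to_numpy()
        assert np.allclose(np.diag(arr), 1.0)
        nz = ~np.isnan(arr)
        assert np.array_equal(nz, nz.T)
        assert np.allclose(arr[nz], arr.T[nz])

    def test_interval_distance_from_table_positions(self):
        gm = self._two_locus_gm()
        # Dna-J starts at 165,009 and Kinesin at 299,335 on the D interval
        assert pair_distance(gm, 0, 2) == 299_335 - 165_009  # = 134,326
        assert pair_distance(gm, 0, 1) == 1                  # within locus

    def test_cross_interval_pairs_unlinked(self):
        from hzscan.variants import concat_matrices

        seqs = {"i%d" % k: "AT"[k % 2] for k in range(12)}
        g_d = call_sites(LocusAlignment("dloc", seqs),
                         LocusAnnotation("dloc", "D", 100, 1), min_alleles=2)
        g_cr = call_sites(LocusAlignment("crloc", seqs),
                          LocusAnnotation("crloc", "Cr", 100, 1), min_alleles=2)
        g_u1 = call_sites(LocusAlignment("u1", seqs),
                          LocusAnnotation("u1", "unlinked", 1, 1), min_alleles=2)
        g_u2 = call_sites(LocusAlignment("u2", seqs),
                          LocusAnnotation("u2", "unlinked", 1, 1), min_alleles=2)
        gm = concat_matrices([g_d, g_cr, g_u1, g_u2])
        assert pair_distance(gm, 0, 1) is None     # D x Cr
        assert pair_distance(gm, 0, 2) is None     # D x unlinked
        assert pair_distance(gm, 2, 3) is None     # different unlinked loci
        assert pair_distance(gm, 2, 2) == 0        # within an unlinked locus

    def test_too_few_sites(self):
        gm = make_matrix({"i%d" % k: "AT"[k % 2] for k in range(12)})
        with pytest.raises(HzscanError):
            ld_matrix(gm)


class TestSlidingWindowDecay:
    def _pairs(self, dists, r2s):
        return [
            LDPair(i=k, j=k + 1, n_complete=20, delta=0.0, r2=r, distance_bp=d)
            for k, (d, r) in enumerate(zip(dists, r2s))
        ]

    def test_constant_r2_gives_flat_curve(self):
        pairs = self._pairs(range(100), [0.3] * 100)
        curve = sliding_window_decay(pairs, window=50)
        assert np.allclose(curve.mean_r2, 0.3)
        assert len(curve) == 51

    def test_window_larger_than_pairs_warns_single_point(self):
        pairs = self._pairs([10, 20, 30], [0.1, 0.2, 0.3])
        with pytest.warns(UserWarning):
            curve = sliding_window_decay(pairs, window=50)
        assert len(curve) == 1
        assert curve.mean_r2.iloc[0] == pytest.approx(0.2)

    def test_admixed_population_decay_is_decreasing(self, default_sim):
        """Windowed r^2 in the admixed population falls with distance."""
        from hzscan.pipeline import RunConfig, build_genotype_matrices
        from hzscan.variants import concat_matrices

        cfg = RunConfig()
        mats = build_genotype_matrices(default_sim.alignments,
                                       default_sim.annotations, cfg)
        gm = concat_matrices(list(mats.values()))
        adm = [s.individual_id for s in default_sim.samples
               if s.population == "admixed"]
        pairs, _ = ld_matrix(gm, individual_ids=adm, min_pairs=10)
        curve = sliding_window_decay(pairs, window=50)
        rho = stats.spearmanr(curve.distance_bp, curve.mean_r2)
        assert rho.statistic < 0
        assert rho.pvalue < 1e-6
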