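"""Association scan: phenotype coding with Cr dominance, the trend test
against the textbook Cochran-Armitage oracle, permutation calibration and
parameter recovery on synthetic data."""

import numpy as np
import pytest
from scipy import stats

from hzscan.assoc import association_scan, phenotype_scores, trend_test
from hzscan.errors import NoTestError
from hzscan.io import SampleMeta
from hzscan.simulate import CausalSite, SimConfig, simulate_hybrid_zone
from hzscan.pipeline import RunConfig, build_genotype_matrices
from hzscan.variants import concat_matrices


# ---------------------------------------------------------------- oracle --

def oracle_cochran_armitage(dosage: np.ndarray, outcome: np.ndarray) -> float:
    """Textbook Cochran-Armitage trend chi^2 from the 2x3 contingency table
    of binary outcome by genotype (scores 0, 1, 2)."""
    N = dosage.size
    table = np.zeros((2, 3))
    for d, o in zip(dosage.astype(int), outcome.astype(int)):
        table[o, d] += 1
    s = np.array([0.0, 1.0, 2.0])
    col = table.sum(axis=0)
    n1 = table[1].sum()
    n0 = table[0].sum()
    num = N * np.sum(s * table[1]) - n1 * np.sum(s * col)
    den = n1 * n0 * (N * np.sum(s**2 * col) - np.sum(s * col) ** 2)
    return float(N * num**2 / den) if den else np.nan


# ----------------------------------------------------------------- tests --

def make_sample(i, pop, d, cr, amb=False):
    return SampleMeta(f"x{i}", pop, d, cr, amb)


class TestPhenotypeScores:
    def test_dominance_coding(self):
        samples = [
            make_sample(0, "favorinus", 0.0, 0.0),
            make_sample(1, "admixed", 0.5, 1.0),
            make_sample(2, "emma", 1.0, 0.5, amb=True),   # emma on both axes
        ]
        assert phenotype_scores(samples, "D").tolist() == [0.0, 0.5, 1.0]
        assert phenotype_scores(samples, "Cr").tolist() == [0.0, 1.0, 0.5]

    def test_sensitivity_recode_flips_only_ambiguous(self):
        samples = [
            make_sample(0, "admixed", 0.0, 0.5),           # true hybrid, no flag
            make_sample(1, "emma", 1.0, 0.5, amb=True),
        ]
        recoded = phenotype_scores(samples, "Cr", cr_sensitivity_recode=True)
        assert recoded.tolist() == [0.5, 1.0]

    def test_unknown_axis(self):
        with pytest.raises(NoTestError):
            phenotype_scores([], "Sd")


class TestTrendTest:
    def test_perfect_trend_example(self):
        chi2, p = trend_test(
            np.array([2, 2, 1, 1, 0, 0], float),
            np.array([1, 1, 0.5, 0.5, 0, 0]),
            min_n=6,
        )
        assert chi2 == pytest.approx(6.0, abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(6.0, 1), abs=1e-12)
        assert p == pytest.approx(0.0143, abs=5e-4)

    def test_affine_phenotype_invariance(self, rng):
        dos = rng.binomial(2, 0.4, 40).astype(float)
        ph = rng.choice([0.0, 0.5, 1.0], 40)
        if np.all(ph == ph[0]) or np.all(dos == dos[0]):
            pytest.skip("degenerate draw")
        a = trend_test(dos, ph)
        b = trend_test(dos, 2 * ph)       # 0/0.5/1 -> 0/1/2
        assert a == pytest.approx(b, abs=1e-12)

    def test_constant_vectors_signal_no_test(self):
        with pytest.raises(NoTestError):
            trend_test(np.ones(20), np.linspace(0, 1, 20))
        with pytest.raises(NoTestError):
            trend_test(np.arange(20, dtype=float) % 3, np.full(20, 0.5))

    def test_cochran_armitage_equivalence(self, rng):
        """chi^2 = N r^2 equals the textbook CA statistic on 2x3 tables."""
        checked = 0
        while checked < 100:
            dos = rng.binomial(2, rng.uniform(0.2, 0.8), 60).astype(float)
            out = rng.binomial(1, 0.5, 60).astype(float)
            try:
                chi2, _ = trend_test(dos, out, min_n=10)
            except NoTestError:
                continue
            oracle = oracle_cochran_armitage(dos, out)
            assert chi2 == pytest.approx(oracle, abs=1e-10)
            checked += 1

    def test_permutation_type_one_error(self, default_sim):
        """Nominal 5% level holds under phenotype permutation."""
        rng = np.random.default_rng(77)
        cfg = RunConfig()
        mats = build_genotype_matrices(default_sim.alignments,
                                       default_sim.annotations, cfg)
        gm = concat_matrices(list(mats.values()))
        from hzscan.variants import dosage_vector

        # a common unlinked site, ordered as the sample table
        site_idx = next(
            i for i, s in enumerate(gm.sites)
            if s.interval == "unlinked" and s.status == "biallelic_informative"
            and 0.3 < s.maf < 0.5
        )
        order = [s.individual_id for s in default_sim.samples]
        dos = dosage_vector(gm, site_idx, gm.sites[site_idx].minor_alleles[0])
        dos = dos[gm.individual_indices(order)]
        ph = phenotype_scores(default_sim.samples, "D")
        hits = 0
        n_perm = 5000
        for _ in range(n_perm):
            _, p = trend_test(dos, rng.permutation(ph))
            hits += p < 0.05
        assert 0.04 <= hits / n_perm <= 0.06

    def test_chi2_null_tail_calibration(self, rng):
        """Permutation chi^2 upper tails match the 1-df chi-square at the
        levels that matter for testing (the permutation null is discrete, so
        only tail probabilities — not the full CDF — are expected to agree)."""
        dos = rng.binomial(2, 0.5, 76).astype(float)
        ph = np.repeat([0.0, 0.5, 1.0], [20, 42, 14])
        vals = np.array([
            trend_test(dos, rng.permutation(ph))[0] for _ in range(2000)
        ])
        for alpha in (0.10, 0.05, 0.01):
            crit = stats.chi2.isf(alpha, 1)
            emp = np.mean(vals > crit)
            se = np.sqrt(alpha * (1 - alpha) / vals.size)
            assert abs(emp - alpha) < 4 * se + 0.005


class TestAssociationScan:
    def test_causal_axis_peak_localizes(self, default_sim):
        cfg = RunConfig()
        mats = build_genotype_matrices(default_sim.alignments,
                                       default_sim.annotations, cfg)
        gm = concat_matrices(list(mats.values()))
        df = association_scan(gm, default_sim.samples)
        for axis, causal_coord in (("D", 310_000), ("Cr", 213_000)):
            sub = df[(df.phenotype_axis == axis) & (df.interval == axis)]
            top = sub.loc[sub.p.idxmin()]
            assert abs(top.interval_coordinate - causal_coord) < 100_000

    def test_bonferroni_threshold_recomputed_per_dataset(self, default_sim):
        cfg = RunConfig()
        mats = build_genotype_matrices(default_sim.alignments,
                                       default_sim.annotations, cfg)
        gm = concat_matrices(list(mats.values()))
        df = association_scan(gm, default_sim.samples, alpha=0.05)
        for axis, sub in df.groupby("phenotype_axis"):
            thr = 0.05 / len(sub)
            assert (sub.bonferroni_significant == (sub.p < thr)).all()

    def test_neutral_dataset_controls_family_wise_error(self):
        """No Bonferroni hits on most all-neutral replicates."""
        hits = 0
        for seed in range(8):
            cfg = SimConfig(seed=1000 + seed).neutral()
            res = simulate_hybrid_zone(cfg)
            mats = build_genotype_matrices(res.alignments, res.annotations,
                                           RunConfig())
            gm = concat_matrices(list(mats.values()))
            df = association_scan(gm, res.samples)
            hits += int(df.bonferroni_significant.any())
        assert hits <= 1

    def test_monotonic_power_in_frequency_difference(self):
        """Median causal-flank chi^2 never decreases with delta."""
        loci = tuple((f"L{k}", "D", 1 + 20_000 * k) for k in range(4))
        medians = []
        for delta in (0.2, 0.5, 0.9):
            tops = []
            for seed in range(12):
                cfg = SimConfig(
                    loci=loci,
                    causal_sites=(CausalSite("D", 35_000,
                                             f_p=(1 - delta) / 2,
                                             f_e=(1 + delta) / 2),),
                    seed=3000 + seed,
                )
                res = simulate_hybrid_zone(cfg)
                mats = build_genotype_matrices(res.alignments, res.annotations,
                                               RunConfig())
                gm = concat_matrices(list(mats.values()))
                df = association_scan(gm, res.samples)
                sub = df[df.phenotype_axis == "D"]
                tops.append(sub.chi2.max())
            medians.append(np.median(tops))
        assert medians[0] <= medians[1] <= medians[2]
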