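"""Composite LD between unphased genotypes and its decay with distance.

Burrows' composite Delta needs no phasing and no Hardy-Weinberg assumption:
it is computed directly from diploid genotype counts (and equals half the
dosage covariance).  Ancestry junctions in admixed individuals make r^2
fall with physical distance; a sliding-window average over 50 consecutive
site pairs shows the decay curve.
"""

from scipy import stats

from hzscan import SimConfig, simulate_hybrid_zone
from hzscan.ld import ld_matrix, sliding_window_decay
from hzscan.pipeline import RunConfig, build_genotype_matrices
from hzscan.variants import concat_matrices

res = simulate_hybrid_zone(SimConfig(seed=7))
mats = build_genotype_matrices(res.alignments, res.annotations, RunConfig())
gm = concat_matrices(list(mats.values()))

for pop in ("favorinus", "admixed"):
    ids = [s.individual_id for s in res.samples if s.population == pop]
    pairs, omitted = ld_matrix(gm, individual_ids=ids)
    curve = sliding_window_decay(pairs, window=50)
    rho = stats.spearmanr(curve.distance_bp, curve.mean_r2)
    near = curve[curve.distance_bp < 1_000].mean_r2.mean()
    far = curve[curve.distance_bp > 100_000].mean_r2.mean()
    print(f"{pop:10s}: {len(pairs)} pairs; windowed r^2 {near:.3f} at <1 kb "
          f"vs {far:.3f} at >100 kb; Spearman(distance, r^2) = {rho.statistic:+.2f}")
print("Admixture LD decays with distance (negative Spearman); the pure "
      "population shows only sampling noise at all distances.")
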