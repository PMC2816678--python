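"""Genotype-by-phenotype association with dominance-aware scoring.

Every common SNP is tested against both color-pattern axes with the
chi-squared linear trend test (chi^2 = N r^2 between allele dosage and the
0.0/0.5/1.0 phenotype score).  Bonferroni control uses the number of sites
actually tested.  The top hits should flank the causal coordinates.
"""

from hzscan import SimConfig, simulate_hybrid_zone, association_scan
from hzscan.pipeline import RunConfig, build_genotype_matrices
from hzscan.variants import concat_matrices

res = simulate_hybrid_zone(SimConfig(seed=7))
mats = build_genotype_matrices(res.alignments, res.annotations, RunConfig())
gm = concat_matrices(list(mats.values()))

df = association_scan(gm, res.samples, alpha=0.05)
for axis, causal in (("D", 310_000), ("Cr", 213_000)):
    sub = df[df.phenotype_axis == axis]
    n_sig = int(sub.bonferroni_significant.sum())
    top = sub.loc[sub.p.idxmin()]
    print(f"{axis} axis: {len(sub)} sites tested, {n_sig} Bonferroni-significant"
          f" (threshold 0.05/{len(sub)})")
    print(f"  strongest hit {top.site} at interval coordinate "
          f"{top.interval_coordinate:,} (-log10 p = {top.minus_log10_p:.1f}); "
          f"true causal site at {causal:,}")

# sensitivity of the dominance convention: recode ambiguous Cr 0.5 -> 1.0
df_alt = association_scan(gm, res.samples, cr_sensitivity_recode=True)
top = df[df.phenotype_axis == "Cr"].nsmallest(5, "p").set_index("site")
alt = df_alt[df_alt.phenotype_axis == "Cr"].set_index("site")
shift = (top.minus_log10_p - alt.loc[top.index].minus_log10_p).abs().max()
still_sig = alt.loc[top.index].bonferroni_significant.all()
print(f"recoding ambiguous Cr scores 0.5->1.0 shifts the top hits' -log10 p "
      f"by at most {shift:.2f}; all top hits stay Bonferroni-significant: "
      f"{still_sig}")
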