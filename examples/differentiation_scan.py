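"""F_ST between the pure races, per coding region and per SNP.

Hudson-style F_ST = 1 - Hw/Hb summarizes each locus; Weir-Cockerham theta
scores individual SNPs.  Loci flanking the causal color-pattern sites stand
out against the unlinked background — the hitchhiking footprint the scan is
designed to detect.
"""

from hzscan import SimConfig, simulate_hybrid_zone
from hzscan.pipeline import RunConfig, build_genotype_matrices, fst_tables, per_snp_fst

res = simulate_hybrid_zone(SimConfig(seed=7))
mats = build_genotype_matrices(res.alignments, res.annotations, RunConfig())
region, summary = fst_tables(mats, res.annotations, res.samples)
snp = per_snp_fst(mats, res.samples)

pure = region[(region.pop_a == "favorinus") & (region.pop_b == "emma")]
print("mean F_ST (favorinus vs emma) by interval:")
print(summary.to_string(index=False))
print("\ntop regions:")
print(pure.sort_values("fst", ascending=False).head(5)[
    ["locus", "interval", "fst"]].to_string(index=False))
print("\ntop per-SNP Weir-Cockerham estimates:")
print(snp.sort_values("wc_fst", ascending=False).head(5).to_string(index=False))
print("\nThe causal coordinates are D:310,000 and Cr:213,000 in this dataset;"
      "\nthe highest-F_ST loci flank them while unlinked loci sit near zero.")
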