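# Methods

## Scope and data model

`hzscan` analyzes per-locus multiple alignments of diploid consensus
sequences from a hybrid-zone transect. Heterozygous positions are encoded
with the six two-fold IUPAC codes (R, Y, S, W, K, M); three- and four-fold
codes are rejected rather than guessed, because a diploid carries at most
two alleles at a site. Gap `-` and `N` are both treated as missing data:
no indel model is applied, and indel characters cannot enter SNP
statistics. Coordinates are 1-based and inclusive throughout; a site's
interval coordinate is its locus' position along the interval plus its
offset minus one.

Unphased diploids contribute two alleles per site everywhere. This is
exact for π, S, Watterson's θ and Tajima's D (all functions of site
frequency spectra), and the LD and association statistics are chosen
specifically to be computable from unphased genotype counts.

## Site classification

Minor allele frequencies are computed over non-missing alleles. A column
needs `min_alleles` non-missing alleles (default 40, roughly half a
76-diploid panel) to be surveyed at all; surveyed monomorphic columns are
counted so π denominators reflect the sequence actually screened.
Classification uses an inclusive threshold (frequency ≥ 0.05 passes; the
comparator is a config knob since either convention is defensible):

* bi-allelic, common minor → informative;
* multi-allelic, ≥ 2 common minors → excluded from LD, kept for
  association;
* other multi-allelic → all non-major alleles merged into one minor
  class ("condensed"); informative if the merged class is common.

Merging all non-major alleles is the only parameter-free reading of
"condensing to bi-allelic": it preserves the total minor frequency and
never changes the major allele or the sampled allele count.

## Diversity and the coalescent null

Per-site π uses the unbiased estimator `n/(n−1)(1 − Σp²)` with the
per-site allele count, so missing data cost only information, not bias.
Tajima's D needs a single n for its constants; with missing data we take
the floor of the mean per-site allele count over segregating sites
(conservative rounding). Concatenation over a chromosome sums S, π and L
and recomputes D with the S-weighted mean n.

The neutrality test simulates the standard n-coalescent without
recombination or demography: exponential waiting times with rate
k(k−1)/2 in units of 2N generations, uniform pair merging, and mutations
as a Poisson process of rate θ/2 per unit branch length (per-branch
Poisson counts, which is exactly the multinomial allocation of a Poisson
total). θ per locus is the Watterson estimate from the observed data —
the conventional choice when the simulation is anchored to observed S.
Replicates with S = 0 have undefined D and are dropped, with the count
reported. The p-value doubles the smaller tail and caps at 1; this
construction is exactly uniform under a continuous null and reproduces
symmetric star-type significance calls. Two code paths implement the
model — an explicit per-tree simulator (which can emit haplotypes) and a
vectorized batch path used for the 10,000-replicate tests — and the suite
checks them against each other and against msprime by two-sample KS.

Loci here are short (~520 bp), so a no-recombination null is the natural
conservative choice; with intra-locus recombination the true D
distribution would be tighter and the test more liberal.

## Differentiation

Per region: Hudson-style `F_ST = 1 − H_w/H_b`, with the two populations
weighted equally in H_w regardless of sample size (sample-size weighting
is the main alternative; equal weights keep the estimator symmetric under
relabeling). Sites where either population has fewer than two alleles are
skipped in both sums. H_b = 0 (both populations monomorphic and
identical) is signaled as undefined, not returned as NaN. Per SNP:
Weir–Cockerham θ̂ from the (a, b, c) variance components on diploid
genotype counts, which uses observed heterozygosity and therefore does
not assume Hardy–Weinberg. Negative estimates are reported as computed —
clamping would bias the panmixia calibration.

## Composite LD

Pairs use pairwise-complete individuals (listwise deletion would discard
most of a sparse matrix); a pair needs `min_pairs = 10` complete
individuals or it is omitted and counted. Physical distance is defined
for pairs on the same mapped interval and for pairs within one locus;
cross-interval pairs and pairs spanning different unlinked loci carry an
unlinked flag and stay out of decay curves. The sliding window averages
50 consecutive site *pairs* ordered by distance (averaging over pairs
makes "plotted by distance" well-defined; a per-SNP window would mix
distances).

## Association

Phenotypes are scored 0.0 / 0.5 / 1.0 per axis. The Cr axis carries the
dominance rule: individuals emma-type on both axes cannot be Cr-genotyped
from phenotype and are coded 0.5 with an ambiguity flag; a sensitivity
recode (0.5 → 1.0 for flagged individuals) is available and its effect on
the top hits is reported by `examples/association_scan.py`. The trend
statistic N·r² is referred to the 1-df chi-square; for multi-allelic
sites each common allele is dosage-tested and the best p is multiplied by
the number of alleles tested (within-site Bonferroni), keeping every test
at 1 df while controlling site-level error. The genome-wide Bonferroni
threshold divides α by the number of sites actually tested per axis,
recomputed per dataset. No population-structure correction is applied —
the design relies on admixture having shuffled backgrounds, and the
all-neutral calibration below measures the residual family-wise error.

## The synthetic hybrid zone

The generator emulates the study design the pipeline targets: 20 + 42 +
14 diploids; 520-bp coding fragments at fixed positions across a ~1.4 Mb
D interval (12 loci) and a ~250 kb Cr interval (10 loci) plus three
unlinked loci; an informative SNP every ~30 bp and a rare SNP every
~12 bp in expectation.

* **Ancestry.** Each admixed haplotype is a Markov mosaic: first-site
  ancestry Bernoulli(hᵢ) in the individual's hybrid index
  hᵢ ~ Beta(1, 1), junctions Poisson with rate ρ = 10⁻⁵/bp, each junction
  redrawing from Bernoulli(hᵢ). This ancestry-junction model (rather than
  a full coalescent with recombination) has a closed-form LD decay —
  `r²(d) = ((2E[h(1−h)]e^{−ρd} + 4Var h)/(2E[h(1−h)] + 4Var h))²` — that
  the tests verify by Monte Carlo, and it directly encodes the
  population-sieve picture of ongoing admixture. Pure individuals carry
  their own ancestry except that with probability 0.05 one haplotype is a
  whole-interval migrant ("largely pure" field samples).
* **Frequencies.** Neutral sites share one frequency in both parental
  backgrounds, drawn from Beta(0.8, 0.8) truncated to [0.05, 0.95] for
  common sites and Uniform(0.005, 0.045) minor frequencies for rare
  sites. Sites flanking a causal coordinate acquire a background
  difference δ(d) = (f_E − f_P)·e^{−d/L_sel} (L_sel = 100 kb), scaled by
  2·min(p₀, 1−p₀) and symmetric about the base frequency — so the
  hitchhiking footprint creates differentiation without distorting the
  site-frequency spectrum. Causal sites themselves sit at 0.02 / 0.98:
  strongly differentiated, but a fixed sample difference is the exception
  at these sample sizes.
* **Phenotypes.** Noiseless functions of the causal genotypes: D
  codominant (score = emma-allele dosage / 2), Cr dominant (any emma
  allele removes the bar), with the observational ambiguity rule above.
  The all-neutral null configuration keeps the causal sites polymorphic
  but sets f_P = f_E, so phenotypes segregate yet are independent of
  every genotyped site.

What the generator does **not** emulate: within-locus gametic LD beyond
ancestry (alleles are drawn independently per site given ancestry, i.e.
free intra-locus recombination), genealogical correlation among sites of
a locus, sequencing error, indels, and multi-allelic SNPs. Consequences:
short-range LD inside pure populations is pure sampling noise (real data
show within-gene LD), and locus-level Tajima's D is shrunk toward zero
relative to a linked-genealogy reality, so the coalescent neutrality test
rarely rejects on synthetic data. Passing tests therefore demonstrate
estimator correctness and the admixture/hitchhiking signal chain, not a
full likeness of field data.

## Problem sizes and numerics

Default analysis sizes: 10,000 coalescent replicates per locus ×
population; the full default pipeline (25 loci, ~480 informative SNPs,
four LD panels of ~120k pairs each) completes in well under a minute on
one core. Calibration checks in the acceptance suite use n = 28, θ = 10
at 10,000 replicates, 500 nested uniformity tests at 2,000 replicates,
200 panmictic F_ST replicates, 50 recovery replicates and 100 all-neutral
replicates. Oracle tolerances are 1e-10 (Tajima constants vs exact
rationals; trend vs Cochran–Armitage), 1e-12 (composite LD vs dosage
moments) and 1e-8 (Weir–Cockerham vs an independently coded nested-ANOVA
evaluation). Ties in major-allele selection break deterministically by
base order; all randomness flows from named `numpy` generators seeded in
the run config, and per-stage results are byte-identical across reruns
with the same seed (timings are deliberately kept out of the manifest).

## Known limitations

No VCF ingestion (FASTA consensus in, TSV out); no haplotype-EM gametic
D; no demographic or recombining nulls; no FDR alternative to Bonferroni
(hook only); the multi-allelic association scheme (per-allele tests with
within-site Bonferroni) is one defensible reading among several.
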