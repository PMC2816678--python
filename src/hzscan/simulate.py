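"""Synthetic hybrid-zone data generator with ground truth.

Emulates a transect across a narrow butterfly hybrid zone: two phenotypically
pure parental populations and an admixed center, surveyed at ~520 bp coding
fragments spaced along two color-pattern intervals (D and Cr) plus unlinked
control loci.  Each admixed haplotype is an ancestry mosaic: the ancestry at
the first site is Bernoulli(h_i) in the individual's hybrid index h_i, and
junctions along the interval arrive as a Poisson process of rate ``rho`` per
bp, each redrawing the ancestry from Bernoulli(h_i).  Alleles are drawn from
ancestry-specific site frequencies.  Neutral sites share one frequency in
both parental backgrounds; sites flanking a causal coordinate acquire a
background-specific frequency difference delta(d) that decays as
exp(-d / l_sel) with distance d (an exponential hitchhiking footprint of
scale ``l_sel``), scaled by the difference the site's base frequency can
accommodate and symmetric about it, so the site-frequency spectrum away
from the causal sites is untouched.  Causal sites are differentiated but not
fixed (default parental frequencies 0.02 vs 0.98).

Phenotypes are noiseless functions of the causal genotypes: the D axis is
codominant (score = dosage of the emma allele / 2), the Cr axis is dominant
(any emma allele removes the yellow hindwing bar), and emma-type individuals
on both axes get the observational ambiguity code cr_score = 0.5.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import HzscanError
from .io import (
    LocusAlignment,
    LocusAnnotation,
    SampleMeta,
    write_locus_alignment,
    write_locus_table,
    write_sample_table,
)

_REV_IUPAC = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}

#: Default locus layout: name, interval, 1-based position along the interval.
#: Positions mirror the study design this generator emulates (520 bp coding
#: fragments spaced across a ~1.4 Mb D interval, a ~250 kb Cr interval, and
#: three unlinked control loci).
DEFAULT_LOCI: tuple[tuple[str, str, int], ...] = (
    ("Cyta", "D", 91_726),
    ("Dna-J", "D", 165_009),
    ("3P", "D", 237_736),
    ("Slu7", "D", 283_611),
    ("Kinesin", "D", 299_335),
    ("GPCR", "D", 309_248),
    ("Abh", "D", 322_422),
    ("VanGogh", "D", 513_028),
    ("Gn6", "D", 517_433),
    ("THAP", "D", 552_580),
    ("Gn18", "D", 579_264),
    ("Has1", "D", 1_442_402),
    ("Forkhead", "Cr", 1),
    ("B9", "Cr", 54_672),
    ("Treh-A", "Cr", 66_809),
    ("Treh-B", "Cr", 67_583),
    ("BESS", "Cr", 104_621),
    ("WD40", "Cr", 130_877),
    ("Unkempt", "Cr", 177_423),
    ("recQ", "Cr", 190_761),
    ("Invertase", "Cr", 201_977),
    ("LRR", "Cr", 249_391),
    ("Caspase", "unlinked", 1),
    ("SUZ12", "unlinked", 1),
    ("Wingless", "unlinked", 1),
)


@dataclass(frozen=True)
class CausalSite:
    """A selected site: interval, coordinate and parental allele frequencies."""

    interval: str
    coordinate: int
    f_p: float = 0.02     # emma-allele frequency in the favorinus background
    f_e: float = 0.98     # ... in the emma background

    def __post_init__(self) -> None:
        if not (0.0 < self.f_p < 1.0 and 0.0 < self.f_e < 1.0):
            raise HzscanError("causal frequencies must lie in (0, 1)")


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic hybrid zone."""

    n_favorinus: int = 20
    n_admixed: int = 42
    n_emma: int = 14
    loci: tuple[tuple[str, str, int], ...] = DEFAULT_LOCI
    locus_length: int = 520
    snp_spacing: int = 30        # expected bp between common (informative) SNPs
    rare_spacing: int = 12       # expected bp between rare (MAF<0.05) SNPs
    causal_sites: tuple[CausalSite, ...] = (
        CausalSite("D", 310_000),
        CausalSite("Cr", 213_000),
    )
    l_sel: float = 100_000.0     # hitchhiking footprint scale (bp)
    rho: float = 1e-5            # ancestry-junction rate per bp per haplotype
    hybrid_index_beta: tuple[float, float] = (1.0, 1.0)
    contamination_eps: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_favorinus, self.n_admixed, self.n_emma) < 1:
            raise HzscanError("population sizes must be positive")
        if self.rho < 0:
            raise HzscanError("rho must be non-negative")
        if not 0.0 <= self.contamination_eps < 1.0:
            raise HzscanError("contamination_eps must lie in [0, 1)")
        if self.l_sel <= 0:
            raise HzscanError("l_sel must be positive")

    def neutral(self) -> "SimConfig":
        """All-neutral null: causal frequency difference set to zero.

        Phenotypes still segregate (the causal alleles are polymorphic at
        frequency 0.5 in both parental backgrounds) but are independent of
        every genotyped site, so any association hit is a false positive.
        """
        return replace(
            self,
            causal_sites=tuple(
                replace(c, f_p=0.5, f_e=0.5) for c in self.causal_sites
            ),
        )


@dataclass
class SimTruth:
    """Generator ground truth for recovery tests."""

    hybrid_index: dict[str, float]
    causal_genotypes: dict[str, dict[str, int]]      # interval -> id -> dosage
    site_frequencies: dict[tuple[str, int], tuple[float, float]]  # (locus, offset) -> (p_P, p_E)
    ancestry: dict[str, np.ndarray] = field(default_factory=dict)  # group -> (n_ind, 2, n_coords)
    ancestry_coords: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class SimResult:
    alignments: dict[str, LocusAlignment]
    samples: list[SampleMeta]
    annotations: list[LocusAnnotation]
    truth: SimTruth

    def write(self, out_dir: str | os.PathLike) -> None:
        os.makedirs(out_dir, exist_ok=True)
        for name, aln in self.alignments.items():
            write_locus_alignment(aln, os.path.join(out_dir, f"{name}.fasta"))
        write_sample_table(self.samples, os.path.join(out_dir, "samples.tsv"))
        write_locus_table(self.annotations, os.path.join(out_dir, "loci.tsv"))


def _draw_site_positions(rng: np.random.Generator, length: int, spacing: int) -> np.ndarray:
    """Bernoulli(1/spacing) per bp -> expected one site every ``spacing`` bp."""
    return np.nonzero(rng.random(length) < 1.0 / spacing)[0]


def _ancestry_walk(
    rng: np.random.Generator,
    h: np.ndarray,
    coords: np.ndarray,
    rho: float,
) -> np.ndarray:
    """Markov ancestry along sorted coords for haplotypes with indices h.

    Returns a (len(h), len(coords)) 0/1 array (1 = emma ancestry).  Between
    consecutive coordinates the ancestry is redrawn from Bernoulli(h) with
    probability 1 - exp(-rho * gap); multiple junctions collapse to a single
    redraw by the Markov property.
    """
    H, C = h.size, coords.size
    anc = np.empty((H, C), dtype=np.int8)
    anc[:, 0] = rng.random(H) < h
    gaps = np.diff(coords)
    p_switch = 1.0 - np.exp(-rho * gaps)
    for c in range(1, C):
        redraw = rng.random(H) < p_switch[c - 1]
        new = rng.random(H) < h
        anc[:, c] = np.where(redraw, new, anc[:, c - 1])
    return anc


def simulate_hybrid_zone(cfg: SimConfig) -> SimResult:
    """Generate one synthetic hybrid-zone dataset with ground truth."""
    rng = np.random.default_rng(cfg.seed)

    ids = (
        [f"fav{i + 1:03d}" for i in range(cfg.n_favorinus)]
        + [f"adm{i + 1:03d}" for i in range(cfg.n_admixed)]
        + [f"emm{i + 1:03d}" for i in range(cfg.n_emma)]
    )
    pops = (
        ["favorinus"] * cfg.n_favorinus
        + ["admixed"] * cfg.n_admixed
        + ["emma"] * cfg.n_emma
    )
    n_ind = len(ids)
    a, b = cfg.hybrid_index_beta
    hybrid_index = np.where(
        np.array(pops) == "favorinus",
        0.0,
        np.where(np.array(pops) == "emma", 1.0, np.nan),
    )
    hybrid_index[np.isnan(hybrid_index)] = rng.beta(a, b, size=cfg.n_admixed)

    annotations = [
        LocusAnnotation(name, interval, pos, cfg.locus_length)
        for name, interval, pos in cfg.loci
    ]
    causal_by_interval = {c.interval: c for c in cfg.causal_sites}

    # ancestry groups: each mapped interval is one linkage block; each
    # unlinked locus segregates independently
    groups: dict[str, list[LocusAnnotation]] = {}
    for ann in annotations:
        key = ann.interval if ann.interval != "unlinked" else f"unlinked:{ann.locus_name}"
        groups.setdefault(key, []).append(ann)

    alignments: dict[str, LocusAlignment] = {}
    site_frequencies: dict[tuple[str, int], tuple[float, float]] = {}
    causal_genotypes: dict[str, dict[str, int]] = {}
    truth_anc: dict[str, np.ndarray] = {}
    truth_coords: dict[str, np.ndarray] = {}

    for key, group in groups.items():
        interval = group[0].interval
        causal = causal_by_interval.get(interval)

        # -- site layout and ancestry-specific frequencies -------------------
        locus_sites: dict[str, np.ndarray] = {}
        coords_list = []
        pP_list, pE_list = [], []
        for ann in group:
            common = _draw_site_positions(rng, ann.length, cfg.snp_spacing)
            rare = _draw_site_positions(rng, ann.length, cfg.rare_spacing)
            rare = rare[~np.isin(rare, common)]
            offsets = np.sort(np.concatenate([common, rare]))
            locus_sites[ann.locus_name] = offsets
            is_common = np.isin(offsets, common)
            p0 = np.empty(offsets.size)
            # common sites: broad U-shaped frequency spectrum kept informative
            n_c = int(is_common.sum())
            draw = rng.beta(0.8, 0.8, size=4 * n_c + 8)
            draw = draw[(draw >= 0.05) & (draw <= 0.95)]
            while draw.size < n_c:
                extra = rng.beta(0.8, 0.8, size=4 * n_c + 8)
                draw = np.concatenate([draw, extra[(extra >= 0.05) & (extra <= 0.95)]])
            p0[is_common] = draw[:n_c]
            # rare sites: minor frequency below the informative threshold
            n_r = int((~is_common).sum())
            minor = rng.uniform(0.005, 0.045, size=n_r)
            flip = rng.random(n_r) < 0.5
            p0[~is_common] = np.where(flip, minor, 1.0 - minor)

            coord = ann.interval_position + offsets  # offsets 0-based here
            if causal is not None:
                # hitchhiking footprint: the parental backgrounds differ by
                # delta(d) = (f_e - f_p) * exp(-d / l_sel), scaled by what the
                # site's base frequency can accommodate (a nearly fixed site
                # cannot be strongly differentiated); the mean frequency and
                # hence the MAF class of the site is preserved
                d = np.abs(coord - causal.coordinate)
                delta = (causal.f_e - causal.f_p) * np.exp(-d / cfg.l_sel)
                sign = np.where(rng.random(offsets.size) < 0.5, 1.0, -1.0)
                half = 0.5 * delta * 2.0 * np.minimum(p0, 1.0 - p0) * sign
                pP = np.clip(p0 - half, 0.001, 0.999)
                pE = np.clip(p0 + half, 0.001, 0.999)
            else:
                pP = p0.copy()
                pE = p0.copy()
            for off, fp, fe in zip(offsets, pP, pE):
                site_frequencies[(ann.locus_name, int(off) + 1)] = (float(fp), float(fe))
            coords_list.append(coord)
            pP_list.append(pP)
            pE_list.append(pE)

        coords = np.concatenate(coords_list)
        pP = np.concatenate(pP_list)
        pE = np.concatenate(pE_list)
        if causal is not None:
            coords = np.append(coords, causal.coordinate)
            pP = np.append(pP, causal.f_p)
            pE = np.append(pE, causal.f_e)
        order = np.argsort(coords, kind="stable")
        coords, pP, pE = coords[order], pP[order], pE[order]
        if np.unique(coords).size != coords.size:
            raise HzscanError(
                f"{key}: coordinate collision (causal site inside a sampled locus?)"
            )

        # -- haplotype ancestries -------------------------------------------
        # two haplotypes per individual, flattened (ind-major)
        h_hap = np.repeat(hybrid_index, 2)
        anc = _ancestry_walk(rng, h_hap, coords, cfg.rho)
        # pure individuals: constant own ancestry, except rare migrant haplotypes
        pop_hap = np.repeat(pops, 2)
        for own, label in ((0, "favorinus"), (1, "emma")):
            mask = pop_hap == label
            anc[mask, :] = own
        migrant = rng.random(n_ind) < cfg.contamination_eps
        which_hap = rng.integers(0, 2, size=n_ind)
        for i in range(n_ind):
            if pops[i] == "admixed" or not migrant[i]:
                continue
            other = 1 - (0 if pops[i] == "favorinus" else 1)
            anc[2 * i + which_hap[i], :] = other

        truth_anc[key] = anc.reshape(n_ind, 2, coords.size)
        truth_coords[key] = coords

        # -- alleles ---------------------------------------------------------
        p_hap = np.where(anc == 1, pE[None, :], pP[None, :])
        alt = (rng.random(p_hap.shape) < p_hap).astype(np.int8)

        if causal is not None:
            causal_col = int(np.nonzero(coords == causal.coordinate)[0][0])
            dosage = alt[:, causal_col].reshape(n_ind, 2).sum(axis=1)
            causal_genotypes[interval] = {ids[i]: int(dosage[i]) for i in range(n_ind)}

        # -- emit per-locus diploid consensus sequences ----------------------
        col_of = {int(c): k for k, c in enumerate(coords)}
        for ann in group:
            offsets = locus_sites[ann.locus_name]
            bases = rng.choice(list("ACGT"), size=ann.length)
            seqs = {}
            # per site: pick ref/alt bases (distinct), deterministic given rng
            site_cols = [col_of[int(ann.interval_position + off)] for off in offsets]
            ref_alt = []
            for off in offsets:
                ref = bases[off]
                others = [x for x in "ACGT" if x != ref]
                ref_alt.append((ref, others[rng.integers(0, 3)]))
            for i, ind in enumerate(ids):
                seq = bases.copy()
                for (off, (ref, altb), col) in zip(offsets, ref_alt, site_cols):
                    a1 = altb if alt[2 * i, col] else ref
                    a2 = altb if alt[2 * i + 1, col] else ref
                    seq[off] = a1 if a1 == a2 else _REV_IUPAC[frozenset((a1, a2))]
                seqs[ind] = "".join(seq)
            alignments[ann.locus_name] = LocusAlignment(ann.locus_name, seqs)

    # -- phenotypes ----------------------------------------------------------
    d_dosage = causal_genotypes.get("D", {i: 0 for i in ids})
    cr_dosage = causal_genotypes.get("Cr", {i: 0 for i in ids})
    samples = []
    for ind in ids:
        d_score = d_dosage[ind] / 2.0
        cr = cr_dosage[ind]
        cr_score = cr / 2.0
        ambiguous = False
        if d_score == 1.0 and cr >= 1:
            # emma-type on both axes: Cr genotype hidden by dominance
            cr_score = 0.5
            ambiguous = True
        samples.append(
            SampleMeta(
                individual_id=ind,
                population=pops[ids.index(ind)],
                d_score=d_score,
                cr_score=cr_score,
                cr_dominant_ambiguous=ambiguous,
            )
        )

    truth = SimTruth(
        hybrid_index={ids[i]: float(hybrid_index[i]) for i in range(n_ind)},
        causal_genotypes=causal_genotypes,
        site_frequencies=site_frequencies,
        ancestry=truth_anc,
        ancestry_coords=truth_coords,
    )
    return SimResult(alignments, samples, annotations, truth)


def expected_ancestry_r2(cfg: SimConfig, d: float) -> float:
    """Model-implied squared correlation of ancestry dosage at distance d.

    For two purely ancestry-determined markers in the admixed population,
    with E = E[h(1-h)] and V = Var(h) under the hybrid-index Beta prior:

        Cov = 2 E exp(-rho d) + 4 V,   Var = 2 E + 4 V,
        r^2(d) = (Cov / Var)^2

    The exp(-2 rho d) junction decay is floored by the between-individual
    admixture LD set by Var(h).  Used only as a closed-form check of the
    generator.
    """
    if d < 0:
        raise HzscanError("distance must be non-negative")
    a, b = cfg.hybrid_index_beta
    s = a + b
    ehq = a * b / (s * (s + 1))           # E[h(1-h)]
    var_h = a * b / (s**2 * (s + 1))      # Var(h)
    cov = 2 * ehq * np.exp(-cfg.rho * d) + 4 * var_h
    var = 2 * ehq + 4 * var_h
    return float((cov / var) ** 2)
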