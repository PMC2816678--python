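"""From alignments to a genotype matrix: site calling, MAF classification,
multi-allelic condensing and per-individual allele dosages.

Unphased diploid consensus sequences are decoded into unordered allele
pairs; gap ``-`` and ``N`` become missing data.  Polymorphic sites are
classified by minor allele frequency: sites with MAF < 0.05 are too rare to
be informative, multi-allelic sites whose non-major alleles are all rare are
condensed to bi-allelic by merging every non-major allele into one minor
class, and multi-allelic sites with two or more common minor alleles are
excluded from LD (but kept for association testing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import HzscanError, MetadataError
from .io import LocusAlignment, LocusAnnotation

#: Two-fold IUPAC ambiguity codes -> unordered allele pair.
IUPAC_HET = {
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}

#: Sentinel allele naming the merged minor class of a condensed site.
MERGED_MINOR = "*"

STATUS_RARE = "rare"
STATUS_BIALLELIC = "biallelic_informative"
STATUS_CONDENSED = "condensed_biallelic"
STATUS_EXCLUDED = "multiallelic_excluded"

#: Statuses whose sites enter the composite-LD analysis.
LD_STATUSES = (STATUS_BIALLELIC, STATUS_CONDENSED)
#: Statuses whose sites enter the association scan (common sites only).
ASSOC_STATUSES = (STATUS_BIALLELIC, STATUS_CONDENSED, STATUS_EXCLUDED)


def decode_base(ch: str) -> tuple[str, str] | None:
    """Decode one consensus character into an allele pair, or None if missing."""
    if ch in "ACGT":
        return (ch, ch)
    if ch in IUPAC_HET:
        return IUPAC_HET[ch]
    if ch in "-N":
        return None
    raise MetadataError(f"cannot decode consensus character {ch!r}")


@dataclass
class SiteRecord:
    """One polymorphic site and its allele bookkeeping."""

    locus_name: str
    offset: int                      # 1-based bp within the locus
    interval: str
    interval_coordinate: int         # locus interval_position + offset - 1
    allele_counts: dict[str, int]
    n_alleles_sampled: int
    maf: float                       # frequency of the most common minor allele
    status: str | None = None
    major_allele: str = field(init=False)
    minor_class: tuple[str, ...] | None = None  # alleles merged when condensed

    def __post_init__(self) -> None:
        assert sum(self.allele_counts.values()) == self.n_alleles_sampled
        # deterministic tie-break: higher count first, then base order
        self.major_allele = max(
            sorted(self.allele_counts), key=lambda a: self.allele_counts[a]
        )

    @property
    def minor_alleles(self) -> list[str]:
        return sorted(a for a in self.allele_counts if a != self.major_allele)

    def allele_frequency(self, allele: str) -> float:
        if allele == MERGED_MINOR:
            count = sum(self.allele_counts[a] for a in self.minor_alleles)
        else:
            count = self.allele_counts.get(allele, 0)
        return count / self.n_alleles_sampled


@dataclass
class GenotypeMatrix:
    """Individuals x sites of unordered diploid allele pairs.

    ``genotypes`` has shape (n_individuals, n_sites, 2) with ``''`` marking a
    missing call.  ``surveyed_length`` counts alignment columns with enough
    non-missing alleles to be classified (polymorphic or not); it is the
    denominator for per-bp diversity.  ``monomorphic_count`` is the number of
    surveyed columns that carried a single allele.
    """

    individuals: list[str]
    sites: list[SiteRecord]
    genotypes: np.ndarray
    surveyed_length: int
    monomorphic_count: int

    def __post_init__(self) -> None:
        assert self.genotypes.shape == (len(self.individuals), len(self.sites), 2)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def individual_indices(self, ids: list[str]) -> np.ndarray:
        lookup = {ind: i for i, ind in enumerate(self.individuals)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise MetadataError(f"unknown individual id {exc.args[0]!r}") from exc


def call_sites(
    aln: LocusAlignment,
    annot: LocusAnnotation,
    min_alleles: int = 40,
) -> GenotypeMatrix:
    """Inventory polymorphic sites of one locus alignment.

    Columns with fewer than ``min_alleles`` non-missing alleles are dropped
    from the survey entirely (they cannot be classified).  Monomorphic
    surveyed columns are only counted — they carry no SiteRecord but do
    enter the per-bp diversity denominator.
    """
    if aln.locus_name != annot.locus_name:
        raise MetadataError(
            f"alignment {aln.locus_name!r} does not match annotation {annot.locus_name!r}"
        )
    individuals = aln.individuals
    n_ind = len(individuals)
    # decode everything once: (n_ind, length, 2) of single characters
    decoded = np.full((n_ind, aln.length, 2), "", dtype="U1")
    for i, ind in enumerate(individuals):
        for j, ch in enumerate(aln.sequences[ind]):
            pair = decode_base(ch)
            if pair is not None:
                decoded[i, j, 0], decoded[i, j, 1] = pair

    sites: list[SiteRecord] = []
    site_cols: list[int] = []
    surveyed = 0
    monomorphic = 0
    for j in range(aln.length):
        col = decoded[:, j, :].ravel()
        present = col[col != ""]
        if present.size < min_alleles:
            continue
        surveyed += 1
        alleles, counts = np.unique(present, return_counts=True)
        if alleles.size < 2:
            monomorphic += 1
            continue
        allele_counts = dict(zip(alleles.tolist(), counts.tolist()))
        n_sampled = int(present.size)
        major = max(sorted(allele_counts), key=lambda a: allele_counts[a])
        maf = max(
            allele_counts[a] for a in allele_counts if a != major
        ) / n_sampled
        sites.append(
            SiteRecord(
                locus_name=aln.locus_name,
                offset=j + 1,
                interval=annot.interval,
                interval_coordinate=annot.interval_position + j,
                allele_counts=allele_counts,
                n_alleles_sampled=n_sampled,
                maf=maf,
            )
        )
        site_cols.append(j)

    genotypes = decoded[:, site_cols, :] if site_cols else np.full((n_ind, 0, 2), "", dtype="U1")
    return GenotypeMatrix(
        individuals=individuals,
        sites=sites,
        genotypes=genotypes,
        surveyed_length=surveyed,
        monomorphic_count=monomorphic,
    )


def concat_matrices(matrices: list[GenotypeMatrix]) -> GenotypeMatrix:
    """Concatenate per-locus matrices over the same individuals."""
    if not matrices:
        raise HzscanError("nothing to concatenate")
    individuals = matrices[0].individuals
    for m in matrices[1:]:
        if m.individuals != individuals:
            raise MetadataError("matrices disagree on individuals")
    return GenotypeMatrix(
        individuals=individuals,
        sites=[s for m in matrices for s in m.sites],
        genotypes=np.concatenate([m.genotypes for m in matrices], axis=1),
        surveyed_length=sum(m.surveyed_length for m in matrices),
        monomorphic_count=sum(m.monomorphic_count for m in matrices),
    )


def classify_and_condense(
    sites: list[SiteRecord], maf_threshold: float = 0.05
) -> list[SiteRecord]:
    """Assign each site its MAF class, condensing multi-allelic sites.

    Rules (frequencies over non-missing alleles; the threshold comparison is
    inclusive, >=):

    * bi-allelic, minor frequency >= threshold -> ``biallelic_informative``
    * multi-allelic with >= 2 non-major alleles each at frequency >=
      threshold -> ``multiallelic_excluded`` (kept for association, dropped
      from LD)
    * any other multi-allelic site -> all non-major alleles merged into one
      minor class; ``condensed_biallelic`` if the merged class reaches the
      threshold, else ``rare``
    * everything below threshold -> ``rare``
    """
    if not 0 < maf_threshold < 0.5:
        raise HzscanError(f"maf_threshold {maf_threshold} outside (0, 0.5)")
    for site in sites:
        minors = site.minor_alleles
        freqs = {a: site.allele_frequency(a) for a in minors}
        common = [a for a in minors if freqs[a] >= maf_threshold]
        if len(minors) == 1:
            site.status = STATUS_BIALLELIC if common else STATUS_RARE
            site.minor_class = None
        elif len(common) >= 2:
            site.status = STATUS_EXCLUDED
            site.minor_class = None
        else:
            merged_freq = sum(freqs.values())
            site.minor_class = tuple(minors)
            if merged_freq >= maf_threshold:
                site.status = STATUS_CONDENSED
            else:
                site.status = STATUS_RARE
    return sites


def dosage_vector(
    gm: GenotypeMatrix, site_index: int, focal_allele: str
) -> np.ndarray:
    """Per-individual count of ``focal_allele`` (0/1/2, NaN = missing).

    ``focal_allele`` may be :data:`MERGED_MINOR` at a condensed site, in
    which case every allele of the merged minor class counts.
    """
    site = gm.sites[site_index]
    if focal_allele == MERGED_MINOR:
        if site.minor_class is None:
            raise HzscanError(
                f"site {site.locus_name}:{site.offset} has no merged minor class"
            )
        members = set(site.minor_class)
    else:
        if focal_allele not in site.allele_counts:
            raise HzscanError(
                f"allele {focal_allele!r} absent at {site.locus_name}:{site.offset}"
            )
        members = {focal_allele}

    geno = gm.genotypes[:, site_index, :]
    missing = geno[:, 0] == ""
    dosage = np.isin(geno, list(members)).sum(axis=1).astype(float)
    dosage[missing] = np.nan
    return dosage


def dosage_matrix(
    gm: GenotypeMatrix, site_indices: list[int] | None = None
) -> tuple[np.ndarray, list[int]]:
    """Minor-allele dosage matrix (individuals x sites) for LD-eligible coding.

    For each site the focal allele is the single minor allele (bi-allelic) or
    the merged minor class (condensed).  Returns the matrix and the site
    indices used.
    """
    if site_indices is None:
        site_indices = [
            i for i, s in enumerate(gm.sites) if s.status in LD_STATUSES
        ]
    cols = []
    for i in site_indices:
        site = gm.sites[i]
        focal = MERGED_MINOR if site.minor_class else site.minor_alleles[0]
        cols.append(dosage_vector(gm, i, focal))
    X = np.column_stack(cols) if cols else np.empty((gm.n_individuals, 0))
    return X, site_indices
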