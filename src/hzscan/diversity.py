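"""Nucleotide diversity, Watterson's theta and Tajima's D.

All three statistics are functions of per-site allele counts, so unphased
diploids simply contribute two alleles per site.  pi is the mean number of
pairwise differences, computed per site as the unbiased heterozygosity
``n/(n-1) * (1 - sum p_i^2)`` and summed over sites; per-bp pi divides by
the surveyed length (polymorphic plus monomorphic columns with data).
Tajima's D uses the standard 1989 normalizing constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import EmptyInputError, HzscanError, UndefinedStatisticError
from .variants import GenotypeMatrix


@dataclass(frozen=True)
class TajimaConstants:
    """Normalizing constants for Tajima's D at sample size ``n`` alleles."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def for_n(cls, n: int) -> "TajimaConstants":
        if n < 2:
            raise HzscanError(f"need n >= 2 alleles, got {n}")
        a1 = sum(1.0 / i for i in range(1, n))
        a2 = sum(1.0 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        return cls(n, a1, a2, b1, b2, c1, c2, e1, e2)


def harmonic_a1(n: int) -> float:
    """a1 = sum_{i=1}^{n-1} 1/i for a sample of n alleles."""
    return sum(1.0 / i for i in range(1, n))


def site_pi(counts: dict[str, int] | np.ndarray) -> float:
    """Unbiased per-site heterozygosity n/(n-1) * (1 - sum p^2)."""
    c = np.asarray(list(counts.values()) if isinstance(counts, dict) else counts, float)
    n = c.sum()
    if n < 2:
        raise UndefinedStatisticError("need >= 2 alleles at a site")
    p = c / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def tajimas_d(S: int, pi_total: float, n: int) -> float:
    """Tajima's D from segregating sites, total pi and allele count."""
    if S == 0:
        raise UndefinedStatisticError("Tajima's D is undefined when S = 0")
    if n < 4:
        raise HzscanError("Tajima's D needs n >= 4 alleles")
    k = TajimaConstants.for_n(n)
    var = k.e1 * S + k.e2 * S * (S - 1)
    return (pi_total - S / k.a1) / math.sqrt(var)


def watterson_theta(S: int, n: int) -> float:
    """Watterson's estimate theta_W = S / a1(n) (per locus, not per bp)."""
    if n < 2:
        raise HzscanError("need n >= 2 alleles")
    return S / harmonic_a1(n)


@dataclass
class DiversityStats:
    """Per-locus (or concatenated) diversity summary for one population."""

    locus_name: str
    population: str
    L: int                      # surveyed bp
    S: int                      # segregating sites
    n: int                      # allele count used for D (see below)
    pi_total: float             # mean pairwise differences per locus
    pi_per_bp: float
    theta_w: float
    tajima_d: float | None      # None iff S = 0 or n < 4
    p_neutral: float | None = None


def _population_site_counts(
    gm: GenotypeMatrix, idx: np.ndarray
) -> list[np.ndarray]:
    """Allele counts per site restricted to the individuals in ``idx``."""
    out = []
    for j in range(gm.n_sites):
        geno = gm.genotypes[np.ix_(idx, [j])][:, 0, :].ravel()
        present = geno[geno != ""]
        _, counts = np.unique(present, return_counts=True)
        out.append(counts)
    return out


def pi_locus(
    gm: GenotypeMatrix, individual_ids: list[str] | None = None
) -> tuple[float, float]:
    """Total and per-bp pi within one set of individuals."""
    stats = diversity_stats(gm, population="", individual_ids=individual_ids)
    return stats.pi_total, stats.pi_per_bp


def diversity_stats(
    gm: GenotypeMatrix,
    population: str = "",
    individual_ids: list[str] | None = None,
    locus_name: str | None = None,
) -> DiversityStats:
    """pi, S, theta_W and Tajima's D for one locus and one population.

    With missing data pi uses the per-site allele count; the constants of
    Tajima's D need one shared n, taken as the floor of the mean per-site
    allele count over segregating sites (conservative rounding).
    """
    if individual_ids is None:
        idx = np.arange(gm.n_individuals)
    else:
        idx = gm.individual_indices(individual_ids)
    if idx.size == 0:
        raise EmptyInputError("no individuals left after population filtering")
    if locus_name is None:
        names = {s.locus_name for s in gm.sites}
        locus_name = names.pop() if len(names) == 1 else "concatenated"

    pi_total = 0.0
    S = 0
    ns = []
    for counts in _population_site_counts(gm, idx):
        n_site = counts.sum()
        if n_site < 2:
            continue
        if counts.size >= 2:
            S += 1
            ns.append(n_site)
            pi_total += site_pi(counts)
    L = gm.surveyed_length
    n = int(np.floor(np.mean(ns))) if ns else 2 * idx.size
    theta = watterson_theta(S, n) if S else 0.0
    try:
        d = tajimas_d(S, pi_total, n) if S else None
    except HzscanError:
        d = None
    return DiversityStats(
        locus_name=locus_name,
        population=population,
        L=L,
        S=S,
        n=n,
        pi_total=pi_total,
        pi_per_bp=pi_total / L if L else 0.0,
        theta_w=theta,
        tajima_d=d,
    )


def concatenate_loci(
    stats: list[DiversityStats], group_name: str = "concatenated"
) -> DiversityStats:
    """Pool per-locus stats sampled on the same chromosome.

    S, pi and L are additive; D is recomputed on the pooled values with a
    shared n (floor of the S-weighted mean of per-locus n).
    """
    if not stats:
        raise EmptyInputError("nothing to concatenate")
    pops = {s.population for s in stats}
    if len(pops) != 1:
        raise HzscanError("cannot concatenate across populations")
    S = sum(s.S for s in stats)
    pi_total = sum(s.pi_total for s in stats)
    L = sum(s.L for s in stats)
    if S:
        n = int(np.floor(sum(s.n * s.S for s in stats) / S))
    else:
        n = min(s.n for s in stats)
    theta = watterson_theta(S, n) if S else 0.0
    try:
        d = tajimas_d(S, pi_total, n) if S else None
    except HzscanError:
        d = None
    return DiversityStats(
        locus_name=group_name,
        population=pops.pop(),
        L=L,
        S=S,
        n=n,
        pi_total=pi_total,
        pi_per_bp=pi_total / L if L else 0.0,
        theta_w=theta,
        tajima_d=d,
    )
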