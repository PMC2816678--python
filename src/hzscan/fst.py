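"""Population differentiation: Hudson-style F_ST per region and
Weir-Cockerham theta per SNP.

The per-region estimator is F_ST = 1 - Hw/Hb, with Hw the mean within-
population pairwise diversity (the two populations weighted equally) and Hb
the mean pairwise difference between one allele from each population,
both summed over surveyed sites.  The per-SNP estimator is the
Weir & Cockerham (1984) variance-components theta on diploid genotype
counts, which accounts for sample size and observed heterozygosity.
Negative estimates are reported as computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedStatisticError
from .variants import GenotypeMatrix


@dataclass
class FstResult:
    unit: str                        # locus name or "site:<locus>:<offset>"
    pop_pair: tuple[str, str]
    fst: float
    h_within: float
    h_between: float


def _site_counts(gm: GenotypeMatrix, idx: np.ndarray, j: int) -> dict[str, int]:
    geno = gm.genotypes[np.ix_(idx, [j])][:, 0, :].ravel()
    present = geno[geno != ""]
    alleles, counts = np.unique(present, return_counts=True)
    return dict(zip(alleles.tolist(), counts.tolist()))


def hudson_fst_region(
    gm: GenotypeMatrix,
    ids_a: list[str],
    ids_b: list[str],
    pop_pair: tuple[str, str] = ("A", "B"),
    unit: str | None = None,
) -> FstResult:
    """Hudson-style F_ST = 1 - Hw/Hb over all sites of a region.

    Sites where either population has fewer than two non-missing alleles are
    skipped in both numerator and denominator.  Raises when Hb = 0 (both
    populations monomorphic and identical across the region).
    """
    idx_a = gm.individual_indices(ids_a)
    idx_b = gm.individual_indices(ids_b)
    hw = 0.0
    hb = 0.0
    for j in range(gm.n_sites):
        ca = _site_counts(gm, idx_a, j)
        cb = _site_counts(gm, idx_b, j)
        na = sum(ca.values())
        nb = sum(cb.values())
        if na < 2 or nb < 2:
            continue
        pa = {a: c / na for a, c in ca.items()}
        pb = {a: c / nb for a, c in cb.items()}
        het_a = na / (na - 1) * (1.0 - sum(p**2 for p in pa.values()))
        het_b = nb / (nb - 1) * (1.0 - sum(p**2 for p in pb.values()))
        hw += 0.5 * (het_a + het_b)
        hb += 1.0 - sum(pa.get(al, 0.0) * pb.get(al, 0.0) for al in set(pa) | set(pb))
    if hb == 0.0:
        raise UndefinedStatisticError(
            "between-population diversity is zero; F_ST undefined"
        )
    if unit is None:
        names = {s.locus_name for s in gm.sites}
        unit = names.pop() if len(names) == 1 else "region"
    return FstResult(unit, pop_pair, 1.0 - hw / hb, hw, hb)


def wc_fst_snp(
    dosages_a: np.ndarray,
    dosages_b: np.ndarray,
    pop_pair: tuple[str, str] = ("A", "B"),
    unit: str = "site",
) -> FstResult:
    """Weir-Cockerham theta for one bi-allelic (or condensed) SNP.

    Inputs are per-individual focal-allele dosages (0/1/2, NaN missing) in
    each population.  Variance components a (among populations),
    b (among individuals within populations) and c (within individuals) are
    evaluated from sample sizes, allele frequencies and observed
    heterozygote proportions; theta = a / (a + b + c).
    """
    r = 2
    comp = []
    for dos in (dosages_a, dosages_b):
        dos = np.asarray(dos, float)
        dos = dos[~np.isnan(dos)]
        if dos.size == 0:
            raise UndefinedStatisticError("population has no genotype calls")
        n_i = dos.size
        p_i = dos.mean() / 2.0
        h_i = np.mean(dos == 1)
        comp.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comp
    if (p1 == 0 and p2 == 0) or (p1 == 1 and p2 == 1):
        raise UndefinedStatisticError("site monomorphic across both populations")
    nbar = (n1 + n2) / 2.0
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2
        - (1.0 / (nbar - 1))
        * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - ((r - 1) / r) * s2
        - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2.0
    denom = a + b + c
    if denom == 0:
        raise UndefinedStatisticError("zero total variance; theta undefined")
    # h_within / h_between describe the Hudson estimator; not meaningful here
    return FstResult(unit, pop_pair, float(a / denom), float("nan"), float("nan"))
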