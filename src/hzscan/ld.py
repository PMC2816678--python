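"""Burrows composite linkage disequilibrium for unphased diploid genotypes.

The composite estimate (Weir's Delta-hat) measures the sum of gametic and
non-gametic disequilibrium directly from diploid genotype counts, without
assuming Hardy-Weinberg equilibrium or known phase.  With focal-allele
dosages x, y in {0, 1, 2} over N pairwise-complete individuals,

    Delta-hat = mean(x * y) / 2 - 2 * pA * pB          (pA = mean(x) / 2)

which equals half the population covariance of the dosage vectors.  The
composite correlation is r = Delta-hat / sqrt((pA qA + DA)(pB qB + DB))
with DA, DB the within-site Hardy-Weinberg disequilibria; its square equals
the squared Pearson correlation of the dosages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import HzscanError, MonomorphicSiteError, UndefinedStatisticError
from .variants import GenotypeMatrix, LD_STATUSES, dosage_matrix


def composite_delta(
    dos_a: np.ndarray, dos_b: np.ndarray, min_pairs: int = 10
) -> tuple[float, float, float, float, float, int]:
    """Composite Burrows disequilibrium for one site pair.

    Returns ``(delta, pA, pB, DA, DB, n_complete)`` computed over
    individuals with both genotypes present.  DA = P(AA homozygote) - pA^2
    is the within-site HW disequilibrium at the first site.
    """
    x = np.asarray(dos_a, float)
    y = np.asarray(dos_b, float)
    if x.shape != y.shape:
        raise HzscanError("dosage vectors differ in length")
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < min_pairs:
        raise HzscanError(f"only {n} complete pairs (< min_pairs={min_pairs})")
    x, y = x[ok], y[ok]
    pA = x.mean() / 2.0
    pB = y.mean() / 2.0
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise MonomorphicSiteError("a site is monomorphic among complete individuals")
    delta = float(np.mean(x * y) / 2.0 - 2.0 * pA * pB)
    DA = float(np.mean(x == 2) - pA**2)
    DB = float(np.mean(y == 2) - pB**2)
    return delta, float(pA), float(pB), DA, DB, n


def composite_r2(delta: float, pA: float, pB: float, DA: float, DB: float) -> float:
    """Composite correlation squared from Delta-hat and its denominators."""
    denom = (pA * (1 - pA) + DA) * (pB * (1 - pB) + DB)
    if denom <= 0:
        raise UndefinedStatisticError("zero denominator; composite r undefined")
    r = delta / np.sqrt(denom)
    return float(r * r)


@dataclass
class LDPair:
    """One unordered site pair with its composite LD estimates."""

    i: int
    j: int
    n_complete: int
    delta: float
    r2: float
    distance_bp: int | None     # None = unlinked (different intervals/loci)


def pair_distance(gm: GenotypeMatrix, i: int, j: int) -> int | None:
    """Physical distance in bp, or None for pairs without a shared axis.

    Distance is defined for pairs on the same mapped interval (D or Cr) and
    for pairs within the same locus; loci on the unlinked interval have no
    shared coordinate system between them.
    """
    si, sj = gm.sites[i], gm.sites[j]
    same_locus = si.locus_name == sj.locus_name
    same_mapped = si.interval == sj.interval and si.interval != "unlinked"
    if same_locus or same_mapped:
        return abs(si.interval_coordinate - sj.interval_coordinate)
    return None


def ld_matrix(
    gm: GenotypeMatrix,
    site_indices: list[int] | None = None,
    individual_ids: list[str] | None = None,
    min_pairs: int = 10,
) -> tuple[list[LDPair], int]:
    """Composite delta and r^2 for all unordered pairs of LD-eligible sites.

    Uses pairwise-complete individuals per pair.  Pairs with fewer than
    ``min_pairs`` complete individuals, or with a site monomorphic among
    them, are omitted; the second return value counts the omissions.
    """
    if site_indices is None:
        site_indices = [i for i, s in enumerate(gm.sites) if s.status in LD_STATUSES]
    if len(site_indices) < 2:
        raise HzscanError("need at least 2 LD-eligible sites")
    X, _ = dosage_matrix(gm, site_indices)
    if individual_ids is not None:
        X = X[gm.individual_indices(individual_ids)]

    M = (~np.isnan(X)).astype(float)
    X0 = np.nan_to_num(X)
    N = M.T @ M
    Sx = X0.T @ M
    Sxy = X0.T @ X0
    Sx2 = (X0 * X0).T @ M
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_x = Sx / N                     # mean of site-row dosage over pair-complete
        mean_y = mean_x.T
        cov = Sxy / N - mean_x * mean_y
        var_x = Sx2 / N - mean_x**2
        var_y = var_x.T
        delta = cov / 2.0
        r2 = cov**2 / (var_x * var_y)

    pairs: list[LDPair] = []
    omitted = 0
    m = len(site_indices)
    for a in range(m):
        for b in range(a + 1, m):
            n_ab = int(N[a, b])
            if n_ab < min_pairs or var_x[a, b] <= 0 or var_y[a, b] <= 0:
                omitted += 1
                continue
            pairs.append(
                LDPair(
                    i=site_indices[a],
                    j=site_indices[b],
                    n_complete=n_ab,
                    delta=float(delta[a, b]),
                    r2=float(r2[a, b]),
                    distance_bp=pair_distance(gm, site_indices[a], site_indices[b]),
                )
            )
    return pairs, omitted


def pairs_to_frame(gm: GenotypeMatrix, pairs: list[LDPair], population: str = "all") -> pd.DataFrame:
    rows = []
    for p in pairs:
        si, sj = gm.sites[p.i], gm.sites[p.j]
        rows.append(
            (
                f"{si.locus_name}:{si.offset}",
                f"{sj.locus_name}:{sj.offset}",
                si.interval,
                sj.interval,
                p.distance_bp,
                p.delta,
                p.r2,
                p.n_complete,
                population,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "site_i", "site_j", "interval_i", "interval_j",
            "distance_bp", "delta", "r2", "n", "population",
        ],
    )


def square_matrix(
    gm: GenotypeMatrix, pairs: list[LDPair], site_indices: list[int]
) -> pd.DataFrame:
    """Symmetric r^2 matrix (unit diagonal) over the given sites."""
    labels = [f"{gm.sites[i].locus_name}:{gm.sites[i].offset}" for i in site_indices]
    pos = {idx: k for k, idx in enumerate(site_indices)}
    mat = np.full((len(site_indices), len(site_indices)), np.nan)
    np.fill_diagonal(mat, 1.0)
    for p in pairs:
        a, b = pos[p.i], pos[p.j]
        mat[a, b] = mat[b, a] = p.r2
    return pd.DataFrame(mat, index=labels, columns=labels)


def sliding_window_decay(pairs: list[LDPair], window: int = 50) -> pd.DataFrame:
    """Moving average of r^2 over ``window`` consecutive pairs by distance.

    Only pairs with a defined physical distance enter.  Pairs are sorted by
    distance and a step-1 moving window of ``window`` pairs is averaged; the
    x coordinate is the mean distance in the window.  With fewer pairs than
    the window, a single averaged point is returned with a warning.
    """
    linked = [p for p in pairs if p.distance_bp is not None and np.isfinite(p.r2)]
    if not linked:
        raise HzscanError("no pairs with defined distance")
    linked.sort(key=lambda p: (p.distance_bp, p.i, p.j))
    d = np.array([p.distance_bp for p in linked], float)
    r2 = np.array([p.r2 for p in linked])
    if len(linked) < window:
        warnings.warn(
            f"only {len(linked)} pairs for window={window}; returning one point",
            stacklevel=2,
        )
        return pd.DataFrame({"distance_bp": [d.mean()], "mean_r2": [r2.mean()]})
    kernel = np.ones(window) / window
    mean_r2 = np.convolve(r2, kernel, mode="valid")
    mean_d = np.convolve(d, kernel, mode="valid")
    return pd.DataFrame({"distance_bp": mean_d, "mean_r2": mean_r2})
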