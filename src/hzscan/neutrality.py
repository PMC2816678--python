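"""Infinite-sites coalescent null and simulation p-values for Tajima's D.

The null is the standard neutral n-coalescent without recombination: while
k lineages remain, the waiting time to the next merger is exponential with
rate k(k-1)/2 (time in units of 2N generations) and the merging pair is
uniform.  Mutations fall on branches as a Poisson process of rate theta/2
per unit branch length, so E[S] = theta * a1(n-1) and E[pi] = theta.

Two code paths implement the same model: an explicit per-tree simulator
(which can also emit haplotypes, useful for building panmictic genotype
samples) and a vectorized batch path used for the 10,000-replicate
neutrality tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import HzscanError, UndefinedStatisticError
from .diversity import tajimas_d, harmonic_a1


@dataclass
class Branch:
    """One finalized coalescent branch."""

    length: float          # in units of 2N generations
    n_leaves: int
    leaves: tuple[int, ...]


@dataclass
class CoalescentTree:
    n: int
    branches: list[Branch]

    @property
    def total_length(self) -> float:
        return sum(b.length for b in self.branches)


@dataclass
class CoalescentReplicate:
    n: int
    total_tree_length: float
    S: int
    pi_total: float
    tajima_d: float | None


def simulate_genealogy(n: int, rng: np.random.Generator) -> CoalescentTree:
    """Simulate one neutral coalescent genealogy of ``n`` samples."""
    if n < 2:
        raise HzscanError(f"need n >= 2 samples, got {n}")
    # active lineages: birth time + leaf set
    births = [0.0] * n
    leaves = [(i,) for i in range(n)]
    t = 0.0
    branches: list[Branch] = []
    k = n
    while k > 1:
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        for m in (i, j):
            branches.append(Branch(t - births[m], len(leaves[m]), leaves[m]))
        merged = tuple(sorted(leaves[i] + leaves[j]))
        # replace i with the merged lineage, drop j (swap-with-last)
        births[i] = t
        leaves[i] = merged
        births[j] = births[k - 1]
        leaves[j] = leaves[k - 1]
        births.pop()
        leaves.pop()
        k -= 1
    return CoalescentTree(n=n, branches=branches)


def drop_mutations(
    tree: CoalescentTree,
    theta: float,
    rng: np.random.Generator,
    return_genotypes: bool = False,
) -> CoalescentReplicate | tuple[CoalescentReplicate, np.ndarray]:
    """Scatter infinite-sites mutations on a genealogy.

    Mutation counts per branch are independent Poisson(theta * length / 2),
    equivalent to a Poisson total allocated multinomially by branch length.
    With ``return_genotypes`` also returns the (n, S) 0/1 haplotype matrix.
    """
    if theta < 0:
        raise HzscanError("theta must be non-negative")
    n = tree.n
    lengths = np.array([b.length for b in tree.branches])
    muts = rng.poisson(theta * lengths / 2.0)
    S = int(muts.sum())
    sizes = np.array([b.n_leaves for b in tree.branches])
    npairs = n * (n - 1) / 2.0
    pi_total = float(np.sum(muts * sizes * (n - sizes)) / npairs)
    try:
        d = tajimas_d(S, pi_total, n) if S else None
    except HzscanError:
        d = None
    rep = CoalescentReplicate(n, tree.total_length, S, pi_total, d)
    if not return_genotypes:
        return rep
    haplotypes = np.zeros((n, S), dtype=np.int8)
    col = 0
    for b, m in zip(tree.branches, muts):
        for _ in range(int(m)):
            haplotypes[list(b.leaves), col] = 1
            col += 1
    return rep, haplotypes


def batch_replicates(
    n: int, theta: float, reps: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized coalescent replicates: arrays of S, pi_total and D.

    D is NaN for replicates with S = 0 (undefined).  Statistically identical
    to repeated :func:`simulate_genealogy` + :func:`drop_mutations`.
    """
    if n < 2:
        raise HzscanError(f"need n >= 2 samples, got {n}")
    if theta < 0:
        raise HzscanError("theta must be non-negative")
    R = reps
    births = np.zeros((R, n))
    sizes = np.ones((R, n), dtype=np.int64)
    t = np.zeros(R)
    rows = np.arange(R)
    # 2(n-1) finalized branches per replicate
    br_len = np.empty((R, 2 * (n - 1)))
    br_size = np.empty((R, 2 * (n - 1)), dtype=np.int64)
    out = 0
    for k in range(n, 1, -1):
        t = t + rng.exponential(2.0 / (k * (k - 1)), size=R)
        a = rng.integers(0, k, size=R)
        b = rng.integers(0, k - 1, size=R)
        b = b + (b >= a)
        i = np.minimum(a, b)
        j = np.maximum(a, b)
        br_len[:, out] = t - births[rows, i]
        br_size[:, out] = sizes[rows, i]
        br_len[:, out + 1] = t - births[rows, j]
        br_size[:, out + 1] = sizes[rows, j]
        out += 2
        # merged lineage replaces the lower slot; the higher slot takes the
        # last active slot (no-op when j is already last)
        merged = sizes[rows, i] + sizes[rows, j]
        births[rows, i] = t
        sizes[rows, i] = merged
        births[rows, j] = births[rows, k - 1]
        sizes[rows, j] = sizes[rows, k - 1]
    muts = rng.poisson(theta * br_len / 2.0)
    S = muts.sum(axis=1)
    npairs = n * (n - 1) / 2.0
    pi = (muts * br_size * (n - br_size)).sum(axis=1) / npairs
    D = _tajima_d_array(S, pi, n)
    return S, pi, D


def _tajima_d_array(S: np.ndarray, pi: np.ndarray, n: int) -> np.ndarray:
    from .diversity import TajimaConstants

    k = TajimaConstants.for_n(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        var = k.e1 * S + k.e2 * S * (S - 1.0)
        D = (pi - S / k.a1) / np.sqrt(var)
    D = np.where(S > 0, D, np.nan)
    return D


@dataclass
class NeutralityTest:
    """Outcome of a simulation-based two-tailed Tajima's D test."""

    p: float
    reps_requested: int
    reps_used: int          # replicates with S > 0 (D defined)
    n_excluded: int
    d_obs: float
    d_sim_mean: float
    d_sim_q025: float
    d_sim_q975: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


def significance_stars(p: float) -> str:
    """Table-footnote convention: p<0.05 -> '*', p<0.01 -> '**'."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def neutrality_pvalue(
    observed_d: float,
    n: int,
    theta_hat: float,
    reps: int = 10_000,
    rng: np.random.Generator | None = None,
) -> NeutralityTest:
    """Two-tailed simulation p-value for an observed Tajima's D.

    Simulates ``reps`` neutral replicates at the locus' Watterson theta,
    drops S=0 replicates (D undefined, count reported) and doubles the
    smaller tail: p = min(1, 2*min(Pr(D <= obs), Pr(D >= obs))).
    """
    if rng is None:
        rng = np.random.default_rng()
    if theta_hat <= 0:
        raise HzscanError("theta_hat must be positive")
    if observed_d is None or not np.isfinite(observed_d):
        raise UndefinedStatisticError("observed D is undefined")
    _, _, D = batch_replicates(n, theta_hat, reps, rng)
    defined = D[~np.isnan(D)]
    if defined.size == 0:
        raise UndefinedStatisticError(
            "all replicates had S = 0; theta too small to test"
        )
    lo = np.mean(defined <= observed_d)
    hi = np.mean(defined >= observed_d)
    p = min(1.0, 2.0 * min(lo, hi))
    return NeutralityTest(
        p=float(p),
        reps_requested=reps,
        reps_used=int(defined.size),
        n_excluded=int(reps - defined.size),
        d_obs=float(observed_d),
        d_sim_mean=float(defined.mean()),
        d_sim_q025=float(np.quantile(defined, 0.025)),
        d_sim_q975=float(np.quantile(defined, 0.975)),
    )
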