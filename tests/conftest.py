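import numpy as np
import pytest

from hzscan import SimConfig, simulate_hybrid_zone
from hzscan.io import LocusAlignment, LocusAnnotation
from hzscan.variants import call_sites, classify_and_condense


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic hybrid-zone dataset, shared across tests."""
    return simulate_hybrid_zone(SimConfig(seed=7))


def make_matrix(seqs: dict[str, str], interval="D", position=1, min_alleles=2,
                maf_threshold=0.05, locus="locA"):
    """Small genotype matrix straight from consensus strings."""
    aln = LocusAlignment(locus, seqs)
    ann = LocusAnnotation(locus, interval, position, aln.length)
    gm = call_sites(aln, ann, min_alleles=min_alleles)
    classify_and_condense(gm.sites, maf_threshold)
    return gm


def random_genotype_table(rng, n_ind, n_sites, missing_rate=0.0):
    """Random unlinked diploid dosage table (for LD/association identities)."""
    p = rng.uniform(0.1, 0.9, size=n_sites)
    dos = rng.binomial(2, p, size=(n_ind, n_sites)).astype(float)
    if missing_rate:
        mask = rng.random(dos.shape) < missing_rate
        dos[mask] = np.nan
    return dos
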