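import numpy as np
import pytest

from invkaryo import ldscan, simdata
from invkaryo.genio import GenotypeMatrix


@pytest.fixture(scope="session")
def cohort1():
    """Default simulated cohort (strongly diverged inversion, 100 samples)."""
    return simdata.simulate_inversion_cohort(simdata.CohortSimParams(seed=1))


@pytest.fixture(scope="session")
def scan1(cohort1):
    """LD pairs, detected region and diagnostic loci for cohort1."""
    G = cohort1.genotypes
    pairs = ldscan.compute_r2(G)
    region = ldscan.detect_inversion_region(pairs, chrom=G.chrom)
    assert region is not None
    loci = ldscan.select_diagnostic_loci(G, region)
    return pairs, region, loci


@pytest.fixture(scope="session")
def families200():
    """200 ortholog families at the default conditions (t_inv = 1.0 MY)."""
    return simdata.simulate_ortholog_families(
        simdata.OrthologSimParams(n_families=200, seed=5)
    )


def make_matrix(dosages, positions=None, samples=None, chrom="chrT",
                populations=None):
    """Small hand-rolled GenotypeMatrix for unit tests."""
    dosages = np.asarray(dosages, dtype=np.int8)
    ns, nv = dosages.shape
    samples = samples or [f"s{i}" for i in range(ns)]
    positions = positions if positions is not None else np.arange(1, nv + 1)
    pops = populations or {s: "pop" for s in samples}
    return GenotypeMatrix(
        sample_ids=samples,
        chrom=chrom,
        positions=np.asarray(positions),
        ref_allele=np.array(["A"] * nv, dtype=object),
        alt_allele=np.array(["G"] * nv, dtype=object),
        dosages=dosages,
        population_of=pops,
        latitude_of={},
    )
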