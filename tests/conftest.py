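import numpy as np
import pytest

import ssrhyb as sh
from ssrhyb.geno_io import GenotypeMatrix, SampleMetadata


def make_matrix(calls, pops, loci=None, individuals=None):
    """Build a GenotypeMatrix + metadata from a raw (n, L, 2) int array
    (-1 = missing); pairs are sorted for canonical storage."""
    calls = np.asarray(calls, dtype=np.int32)
    n, L = calls.shape[:2]
    individuals = individuals or [f"ind{i:03d}" for i in range(n)]
    loci = loci or [f"L{l + 1}" for l in range(L)]
    m = GenotypeMatrix(individuals, loci, np.sort(calls, axis=2), {})
    from ssrhyb.geno_io import validate_matrix
    validate_matrix(m)
    meta = SampleMetadata.from_populations(individuals, list(pops))
    return m, meta


@pytest.fixture(scope="session")
def two_species_dataset():
    """Two divergent species (30 + 30 purebreds), 17 loci, no observation
    noise — the substrate for admixture and differentiation tests."""
    fm = sh.simulate_frequencies(
        n_species=2, n_loci=17, alleles_per_locus=21, divergence=4,
        null_max=0.0, seed=11,
    )
    plan = sh.CrossPlan([("P1-A", "A", 30), ("P2-V", "V", 30)])
    mat, meta, truth = sh.simulate_individuals(
        fm, plan, sh.ObservationModel(), seed=12)
    return fm, mat, meta, truth


@pytest.fixture(scope="session")
def four_species_dataset():
    """Four species across six populations with nulls, inbreeding and
    failures — a small study-like panel."""
    fm = sh.simulate_frequencies(
        n_species=4, n_loci=6, alleles_per_locus=8, divergence=6,
        null_max=0.1, seed=1,
    )
    pops = ["BY-A", "BY-V", "LT-F", "LT-B", "ZJ-A", "ZJ-V"]
    plan = sh.CrossPlan([(p, p.rsplit("-", 1)[1], 15) for p in pops])
    mat, meta, truth = sh.simulate_individuals(
        fm, plan, sh.ObservationModel(default_f=0.1, default_b=0.02), seed=2)
    return fm, mat, meta, truth
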