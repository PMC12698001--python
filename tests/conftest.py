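import numpy as np
import pytest

import introscan as isc

#: quartet species tree used across the statistics tests:
#: sisters P1/P2, donor P3, outgroup OUT
QUARTET_TREE = "(((P1:0.4,P2:0.4):0.4,P3:0.8):0.6,OUT:1.4);"

#: two-genus tree with zero-length within-genus branches, for noiseless
#: fixed-difference simulations (genus A = donor lineage, genus B hosts the
#: recipients R1/R2)
TWO_GENUS_TREE = (
    "((A1:0.0,A2:0.0):1.0,((B1:0.0,B2:0.0):0.0,(R1:0.0,R2:0.0):0.0):1.0);"
)


@pytest.fixture(scope="session")
def quartet_tree():
    return QUARTET_TREE


@pytest.fixture(scope="session")
def two_genus_tree():
    return TWO_GENUS_TREE


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated dataset with one planted tract."""
    cfg = isc.SimConfig(
        species_tree=QUARTET_TREE,
        n_individuals=4,
        chrom_length=1_000_000,
        n_sites=5_000,
        seed=11,
        events=[isc.IntrogressionEvent("P3", "P2", (500_001, 510_000), rho=0.95)],
    )
    return isc.simulate_genotypes(cfg)


def random_genotype_matrix(rng, n_sites=40, n_per_group=4, missing_rate=0.1):
    """Random genotype matrix + popmap with four groups, for oracle tests."""
    groups = {
        g: [f"{g}_{k}" for k in range(n_per_group)] for g in ("g1", "g2", "g3", "og")
    }
    samples = [m for ms in groups.values() for m in ms]
    geno = rng.integers(0, 3, size=(n_sites, len(samples))).astype(np.int8)
    miss = rng.random(geno.shape) < missing_rate
    geno[miss] = -1
    pos = np.sort(rng.choice(10 * n_sites, size=n_sites, replace=False)) + 1
    bases = np.array(list("ACGT"), dtype=object)
    ref = bases[rng.integers(0, 4, n_sites)]
    alt = bases[(np.array([list("ACGT").index(r) for r in ref]) +
                 rng.integers(1, 4, n_sites)) % 4]
    gm = isc.GenotypeMatrix(
        np.full(n_sites, "chr1", dtype=object), pos, ref, alt, geno, tuple(samples)
    )
    return gm, isc.PopulationMap(groups)
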