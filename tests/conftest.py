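import numpy as np
import pytest

from divscan.scan import GeneAnnotation
from divscan.synth import PlantedWindow, SyntheticGenomeConfig, generate_genome
from divscan.vcfio import GenotypeMatrix, PopulationMap


@pytest.fixture(scope="session")
def small_genome():
    """A 2-scaffold, 1-Mb-per-scaffold synthetic genome with one planted
    window and one planted gene; shared across tests (read-only)."""
    from divscan.synth import PlantedGene

    cfg = SyntheticGenomeConfig(
        n_scaffolds=2,
        scaffold_length=1_000_000,
        planted_windows=[PlantedWindow("scaffold_0", 3)],
        planted_genes=[PlantedGene(GeneAnnotation("geneX", "scaffold_1", 450_000, 470_000))],
        seed=1234,
    )
    return generate_genome(cfg)


@pytest.fixture()
def tiny_gm():
    """Hand-built 6-site, 4+4-sample matrix covering corner cases."""
    samples = [f"A{i}" for i in range(4)] + [f"B{i}" for i in range(4)]
    popmap = PopulationMap({s: ("P1" if s.startswith("A") else "P2") for s in samples})
    dosages = np.array([
        [0, 0, 0, 0, 2, 2, 2, 2],     # fixed difference
        [1, 1, 0, 0, 0, 0, 0, 0],     # private polymorphism in P1
        [0, 0, 0, 0, 0, 0, 0, 0],     # monomorphic
        [1, 0, 2, 1, 1, 0, 2, 1],     # shared polymorphism
        [2, 2, 2, 2, 0, 0, 0, -1],    # fixed difference with one missing
        [0, 1, -1, -1, 2, 2, 2, 2],   # het in P1 -> not fixed
    ], dtype=np.int8)
    return GenotypeMatrix(
        samples=samples,
        popmap=popmap,
        scaffolds=np.array(["s1"] * 6, dtype=object),
        positions=np.array([100, 200, 300, 400, 500, 600], dtype=np.int64),
        ref=np.array(list("ACGTAC"), dtype="<U1"),
        alt=np.array(list("TGCATG"), dtype="<U1"),
        dosages=dosages,
    )
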