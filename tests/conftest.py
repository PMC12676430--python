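import numpy as np
import pytest

from kdrpop.core_io import GenotypeMatrix, SampleMetadata, VariantTable
from kdrpop.diplotype import default_kdr_panel
from kdrpop.synthetic_data import PopulationSpec, simulate_kdr_cohort


@pytest.fixture(scope="session")
def panel():
    return default_kdr_panel()


@pytest.fixture
def tiny_variants():
    """Two sites on 2L: one biallelic, one triallelic."""
    return VariantTable(contig=["2L", "2L"], pos=np.array([100, 200]),
                        ref=["G", "A"], alts=[("T", "C"), ("G",)])


@pytest.fixture
def tiny_genotypes():
    calls = np.array([
        [[0, 1], [0, 0]],
        [[2, 2], [0, 1]],
        [[-1, -1], [1, 1]],
    ], dtype=np.int16)
    phased = np.array([[False, False], [True, True], [False, False]])
    return GenotypeMatrix(calls, phased)


@pytest.fixture
def tiny_metadata():
    return [
        SampleMetadata("S1", "An_coluzzii", "Bana", "Sudanian", "F"),
        SampleMetadata("S2", "An_coluzzii", "Bana", "Sudanian", "M"),
        SampleMetadata("S3", "An_gambiae_ss", "Gama", "Sudano_Sahelian", "F"),
    ]


@pytest.fixture(scope="session")
def small_cohort(panel):
    """A 3-population phased cohort with known class structure."""
    specs = [
        PopulationSpec("popA", "An_coluzzii", "Bana", "Sudanian", 40,
                       {"LVI": 0.3, "FVI": 0.2, "LL1T": 0.3, "FL1T": 0.2},
                       n_background_sites=50),
        PopulationSpec("popB", "An_gambiae_ss", "Gama", "Sudano_Sahelian", 30,
                       {"FVI": 1.0}, n_background_sites=30),
        PopulationSpec("popC", "An_arabiensis", "Nassan", "Sudano_Sahelian",
                       30, {"FVI": 0.5, "SVI": 0.5}, n_background_sites=30),
    ]
    return simulate_kdr_cohort(specs, seed=7, panel=panel)
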