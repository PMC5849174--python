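import numpy as np
import pytest

from polyrisk.genotype_io import GenotypeMatrix, PhenotypeTable, SnpRecord
from polyrisk.synthetic_data import paper_like_panel, simulate_cohort


@pytest.fixture
def tiny_snps():
    return [
        SnpRecord("rs1", "1", 1000, "A", "G"),
        SnpRecord("rs2", "2", 2000, "C", "T"),
        SnpRecord("rs3", "3", 3000, "G", "A"),
    ]


@pytest.fixture
def tiny_gm(tiny_snps):
    dosage = np.array(
        [
            [0.0, 1.0, 2.0],
            [1.0, np.nan, 0.0],
            [2.0, 2.0, 1.0],
            [0.0, 0.0, np.nan],
        ]
    )
    return GenotypeMatrix(["s1", "s2", "s3", "s4"], tiny_snps, dosage)


@pytest.fixture
def tiny_phen():
    return PhenotypeTable.from_arrays(
        ["s1", "s2", "s3", "s4"],
        [True, False, True, False],
        [52.0, 41.0, 55.0, np.nan],
    )


@pytest.fixture(scope="session")
def preset_cohorts():
    """Full-size preset two-cohort simulation, shared across tests."""
    return simulate_cohort(paper_like_panel(seed=11))


@pytest.fixture(scope="session")
def small_sim_config():
    """Reduced-size preset for fast end-to-end pipeline tests."""
    return {
        "seed": 11,
        "simulate": {
            "preset": "paper_like",
            "n_cases_1": 400,
            "n_controls_1": 300,
            "n_cases_2": 150,
            "n_controls_2": 120,
        },
    }
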