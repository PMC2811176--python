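import numpy as np
import pandas as pd
import pytest

from helpscan.io_model import MethylationMatrix, SampleTable
from helpscan.synthetic import SimulationConfig, simulate_cohort


def make_matrix(values: np.ndarray, samples: list[str]) -> MethylationMatrix:
    """Matrix with auto-generated chr1 locus keys, one per row."""
    keys = [f"chr1:{1001 + 2000 * i}-{1500 + 2000 * i}" for i in range(values.shape[0])]
    return MethylationMatrix(pd.DataFrame(values, index=keys, columns=samples))


def make_sample_table(n_pairs: int) -> SampleTable:
    records = pd.DataFrame(
        {
            "sample_id": [f"case_{i+1}" for i in range(n_pairs)] + [f"ctrl_{i+1}" for i in range(n_pairs)],
            "group": ["case"] * n_pairs + ["control"] * n_pairs,
            "pair_id": [f"P{i+1:02d}" for i in range(n_pairs)] * 2,
            "gender": ["M" if i % 2 == 0 else "F" for i in range(n_pairs)] * 2,
            "ethnicity": ["x"] * (2 * n_pairs),
        }
    )
    return SampleTable(records)


@pytest.fixture(scope="session")
def small_cohort():
    """2000-locus, 5-pair cohort with 2% planted differential loci."""
    config = SimulationConfig(n_loci=2000, n_pairs=5, frac_differential=0.02, seed=11)
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no differential loci (null calibration fixture)."""
    config = SimulationConfig(n_loci=4000, n_pairs=5, frac_differential=0.0, seed=23)
    return simulate_cohort(config)
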