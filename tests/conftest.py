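import numpy as np
import pandas as pd
import pytest

from domestiscan import (
    SamplePanel,
    SweepSpec,
    VariantTable,
    generate_cohort,
    two_population_model,
)
from domestiscan.demography import DemographicModel


@pytest.fixture(scope="session")
def fast_model():
    """Small-Ne dog/wolf split: fast to simulate, same structure as the
    default study model."""
    return two_population_model(
        n_dog=3_000, n_wolf=2_000, n_ancestral=4_000, split_time=1_500
    )


@pytest.fixture(scope="session")
def single_pop_model():
    return DemographicModel(lineages={"dog": 3_000})


@pytest.fixture(scope="session")
def small_cohort(fast_model):
    """1.5-Mb cohort with one fixed sweep (residual 0.05) and ancient pool."""
    sweeps = [SweepSpec("1", 500_000, 900_000, residual=0.05)]
    return generate_cohort(
        fast_model, {"1": 1_500_000}, sweeps=sweeps, n_dogs=12, n_wolves=8, seed=7
    )


@pytest.fixture()
def toy_panel():
    return SamplePanel(
        pd.DataFrame(
            {
                "sample": ["d1", "d2", "d3", "w1", "w2", "a1"],
                "population": ["dog", "dog", "dog", "wolf", "wolf", "ancient"],
                "sex": ["male", "female", "female", "male", "female", "female"],
            }
        )
    )


def make_table(gt, samples, pos=None, chrom="1", region_class=None):
    """Hand-built VariantTable from a dosage matrix (n_sites x n_samples)."""
    gt = np.asarray(gt, dtype=np.int8)
    n = gt.shape[0]
    pos = np.asarray(pos if pos is not None else np.arange(1, n + 1) * 100, dtype=np.int64)
    rc = (
        np.asarray(region_class, dtype=np.int8)
        if region_class is not None
        else np.zeros(n, dtype=np.int8)
    )
    return VariantTable(
        chrom=np.full(n, chrom, dtype=object),
        pos=pos,
        ref=np.full(n, "A", dtype=object),
        alt=np.full(n, "G", dtype=object),
        gt=gt,
        samples=list(samples),
        region_class=rc,
        chrom_lengths={chrom: int(pos.max()) + 1000 if n else 1000},
    )
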