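import numpy as np
import pandas as pd
import pytest

import coinvasion as cv


@pytest.fixture(scope="session")
def pool():
    return cv.DEFAULT_POOL


@pytest.fixture(scope="session")
def co_design(pool):
    """The default co-invasion design: 70 treatments, 6 replicates."""
    return cv.enumerate_co_invasion(pool, 2, 4, 6)


@pytest.fixture(scope="session")
def single_design(pool):
    """The full single-invasion design: 75 treatments."""
    return cv.enumerate_single_invasion(pool, 1, 4)


@pytest.fixture(scope="session")
def noise_free_model():
    return cv.ObservationModel(count_noise="none", detection_limit=0.0)


@pytest.fixture(scope="session")
def neutral_counts(co_design, noise_free_model):
    """Noise-free neutral-community dataset over the full co design."""
    return cv.generate_dataset(
        co_design, cv.preset("neutral"), model=noise_free_model, master_seed=11
    )


@pytest.fixture(scope="session")
def stabilized_rgr(pool, co_design):
    """Replicate-level RGRs from the stabilized preset with default noise."""
    counts = cv.generate_dataset(co_design, cv.preset("stabilized"), master_seed=2026)
    return cv.compute_all(counts, co_design, pool)


def tiny_counts(
    treatment_id="X_into_B",
    focal="X",
    residents=("B",),
    n0_focal=10.0,
    n1_focal=40.0,
    n0_res=(200.0,),
    n1_res=(500.0,),
    replicate=1,
    assay_days=7.0,
):
    """Hand-assembled one-replicate counts table for direct RGR checks."""
    rows = [
        {
            "treatment_id": treatment_id,
            "replicate": replicate,
            "species": focal,
            "role": "invader",
            "N0": n0_focal,
            "N1": n1_focal,
            "below_detection": n1_focal <= 0,
            "assay_days": assay_days,
        }
    ]
    for sp, a, b in zip(residents, n0_res, n1_res):
        rows.append(
            {
                "treatment_id": treatment_id,
                "replicate": replicate,
                "species": sp,
                "role": "resident",
                "N0": a,
                "N1": b,
                "below_detection": b <= 0,
                "assay_days": assay_days,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
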