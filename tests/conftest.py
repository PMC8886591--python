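import numpy as np
import pandas as pd
import pytest

from morphoscore import ROICohort, SimConfig, make_weight_profile, simulate_cohort


@pytest.fixture(scope="session")
def scz_profile():
    return make_weight_profile("scz_like")


@pytest.fixture(scope="session")
def adhd_profile():
    return make_weight_profile("adhd_like")


@pytest.fixture(scope="session")
def sim_cohort(scz_profile):
    """60-subject, 75-ROI case/control cohort with scz-shaped case shifts."""
    cfg = SimConfig(
        n_per_group={"control": 40, "case": 20},
        profiles={"case": (scz_profile, 0.5)},
        seed=1,
    )
    cohort, truth = simulate_cohort(cfg)
    return cohort, truth


def make_tiny_cohort(values_by_roi, groups=None, seed=0):
    """Small hand-specified cohort: dict roi_name -> value list."""
    n = len(next(iter(values_by_roi.values())))
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(
        {
            "group": groups if groups is not None else ["control"] * n,
            "age": rng.normal(35, 10, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "icv": rng.normal(1.45e6, 1.3e5, n),
            **{k: np.asarray(v, float) for k, v in values_by_roi.items()},
        },
        index=pd.Index([f"s{i}" for i in range(n)], name="subject_id"),
    )
    meta = {k: k.rsplit("_", 1)[-1] for k in values_by_roi}
    return ROICohort(data=data, roi_meta=meta)
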