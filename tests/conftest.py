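import numpy as np
import pandas as pd
import pytest

from patellasex import generate_cohort, pooled_spec

#: Printed pooled per-sex moments (mean, SD) of the six measurements, mm.
POOLED_MOMENTS = {
    "maxh": {"M": (42.07, 3.14), "F": (37.25, 2.83)},
    "maxb": {"M": (43.77, 3.28), "F": (38.85, 3.23)},
    "maxt": {"M": (20.38, 1.62), "F": (18.13, 1.75)},
    "haf": {"M": (30.26, 2.65), "F": (27.42, 2.80)},
    "mafb": {"M": (19.70, 2.02), "F": (17.44, 2.23)},
    "lafb": {"M": (26.34, 2.70), "F": (23.40, 2.60)},
}


@pytest.fixture(scope="session")
def pooled_table() -> pd.DataFrame:
    """One default synthetic cohort (130 per sex), shared across tests."""
    return generate_cohort(pooled_spec(seed=0))


def affine_standardize(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Rescale a sample so its sample mean and SD (ddof=1) are exact."""
    x = np.asarray(x, dtype=float)
    return mean + (x - x.mean()) * sd / x.std(ddof=1)


@pytest.fixture(scope="session")
def exact_moment_table() -> pd.DataFrame:
    """n=130-per-sex table whose sample moments equal the printed values exactly."""
    rng = np.random.default_rng(42)
    cols = {}
    for var, by_sex in POOLED_MOMENTS.items():
        male = affine_standardize(rng.standard_normal(130), *by_sex["M"])
        female = affine_standardize(rng.standard_normal(130), *by_sex["F"])
        cols[var] = np.concatenate([male, female])
    df = pd.DataFrame(cols)
    df["sex"] = ["M"] * 130 + ["F"] * 130
    return df
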