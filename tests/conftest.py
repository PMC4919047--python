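import numpy as np
import pandas as pd
import pytest

from cflung.mbw import MbwAnalyzer
from cflung.synthetic import (
    LungModelParams,
    default_cohort_effects,
    generate_cohort,
    make_lung_fld_truth,
    simulate_mge_stack,
    simulate_washout,
)


@pytest.fixture(scope="session")
def single_comp_params():
    """Homogeneous lung matching the closed-form dilution series."""
    return LungModelParams(frc_total=3.0, tidal_volume=1.0, dead_space=0.0)


@pytest.fixture(scope="session")
def single_comp_trace(single_comp_params):
    return simulate_washout(single_comp_params)


@pytest.fixture(scope="session")
def two_comp_params():
    return LungModelParams.two_compartment(dead_space=0.15)


@pytest.fixture(scope="session")
def two_comp_trace(two_comp_params):
    return simulate_washout(two_comp_params)


@pytest.fixture(scope="session")
def analyzer():
    return MbwAnalyzer()


@pytest.fixture(scope="session")
def lung_truth():
    return make_lung_fld_truth()


@pytest.fixture(scope="session")
def lung_stack(lung_truth):
    return simulate_mge_stack(lung_truth)


@pytest.fixture(scope="session")
def cohort():
    return generate_cohort(default_cohort_effects(seed=20160623))


def cohort_long_mfld(df: pd.DataFrame) -> pd.DataFrame:
    """Wide cohort -> long (subject x volume x region) mFLD table."""
    rows = []
    for _, s in df.iterrows():
        for vol in ("FRC", "TLC"):
            for reg in ("central", "peripheral"):
                rows.append(
                    dict(
                        subject=s["id"],
                        group=s["group"],
                        volume=vol,
                        region=reg,
                        value=s[f"{reg}_mfld_{vol.lower()}"],
                    )
                )
    return pd.DataFrame(rows)
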