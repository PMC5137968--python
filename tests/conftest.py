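import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from mmse_groups.scoring import CATEGORIES, builtin_systems
from mmse_groups.synthetic import generate_cohort, scaled_config


@pytest.fixture(scope="session")
def systems():
    return builtin_systems()


@pytest.fixture(scope="session")
def small_cohort():
    """A ~10%-scale cohort with the default (published) structure."""
    return generate_cohort(scaled_config(0.1, seed=7))


def rates_frame(rows: dict[str, tuple[float, ...]]) -> pd.DataFrame:
    """Build a rates table from {patient_id: (orientation, ..., language)}."""
    out = []
    for pid, vals in rows.items():
        rec = {"patient_id": pid}
        rec.update(dict(zip(CATEGORIES, vals)))
        out.append(rec)
    return pd.DataFrame(out)
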