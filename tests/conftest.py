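import numpy as np
import pandas as pd
import pytest

from iscn.atlas import dk_atlas_fixture, thickness_columns
from iscn.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def atlas():
    return dk_atlas_fixture()


@pytest.fixture(scope="session")
def thk_cols():
    return thickness_columns()


@pytest.fixture(scope="session")
def small_cohort():
    """300-subject, 3-site cohort with default planted structure."""
    cfg = SimulationConfig(n_cases=140, n_controls=160, n_sites=3, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """Single-site cohort with no batch effects (for calibration checks)."""
    cfg = SimulationConfig(
        n_cases=150, n_controls=250, n_sites=1, seed=7,
        site_shift_sd=0.0, site_scale_sd=0.0,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full demonstration pipeline run, shared across tests."""
    from iscn.pipeline import PipelineConfig, run_pipeline
    from iscn.simulate import demo_cohort

    df, truth = demo_cohort(seed=0)
    out = run_pipeline(PipelineConfig.demo(), df, tmp_path_factory.mktemp("run") / "a")
    return df, truth, out


def make_frame(thickness: np.ndarray, dx=None, seed: int = 0) -> pd.DataFrame:
    """Wrap a subjects x 68 thickness array in a minimal cohort table."""
    rng = np.random.default_rng(seed)
    n = thickness.shape[0]
    df = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "site": ["site00"] * n,
            "dx": np.zeros(n, dtype=int) if dx is None else np.asarray(dx),
            "age": rng.uniform(20, 60, n),
            "sex": rng.choice(["F", "M"], n),
            "icv": rng.normal(1.5e6, 1e5, n),
            "duration": np.nan,
        }
    )
    return pd.concat(
        [df, pd.DataFrame(thickness, columns=thickness_columns())], axis=1
    )
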