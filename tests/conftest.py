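import numpy as np
import pandas as pd
import pytest

from mitoabund.synthio import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort reused by read-only tests."""
    return simulate_cohort(SimulationConfig(seed=42, n_samples=600, n_variants=20))


@pytest.fixture(scope="session")
def truth_only_config():
    """Config with minimal probe/variant payload for truth-level studies."""
    def make(seed, n_samples, **kw):
        return SimulationConfig(
            seed=seed, n_samples=n_samples, n_mt_probes=2, n_auto_probes=2,
            n_variants=kw.pop("n_variants", 2), **kw,
        )
    return make


def make_intensity(l2r: np.ndarray, panel: str, sample_ids=None, probe_ids=None) -> pd.DataFrame:
    """Wide L2R matrix (samples x probes) -> long intensity table."""
    n, p = l2r.shape
    sample_ids = sample_ids or [f"S{i}" for i in range(n)]
    probe_ids = probe_ids or [f"{panel}_{j}" for j in range(p)]
    return pd.DataFrame(
        {
            "sample_id": np.repeat(sample_ids, p),
            "probe_id": np.tile(probe_ids, n),
            "panel": panel,
            "l2r": l2r.ravel(),
        }
    )
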