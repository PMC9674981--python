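import numpy as np
import pytest
from hypothesis import settings

import vimflow as vf
from vimflow.population import calibrate_for_pipeline

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def matched_calibration():
    """Deterministic calibration matched to the pipeline's conventions."""
    return calibrate_for_pipeline(seed=0)


@pytest.fixture(scope="session")
def salt_condition_set():
    """One low/high salt synthetic experiment reused across tests.

    High salt: 1.48-fold faster lateral assembly, 3x elongation rate,
    1.6-fold mass per cross section, stronger compaction overshoot.
    """
    base = vf.TraceConfig(sample_rate=1000.0)
    levels = [
        dict(salt=50.0, lateral_factor=1.0, elongation_rate=1.0,
             mass_per_cs_factor=1.0, compaction_overshoot=0.05),
        dict(salt=160.0, lateral_factor=1.48, elongation_rate=3.0,
             mass_per_cs_factor=1.6, compaction_overshoot=0.4),
    ]
    traces = vf.generate_condition_set(base, levels, n_replicates=3, seed=5)
    low = [t for t in traces if t.meta["condition_index"] == 0]
    high = [t for t in traces if t.meta["condition_index"] == 1]
    return {"low": low, "high": high, "levels": levels, "base": base}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
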