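import numpy as np
import pytest

from cpreeg.config import CouplingModel, RunConfig, ScenarioConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def coupling():
    return CouplingModel()


@pytest.fixture
def fast_scenario():
    """Shrunk timeline for quick subject-level tests (structure unchanged)."""
    return ScenarioConfig(
        baseline_s=10.0,
        untreated_vf_s=12.0,
        decay_delay_s=2.0,
        decay_tau_s=2.0,
        compression_s=8.0,
        pause_s=3.5,
        post_shock_gap_s=2.0,
        monitoring_s=10.0,
        seed=7,
    )


@pytest.fixture
def fast_run_config(fast_scenario, tmp_path):
    return RunConfig(
        mode="simulate",
        n_subjects=2,
        scenario=fast_scenario,
        out_dir=str(tmp_path / "out"),
        seed=11,
    )
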