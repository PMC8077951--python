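import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from isomirpe.pipeline import RunConfig, run_experiment
from isomirpe.reference import anchor_all, make_synthetic_reference


@pytest.fixture(scope="session")
def small_reference():
    """20 synthetic miRNAs with anchors, shared across unit tests."""
    hairpins, matures, name_map = make_synthetic_reference(20, seed=11)
    anchors = anchor_all(matures, hairpins, name_map)
    return hairpins, matures, name_map, anchors


@pytest.fixture(scope="session")
def hiseq_experiment():
    """Full-scale four-mode experiment under the default error profile."""
    return run_experiment(RunConfig(seed=1, n_mirnas=100, n_replicates=3))


@pytest.fixture(scope="session")
def clean_experiment():
    """Error-free, no-orientation-discard experiment: counts are exact."""
    return run_experiment(
        RunConfig(
            seed=1,
            n_mirnas=100,
            n_replicates=1,
            profile_kind="uniform",
            profile_epsilon=0.0,
            discard_rc=False,
            eval_tolerance=0.0,
            n_perm=50,
        )
    )
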