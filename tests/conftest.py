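import pathlib
import sys

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(pathlib.Path(__file__).parent))  # for `import oracles`

from causalsupport import ModelConfig, extract_pair_dataset, load_design

settings.register_profile(
    "suite", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_config():
    return ModelConfig()


@pytest.fixture(scope="session")
def designs():
    return {group: load_design(group) for group in ("C_strong_I_weak", "C_weak_I_strong")}


@pytest.fixture(scope="session")
def scenario_datasets(designs):
    """The eight model-input datasets: 2 pairs x 2 groups x 2 phases (phase 2 cumulative)."""
    datasets = []
    for group, design in designs.items():
        for pair in ("confounded_CD", "interacting_IJ"):
            for phase, cumulative in (("phase1", False), ("phase2", True)):
                datasets.append(extract_pair_dataset(design, pair, phase, cumulative=cumulative))
    return datasets
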