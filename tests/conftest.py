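import pytest
from hypothesis import settings

from mztseq.simulate import SimulationConfig
from mztseq.pipeline import Workspace

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_ws() -> Workspace:
    """The default study-condition dataset (2000 genes, 2 reps, 1e6 reads)."""
    return Workspace.from_config(SimulationConfig(), with_sequences=True)


@pytest.fixture(scope="session")
def small_ws() -> Workspace:
    """A reduced dataset for faster module-level checks."""
    return Workspace.from_config(
        SimulationConfig(n_genes=400, seed=5), with_sequences=True
    )
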