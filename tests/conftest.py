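import numpy as np
import pytest

from lipidbank import synthetic as syn
from lipidbank import workflow as wf


MINIMAL_ENTRY_YAML = """\
DOI: 10.5281/zenodo.0000000
TRJ: traj.xtc
TPR: topol.tpr
SOFTWARE: gromacs
TEMPERATURE: 310.0
TIMELEFTOUT: 0.0
TRJLENGTH: 500.0
COMPOSITION:
  POPC:
    NAME: POPC
    MAPPING: POPC_fixture.yaml
    COUNT: 128
  SOL:
    NAME: TIP3
    MAPPING: SOL_fixture.yaml
    COUNT: 5120
"""


@pytest.fixture
def minimal_entry_yaml() -> str:
    return MINIMAL_ENTRY_YAML


@pytest.fixture(scope="session")
def mini_databank(tmp_path_factory):
    """One synthetic mini-databank tree, analyzed end to end."""
    root = syn.make_mini_databank(tmp_path_factory.mktemp("databank"), seed=7)
    records = wf.run_pipeline(root)
    return root, records


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
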