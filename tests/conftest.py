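from pathlib import Path

import pytest

from trailmetrics.data import araripe_config_path
from trailmetrics.pipeline import run_pipeline
from trailmetrics.trail_model import read_segment_table


DATA_DIR = Path(araripe_config_path()).parent


@pytest.fixture(scope="session")
def araripe_config():
    return araripe_config_path()


@pytest.fixture(scope="session")
def sitio_fundao():
    return read_segment_table(DATA_DIR / "sitio_fundao.csv", name="Sítio Fundão")


@pytest.fixture(scope="session")
def pontal():
    return read_segment_table(DATA_DIR / "pontal_santa_cruz.csv", name="Pontal de Santa Cruz")


@pytest.fixture(scope="session")
def missao_velha():
    return read_segment_table(DATA_DIR / "missao_velha.csv", name="Missão Velha Waterfall")


@pytest.fixture(scope="session")
def araripe_result(araripe_config):
    with pytest.warns(UserWarning):
        return run_pipeline(araripe_config, seed=1)
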