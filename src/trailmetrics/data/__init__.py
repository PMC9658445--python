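"""Packaged worked-example data: the three Araripe UGG geosite trails."""

from importlib import resources
from pathlib import Path


def araripe_config_path() -> Path:
    """Path to the packaged Araripe trails configuration."""
    return Path(resources.files(__package__) / "araripe.yaml")
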