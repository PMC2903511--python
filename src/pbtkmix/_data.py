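"""Access to packaged configuration data."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml


def packaged_data_path(*parts: str) -> Path:
    """Filesystem path of a packaged data file (``pbtkmix/data/...``)."""
    root = resources.files("pbtkmix") / "data"
    path = root.joinpath(*parts)
    return Path(str(path))


def load_packaged_yaml(*parts: str) -> dict:
    with open(packaged_data_path(*parts)) as fh:
        return yaml.safe_load(fh)
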