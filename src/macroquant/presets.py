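"""Named parameter presets.

The bundled ``presets.yaml`` collects every scalar the study prints that
the simulators and recovery tests depend on (speeds, persistence
indices, membrane/cytoplasm ratios, intensity and shape moments).  Each
entry in the file carries a provenance comment.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigError

_CACHE: dict | None = None


def load_presets(path: str | Path | None = None) -> dict:
    """Load the preset bundle as a nested dict.

    Parameters
    ----------
    path
        Optional path to an alternative YAML preset file.  By default the
        bundled ``presets.yaml`` is loaded (and cached).
    """
    global _CACHE
    if path is not None:
        with open(path) as fh:
            return yaml.safe_load(fh)
    if _CACHE is None:
        text = resources.files("macroquant").joinpath("presets.yaml").read_text()
        _CACHE = yaml.safe_load(text)
    return _CACHE


def get_preset(dotted: str, presets: dict | None = None):
    """Resolve a dotted preset key, e.g. ``"tracks.control_pre_gb.speed_um_min"``.

    Raises
    ------
    ConfigError
        If any key along the path does not exist.
    """
    node = presets if presets is not None else load_presets()
    for key in dotted.split("."):
        if not isinstance(node, dict) or key not in node:
            raise ConfigError(f"unknown preset {dotted!r} (failed at {key!r})")
        node = node[key]
    return node
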