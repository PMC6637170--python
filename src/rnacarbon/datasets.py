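"""Access to the bundled data files (end-member table, RNA sample,
method-validation table, synthetic demo community)."""

from __future__ import annotations

import importlib.resources
from pathlib import Path

__all__ = ["path", "rifle_endmembers", "rifle_sample", "table1"]


def path(name: str) -> Path:
    """Filesystem path of a bundled data file."""
    p = Path(importlib.resources.files("rnacarbon.data") / name)
    if not p.exists():
        raise FileNotFoundError(f"no bundled data file named {name!r}")
    return p


def rifle_endmembers():
    """Rifle LQ107 end-member table as a list of :class:`EndMember`."""
    from .mixing import read_endmembers

    return read_endmembers(path("rifle_endmembers.csv"))


def rifle_sample():
    """The groundwater RNA measurement as ``(name, delta14c, sigma)``."""
    from .mixing import read_sample

    return read_sample(path("rifle_sample.csv"))


def table1():
    """The method-validation table as a DataFrame (integrity-checked)."""
    from .validation import load_table1

    return load_table1()
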