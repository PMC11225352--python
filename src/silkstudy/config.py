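"""Packaged default constants.

The shipped ``defaults.yaml`` holds every structural constant of the transport
model (compartment volume coefficients, processing delay, leucine infusion
settings, unit conversions).  They are configuration, not code: modules read them
through :func:`load_defaults` and accept overrides everywhere.
"""

from __future__ import annotations

import copy
import functools
from importlib import resources

import yaml


@functools.lru_cache(maxsize=1)
def _load_defaults_cached() -> dict:
    text = resources.files("silkstudy").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def load_defaults() -> dict:
    """Return a deep copy of the packaged default configuration."""
    return copy.deepcopy(_load_defaults_cached())


def defaults_view() -> dict:
    """Read-only view of the packaged defaults (no copy).

    Hot paths (the simulator inside the grid fit) read structural constants
    thousands of times; callers must not mutate the returned mapping.
    """
    return _load_defaults_cached()


def volume_coefficients(defaults: dict | None = None) -> dict[str, tuple[float, float]]:
    """Age-linear (a, b) coefficients per CSF compartment, mL and mL/year."""
    d = defaults or defaults_view()
    vols = d["volumes"]
    return {
        name: (float(vols[name]["a"]), float(vols[name]["b"]))
        for name in ("ventricular", "cisternal", "cranial_sas")
    }
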