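"""Access to the packaged default configuration files (YAML).

Available names: ``default_cohort.yaml`` (two-arm cohort spec),
``base_case_cost.yaml`` (cost-model base case), ``best_case.yaml`` /
``worst_case.yaml`` (sensitivity scenarios), ``ebus_arms.yaml``
(staging-pathway arm inputs). These mirror the in-code defaults; tests
keep the two in sync.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path


def packaged_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    path = resources.files("mdcecon").joinpath("data", name)
    with resources.as_file(path) as p:
        return Path(p)


def list_packaged() -> list:
    return sorted(p.name for p in resources.files("mdcecon").joinpath("data").iterdir())
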