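"""Fitted parameter-set fixtures shipped with the package.

The ensemble was produced by reduced-scale SRES runs against the full
16-condition registry (seeded, reproducible via ``clock3 fit``), then
verified at the standard simulation configuration.  Each file round-trips
through :class:`~clock3.network.ParameterSet` text I/O.
"""

from __future__ import annotations

import importlib.resources

from .network import ParameterSet

__all__ = ["load_fitted_ensemble", "fixture_names"]


def _fixture_dir():
    return importlib.resources.files("clock3").joinpath("data/fitted")


def fixture_names() -> list[str]:
    return sorted(p.name for p in _fixture_dir().iterdir()
                  if p.name.endswith(".txt"))


def load_fitted_ensemble() -> list[ParameterSet]:
    """All shipped fitted parameter sets, in filename order."""
    out = []
    for name in fixture_names():
        text = _fixture_dir().joinpath(name).read_text()
        out.append(ParameterSet.from_text(text))
    if not out:
        raise FileNotFoundError("no fitted parameter-set fixtures found")
    return out
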