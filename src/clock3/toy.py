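"""A small synthetic activator–repressor relaxation oscillator.

Nine species, fifteen rates: an activator protein ``A`` binds its own
promoter (positive feedback) and the repressor's promoter; both genes
transcribe with a basal and a strongly activator-enhanced rate; the repressor
``R`` sequesters ``A`` into a complex ``C`` in which the activator decays,
releasing ``R``.  Positive feedback plus stoichiometric sequestration gives
robust relaxation oscillations over a broad parameter range, which makes this
network a convenient ground-truth system: condition registries can be
generated from known rates and an estimator must recover the period
phenotypes.

This is a synthetic benchmark network, not a reduction of the full clock.
The default rates put the free-running period near a circadian day.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .network import Reaction, ReactionNetwork, TermKind
from .species import Kind, SpeciesCode

__all__ = ["ToyParams", "ToyNetwork", "TOY_DEFAULTS",
           "build_toy_network", "toy_initial_state"]

TOY_DEFAULTS: dict[str, float] = {
    "thA": 0.03133,      # A binding its own promoter (1/(a.u. h))
    "thAd": 1.566519,    # ... unbinding (1/h)
    "thR": 0.03133,      # A binding the repressor promoter
    "thRd": 3.133038,    # ... unbinding
    "aA": 12.532151,     # basal transcription, activator gene (1/h)
    "aAp": 125.321511,   # activated transcription, activator gene
    "aR": 0.006266,      # basal transcription, repressor gene
    "aRp": 12.532151,    # activated transcription, repressor gene
    "bA": 12.532151,     # translation, activator (1/h)
    "bR": 1.253215,      # translation, repressor
    "umA": 3.133038,     # activator mRNA decay (1/h)
    "umR": 0.313304,     # repressor mRNA decay
    "dA": 0.626608,      # activator decay (1/h)
    "dR": 0.125322,      # repressor decay
    "gC": 1.253215,      # decay of A inside the A-R complex, releasing R (1/h)
}

#: association rate of A and R (fixed; sequestration is fast and tight)
TOY_SEQUESTRATION_RATE = 0.062661


class ToyParams:
    """Plain named-rate container with the mapping surface the compiler needs."""

    def __init__(self, values: Mapping[str, float] | None = None):
        values = dict(values or {})
        unknown = set(values) - set(TOY_DEFAULTS)
        if unknown:
            raise KeyError(f"unknown toy parameters: {sorted(unknown)}")
        self.values = {**TOY_DEFAULTS, **values, "at": TOY_SEQUESTRATION_RATE}

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def replace(self, **edits: float) -> "ToyParams":
        vals = {k: v for k, v in self.values.items() if k != "at"}
        vals.update(edits)
        return ToyParams(vals)


class ToyNetwork(ReactionNetwork):
    def default_initial_state(self) -> np.ndarray:
        return toy_initial_state(self)


def build_toy_network() -> ToyNetwork:
    def sp(lab: str) -> SpeciesCode:
        kind = (Kind.promoter_state if lab.startswith("D")
                else Kind.mRNA if lab.startswith("M") else Kind.protein_complex)
        return SpeciesCode(lab, kind)

    species = [sp(l) for l in
               ("DA", "DAa", "DR", "DRa", "MA", "MR", "A", "R", "C")]
    rx = [
        Reaction("thA", ("DA", "A"), ("DAa",), TermKind.binding),
        Reaction("thAd", ("DAa",), ("DA", "A"), TermKind.unbinding),
        Reaction("thR", ("DR", "A"), ("DRa",), TermKind.binding),
        Reaction("thRd", ("DRa",), ("DR", "A"), TermKind.unbinding),
        Reaction("aA", ("DA",), ("DA", "MA"), TermKind.transcription_activation),
        Reaction("aAp", ("DAa",), ("DAa", "MA"),
                 TermKind.transcription_activation),
        Reaction("aR", ("DR",), ("DR", "MR"), TermKind.transcription_activation),
        Reaction("aRp", ("DRa",), ("DRa", "MR"),
                 TermKind.transcription_activation),
        Reaction("bA", ("MA",), ("MA", "A"), TermKind.translation),
        Reaction("bR", ("MR",), ("MR", "R"), TermKind.translation),
        Reaction("umA", ("MA",), (), TermKind.degradation),
        Reaction("umR", ("MR",), (), TermKind.degradation),
        Reaction("dA", ("A",), (), TermKind.degradation),
        Reaction("dR", ("R",), (), TermKind.degradation),
        Reaction("at", ("A", "R"), ("C",), TermKind.binding),
        Reaction("gC", ("C",), ("R",), TermKind.degradation),
    ]
    return ToyNetwork(species, rx, list(TOY_DEFAULTS) + ["at"])


def toy_initial_state(network: ReactionNetwork) -> np.ndarray:
    x0 = np.zeros(network.n_species)
    x0[network.index["DA"]] = 1.0
    x0[network.index["DR"]] = 1.0
    x0[network.index["A"]] = 1.0
    return x0
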