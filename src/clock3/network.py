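"""Reaction network of the extended human circadian clock and its ODE compiler.

The model couples the canonical mammalian transcription–translation feedback
loops: the BMAL1–CLOCK/NPAS2 activator (``x000L1``) binds E-box promoters of
*PER1/2/3*, *CRY1/2* and *REV-ERB*; CRY proteins repress both by sequestering
the free activator and by binding the promoter-bound activator; REV-ERB closes
the secondary loop by repressing *BMAL1* transcription.  PER proteins are
phosphorylated by CKIδ/ε, which licenses CRY binding and nuclear transport and
tags PER for faster turnover.  PER3 enters the network as a monomer that pairs
with PER1 (``an``/``dn``); its phosphorylation by CKIδ/ε happens only inside
the PER1–PER3 pair, no PER2–PER3 pair exists, and PER3 and its pair interact
with CRY1/2 and the BMAL1–CLOCK activator directly.  GSK3β phosphorylates
BMAL1 and REV-ERB; CKIδ/ε phosphorylates CLOCK; the kinases themselves are
conserved pools (no synthesis or degradation).

All reactions are mass action (order 0–2).  The derivative of cytoplasmic
unphosphorylated PER1 is exactly

    d(x10000)/dt = tlpo*McPo - upuo*x10000 - ac*x00100*x10000 + dc*x10100
                   - an*x70000*x10000 + dn*x80000

i.e. translation, degradation, CKIδ/ε binding/unbinding and PER1–PER3
pairing/unpairing are the only processes that touch the bare cytoplasmic
monomer.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .species import (
    ACTIVATED_GENES,
    GENES,
    Kind,
    SpeciesCode,
    SpeciesCountError,
    StructuralRules,
    enumerate_species,
)

__all__ = [
    "TermKind",
    "Reaction",
    "ParameterSet",
    "ReactionNetwork",
    "ClockNetwork",
    "build_network",
    "build_rhs",
    "load_whitelist",
    "PARAM_DEFAULTS",
    "PARAM_ROLES",
    "TRANSCRIPTION_RATE",
]


class TermKind(str, Enum):
    translation = "translation"
    degradation = "degradation"
    binding = "binding"
    unbinding = "unbinding"
    phosphorylation = "phosphorylation"
    transport = "transport"
    transcription_activation = "transcription_activation"
    transcription_repression = "transcription_repression"


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction.  ``name`` is the rate-constant symbol; the
    kinetic order equals ``len(reactants)`` (0 = constitutive)."""

    name: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    term_kind: TermKind

    def __post_init__(self) -> None:
        if len(self.reactants) > 2:
            raise ValueError(f"{self.name}: mass action supports at most 2 reactants")


# ---------------------------------------------------------------------------
# parameter table: name -> (default value, term family)
# first-order rates in 1/h, bimolecular rates in 1/(a.u. * h)
# ---------------------------------------------------------------------------

def _per_gene(prefix: str, value: float | Mapping[str, float]) -> dict[str, float]:
    if isinstance(value, Mapping):
        return {f"{prefix}{g.lower()}": value[g] for g in GENES}
    return {f"{prefix}{g.lower()}": value for g in GENES}


PARAM_DEFAULTS: dict[str, float] = {
    # transcription (zero/first order; knockouts zero these)
    "trpo": 2.0, "trpt": 2.0, "trpth": 2.0, "trco": 2.0, "trct": 2.0,
    "trrev": 2.0, "trb": 2.0, "trcl": 0.5,
    # E-box / RORE promoter binding
    "ga": 5.0, "gd": 0.5,
    "gar1": 20.0, "gdr1": 0.1, "gar2": 20.0, "gdr2": 1.0,
    "grev": 10.0, "gdrev": 0.5,
    # mRNA export and decay, per gene
    **_per_gene("ex", 0.5),
    **_per_gene("um", 0.3),
    # translation
    "tlpo": 2.0, "tlpt": 2.0, "tlpth": 2.0, "tlco": 2.0, "tlct": 2.0,
    "tlb": 2.0, "tlcl": 2.0, "tlrev": 2.0,
    # CKIδ/ε binding
    "ac": 2.0, "dc": 0.2, "acth": 20.0, "dcth": 0.2, "accl": 0.5, "dccl": 0.5,
    # phosphorylation
    "hoo": 0.5, "hot": 0.5, "hoth": 0.5, "hocl": 0.2,
    # GSK3β binding and its substrates
    "ag": 1.0, "dg": 1.0, "agb": 0.5, "dgb": 0.5, "hob": 0.2,
    "agr": 0.5, "dgr": 0.5, "hor": 0.2,
    # PER–CRY binding (PER1/2 require bound CKIδ/ε; PER3/pair do not)
    "arco": 5.0, "drco": 0.1, "arct": 5.0, "drct": 0.5,
    "arcth": 20.0, "drcth": 0.1,
    # PER1–PER3 pairing
    "an": 2.0, "dn": 0.2,
    # BMAL1–CLOCK complex and activator sequestration
    "abc": 5.0, "dbc": 0.1, "inbc": 0.5,
    "abro": 20.0, "dbro": 0.05, "abrt": 20.0, "dbrt": 0.5,
    "ab": 5.0, "dab": 0.5, "abth": 5.0, "dabth": 0.5,
    # transport
    "ink": 0.2, "exk": 0.2, "inp": 0.5, "expp": 0.1, "incr": 0.3, "excr": 0.1,
    "inb": 0.3, "incl": 0.3, "inrev": 0.5,
    # degradation
    "upuo": 0.3, "uppo": 1.5, "uput": 0.3, "uppt": 1.5,
    "upth": 0.3, "uppth": 1.5, "uro": 0.3, "urt": 0.6,
    "ub": 0.3, "upb": 1.5, "ucl": 0.2, "upcl": 1.0, "urev": 1.0, "uprev": 2.0,
}

#: gene -> its transcription-rate parameter (knockout = set to zero)
TRANSCRIPTION_RATE: dict[str, str] = {
    "PER1": "trpo", "PER2": "trpt", "PER3": "trpth", "CRY1": "trco",
    "CRY2": "trct", "REV-ERBa/b": "trrev", "BMAL1": "trb", "CLOCK/NPAS2": "trcl",
}

#: biochemical role tags used by variant perturbations and rate comparisons.
PARAM_ROLES: dict[str, tuple[str, ...]] = {
    "acth": ("per3_cki_binding",), "dcth": (),
    "ac": ("per1_cki_binding", "per2_cki_binding"),
    "hoth": ("per3_phosphorylation",),
    "hoo": ("per1_phosphorylation",), "hot": ("per2_phosphorylation",),
    "upth": ("per3_degradation",), "uppth": ("per3_degradation",),
    "upuo": ("per1_degradation",), "uput": ("per2_degradation",),
    "an": ("per1_per3_binding",), "dn": (),
    "arcth": ("per3_cry_binding",),
    "arco": ("per1_cry_binding", "per2_cry_binding"),
    "arct": ("per1_cry_binding", "per2_cry_binding"),
    "tlpo": ("per1_translation",), "tlpt": ("per2_translation",),
    "tlpth": ("per3_translation",),
}

#: parameters introduced for PER3 (absent from the PER1/PER2-only core);
#: these get wide log-space priors anchored on their PER1/PER2 homologs.
PER3_NEW_PARAMS: dict[str, str] = {
    "trpth": "trpo", "expth": "expo", "umpth": "umpo", "tlpth": "tlpo",
    "acth": "ac", "dcth": "dc", "hoth": "hoo",
    "arcth": "arco", "drcth": "drco",
    "an": "ac", "dn": "dc", "abth": "ab", "dabth": "dab",
    "upth": "upuo", "uppth": "uppo",
}


# ---------------------------------------------------------------------------
# reaction generation
# ---------------------------------------------------------------------------

PER12 = (1, 2, 3, 4)
PER3P = (7, 8, 9)
PHOSPHO_P = {1: 3, 2: 4, 8: 9}
PHOSPHO_RATE = {1: "hoo", 2: "hot", 8: "hoth"}
#: PER-unit turnover rates.  The unphosphorylated PER1–PER3 pair (P=8) has no
#: degradation reaction of its own: it turns over through PER3 phosphorylation
#: (then ``uppth``) or by unpairing — phospho-gated turnover, which is what
#: makes the pair's lifetime sensitive to the PER3 phosphorylation rate.
P_DEG_RATE = {1: "upuo", 2: "uput", 3: "uppo", 4: "uppt",
              7: "upth", 9: "uppth"}


def _gene_suffix(g: str) -> str:
    return g.lower()


def build_reactions(species: Sequence[SpeciesCode]) -> list[Reaction]:
    labels = {s.label for s in species}
    rx: list[Reaction] = []

    def add(name: str, reactants: Iterable[str], products: Iterable[str],
            kind: TermKind) -> None:
        r, p = tuple(reactants), tuple(products)
        for lab in (*r, *p):
            if lab not in labels:
                raise KeyError(f"reaction {name}: unknown species {lab}")
        rx.append(Reaction(name, r, p, kind))

    # transcription ---------------------------------------------------------
    for g in ACTIVATED_GENES:
        add(f"tr{_gene_suffix(g)}", [f"G{g}A"], [f"G{g}A", f"Mn{g}"],
            TermKind.transcription_activation)
    add("trb", ["GB"], ["GB", "MnB"], TermKind.transcription_activation)
    add("trcl", [], ["MnCl"], TermKind.transcription_activation)

    # promoter binding ------------------------------------------------------
    for g in ACTIVATED_GENES:
        add("ga", [f"G{g}", "x00011"], [f"G{g}A"], TermKind.binding)
        add("gd", [f"G{g}A"], [f"G{g}", "x00011"], TermKind.unbinding)
        for r, cry in ((1, "x01010"), (2, "x02010")):
            add(f"gar{r}", [f"G{g}A", cry], [f"G{g}AR{r}"],
                TermKind.transcription_repression)
            add(f"gdr{r}", [f"G{g}AR{r}"], [f"G{g}A", cry], TermKind.unbinding)
    add("grev", ["GB", "Revn"], ["GBRev"], TermKind.transcription_repression)
    add("gdrev", ["GBRev"], ["GB", "Revn"], TermKind.unbinding)

    # mRNA export / decay / translation -------------------------------------
    translated = {"Po": "x10000", "Pt": "x20000", "Pth": "x70000",
                  "Co": "x01000", "Ct": "x02000", "B": "Bc", "Cl": "Clc",
                  "Rev": "Revc"}
    for g in GENES:
        s = _gene_suffix(g)
        add(f"ex{s}", [f"Mn{g}"], [f"Mc{g}"], TermKind.transport)
        add(f"um{s}", [f"Mc{g}"], [], TermKind.degradation)
        add(f"tl{s}", [f"Mc{g}"], [f"Mc{g}", translated[g]], TermKind.translation)

    def x(P: int, C: int, K: int, L: int, B: int) -> str:
        return f"x{P}{C}{K}{L}{B}"

    def per_lb() -> list[tuple[int, int]]:
        return [(0, 0), (1, 0), (1, 1)]

    def cry_lb() -> list[tuple[int, int]]:
        return [(0, 0), (1, 0), (1, 1), (0, 1)]

    kin = {0: "x00100", 1: "x00110"}     # free CKIδ/ε by compartment
    gsk = {0: "x00200", 1: "x00210"}     # free GSK3β
    bcf = {0: "x00001", 1: "x00011"}     # free activator

    # CKIδ/ε binding to PER species -----------------------------------------
    for P in (*PER12, *PER3P):
        a, d = ("acth", "dcth") if P in PER3P else ("ac", "dc")
        for C in (0, 1, 2):
            for L, B in per_lb():
                add(a, [x(P, C, 0, L, B), kin[L]], [x(P, C, 1, L, B)],
                    TermKind.binding)
                add(d, [x(P, C, 1, L, B)], [x(P, C, 0, L, B), kin[L]],
                    TermKind.unbinding)
    for L, loc in ((0, "c"), (1, "n")):
        add("accl", [f"Cl{loc}", kin[L]], [f"ClK{loc}"], TermKind.binding)
        add("dccl", [f"ClK{loc}"], [f"Cl{loc}", kin[L]], TermKind.unbinding)
        add("hocl", [f"ClK{loc}"], [f"PCl{loc}", kin[L]], TermKind.phosphorylation)
    # PER1/PER2-carried CKIδ/ε phosphorylates promoter-bound CLOCK, evicting
    # the activator from the E-box (BMAL1 is released, CLOCK leaves
    # phosphorylated); the engagement rate is the CKIδ/ε-CLOCK one
    for P in (1, 2, 3, 4, 8, 9):
        for C in (0, 1, 2):
            carrier = x(P, C, 1, 1, 0)
            for g in ACTIVATED_GENES:
                add("accl", [carrier, f"G{g}A"],
                    [carrier, f"G{g}", "Bn", "PCln"],
                    TermKind.transcription_repression)

    # phosphorylation of CKIδ/ε-bound PER; the kinase is released after the
    # catalytic step (it re-binds through ac/acth for further rounds)
    for P, Pp in PHOSPHO_P.items():
        for C in (0, 1, 2):
            for L, B in per_lb():
                add(PHOSPHO_RATE[P], [x(P, C, 1, L, B)],
                    [x(Pp, C, 0, L, B), kin[L]], TermKind.phosphorylation)

    # GSK3β on CRY, BMAL1 and REV-ERB ---------------------------------------
    for C in (1, 2):
        for L, B in cry_lb():
            add("ag", [x(0, C, 0, L, B), gsk[L]], [x(0, C, 2, L, B)],
                TermKind.binding)
            add("dg", [x(0, C, 2, L, B)], [x(0, C, 0, L, B), gsk[L]],
                TermKind.unbinding)
    for base, (a, d, h) in (("B", ("agb", "dgb", "hob")),
                            ("Rev", ("agr", "dgr", "hor"))):
        for L, loc in ((0, "c"), (1, "n")):
            add(a, [f"{base}{loc}", gsk[L]], [f"{base}G{loc}"], TermKind.binding)
            add(d, [f"{base}G{loc}"], [f"{base}{loc}", gsk[L]], TermKind.unbinding)
            add(h, [f"{base}G{loc}"], [f"P{base}{loc}", gsk[L]],
                TermKind.phosphorylation)

    # PER–CRY binding --------------------------------------------------------
    for P in PER12:   # requires bound CKIδ/ε
        for C, (a, d) in ((1, ("arco", "drco")), (2, ("arct", "drct"))):
            for L, B in per_lb():
                add(a, [x(P, 0, 1, L, B), x(0, C, 0, L, 0)], [x(P, C, 1, L, B)],
                    TermKind.binding)
                add(d, [x(P, C, 1, L, B)], [x(P, 0, 1, L, B), x(0, C, 0, L, 0)],
                    TermKind.unbinding)
    for P in PER3P:   # PER3 interacts with CRY in any kinase state
        for C in (1, 2):
            for K in (0, 1):
                for L, B in per_lb():
                    add("arcth", [x(P, 0, K, L, B), x(0, C, 0, L, 0)],
                        [x(P, C, K, L, B)], TermKind.binding)
                    add("drcth", [x(P, C, K, L, B)],
                        [x(P, 0, K, L, B), x(0, C, 0, L, 0)], TermKind.unbinding)

    # PER1–PER3 pairing, both compartments.  Two channels share one rate pair:
    # bare monomers associate directly, and CKIδ/ε-primed PER1 recruits PER3
    # together with any CRY cargo (the kinase stays on the pair, the CRY with
    # PER3).  Unpairing returns the same partners.
    for L in (0, 1):
        add("an", [x(1, 0, 0, L, 0), x(7, 0, 0, L, 0)], [x(8, 0, 0, L, 0)],
            TermKind.binding)
        add("dn", [x(8, 0, 0, L, 0)], [x(1, 0, 0, L, 0), x(7, 0, 0, L, 0)],
            TermKind.unbinding)
        for C in (0, 1, 2):
            add("an", [x(1, 0, 1, L, 0), x(7, C, 0, L, 0)], [x(8, C, 1, L, 0)],
                TermKind.binding)
            add("dn", [x(8, C, 1, L, 0)], [x(1, 0, 1, L, 0), x(7, C, 0, L, 0)],
                TermKind.unbinding)

    # BMAL1–CLOCK complex formation, transport, sequestration ----------------
    for L, loc in ((0, "c"), (1, "n")):
        add("abc", [f"B{loc}", f"Cl{loc}"], [bcf[L]], TermKind.binding)
        add("dbc", [bcf[L]], [f"B{loc}", f"Cl{loc}"], TermKind.unbinding)
    add("inbc", ["x00001"], ["x00011"], TermKind.transport)
    for C, (a, d) in ((1, ("abro", "dbro")), (2, ("abrt", "dbrt"))):
        for K in (0, 2):
            for L in (0, 1):
                add(a, [x(0, C, K, L, 0), bcf[L]], [x(0, C, K, L, 1)],
                    TermKind.binding)
                add(d, [x(0, C, K, L, 1)], [x(0, C, K, L, 0), bcf[L]],
                    TermKind.unbinding)
    for P in (*PER12, *PER3P):  # PER-containing complexes engage it in the nucleus
        a, d = ("abth", "dabth") if P in PER3P else ("ab", "dab")
        for C in (0, 1, 2):
            for K in (0, 1):
                add(a, [x(P, C, K, 1, 0), "x00011"], [x(P, C, K, 1, 1)],
                    TermKind.binding)
                add(d, [x(P, C, K, 1, 1)], [x(P, C, K, 1, 0), "x00011"],
                    TermKind.unbinding)

    # transport --------------------------------------------------------------
    for K in (1, 2):
        add("ink", [x(0, 0, K, 0, 0)], [x(0, 0, K, 1, 0)], TermKind.transport)
        add("exk", [x(0, 0, K, 1, 0)], [x(0, 0, K, 0, 0)], TermKind.transport)
    for P in (*PER12, *PER3P):
        for C in (0, 1, 2):
            for K in (0, 1):
                if C == 0 and K == 0 and P not in (3, 4, 9):
                    continue  # bare unphosphorylated monomers stay put
                add("inp", [x(P, C, K, 0, 0)], [x(P, C, K, 1, 0)],
                    TermKind.transport)
                add("expp", [x(P, C, K, 1, 0)], [x(P, C, K, 0, 0)],
                    TermKind.transport)
    for C in (1, 2):
        for K in (0, 2):
            add("incr", [x(0, C, K, 0, 0)], [x(0, C, K, 1, 0)], TermKind.transport)
            add("excr", [x(0, C, K, 1, 0)], [x(0, C, K, 0, 0)], TermKind.transport)
    for name, base in (("inb", "B"), ("incl", "Cl"), ("inrev", "Rev")):
        add(name, [f"{base}c"], [f"{base}n"], TermKind.transport)

    # degradation ------------------------------------------------------------
    # PER unit removal destroys the PER content (the phosphorylated PER1–PER3
    # pair turns over as a unit); bound CKIδ/ε is released, CRY/activator
    # remainders survive as the corresponding species.
    for P in sorted(P_DEG_RATE):
        for C in (0, 1, 2):
            for K in (0, 1):
                for L, B in per_lb():
                    prods = []
                    if P == 9:
                        # proteasomal targeting of phospho-PER3: the PER1
                        # partner survives the pair's turnover and emerges
                        # phosphorylated (it passed through the CKIδ/ε cycle)
                        prods.append(x(3, C, K, L, B))
                    else:
                        if C or B:
                            prods.append(x(0, C, 0, L, B))
                        if K:
                            prods.append(kin[L])
                    add(P_DEG_RATE[P], [x(P, C, K, L, B)], prods,
                        TermKind.degradation)
    # CRY degrades only outside PER complexes (complexed CRY is protected)
    for C, rate in ((1, "uro"), (2, "urt")):
        for K in (0, 2):
            for L, B in cry_lb():
                prods = []
                if K:
                    prods.append(gsk[L])
                if B:
                    prods.append(bcf[L])
                add(rate, [x(0, C, K, L, B)], prods, TermKind.degradation)
    for base, (u, up) in (("B", ("ub", "upb")), ("Cl", ("ucl", "upcl")),
                          ("Rev", ("urev", "uprev"))):
        for loc in ("c", "n"):
            add(u, [f"{base}{loc}"], [], TermKind.degradation)
            add(up, [f"P{base}{loc}"], [], TermKind.degradation)

    return rx


# ---------------------------------------------------------------------------
# parameter sets
# ---------------------------------------------------------------------------

class ParameterSet:
    """Named nonnegative reaction rates with allowed ranges.

    Exactly one value per model parameter; every value must sit inside its
    range.  Text round-trip (`to_text`/`from_text`) preserves the decimal
    strings bit-exactly.
    """

    def __init__(self, values: Mapping[str, float],
                 ranges: Mapping[str, tuple[float, float]] | None = None):
        self.values = dict(values)
        self.ranges = {k: tuple(v) for k, v in (ranges or {}).items()} or \
            default_ranges(self.values)
        missing = set(PARAM_DEFAULTS) - set(self.values)
        extra = set(self.values) - set(PARAM_DEFAULTS)
        if missing or extra:
            raise ValueError(
                f"parameter set mismatch: missing={sorted(missing)}, "
                f"unknown={sorted(extra)}")
        for k, v in self.values.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {k} must be finite and >= 0, got {v}")
            lo, hi = self.ranges[k]
            if not (lo - 1e-12 <= v <= hi + 1e-12):
                raise ValueError(f"parameter {k}={v} outside range [{lo}, {hi}]")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def copy(self) -> "ParameterSet":
        return ParameterSet(self.values, self.ranges)

    def replace(self, **edits: float) -> "ParameterSet":
        vals = dict(self.values)
        ranges = dict(self.ranges)
        for k, v in edits.items():
            if k not in vals:
                raise KeyError(f"unknown parameter {k!r}")
            vals[k] = v
            lo, hi = ranges[k]
            ranges[k] = (min(lo, v), max(hi, v))
        return ParameterSet(vals, ranges)

    def to_text(self) -> str:
        lines = [f"{k}\t{self.values[k]!r}\t{self.ranges[k][0]!r}\t{self.ranges[k][1]!r}"
                 for k in sorted(self.values)]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ParameterSet":
        values: dict[str, float] = {}
        ranges: dict[str, tuple[float, float]] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            name, v = parts[0], float(parts[1])
            values[name] = v
            if len(parts) >= 4:
                ranges[name] = (float(parts[2]), float(parts[3]))
        return cls(values, ranges or None)

    @classmethod
    def defaults(cls) -> "ParameterSet":
        return cls(PARAM_DEFAULTS)


def default_ranges(values: Mapping[str, float]) -> dict[str, tuple[float, float]]:
    """±50% bands around each rate; PER3-specific rates get a 10× wider
    log-space band around their PER1/PER2 homolog (their biological prior)."""
    ranges: dict[str, tuple[float, float]] = {}
    for k, v in values.items():
        if k in PER3_NEW_PARAMS:
            anchor = values[PER3_NEW_PARAMS[k]]
            ranges[k] = (0.5 * anchor / 10.0, 1.5 * anchor * 10.0)
        else:
            ranges[k] = (0.5 * v, 1.5 * v)
        if k in PER3_NEW_PARAMS:
            lo, hi = ranges[k]
            ranges[k] = (min(lo, v), max(hi, v))
    return ranges


# ---------------------------------------------------------------------------
# the compiled network
# ---------------------------------------------------------------------------

@dataclass
class ReactionNetwork:
    """A mass-action reaction network compiled to flat ODE arrays.

    Base class carrying the machinery shared by the full clock model and the
    small synthetic networks used for estimator validation.
    """

    species: list[SpeciesCode]
    reactions: list[Reaction]
    parameters: list[str]

    index: dict[str, int] = field(init=False, repr=False)
    _compiled: tuple | None = field(default=None, init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = {s.label: i for i, s in enumerate(self.species)}
        used_species = {lab for r in self.reactions
                        for lab in (*r.reactants, *r.products)}
        unused = set(self.index) - used_species
        if unused:
            raise ValueError(f"species appear in no reaction: {sorted(unused)}")
        used_params = {r.name for r in self.reactions}
        if used_params != set(self.parameters):
            raise ValueError(
                f"parameter/reaction mismatch: "
                f"unused={sorted(set(self.parameters) - used_params)}, "
                f"unknown={sorted(used_params - set(self.parameters))}")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_parameters(self) -> int:
        return len(self.parameters)

    # -- compilation to flat arrays ----------------------------------------
    def compiled(self) -> tuple:
        """Per-reaction arrays: (param index, reactant1, reactant2, stoich CSR).

        ``reactant2 == -1`` marks first-order, both ``-1`` zero-order terms.
        The stoichiometry matrix maps reaction fluxes to species derivatives.
        """
        if self._compiled is None:
            pidx = {p: i for i, p in enumerate(self.parameters)}
            nrx = len(self.reactions)
            kidx = np.empty(nrx, dtype=np.int64)
            r1 = np.full(nrx, -1, dtype=np.int64)
            r2 = np.full(nrx, -1, dtype=np.int64)
            from scipy import sparse
            S = sparse.lil_matrix((self.n_species, nrx), dtype=np.float64)
            for j, rxn in enumerate(self.reactions):
                kidx[j] = pidx[rxn.name]
                rs = [self.index[lab] for lab in rxn.reactants]
                if rs:
                    r1[j] = rs[0]
                if len(rs) > 1:
                    r2[j] = rs[1]
                for i in rs:
                    S[i, j] -= 1.0
                for lab in rxn.products:
                    S[self.index[lab], j] += 1.0
            self._compiled = (kidx, r1, r2, S.tocsr())
        return self._compiled

    def rate_vector(self, params: ParameterSet) -> np.ndarray:
        missing = [p for p in self.parameters if p not in params.values]
        if missing:
            raise KeyError(f"missing parameters: {missing}")
        k = np.array([params[p] for p in self.parameters], dtype=np.float64)
        if np.any(k < 0):
            bad = [p for p, v in zip(self.parameters, k) if v < 0]
            raise ValueError(f"negative parameters: {bad}")
        return k

    def _group_conserved(self, indices: Sequence[int]) -> bool:
        kidx, r1, r2, S = self.compiled()
        col = np.asarray(S[indices, :].sum(axis=0)).ravel()
        return bool(np.all(col == 0))

    def default_initial_state(self) -> np.ndarray:
        """Uniform small positive preset; subclasses refine it."""
        return np.full(self.n_species, 0.1)


@dataclass
class ClockNetwork(ReactionNetwork):
    """The full extended clock network: exactly 208 state variables and 100
    named rates, with conserved kinase pools and promoter totals."""

    genes: tuple[str, ...] = ("PER1", "PER2", "PER3", "CRY1", "CRY2",
                              "BMAL1", "CLOCK/NPAS2", "REV-ERBa/b")

    def __post_init__(self) -> None:
        if len(self.species) != 208:
            raise SpeciesCountError(
                f"expected 208 state variables, got {len(self.species)}")
        if len(self.parameters) != 100:
            raise ValueError(f"expected 100 parameters, got {len(self.parameters)}")
        super().__post_init__()

    def conservation_groups(self) -> list[dict]:
        """Index sets whose summed derivative is identically zero.

        The kinase pools (CKIδ/ε, GSK3β across free and bound forms) and each
        gene's promoter states are conserved; verified symbolically by summing
        stoichiometric contributions.
        """
        groups = []
        cki = [s.label for s in self.species
               if (s.is_x and (s.K == 1 or (s.P == 0 and s.C == 0 and s.K == 1)))
               or s.label.startswith("ClK")]
        gsk = [s.label for s in self.species if (s.is_x and s.K == 2)
               or s.label in ("BGc", "BGn", "RevGc", "RevGn")]
        groups.append({"name": "CKId/e", "members": cki})
        groups.append({"name": "GSK3b", "members": gsk})
        for g in ACTIVATED_GENES:
            groups.append({"name": f"promoter_{g}",
                           "members": [f"G{g}", f"G{g}A", f"G{g}AR1", f"G{g}AR2"]})
        groups.append({"name": "promoter_B", "members": ["GB", "GBRev"]})
        for grp in groups:
            grp["indices"] = [self.index[lab] for lab in grp["members"]]
            grp["conserved"] = self._group_conserved(grp["indices"])
        return groups

    def default_initial_state(self) -> np.ndarray:
        """Structured preset: free promoters at unit copy number, free kinases
        at 1.0 a.u. (these set the conserved pools), bound kinase/promoter
        forms empty, everything else 0.1 a.u.  Limit-cycle features are
        insensitive to this choice once the transient is discarded."""
        x0 = np.full(self.n_species, 0.1)
        for s in self.species:
            if s.kind is Kind.promoter_state:
                x0[self.index[s.label]] = 1.0 if s.label in (
                    "GB", "GPo", "GPt", "GPth", "GCo", "GCt", "GRev") else 0.0
            elif s.is_x and (s.K or 0) > 0 and (s.P or s.C):
                x0[self.index[s.label]] = 0.0
            elif s.label in ("BGc", "BGn", "ClKc", "ClKn", "RevGc", "RevGn"):
                x0[self.index[s.label]] = 0.0
        for lab in ("x00100", "x00110", "x00200", "x00210"):
            x0[self.index[lab]] = 1.0
        return x0


def load_whitelist() -> list[str]:
    ref = importlib.resources.files("clock3").joinpath("data/species_whitelist.txt")
    return [ln.strip() for ln in ref.read_text().splitlines()
            if ln.strip() and not ln.startswith("#")]


def build_network(rules: StructuralRules | None = None,
                  validate_whitelist: bool = True) -> ClockNetwork:
    """Assemble the full 208-species / 100-parameter clock network."""
    wl = load_whitelist() if validate_whitelist else None
    species = enumerate_species(rules, whitelist=wl)
    reactions = build_reactions(species)
    return ClockNetwork(species, reactions, list(PARAM_DEFAULTS))


def build_rhs(network: ClockNetwork, params: ParameterSet
              ) -> Callable[[np.ndarray, float], np.ndarray]:
    """Compile the network into a pure, time-autonomous derivative function.

    The returned callable evaluates all 208 derivatives under mass-action
    kinetics: each reaction contributes ``+rate`` to its products and
    ``-rate`` to its reactants, with rate = k · (product of reactant levels).
    """
    kidx, r1, r2, S = network.compiled()
    k = network.rate_vector(params)
    kflux = k[kidx]
    first = r2 < 0
    zero_order = (r1 < 0) & first

    def rhs(state: np.ndarray, t: float = 0.0) -> np.ndarray:
        flux = np.where(zero_order, kflux,
                        np.where(first, kflux * state[np.where(r1 >= 0, r1, 0)],
                                 kflux * state[np.where(r1 >= 0, r1, 0)]
                                 * state[np.where(r2 >= 0, r2, 0)]))
        return S.dot(flux)

    return rhs
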