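"""Species inventory and naming convention for the extended human clock network.

Every protein or protein complex built from PER/CRY subunits is written in the
``x[P][C][K][L][B]`` convention:

* ``P`` — PER content and phospho-state (0 none, 1 PER1, 2 PER2, 3 phospho-PER1,
  4 phospho-PER2, 7 PER3, 8 PER1–PER3, 9 PER1–PER3 with PER3 phosphorylated;
  5 and 6 are reserved for structurally excluded forms: a free phospho-PER3 and
  a PER2–PER3 pair).
* ``C`` — CRY content (0 none, 1 CRY1, 2 CRY2).
* ``K`` — bound kinase (0 none, 1 CKIδ/ε, 2 GSK3β).
* ``L`` — location (0 cytoplasm, 1 nucleus).
* ``B`` — whether a BMAL1–CLOCK/NPAS2 activator complex is bound (0/1).

``x10000`` is unphosphorylated cytoplasmic PER1, ``x00100`` free cytoplasmic
CKIδ/ε, ``x10100`` the PER1–CKIδ/ε complex, ``x70000`` cytoplasmic PER3 and
``x80000`` the cytoplasmic PER1–PER3 pair.

mRNA species use the ``Mn``/``Mc`` (nuclear/cytoplasmic) prefix convention,
e.g. ``McPo`` is cytoplasmic PER1 mRNA.  E-box promoter states are ``G<gene>``
(free), ``G<gene>A`` (activator bound) and ``G<gene>AR1``/``G<gene>AR2``
(activator plus a repressing CRY1/CRY2).  BMAL1, CLOCK/NPAS2 and REV-ERBα/β
proteins and their kinase complexes carry short mnemonic labels (``Bc``,
``ClKn``, ``PRevc``, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable

__all__ = [
    "GENES",
    "ACTIVATED_GENES",
    "Kind",
    "SpeciesCode",
    "StructuralRules",
    "enumerate_species",
    "parse_species",
    "SpeciesCountError",
]

#: gene tags, in the fixed model order. ``Po``/``Pt``/``Pth`` are PER1/PER2/PER3
#: ("one"/"two"/"three"), ``Co``/``Ct`` CRY1/CRY2, ``B`` BMAL1, ``Cl`` the merged
#: CLOCK/NPAS2 pair and ``Rev`` the merged REV-ERBα/β pair.
GENES: tuple[str, ...] = ("Po", "Pt", "Pth", "Co", "Ct", "B", "Cl", "Rev")

#: genes transcribed from E-box promoters activated by the BMAL1–CLOCK complex.
ACTIVATED_GENES: tuple[str, ...] = ("Po", "Pt", "Pth", "Co", "Ct", "Rev")

GENE_NAMES = {
    "Po": "PER1", "Pt": "PER2", "Pth": "PER3", "Co": "CRY1", "Ct": "CRY2",
    "B": "BMAL1", "Cl": "CLOCK/NPAS2", "Rev": "REV-ERBa/b",
}

# digit -> meaning tables (kept as data so tests can probe the convention)
P_MEANING = {
    0: None,
    1: ("PER1", False),
    2: ("PER2", False),
    3: ("PER1", True),
    4: ("PER2", True),
    7: ("PER3", False),
    8: ("PER1-PER3", False),
    9: ("PER1-PER3", True),   # phosphorylated on PER3
}
P_EXCLUDED = {5: ("PER3", True), 6: ("PER2-PER3", False)}
C_MEANING = {0: None, 1: "CRY1", 2: "CRY2"}
K_MEANING = {0: None, 1: "CKId/e", 2: "GSK3b"}


class Kind(str, Enum):
    protein_complex = "protein_complex"
    mRNA = "mRNA"
    promoter_state = "promoter_state"


@dataclass(frozen=True, order=True)
class SpeciesCode:
    """One molecular species: an x-code complex, an mRNA, a promoter state or a
    named protein (BMAL1/CLOCK/REV-ERB forms, which fall outside the x grammar)."""

    label: str
    kind: Kind = Kind.protein_complex
    P: int | None = None
    C: int | None = None
    K: int | None = None
    L: int | None = None
    B: int | None = None

    @property
    def is_x(self) -> bool:
        return self.P is not None

    def render(self) -> str:
        if self.is_x:
            return f"x{self.P}{self.C}{self.K}{self.L}{self.B}"
        return self.label

    def with_digits(self, **kw: int) -> "SpeciesCode":
        new = replace(self, **kw)
        return replace(new, label=new.render())

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def parse_species(label: str) -> SpeciesCode:
    """Parse a canonical label back into a :class:`SpeciesCode`.

    Round-trips with :meth:`SpeciesCode.render` for every inventory member.
    """
    if label.startswith("x") and len(label) == 6 and label[1:].isdigit():
        P, C, K, L, B = (int(d) for d in label[1:])
        if P in P_EXCLUDED:
            raise ValueError(
                f"{label}: P digit {P} denotes a structurally excluded form "
                f"({P_EXCLUDED[P][0]})"
            )
        if P not in P_MEANING or C not in C_MEANING or K not in K_MEANING \
                or L not in (0, 1) or B not in (0, 1):
            raise ValueError(f"{label}: digit outside the convention")
        return SpeciesCode(label, Kind.protein_complex, P, C, K, L, B)
    if label.startswith(("Mc", "Mn")):
        gene = label[2:]
        if gene not in GENES:
            raise ValueError(f"{label}: unknown gene tag {gene!r}")
        return SpeciesCode(label, Kind.mRNA)
    if label.startswith("G"):
        return SpeciesCode(label, Kind.promoter_state)
    named = {f"{b}{suffix}{loc}" for b in ("B", "Cl", "Rev")
             for suffix in ("", "G", "K") for loc in ("c", "n")} | \
            {f"P{b}{loc}" for b in ("B", "Cl", "Rev") for loc in ("c", "n")}
    if label in named:
        return SpeciesCode(label, Kind.protein_complex)
    raise ValueError(f"{label!r} is not a recognised species label")


@dataclass(frozen=True)
class StructuralRules:
    """Structural assumptions that shape the species inventory.

    The defaults encode the model's biology: PER3 is phosphorylated by CKIδ/ε
    but only inside a PER1–PER3 pair, no PER2–PER3 pair exists, PER3 interacts
    with CRY1/CRY2 and the BMAL1–CLOCK/NPAS2 activator, CRY–activator complexes
    occur in both compartments while PER-containing activator complexes are
    nuclear, and GSK3β/CKIδ/ε additionally process BMAL1, REV-ERB and CLOCK.
    Relaxing a flag changes the inventory and is rejected against the shipped
    whitelist (used by tests to show the assumptions are load-bearing).
    """

    allow_per2_per3_pair: bool = False
    allow_free_phospho_per3: bool = False
    per_activator_nuclear_only: bool = True
    cry_activator_both_compartments: bool = True
    kinase_modules_on_bmal_clock_rev: bool = True
    promoter_repressors: tuple[int, ...] = (1, 2)  # CRY digits that repress


def _x(P: int, C: int, K: int, L: int, B: int) -> SpeciesCode:
    return SpeciesCode(f"x{P}{C}{K}{L}{B}", Kind.protein_complex, P, C, K, L, B)


def _named(label: str) -> SpeciesCode:
    return SpeciesCode(label, Kind.protein_complex)


def enumerate_species(rules: StructuralRules | None = None,
                      whitelist: Iterable[str] | None = None) -> list[SpeciesCode]:
    """Enumerate the full species inventory in its fixed, deterministic order.

    Order: mRNAs (per gene, nuclear then cytoplasmic), promoter states, named
    BMAL1/CLOCK/REV-ERB proteins, then x-coded complexes sorted by digits.

    If *whitelist* is given (defaults to the shipped inventory when the network
    is built), a count or membership mismatch raises :class:`SpeciesCountError`
    listing the symmetric difference — the signal that the structural rules
    diverge from the published inventory.
    """
    rules = rules or StructuralRules()
    out: list[SpeciesCode] = []

    for g in GENES:
        out.append(SpeciesCode(f"Mn{g}", Kind.mRNA))
        out.append(SpeciesCode(f"Mc{g}", Kind.mRNA))

    for g in ACTIVATED_GENES:
        out.append(SpeciesCode(f"G{g}", Kind.promoter_state))
        out.append(SpeciesCode(f"G{g}A", Kind.promoter_state))
        for r in rules.promoter_repressors:
            out.append(SpeciesCode(f"G{g}AR{r}", Kind.promoter_state))
    out.append(SpeciesCode("GB", Kind.promoter_state))
    out.append(SpeciesCode("GBRev", Kind.promoter_state))

    # named proteins: BMAL1, CLOCK/NPAS2, REV-ERB and their kinase forms
    for base, kin in (("B", "G"), ("Cl", "K"), ("Rev", "G")):
        for loc in ("c", "n"):
            out.append(_named(f"{base}{loc}"))
        if rules.kinase_modules_on_bmal_clock_rev:
            for loc in ("c", "n"):
                out.append(_named(f"{base}{kin}{loc}"))   # kinase-bound
            for loc in ("c", "n"):
                out.append(_named(f"P{base}{loc}"))       # phosphorylated

    # x grammar ------------------------------------------------------------
    xs: list[SpeciesCode] = []
    for K in (1, 2):            # free kinases
        for L in (0, 1):
            xs.append(_x(0, 0, K, L, 0))
    for L in (0, 1):            # free activator complex BMAL1-CLOCK
        xs.append(_x(0, 0, 0, L, 1))

    def lb_combos(per_containing: bool) -> list[tuple[int, int]]:
        combos = [(0, 0), (1, 0), (1, 1)]
        if per_containing:
            if not rules.per_activator_nuclear_only:
                combos.append((0, 1))
        elif rules.cry_activator_both_compartments:
            combos.append((0, 1))
        return combos

    for C in (1, 2):            # CRY-only species (GSK3β is the CRY kinase)
        for K in (0, 2):
            for L, B in lb_combos(per_containing=False):
                xs.append(_x(0, C, K, L, B))

    p_digits = [1, 2, 3, 4, 7, 8, 9]
    if rules.allow_free_phospho_per3:
        p_digits.append(5)
    if rules.allow_per2_per3_pair:
        p_digits.append(6)
    for P in sorted(p_digits):  # PER-containing species (CKIδ/ε is the kinase)
        for C in (0, 1, 2):
            for K in (0, 1):
                for L, B in lb_combos(per_containing=True):
                    xs.append(_x(P, C, K, L, B))

    out.extend(sorted(xs, key=lambda s: s.label))

    if whitelist is not None:
        want = list(whitelist)
        got = [s.label for s in out]
        if got != want:
            missing = sorted(set(want) - set(got))
            extra = sorted(set(got) - set(want))
            raise SpeciesCountError(
                f"generated inventory ({len(got)} species) does not match the "
                f"shipped whitelist ({len(want)} species); "
                f"missing={missing}; unexpected={extra}"
            )
    return out


class SpeciesCountError(ValueError):
    """Raised when structural rules produce an inventory that diverges from
    the shipped 208-species whitelist."""
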