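"""Genetic backgrounds as parameter-set transformations, and the registry of
experimental phenotype conditions used for fitting and validation.

A knockout zeroes the transcription rate of the corresponding gene.  The two
*PER3* polymorphisms are modelled as multiplicative edits of the biochemical
rate their molecular lesion affects:

* P415A/H417R — the double missense mutation associated with familial
  advanced sleep phase: 80% reduction of the PER1–PER3 binding rate together
  with an 8-fold increase of the PER3 degradation rate.
* P864A (SNP rs228697) — 80% decrease of the PER3–CKIδ/ε binding rate.
* VNTR (rs57875989) — the 4-repeat allele carries fewer CKIδ/ε target sites:
  homozygous 4,4 = 40% decrease of the PER3 phosphorylation rate; homozygous
  5,5 = 4-fold increase.  The heterozygote is the unmodified baseline, so the
  homozygote conditions are judged relative to an unperturbed simulation.

Each edit applies to every parameter tagged with the corresponding
biochemical role (e.g. "PER3 degradation" covers both the unphosphorylated
and the phosphorylated pair turnover rates).

The registry holds 16 phenotype conditions over 12 genetic backgrounds:
period direction (with the 2–6% chronotype band for the variants), amplitude
behaviour and rhythmicity, with companion amplitude/expression conditions
for the arrhythmic knockouts and the wild-type reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

from .features import (
    BMAL1_KO_MARKER,
    DEFAULT_MARKER,
    OscillationFeatures,
    extract_features,
)
from .integrators import IntegrationError, SimulationConfig, Trajectory, integrate
from .network import PARAM_ROLES, TRANSCRIPTION_RATE, ClockNetwork, ParameterSet

__all__ = [
    "EditOp",
    "Perturbation",
    "Expectation",
    "Condition",
    "apply_perturbation",
    "knockout",
    "role_multiplier",
    "builtin_conditions",
    "evaluate_condition",
    "ConditionOutcome",
]

#: "unchanged" means a period shift below this (percent); directional calls
#: must exceed it (the numerical-noise floor from the solver cross-checks).
UNCHANGED_TOL_PCT = 0.5
DIRECTION_FLOOR_PCT = 0.25


class EditOp(str, Enum):
    set_zero = "set_zero"
    multiply = "multiply"


@dataclass(frozen=True)
class Perturbation:
    name: str
    edits: tuple[tuple[str, EditOp, float], ...] = ()

    def __post_init__(self) -> None:
        for pname, op, factor in self.edits:
            if op is EditOp.multiply and not factor > 0:
                raise ValueError(f"{self.name}: multiply factor must be > 0")


def knockout(gene: str) -> Perturbation:
    """Zero the transcription rate of *gene* (e.g. "PER3")."""
    if gene not in TRANSCRIPTION_RATE:
        raise KeyError(f"unknown gene {gene!r}")
    return Perturbation(f"{gene}_KO",
                        ((TRANSCRIPTION_RATE[gene], EditOp.set_zero, 0.0),))


def role_multiplier(name: str, role: str, factor: float) -> Perturbation:
    """Multiply every parameter tagged with *role* by *factor*."""
    params = sorted(p for p, roles in PARAM_ROLES.items() if role in roles)
    if not params:
        raise KeyError(f"no parameter carries role {role!r}")
    return Perturbation(name, tuple((p, EditOp.multiply, factor) for p in params))


def _merge(name: str, *perts: Perturbation) -> Perturbation:
    return Perturbation(name, tuple(e for p in perts for e in p.edits))


def apply_perturbation(params: ParameterSet, perturbation: Perturbation
                       ) -> ParameterSet:
    """Return an edited copy of *params*; the original is untouched.

    ``set_zero`` is reserved for transcription rates (knockouts) and is
    idempotent; ``multiply`` edits compose multiplicatively.
    """
    edits: dict[str, float] = {}
    for pname, op, factor in perturbation.edits:
        if pname not in params.values:
            raise KeyError(f"perturbation {perturbation.name}: "
                           f"unknown parameter {pname!r}")
        if op is EditOp.set_zero:
            if pname not in TRANSCRIPTION_RATE.values():
                raise ValueError(
                    f"set_zero is reserved for transcription rates, got {pname}")
            edits[pname] = 0.0
        else:
            edits[pname] = edits.get(pname, params[pname]) * factor
    return params.replace(**edits)


class Expectation(str, Enum):
    period_shorter = "period_shorter"
    period_longer = "period_longer"
    arrhythmic = "arrhythmic"
    unchanged = "unchanged"
    expression_decreased_arrhythmic = "expression_decreased_arrhythmic"
    rhythmic_wt = "rhythmic_wt"          # wild-type reference: ~24 h rhythm
    amplitude_decreased = "amplitude_decreased"


@dataclass(frozen=True)
class Condition:
    id: str
    perturbation: Perturbation
    expected: Expectation
    marker: str = DEFAULT_MARKER
    band_pct: tuple[float, float] | None = None   # percent period-shift band
    source: str = "knockout_literature"
    canonical: bool = True    # derivable from the main phenotype descriptions

    def __post_init__(self) -> None:
        if self.band_pct is not None:
            lo, hi = self.band_pct
            if self.expected not in (Expectation.period_shorter,
                                     Expectation.period_longer):
                raise ValueError(f"{self.id}: band only valid for period shifts")
            if not (0 < lo < hi):
                raise ValueError(f"{self.id}: need 0 < lo < hi")


CHRONOTYPE_BAND = (2.0, 6.0)   # percent; FASPD/DSPD & extreme chronotypes

_P415A = _merge("PER3_P415A_H417R",
                role_multiplier("", "per1_per3_binding", 0.2),
                role_multiplier("", "per3_degradation", 8.0))
_P864A = role_multiplier("PER3_P864A", "per3_cki_binding", 0.2)
_VNTR44 = role_multiplier("PER3_VNTR_4_4", "per3_phosphorylation", 0.6)
_VNTR55 = role_multiplier("PER3_VNTR_5_5", "per3_phosphorylation", 4.0)
_WT = Perturbation("WT", ())


def builtin_conditions() -> list[Condition]:
    """The 16 phenotype conditions over 12 genetic backgrounds.

    Backgrounds: WT, six single knockouts, the CRY1/CRY2 double knockout and
    four PER3 variants (the NPAS2 knockout is a no-op background because
    CLOCK and NPAS2 are merged into one gene — flagged by its source tag).
    The knockout/variant backgrounds with qualitative amplitude or expression
    phenotypes contribute the additional conditions.
    """
    c = Condition
    return [
        # --- wild-type reference (1 background, 2 conditions)
        c("WT_rhythmic_24h", _WT, Expectation.rhythmic_wt),
        c("WT_markers_coherent", _WT, Expectation.rhythmic_wt, marker="MnPt",
          canonical=False, source="marker_consistency"),
        # --- knockouts (7 backgrounds, 8 conditions)
        c("PER1_KO_short", knockout("PER1"), Expectation.period_shorter),
        c("PER2_KO_short", knockout("PER2"), Expectation.period_shorter),
        c("PER3_KO_short", knockout("PER3"), Expectation.period_shorter),
        c("CRY1_KO_short", knockout("CRY1"), Expectation.period_shorter),
        c("CRY2_KO_long", knockout("CRY2"), Expectation.period_longer),
        c("CRY1_CRY2_KO_arrhythmic",
          _merge("CRY1_CRY2_KO", knockout("CRY1"), knockout("CRY2")),
          Expectation.arrhythmic),
        c("BMAL1_KO_PER2_down_arrhythmic", knockout("BMAL1"),
          Expectation.expression_decreased_arrhythmic, marker=BMAL1_KO_MARKER),
        c("NPAS2_KO_unchanged", Perturbation("NPAS2_KO", ()),
          Expectation.unchanged, source="merged_gene_noop"),
        # --- PER3 variants (4 backgrounds, 6 conditions)
        c("P415A_H417R_FASPD_short", _P415A, Expectation.period_shorter,
          band_pct=CHRONOTYPE_BAND, source="variant_literature"),
        c("P415A_H417R_rhythmic", _P415A, Expectation.rhythmic_wt,
          canonical=False, source="variant_literature"),
        c("P864A_DSPD_long", _P864A, Expectation.period_longer,
          band_pct=CHRONOTYPE_BAND, source="variant_literature"),
        c("VNTR44_long_vs_het", _VNTR44, Expectation.period_longer,
          band_pct=CHRONOTYPE_BAND, source="variant_literature"),
        c("VNTR55_short_vs_het", _VNTR55, Expectation.period_shorter,
          band_pct=CHRONOTYPE_BAND, source="variant_literature"),
        c("VNTR55_rhythmic", _VNTR55, Expectation.rhythmic_wt,
          canonical=False, source="variant_literature"),
    ]


@dataclass(frozen=True)
class ConditionOutcome:
    condition_id: str
    satisfied: bool
    reason: str
    wt: OscillationFeatures | None
    perturbed: OscillationFeatures | None
    period_shift_pct: float | None


#: wild-type free-running period acceptance band, hours (24 h ± 5%)
WT_PERIOD_BAND = (22.8, 25.2)


def _shift_pct(wt: OscillationFeatures, mut: OscillationFeatures) -> float | None:
    if wt.rhythmic and mut.rhythmic:
        return (mut.period - wt.period) / wt.period * 100.0
    return None


def judge(condition: Condition, wt: OscillationFeatures,
          mut: OscillationFeatures) -> tuple[bool, str, float | None]:
    """Apply the condition's expectation to a WT/perturbed feature pair."""
    shift = _shift_pct(wt, mut)
    e = condition.expected
    if e is Expectation.rhythmic_wt:
        ok = mut.rhythmic and WT_PERIOD_BAND[0] <= mut.period <= WT_PERIOD_BAND[1]
        return ok, f"period={mut.period if mut.rhythmic else None}", shift
    if e is Expectation.arrhythmic:
        return (not mut.rhythmic), f"rhythmic={mut.rhythmic}", shift
    if e is Expectation.expression_decreased_arrhythmic:
        ok = (not mut.rhythmic) and mut.mean_level < 0.5 * wt.mean_level
        return ok, (f"rhythmic={mut.rhythmic}, "
                    f"mean {mut.mean_level:.3g} vs WT {wt.mean_level:.3g}"), shift
    if not (wt.rhythmic and mut.rhythmic):
        return False, "arrhythmic trajectory where a period was expected", shift
    if e is Expectation.unchanged:
        return abs(shift) < UNCHANGED_TOL_PCT, f"|shift|={abs(shift):.3f}%", shift
    lo, hi = condition.band_pct or (DIRECTION_FLOOR_PCT, float("inf"))
    mag = -shift if e is Expectation.period_shorter else shift
    ok = lo <= mag <= hi
    return ok, f"shift={shift:+.3f}% (want {e.value} in [{lo},{hi}]%)", shift


def evaluate_condition(network: ClockNetwork, params: ParameterSet,
                       condition: Condition,
                       sim_config: SimulationConfig | None = None,
                       wt_traj: Trajectory | None = None,
                       ) -> ConditionOutcome:
    """Simulate WT and perturbed systems and test the expected phenotype.

    Pass ``wt_traj`` to reuse one wild-type simulation across the registry.
    Integration failure marks the condition unsatisfied with the reason.
    """
    sim_config = sim_config or SimulationConfig()
    try:
        if wt_traj is None:
            wt_traj = integrate(network, params, sim_config)
        wt = extract_features(wt_traj, condition.marker)
        if condition.perturbation.edits:
            pert_params = apply_perturbation(params, condition.perturbation)
            mut_traj = integrate(network, pert_params, sim_config)
            mut = extract_features(mut_traj, condition.marker)
        else:
            mut = wt
        ok, reason, shift = judge(condition, wt, mut)
        return ConditionOutcome(condition.id, ok, reason, wt, mut, shift)
    except IntegrationError as err:
        return ConditionOutcome(condition.id, False,
                                f"integration failure: {err}", None, None, None)
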