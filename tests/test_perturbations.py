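import numpy as np
import pytest

from clock3.network import TRANSCRIPTION_RATE, ParameterSet
from clock3.perturbations import (EditOp, Expectation, Perturbation,
                                  apply_perturbation, builtin_conditions,
                                  evaluate_condition, knockout,
                                  role_multiplier)


@pytest.fixture(scope="module")
def registry():
    return builtin_conditions()


def test_knockout_zeroes_only_the_transcription_rate(default_params):
    out = apply_perturbation(default_params, knockout("PER3"))
    assert out["trpth"] == 0.0
    changed = {k for k in out.values if out[k] != default_params[k]}
    assert changed == {"trpth"}
    # original untouched
    assert default_params["trpth"] > 0


def test_identity_perturbation_is_noop(default_params):
    out = apply_perturbation(default_params, Perturbation("id", ()))
    assert out.values == default_params.values


def test_set_zero_is_idempotent(default_params):
    once = apply_perturbation(default_params, knockout("CRY1"))
    twice = apply_perturbation(once, knockout("CRY1"))
    assert twice.values == once.values


def test_multiply_edits_compose(default_params):
    half = role_multiplier("h", "per3_phosphorylation", 0.5)
    a = apply_perturbation(apply_perturbation(default_params, half), half)
    b = apply_perturbation(default_params,
                           role_multiplier("q", "per3_phosphorylation", 0.25))
    assert a["hoth"] == pytest.approx(b["hoth"])


def test_unknown_parameter_rejected(default_params):
    bad = Perturbation("bad", (("nosuch", EditOp.multiply, 2.0),))
    with pytest.raises(KeyError, match="nosuch"):
        apply_perturbation(default_params, bad)


def test_set_zero_restricted_to_transcription(default_params):
    bad = Perturbation("bad", (("hoth", EditOp.set_zero, 0.0),))
    with pytest.raises(ValueError, match="transcription"):
        apply_perturbation(default_params, bad)


def test_vntr_44_edits_phosphorylation_by_0_6(default_params):
    registry = {c.id: c for c in builtin_conditions()}
    out = apply_perturbation(default_params,
                             registry["VNTR44_long_vs_het"].perturbation)
    assert out["hoth"] == pytest.approx(0.6 * default_params["hoth"])


def test_registry_16_conditions_12_backgrounds(registry):
    assert len(registry) == 16
    backgrounds = {c.perturbation.name for c in registry} - {"WT"}
    assert len(backgrounds) == 12


def test_registry_expected_directions(registry):
    expected = {
        "PER1_KO_short": Expectation.period_shorter,
        "PER2_KO_short": Expectation.period_shorter,
        "PER3_KO_short": Expectation.period_shorter,
        "CRY1_KO_short": Expectation.period_shorter,
        "CRY2_KO_long": Expectation.period_longer,
        "CRY1_CRY2_KO_arrhythmic": Expectation.arrhythmic,
        "BMAL1_KO_PER2_down_arrhythmic":
            Expectation.expression_decreased_arrhythmic,
        "NPAS2_KO_unchanged": Expectation.unchanged,
        "P415A_H417R_FASPD_short": Expectation.period_shorter,
        "P864A_DSPD_long": Expectation.period_longer,
        "VNTR44_long_vs_het": Expectation.period_longer,
        "VNTR55_short_vs_het": Expectation.period_shorter,
    }
    byid = {c.id: c for c in registry}
    for cid, exp in expected.items():
        assert byid[cid].expected is exp


def test_p415a_h417r_has_binding_and_degradation_edits(registry):
    cond = {c.id: c for c in registry}["P415A_H417R_FASPD_short"]
    edits = {p: f for p, _, f in cond.perturbation.edits}
    assert edits["an"] == pytest.approx(0.2)       # 80% less PER1-PER3 binding
    deg = {p: f for p, f in edits.items() if p in ("upth", "uppth")}
    assert all(f == pytest.approx(8.0) for f in deg.values())  # 8x degradation


def test_p864a_reduces_per3_cki_binding(registry):
    cond = {c.id: c for c in registry}["P864A_DSPD_long"]
    edits = {p: f for p, _, f in cond.perturbation.edits}
    assert edits == {"acth": pytest.approx(0.2)}


def test_variant_bands_are_2_to_6_percent(registry):
    for c in registry:
        if c.band_pct is not None:
            assert c.band_pct == (2.0, 6.0)


def test_bmal1_condition_uses_per2_marker(registry):
    cond = {c.id: c for c in registry}["BMAL1_KO_PER2_down_arrhythmic"]
    assert cond.marker == "MnPt"


def test_unchanged_condition_with_identity_perturbation(
        toy_network, toy_params, toy_config):
    from clock3.perturbations import Condition
    cond = Condition("noop", Perturbation("noop", ()), Expectation.unchanged,
                     marker="MR")
    out = evaluate_condition(toy_network, toy_params, cond, toy_config)
    assert out.satisfied
    assert out.period_shift_pct == pytest.approx(0.0)


def test_integration_failure_marks_condition_unsatisfied(
        toy_network, toy_params):
    """An unstable step size fails gracefully with a reason, not a crash."""
    from clock3.integrators import SimulationConfig
    from clock3.perturbations import Condition
    cfg = SimulationConfig(dt=3.0, t_end=400.0, transient_discard=100.0,
                           sample_every=1)
    cond = Condition("noop", Perturbation("noop", ()), Expectation.unchanged,
                     marker="MR")
    out = evaluate_condition(toy_network, toy_params, cond, cfg)
    assert not out.satisfied
    assert "failure" in out.reason
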