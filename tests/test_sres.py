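import numpy as np
import pytest

from clock3.integrators import SimulationConfig
from clock3.network import ParameterSet
from clock3.perturbations import Condition, EditOp, Expectation, Perturbation
from clock3.sres import (EstimationConfig, CostResult, _stochastic_rank,
                         compare_per_rates, condition_cost, refine_ranges,
                         sres_minimize, sres_search)
from clock3.toy import TOY_DEFAULTS, ToyParams


def test_stochastic_ranking_extremes():
    """pf = 0: feasible always outrank infeasible; pf = 1: objective only."""
    rng = np.random.default_rng(0)
    obj = np.array([5.0, 1.0, 3.0, 0.5])
    viol = np.array([0.0, 2.0, 0.0, 4.0])
    order0 = list(_stochastic_rank(obj, viol, 0.0, rng))
    assert order0 == [2, 0, 1, 3]     # feasible by objective, then by violation
    for seed in range(3):
        order1 = list(_stochastic_rank(obj, viol, 1.0,
                                       np.random.default_rng(seed)))
        assert order1 == [3, 1, 2, 0]  # purely by objective


def test_estimation_config_validation():
    with pytest.raises(ValueError):
        EstimationConfig(parents_mu=20, population_lambda=20)
    with pytest.raises(ValueError):
        EstimationConfig(ranking_pf=1.5)


def test_cost_result_consistency():
    with pytest.raises(ValueError):
        CostResult(1.0, [{"satisfied": True}], feasible=False)


def test_sphere_with_constraint_beats_random_search_oracle():
    """SRES on a constrained sphere must beat plain random search given 10x
    the evaluation budget to the oracle."""
    def f(x):
        return float(np.sum(x ** 2)), max(0.0, 0.5 - x[0])

    bounds = np.array([[0.01, 10.0]] * 5)
    cfg = EstimationConfig(generations=100, parents_mu=3,
                           population_lambda=20, seed=3)
    res = sres_minimize(f, bounds, cfg)
    assert res.feasible_found

    rng = np.random.default_rng(3)
    n_oracle = 10 * (cfg.generations + 1) * cfg.population_lambda
    lo, hi = np.log10(bounds[:, 0]), np.log10(bounds[:, 1])
    best_oracle = np.inf
    for _ in range(n_oracle):
        x = 10 ** rng.uniform(lo, hi)
        obj, viol = f(x)
        if viol == 0 and obj < best_oracle:
            best_oracle = obj
    assert res.feasible_solutions[0][1] < best_oracle


def test_seeded_reproducibility():
    def f(x):
        return float(np.sum((x - 1.0) ** 2)), 0.0

    bounds = np.array([[0.1, 10.0]] * 3)
    cfg = EstimationConfig(generations=30, seed=11)
    a = sres_minimize(f, bounds, cfg)
    b = sres_minimize(f, bounds, cfg)
    assert np.array_equal(a.best_x, b.best_x)
    assert a.best_objective == b.best_objective


def test_solutions_respect_bounds():
    def f(x):
        return float(np.sum(x)), 0.0

    bounds = np.array([[0.5, 2.0]] * 4)
    res = sres_minimize(f, bounds, EstimationConfig(generations=25, seed=2))
    for x, _ in res.feasible_solutions:
        assert np.all(x >= 0.5 - 1e-9) and np.all(x <= 2.0 + 1e-9)


# --- condition cost ---------------------------------------------------------

def _toy_cond(cid, param, factor, expected, band=None):
    pert = Perturbation(cid, ((param, EditOp.multiply, factor),))
    return Condition(cid, pert, expected, marker="MR", band_pct=band,
                     source="toy")


TOY_SIM = SimulationConfig(dt=0.01, t_end=400.0, transient_discard=200.0,
                           sample_every=20)


def toy_registry():
    return [
        Condition("wt_rhythmic", Perturbation("WT", ()),
                  Expectation.rhythmic_wt, marker="MR", source="toy"),
        _toy_cond("slow_repressor_decay_long", "dR", 0.5,
                  Expectation.period_longer, band=(5.0, 40.0)),
        _toy_cond("fast_repressor_decay_short", "dR", 2.0,
                  Expectation.period_shorter, band=(5.0, 40.0)),
        _toy_cond("repressor_loss_arrhythmic", "bR", 1e-6,
                  Expectation.arrhythmic),
    ]


def test_toy_ground_truth_is_feasible(toy_network, toy_params):
    cost = condition_cost(toy_network, toy_params, toy_registry(), TOY_SIM)
    assert cost.feasible, cost.violations
    assert cost.objective == 0.0


def test_deviation_is_distance_to_band_edge(toy_network, toy_params):
    """A period shift just outside its band is charged the percentage-point
    gap to the nearest edge."""
    conds = [_toy_cond("too_tight_band", "dR", 0.5,
                       Expectation.period_longer, band=(30.0, 35.0))]
    cost = condition_cost(toy_network, toy_params, conds, TOY_SIM)
    shift = cost.violations[0]["period_shift_pct"]
    assert not cost.feasible
    expected_dev = 30.0 - shift
    assert cost.violations[0]["deviation"] == pytest.approx(expected_dev,
                                                            abs=1e-9)


def test_rhythm_mismatch_fixed_penalty(toy_network, toy_params):
    from clock3.sres import RHYTHM_MISMATCH_PENALTY
    conds = [_toy_cond("expects_arrhythmic", "dR", 1.0,
                       Expectation.arrhythmic)]
    cost = condition_cost(toy_network, toy_params, conds, TOY_SIM)
    assert cost.violations[0]["deviation"] == RHYTHM_MISMATCH_PENALTY


def test_sres_recovers_toy_condition_phenotypes(toy_network):
    """Desk-scale parameter recovery: searching two rates of the synthetic
    oscillator, SRES reaches feasibility on a registry generated from known
    ground-truth rates."""
    conds = toy_registry()
    free = ["dR", "gC"]
    truth = {p: TOY_DEFAULTS[p] for p in free}
    ranges = {p: (truth[p] / 4.0, truth[p] * 4.0) for p in free}
    start = ToyParams({p: truth[p] * f for p, f in
                       zip(free, (2.5, 0.5))})   # start well off the truth
    cfg = EstimationConfig(generations=12, parents_mu=3,
                           population_lambda=12, seed=7)
    results = sres_search(
        toy_network, conds, cfg, ranges=ranges, start=start,
        sim_config=TOY_SIM, param_names=free,
        param_factory=lambda vals: ToyParams(vals))
    assert any(cost.feasible for _, cost in results)


def test_refine_ranges_collapses_and_clamps():
    names = list(TOY_DEFAULTS)
    ens = [ParameterSetLike({p: 2.0 for p in names}) for _ in range(6)]
    out = refine_ranges(ens)
    for p in names:
        lo, hi = out[p]
        assert lo == pytest.approx(2.0) and hi == pytest.approx(2.0, abs=1e-6)
    # clamping against original limits
    out2 = refine_ranges(ens, original={p: (0.0, 1.5) for p in names})
    assert all(hi <= 1.5 for _, hi in out2.values())


class ParameterSetLike:
    def __init__(self, values):
        self.values = dict(values)

    def __getitem__(self, k):
        return self.values[k]


def test_refine_ranges_order_statistics():
    rng = np.random.default_rng(0)
    ens = [ParameterSetLike({"a": v}) for v in rng.uniform(0, 1, 4000)]
    out = refine_ranges(ens, (0.05, 0.95))
    assert out["a"][0] == pytest.approx(0.05, abs=0.02)
    assert out["a"][1] == pytest.approx(0.95, abs=0.02)


def test_refine_ranges_needs_enough_sets():
    with pytest.raises(ValueError):
        refine_ranges([ParameterSetLike({"a": 1.0})] * 4)
    with pytest.raises(ValueError):
        refine_ranges([])


def test_compare_per_rates_equal_and_planted(default_params):
    ens = [default_params.replace(acth=default_params["ac"],
                                  tlpth=default_params["tlpo"],
                                  arcth=default_params["arco"],
                                  hoth=default_params["hoo"],
                                  upth=default_params["upuo"],
                                  uppth=default_params["upuo"])]
    table = compare_per_rates(ens)
    for role in ("cki_binding", "cry_binding", "translation"):
        r = table[role]["per3_vs_per1"]["geometric_mean_ratio"]
        assert r == pytest.approx(1.0, rel=1e-9)

    planted = [default_params.replace(acth=50.0 * default_params["ac"])]
    r = compare_per_rates(planted)["cki_binding"]["per3_vs_per1"]
    assert r["geometric_mean_ratio"] == pytest.approx(50.0, rel=1e-9)
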