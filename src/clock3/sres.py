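"""Stochastic Ranking Evolutionary Strategy (SRES) parameter estimation.

A (μ,λ) evolution strategy with log-normal self-adaptive mutation, where
survivor selection uses stochastic ranking: a bubble-sort sweep that compares
neighbours by objective value with probability ``pf`` (or when both are
feasible) and by constraint violation otherwise.  With pf = 0 feasible
individuals always outrank infeasible ones; with pf = 1 ranking is purely by
objective.  Mutation acts in log10 parameter space — rates are positive and
their priors span decades — with reflection at the box bounds.

The clock-specific layer scores a parameter set against the phenotype
condition registry: each condition contributes a deviation (0 when the
expected phenotype holds, the percentage-point distance to the nearest band
edge for period conditions, an expression-ratio shortfall for expression
conditions, and a fixed penalty for rhythmicity mismatches or integration
failures).  A set is feasible when every condition is satisfied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .features import extract_features
from .integrators import SimulationConfig, integrate
from .network import PARAM_ROLES, ClockNetwork, ParameterSet
from .perturbations import Condition, ConditionOutcome, evaluate_condition

__all__ = [
    "EstimationConfig",
    "CostResult",
    "condition_cost",
    "sres_minimize",
    "sres_search",
    "refine_ranges",
    "compare_per_rates",
    "RHYTHM_MISMATCH_PENALTY",
    "FAILURE_PENALTY",
]

RHYTHM_MISMATCH_PENALTY = 10.0
FAILURE_PENALTY = 50.0


@dataclass(frozen=True)
class EstimationConfig:
    """SRES controls (defaults follow the published runs: 5,000 generations,
    3 parents, population 20, ranking probability 0.45)."""

    generations: int = 5000
    parents_mu: int = 3
    population_lambda: int = 20
    ranking_pf: float = 0.45
    seed: int = 0
    retained_range_inflation: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.parents_mu < self.population_lambda):
            raise ValueError("require 0 < mu < lambda")
        if not (0.0 <= self.ranking_pf <= 1.0):
            raise ValueError("pf must be a probability")


@dataclass
class CostResult:
    objective: float
    violations: list[dict]
    feasible: bool

    def __post_init__(self) -> None:
        if self.objective < 0:
            raise ValueError("objective must be >= 0")
        if self.feasible != all(v["satisfied"] for v in self.violations):
            raise ValueError("feasible flag inconsistent with violations")


def _deviation(cond: Condition, out: ConditionOutcome) -> float:
    from .perturbations import (DIRECTION_FLOOR_PCT, UNCHANGED_TOL_PCT,
                                Expectation, WT_PERIOD_BAND)

    if out.wt is None and out.perturbed is None:
        return FAILURE_PENALTY
    if out.satisfied:
        return 0.0
    e = cond.expected
    mut = out.perturbed
    if e is Expectation.rhythmic_wt:
        if not mut.rhythmic:
            return RHYTHM_MISMATCH_PENALTY
        lo, hi = WT_PERIOD_BAND
        d = max(lo - mut.period, mut.period - hi, 0.0)
        return d / 24.0 * 100.0
    if e is Expectation.arrhythmic:
        return RHYTHM_MISMATCH_PENALTY
    if e is Expectation.expression_decreased_arrhythmic:
        dev = RHYTHM_MISMATCH_PENALTY if mut.rhythmic else 0.0
        if out.wt.mean_level > 0:
            ratio = mut.mean_level / out.wt.mean_level
            dev += max(0.0, ratio - 0.5) * 2.0 * RHYTHM_MISMATCH_PENALTY
        return dev
    if out.period_shift_pct is None:
        return RHYTHM_MISMATCH_PENALTY
    shift = out.period_shift_pct
    if e is Expectation.unchanged:
        return max(0.0, abs(shift) - UNCHANGED_TOL_PCT)
    lo, hi = cond.band_pct or (DIRECTION_FLOOR_PCT, float("inf"))
    mag = -shift if e is Expectation.period_shorter else shift
    if mag < lo:
        return lo - mag
    if mag > hi:
        return mag - hi
    return 0.0


def condition_cost(network: ClockNetwork, params: ParameterSet,
                   conditions: Sequence[Condition],
                   sim_config: SimulationConfig | None = None) -> CostResult:
    """Aggregate deviation of a parameter set from the expected phenotypes.

    Genetic backgrounds shared by several conditions are simulated once.
    """
    from .perturbations import apply_perturbation, judge

    sim_config = sim_config or SimulationConfig()
    try:
        wt_traj = integrate(network, params, sim_config)
    except Exception as err:  # instability: penalize every condition
        viol = [{"condition": c.id, "satisfied": False,
                 "deviation": FAILURE_PENALTY, "reason": f"WT failed: {err}"}
                for c in conditions]
        return CostResult(FAILURE_PENALTY * len(conditions), viol, False)

    traj_cache: dict[tuple, object] = {}

    def background(cond: Condition):
        key = tuple(sorted(cond.perturbation.edits))
        if not key:
            return wt_traj
        if key not in traj_cache:
            pert = apply_perturbation(params, cond.perturbation)
            traj_cache[key] = integrate(network, pert, sim_config)
        return traj_cache[key]

    violations = []
    total = 0.0
    for cond in conditions:
        try:
            mut_traj = background(cond)
            wt = extract_features(wt_traj, cond.marker)
            mut = extract_features(mut_traj, cond.marker)
            ok, reason, shift = judge(cond, wt, mut)
            out = ConditionOutcome(cond.id, ok, reason, wt, mut, shift)
        except Exception as err:
            out = ConditionOutcome(cond.id, False,
                                   f"integration failure: {err}", None, None,
                                   None)
        dev = _deviation(cond, out)
        total += dev
        violations.append({"condition": cond.id, "satisfied": out.satisfied,
                           "deviation": dev, "reason": out.reason,
                           "period_shift_pct": out.period_shift_pct})
    return CostResult(total, violations, all(v["satisfied"] for v in violations))


# ---------------------------------------------------------------------------
# generic SRES core (also exercised on analytic benchmarks in the tests)
# ---------------------------------------------------------------------------

def _stochastic_rank(obj: np.ndarray, viol: np.ndarray, pf: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Stochastic-ranking bubble sort; returns indices best-to-worst."""
    n = len(obj)
    idx = np.arange(n)
    for sweep in range(n):
        swapped = False
        u = rng.random(n - 1)
        for j in range(n - 1):
            a, b = idx[j], idx[j + 1]
            if (viol[a] == 0 and viol[b] == 0) or u[j] < pf:
                worse = obj[a] > obj[b]
            else:
                worse = viol[a] > viol[b]
            if worse:
                idx[j], idx[j + 1] = b, a
                swapped = True
        if not swapped:
            break
    return idx


@dataclass
class SresResult:
    best_x: np.ndarray
    best_objective: float
    best_violation: float
    feasible_solutions: list[tuple[np.ndarray, float]]
    history: list[dict] = field(default_factory=list)
    feasible_found: bool = False


def sres_minimize(func: Callable[[np.ndarray], tuple[float, float]],
                  bounds: np.ndarray,
                  config: EstimationConfig,
                  x_init: np.ndarray | None = None,
                  log_space: bool = True,
                  keep_feasible: int = 50,
                  sigma_scale: float = 1.0,
                  callback: Callable[[int, dict], None] | None = None
                  ) -> SresResult:
    """Minimize ``func(x) -> (objective, constraint_violation)`` on a box.

    ``constraint_violation`` is 0 for feasible points.  Fully reproducible for
    a fixed :class:`EstimationConfig` seed.  Returns every feasible point
    encountered (up to *keep_feasible*, best first) plus the best-ranked
    point overall.
    """
    rng = np.random.default_rng(config.seed)
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0].copy(), bounds[:, 1].copy()
    if np.any(hi <= lo):
        raise ValueError("bounds must have positive width")
    if log_space:
        if np.any(lo <= 0):
            raise ValueError("log-space search requires positive bounds")
        lo, hi = np.log10(lo), np.log10(hi)
    n = len(lo)
    lam, mu = config.population_lambda, config.parents_mu
    tau = 1.0 / np.sqrt(2.0 * np.sqrt(n))
    tau_p = 1.0 / np.sqrt(2.0 * n)
    sigma0 = (hi - lo) / np.sqrt(n) * sigma_scale

    if x_init is not None:
        # warm start: population scattered around the provided point
        xi = np.log10(x_init) if log_space else np.asarray(x_init, float)
        xi = np.clip(xi, lo, hi)
        X = xi + sigma0 * rng.standard_normal((lam, n))
        X[0] = xi
        X = np.clip(X, lo, hi)
    else:
        X = rng.uniform(lo, hi, size=(lam, n))
    Sig = np.tile(sigma0, (lam, 1))

    def decode(xrow: np.ndarray) -> np.ndarray:
        return 10.0 ** xrow if log_space else xrow

    def evaluate(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ob = np.empty(len(rows))
        vi = np.empty(len(rows))
        for i, row in enumerate(rows):
            ob[i], vi[i] = func(decode(row))
        return ob, vi

    obj, viol = evaluate(X)
    feas: list[tuple[np.ndarray, float]] = []
    best = None
    history = []

    def note_feasible(rows, ob, vi):
        nonlocal feas
        for row, o, v in zip(rows, ob, vi):
            if v == 0:
                feas.append((decode(row).copy(), float(o)))
        feas.sort(key=lambda t: t[1])
        seen, uniq = set(), []
        for x, o in feas:
            key = tuple(np.round(np.log10(np.maximum(x, 1e-300)), 6))
            if key not in seen:
                seen.add(key)
                uniq.append((x, o))
        feas = uniq[:keep_feasible]

    note_feasible(X, obj, viol)

    for gen in range(config.generations):
        order = _stochastic_rank(obj, viol, config.ranking_pf, rng)
        parents = order[:mu]
        if best is None or _better(obj, viol, order[0], best, X):
            best = (X[order[0]].copy(), float(obj[order[0]]),
                    float(viol[order[0]]))
        # offspring: each mutates a uniformly chosen parent
        pidx = parents[rng.integers(0, mu, size=lam)]
        gN = rng.standard_normal(lam)[:, None]
        lN = rng.standard_normal((lam, n))
        Sig = Sig[pidx] * np.exp(tau_p * gN + tau * lN)
        Sig = np.minimum(Sig, np.tile((hi - lo), (lam, 1)))
        X = X[pidx] + Sig * rng.standard_normal((lam, n))
        # reflection at the box bounds
        for _ in range(4):
            X = np.where(X < lo, 2 * lo - X, X)
            X = np.where(X > hi, 2 * hi - X, X)
        X = np.clip(X, lo, hi)
        obj, viol = evaluate(X)
        note_feasible(X, obj, viol)
        rec = {"generation": gen, "best_objective": float(obj.min()),
               "min_violation": float(viol.min()),
               "n_feasible": int((viol == 0).sum())}
        history.append(rec)
        if callback is not None:
            callback(gen, rec)

    order = _stochastic_rank(obj, viol, config.ranking_pf, rng)
    if best is None or _better(obj, viol, order[0], best, X):
        best = (X[order[0]].copy(), float(obj[order[0]]), float(viol[order[0]]))
    return SresResult(decode(best[0]), best[1], best[2],
                      feas, history, feasible_found=bool(feas))


def _better(obj, viol, i, best, X) -> bool:
    _, bo, bv = best
    if viol[i] == 0 and bv > 0:
        return True
    if viol[i] > 0 and bv == 0:
        return False
    if viol[i] == 0:
        return obj[i] < bo
    return viol[i] < bv


# ---------------------------------------------------------------------------
# clock-network front end
# ---------------------------------------------------------------------------

def sres_search(network, conditions: Sequence[Condition],
                config: EstimationConfig,
                ranges: dict[str, tuple[float, float]] | None = None,
                start: ParameterSet | None = None,
                sim_config: SimulationConfig | None = None,
                param_factory: Callable[[dict], object] | None = None,
                param_names: Sequence[str] | None = None,
                sigma_scale: float = 1.0,
                callback: Callable[[int, dict], None] | None = None,
                ) -> list[tuple[ParameterSet, CostResult]]:
    """Search parameter space for sets satisfying the condition registry.

    Returns feasible sets (best objective first) followed by the best-ranked
    infeasible set; reproducible for a fixed config seed.  Works on the full
    clock network by default; a ``param_factory`` (values dict → parameter
    object) extends it to other networks, e.g. the synthetic benchmark.
    """
    sim_config = sim_config or SimulationConfig()
    if ranges is None:
        ranges = (start or ParameterSet.defaults()).ranges
    names = list(param_names if param_names is not None else network.parameters)
    bounds = np.array([ranges[p] for p in names], dtype=float)
    rdict = {p: tuple(ranges[p]) for p in names}
    factory = param_factory or (lambda vals: ParameterSet(vals, rdict))

    def wrap(vec: np.ndarray) -> tuple[float, float]:
        ps = factory(dict(zip(names, vec)))
        cost = condition_cost(network, ps, conditions, sim_config)
        return cost.objective, cost.objective  # objective zero <=> feasible

    x0 = None
    if start is not None:
        x0 = np.array([start[p] for p in names])
        x0 = np.clip(x0, bounds[:, 0], bounds[:, 1])
    res = sres_minimize(wrap, bounds, config, x_init=x0,
                        sigma_scale=sigma_scale, callback=callback)

    out = []
    for x, _ in res.feasible_solutions:
        ps = factory(dict(zip(names, x)))
        out.append((ps, condition_cost(network, ps, conditions, sim_config)))
    if not any(np.allclose(x, res.best_x) for x, _ in res.feasible_solutions):
        ps = factory(dict(zip(names, res.best_x)))
        out.append((ps, condition_cost(network, ps, conditions, sim_config)))
    return out


def refine_ranges(ensemble: Sequence[ParameterSet],
                  quantile_band: tuple[float, float] = (0.05, 0.95),
                  original: dict[str, tuple[float, float]] | None = None
                  ) -> dict[str, tuple[float, float]]:
    """Shrink per-parameter ranges to the ensemble's inter-quantile band.

    Never widens beyond the original biological limits.  Requires ≥ 5 sets.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    if len(ensemble) < 5:
        raise ValueError("range refinement needs at least 5 feasible sets")
    qlo, qhi = quantile_band
    names = list(ensemble[0].values)
    out = {}
    for p in names:
        vals = np.array([ps[p] for ps in ensemble])
        lo, hi = np.quantile(vals, [qlo, qhi])
        if original and p in original:
            olo, ohi = original[p]
            lo = float(np.clip(lo, olo, ohi))
            hi = float(np.clip(hi, olo, ohi))
        if hi <= lo:  # degenerate ensemble: keep a sliver inside the limits
            eps = max(abs(hi) * 1e-9, 1e-12)
            if original and p in original and hi >= original[p][1]:
                lo = hi - eps
            else:
                hi = lo + eps
        out[p] = (float(lo), float(hi))
    return out


PER_RATE_ROLES = ("cki_binding", "cry_binding", "translation", "degradation",
                  "phosphorylation")


def compare_per_rates(ensemble: Sequence[ParameterSet]) -> dict:
    """PER3:PER1 and PER3:PER2 rate ratios per biochemical role.

    Geometric means with log-space dispersion across the ensemble; a role is
    flagged when its geometric mean ratio exceeds 1 by more than twice the
    geometric standard error (a credible excess).
    """
    def role_params(role: str) -> list[str]:
        return sorted(p for p, roles in PARAM_ROLES.items() if role in roles)

    table = {}
    for role in PER_RATE_ROLES:
        p3 = role_params(f"per3_{role}")
        entry = {}
        for ref in ("per1", "per2"):
            pr = role_params(f"{ref}_{role}")
            if not p3 or not pr:
                continue
            logs = []
            for ps in ensemble:
                num = np.exp(np.mean([np.log(ps[p]) for p in p3]))
                den = np.exp(np.mean([np.log(ps[p]) for p in pr]))
                logs.append(np.log(num / den))
            logs = np.array(logs)
            gm = float(np.exp(logs.mean()))
            gsd = float(np.exp(logs.std(ddof=1))) if len(logs) > 1 else 1.0
            se = logs.std(ddof=1) / np.sqrt(len(logs)) if len(logs) > 1 else 0.0
            entry[f"per3_vs_{ref}"] = {
                "geometric_mean_ratio": gm,
                "geometric_sd": gsd,
                "exceeds_one": bool(logs.mean() - 2 * se > 0),
            }
        table[role] = entry
    return table
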