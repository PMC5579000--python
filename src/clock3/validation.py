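"""Leave-One-Out and Leave-Sets-Out validation of phenotype prediction.

Leave-One-Out: each condition of the registry is held out in turn, parameters
are re-estimated against the remaining conditions, and the held-out phenotype
is predicted by a majority vote over the feasible parameter sets found; the
fold is correct when the vote matches the expected phenotype.  Accuracy is
the fraction of correct folds.  Folds with fewer than five feasible sets are
flagged low-power (the vote still counts, on whatever sets exist).

Leave-Sets-Out: estimation uses only the knockout/wild-type conditions; each
SNP/VNTR condition is then evaluated post hoc on the resulting ensemble,
reporting the per-variant direction of the nuclear *BMAL1* mRNA period
change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .integrators import SimulationConfig
from .perturbations import Condition, Expectation
from .sres import CostResult, EstimationConfig, condition_cost, sres_search

__all__ = [
    "FoldRecord",
    "ValidationReport",
    "leave_one_out",
    "leave_sets_out",
    "MIN_FEASIBLE_PER_FOLD",
]

MIN_FEASIBLE_PER_FOLD = 5


@dataclass
class FoldRecord:
    held_out: tuple[str, ...]
    training: tuple[str, ...]
    n_parameter_sets: int
    n_satisfying: int
    predicted_correct_fraction: float
    correct: bool
    low_power: bool
    details: list[dict] = field(default_factory=list)


@dataclass
class ValidationReport:
    mode: str
    folds: list[FoldRecord]

    @property
    def accuracy(self) -> float:
        if not self.folds:
            return float("nan")
        return float(np.mean([f.correct for f in self.folds]))

    @property
    def per_set_accuracy(self) -> float:
        """Fraction of (parameter set, held-out condition) pairs satisfied —
        reported alongside the per-fold accuracy for transparency."""
        n_sets = sum(f.n_parameter_sets for f in self.folds)
        n_ok = sum(f.n_satisfying for f in self.folds)
        return n_ok / n_sets if n_sets else float("nan")


Estimator = Callable[[Sequence[Condition], int], list[tuple[object, CostResult]]]


def _default_estimator(network, est_config: EstimationConfig,
                       sim_config: SimulationConfig | None,
                       ranges=None, start=None, **search_kw) -> Estimator:
    def fit(conditions: Sequence[Condition], seed: int):
        cfg = EstimationConfig(
            generations=est_config.generations,
            parents_mu=est_config.parents_mu,
            population_lambda=est_config.population_lambda,
            ranking_pf=est_config.ranking_pf, seed=seed,
            retained_range_inflation=est_config.retained_range_inflation)
        return sres_search(network, conditions, cfg, ranges=ranges,
                           start=start, sim_config=sim_config, **search_kw)
    return fit


def _judge_fold(network, held: Condition, feasible_sets,
                sim_config) -> FoldRecord:
    details = []
    n_ok = 0
    for ps, _ in feasible_sets:
        cost = condition_cost(network, ps, [held], sim_config)
        ok = cost.violations[0]["satisfied"]
        n_ok += ok
        details.append({"satisfied": ok,
                        "reason": cost.violations[0]["reason"]})
    n = len(feasible_sets)
    frac = n_ok / n if n else 0.0
    return FoldRecord(
        held_out=(held.id,), training=(), n_parameter_sets=n,
        n_satisfying=n_ok, predicted_correct_fraction=frac,
        correct=bool(n and frac > 0.5),
        low_power=n < MIN_FEASIBLE_PER_FOLD, details=details)


def leave_one_out(network, conditions: Sequence[Condition],
                  est_config: EstimationConfig,
                  refined: bool = False,
                  sim_config: SimulationConfig | None = None,
                  estimator: Estimator | None = None,
                  refine_quantiles: tuple[float, float] = (0.05, 0.95),
                  ranges: dict | None = None, start=None,
                  **search_kw) -> ValidationReport:
    """LOO over the condition registry.

    With ``refined=True`` each fold first refines the parameter ranges on its
    own training conditions (never touching the held-out one) and re-estimates
    inside the refined box.  Custom ``estimator`` callables (signature
    ``(training_conditions, seed) -> [(params, cost), ...]``) replace the
    built-in SRES run — used by the tests to validate fold mechanics cheaply.
    """
    if len(conditions) < 2:
        raise ValueError("leave-one-out needs at least 2 conditions")
    fit = estimator or _default_estimator(network, est_config, sim_config,
                                          ranges=ranges, start=start,
                                          **search_kw)
    folds = []
    for i, held in enumerate(conditions):
        training = [c for j, c in enumerate(conditions) if j != i]
        seed = est_config.seed + 1000 * i
        results = fit(training, seed)
        feasible = [(ps, c) for ps, c in results if c.feasible]
        if refined and len(feasible) >= MIN_FEASIBLE_PER_FOLD:
            from .sres import refine_ranges
            ens = [ps for ps, _ in feasible]
            try:
                new_ranges = refine_ranges(ens, refine_quantiles,
                                           original=ranges)
                refit = _default_estimator(network, est_config, sim_config,
                                           ranges=new_ranges,
                                           start=feasible[0][0], **search_kw) \
                    if estimator is None else estimator
                results2 = refit(training, seed + 1)
                feas2 = [(ps, c) for ps, c in results2 if c.feasible]
                if feas2:
                    feasible = feasible + feas2
            except ValueError:
                pass
        rec = _judge_fold(network, held, feasible, sim_config)
        rec.training = tuple(c.id for c in training)
        folds.append(rec)
    return ValidationReport("loo_refined" if refined else "loo_unrefined",
                            folds)


VARIANT_SOURCES = ("variant_literature",)


def leave_sets_out(network, conditions: Sequence[Condition],
                   est_config: EstimationConfig,
                   sim_config: SimulationConfig | None = None,
                   estimator: Estimator | None = None,
                   ranges: dict | None = None, start=None,
                   **search_kw) -> ValidationReport:
    """Hold out every SNP/VNTR condition as one set; train on the rest."""
    variants = [c for c in conditions if c.source in VARIANT_SOURCES]
    training = [c for c in conditions if c.source not in VARIANT_SOURCES]
    if not variants:
        raise ValueError("registry contains no SNP/VNTR conditions to hold out")
    fit = estimator or _default_estimator(network, est_config, sim_config,
                                          ranges=ranges, start=start,
                                          **search_kw)
    results = fit(training, est_config.seed)
    feasible = [(ps, c) for ps, c in results if c.feasible]
    folds = []
    for held in variants:
        rec = _judge_fold(network, held, feasible, sim_config)
        rec.held_out = (held.id,)
        rec.training = tuple(c.id for c in training)
        folds.append(rec)
    return ValidationReport("leave_sets_out", folds)
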