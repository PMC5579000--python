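"""Knockout phenotypes: simulate each gene deletion and compare periods.

A knockout zeroes the gene's transcription rate.  The classic phenotype
pattern for the mammalian clock: PER1/PER2/PER3/CRY1 knockouts shorten the
BMAL1 mRNA period, CRY2 knockout lengthens it, the CRY1/CRY2 double knockout
and the BMAL1 knockout abolish rhythmicity.
"""

from clock3 import (SimulationConfig, build_network, builtin_conditions,
                    evaluate_condition)
from clock3.fixtures import load_fitted_ensemble

network = build_network()
params = load_fitted_ensemble()[0]
config = SimulationConfig(dt=0.005, t_end=600.0, transient_discard=360.0)

for cond in builtin_conditions():
    if "KO" not in cond.perturbation.name:
        continue
    out = evaluate_condition(network, params, cond, config)
    shift = ("n/a" if out.period_shift_pct is None
             else f"{out.period_shift_pct:+.2f}%")
    print(f"{cond.id:32s} expected={cond.expected.value:32s} "
          f"shift={shift:8s} satisfied={out.satisfied}")
# 'shift' is the percent period change of the condition's marker mRNA
# relative to the wild type of the same parameter set.
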