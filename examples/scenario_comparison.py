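"""Compare the five repair-outcome scenarios at reduced scale.

Only senescent-cell dynamics differ between scenarios: the senescence
probability P_SNC, the induction gate time T_SEN, and whether inflammatory
senescent cells pre-exist in the wound.  End states are classified against
the healthy baseline by day-18 matrix, inflammation and macrophage levels.
"""
import dataclasses

from woundcpm import (ScenarioConfig, baseline_params, classify_outcome,
                      run_replicate)
from woundcpm.scenarios import SCENARIO_NAMES

params = baseline_params()
params = dataclasses.replace(params, grid=params.grid.scaled(60))

runs = {}
for name in SCENARIO_NAMES:
    cfg = ScenarioConfig(name=name, duration_days=12.0, replicates=1,
                         sample_period_mcs=3200)
    runs[name] = run_replicate(params, cfg, seed=3)
    f = runs[name].iloc[-1]
    print(f"{name:20s} day{f.day:g}: ecm={f.n_ecm:5.0f} senescent="
          f"{f.n_senescent + f.n_preexisting:3.0f} "
          f"macrophages={f.n_macrophage:3.0f} inf={f.total_inf:7.1f}")

print()
baseline = runs["healthy"]
for name in SCENARIO_NAMES:
    label = classify_outcome(runs[name], baseline)
    print(f"{name:20s} -> {label}")

print("\nExpected pattern: excess or pre-existing senescence yields a "
      "chronic wound (matrix deficit, sustained inflammation); absent or "
      "late senescence yields fibrosis (matrix excess).")
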