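"""Particle-swarm estimation of a behavioural threshold.

Generates synthetic calibration targets by running the simulator at known
thresholds, then asks the swarm to recover the fibroblast-activation PDGF
threshold from those curves.  Because the objective uses common random
numbers, the true threshold scores exactly zero.
"""
import dataclasses

import numpy as np

from woundcpm import (PSOSpec, ScenarioConfig, baseline_params, pso_fit,
                      run_replicate, threshold_objective, timeseries_targets)

params = baseline_params()
small = dataclasses.replace(params, grid=params.grid.scaled(40))
cfg = ScenarioConfig(name="healthy", duration_days=2.0, replicates=1,
                     sample_period_mcs=800, seed=77)

truth = run_replicate(small, cfg, seed=77)
targets = timeseries_targets(truth, ("fibroblasts", "myofibroblasts", "ecm"))

true_value = params.behavior.pdgf_f
objective = threshold_objective(params, targets, duration_days=2.0,
                                lattice_size=40, sample_period_mcs=800,
                                seed=77)
spec = PSOSpec(bounds={"pdgf_f": (0.0, 4 * true_value)},
               swarm_size=5, iterations=4)
res = pso_fit(objective, spec, np.random.default_rng(4))

print(f"true pdgf_f      : {true_value:.4f}")
print(f"recovered pdgf_f : {res.best_position['pdgf_f']:.4f}")
print(f"objective        : {res.best_value:.4f} (mean relative error)")
print(f"evaluations      : {res.n_evaluations}")
print("\nA near-zero objective means the recovered threshold reproduces "
      "the target dynamics; thresholds are identifiable only up to the "
      "objective's flat region (values the dynamics never cross are "
      "indistinguishable).")
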