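"""The (P_SNC, T_SEN) sensitivity sweep at reduced scale.

Five senescence probabilities crossed with five gate times: 25 simulations,
each classified against a healthy baseline run.  Low P_SNC with an early
gate heals; zero or late senescence trends fibrotic; high P_SNC with an
early gate trends chronic.
"""
from woundcpm import SweepSpec, baseline_params, run_sweep

spec = SweepSpec(lattice_size=40, duration_days=3.0,
                 sample_period_mcs=500, seed=1)
result = run_sweep(baseline_params(), spec)

print(f"{result.n_runs} simulations")
header = "P_SNC \\ T_SEN" + "".join(f"{t:>10.0f}" for t in spec.t_sen_values)
print(header + "   (T_SEN in units of 1000 MCS)")
for p in spec.p_snc_values:
    row = "".join(f"{result.classification[(p, t)]:>10s}"
                  for t in spec.t_sen_values)
    print(f"{p:13.3f}" + row)

print("\nLabels come from day-%g end states relative to the healthy "
      "baseline; at this demonstration scale the end states are noise-"
      "dominated, so labels scatter — run with duration_days=18 and "
      "lattice_size=200 for the real classification map."
      % spec.duration_days)
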