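"""Measure the free-cell motility that anchors the model's time scale.

Places a single 8x8-pixel fibroblast on an empty 50x50 lattice (no
chemoattractant) and measures its mean centre-of-mass displacement per
Monte-Carlo step.  The baseline Metropolis temperature is calibrated so this
is ~0.1 pixel/MCS = 0.3 um/MCS, which against a 40 um/h reference migration
speed fixes 1 MCS = 27 s.
"""
from woundcpm import baseline_params
from woundcpm.engine import free_cell_speed

params = baseline_params()
speed = free_cell_speed(params, n_mcs=4000, seeds=(0, 1, 2))
um_per_mcs = params.units.pixels_to_um(speed)

print(f"mean COM displacement : {speed:.4f} pixel/MCS")
print(f"                      = {um_per_mcs:.3f} um/MCS")
print(f"one MCS               = {params.units.mcs_to_seconds(1):.0f} s")
print()
print("The displacement should sit near 0.1 pixel/MCS; larger values mean "
      "the membrane is too 'hot' (temperature too high), smaller values "
      "too rigid.")
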