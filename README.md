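# woundcpm

A Cellular Potts model of dermal wound healing with senescent-cell
dynamics, for systems biologists studying how the timing, abundance and
secretory phenotype of senescent cells steer tissue repair towards healthy
healing, chronic inflammation or fibrosis.

## The model

A 600 µm × 600 µm dermal section (200 × 200 lattice, 3 µm/pixel) evolves by
Metropolis pixel-copy dynamics under the effective energy

```
H = Σ J(τ,τ′)(1 − δ(σ,σ′)) + Σ λ_vol (v − V_t)² + λ_surf (s − S_t)²
```

with a chemotaxis bias −λ·Δc on copies that extend a migrating cell. One
Monte-Carlo step is 27 s (calibrated so a free cell moves ~0.1 pixel/MCS
against a 40 µm/h reference migration speed). Four diffusible species —
PDGF, CSF1, MMP and an aggregate inflammatory SASP field — obey
∂c/∂t = D∇²c − δc + S with no-flux borders.

Cell types are fibroblasts, myofibroblasts, macrophages (M1/M2), senescent
myofibroblasts, pre-existing inflammatory senescent cells, and one-pixel
immobile ECM "cells". Growth follows Monod kinetics (G_max·c/(c+c₀)) gated
by contact inhibition on the medium-surface ratio R_s; mitosis splits a cell
along a random axis at its doubling volume. Threshold rules drive
activation, myofibroblast differentiation, matrix production/degradation,
TIMP-like protease inhibition, macrophage polarization and removal.
Myofibroblasts senesce through a CCN1-mediated probabilistic gate (P_SNC,
opening at time T_SEN) and through juxtacrine/paracrine secondary
induction; senescent cells secrete a fibrogenic SASP (PDGF + ECM) for
~3 days (T_NIS) and a fibrolytic SASP (CSF1 + inflammation + MMP)
afterwards, and are cleared on macrophage contact or by inflammation with
equal probability. Five scenarios vary *only* senescent-cell dynamics:
healthy baseline, high P_SNC (chronic), P_SNC = 0 (fibrotic), delayed
T_SEN (fibrotic), and pre-existing inflammatory senescence (chronic).
On top sit a 5 × 5 (P_SNC × T_SEN) sensitivity sweep and particle-swarm
estimation of the six behavioural thresholds against calibration curves.

See `docs/methods.md` for the full model description, numerical choices
and calibration.

## A worked example

```
$ python examples/healthy_healing.py
  day  n_fibroblast  n_myofibroblast  n_senescent  n_macrophage  n_ecm  closure
 0.00            60                0            0             8   1600     0.14
 1.00            59                1            0             8   1812     0.38
 2.00            56                7            0             8   2048     0.62
 3.00            52               11            0            12   2325     0.76
 4.00            42               16            1            12   2465     0.80
 5.00            36                8           12            11   2555     0.78
 6.00            31                8           15            12   2623     0.70
 7.00            28                2           22            12   2734     0.68
 ...
18.00            22                0            3            28   2199     0.47

myofibroblast peak day : 4.0  (healthy: ~day 4)
senescent peak day     : 7.0  (healthy: ~day 7)
```

PDGF from wound macrophages activates margin fibroblasts, which migrate in,
deposit matrix and differentiate into myofibroblasts (peak ~day 4); from
day ~3.75 the senescence gate opens and the myofibroblast pool converts to
senescent cells (peak ~day 7), whose SASP switches from matrix-building to
matrix-degrading after three days, driving remodelling and immune
clearance. `closure` is the fraction of the original wound area occupied
by cells or matrix. (Exact numbers vary with the seed and lattice size;
the run above used `seed=5` on a 100 × 100 lattice.)

Other narrative scripts in `examples/`: `free_cell_motility.py`,
`scenario_comparison.py`, `parameter_sweep.py`, `threshold_fitting.py`,
`diffusion_fields.py`. A thin CLI mirrors the library:

```
woundcpm simulate --scenario healthy --seed 0 --out runs/healthy
woundcpm sweep --seed 0 --out runs/sweep --lattice-size 60
woundcpm make-fixtures --out curves.csv
woundcpm fit --targets curves.csv --seed 0 --out runs/fit
```

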