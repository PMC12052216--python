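# Methods

`woundcpm` simulates a two-dimensional dermal wound as a multiscale hybrid
model: a Cellular Potts model (CPM) for cell shape and motion, explicit
reaction–diffusion fields for four signalling species, and a rule system for
cell state. This note documents the model, the numerical choices, how the
baseline parameter set was calibrated, and what the synthetic components do
and do not represent.

## Lattice mechanics

The domain is a 200 × 200 pixel lattice (3 µm/pixel, 600 µm × 600 µm).
Generalized cells are sets of pixels with identical integer id; id 0 is
Medium. The effective energy is

```
H = Σ_pairs J(τ,τ′)·(1 − δ(σ,σ′))
  + Σ_cells λ_vol (v − V_t)² + λ_surf (s − S_t)²
```

with contact energy summed over Moore (8-neighbour) pixel pairs. Dynamics
are Metropolis pixel-copy attempts: a random target pixel and a random von
Neumann neighbour as source; the copy is accepted with probability
min(1, exp(−ΔH/T_m)). One Monte-Carlo step (MCS) is width × height
attempts. Chemotaxis enters as a bias term −λ·(c(target) − c(source)) added
to ΔH when a copy extends a chemotacting cell (fibroblasts/myofibroblasts
towards PDGF, macrophages towards inflammation); λ switches to a doubled
value while the moving cell touches ECM, representing migration along
matrix fibres. Borders are fixed (no wraparound), matching the no-flux
fields.

Per-cell caches (volume, surface, centre of mass, medium- and ECM-contact
pair counts) are maintained incrementally by the kernel and rebuilt from
the grid at every behaviour sweep; both paths are verified equal by
property tests, and the incremental ΔH is verified against a brute-force
total-energy oracle on small lattices. Cells may fragment (plain CPM);
one-pixel fragments are culled to Medium at each sweep. A cell whose volume
reaches zero keeps its constraint term until the next sweep buries it and
recycles its id.

ECM is represented as immobile one-pixel cells. Immobility is enforced by a
stiff volume constraint (λ_vol = 500 at target volume 1) rather than by
extreme contact energies, so that adhesion *to* ECM stays physical; the
acceptance probability of moving an ECM pixel is exp(−500/4.2) ≈ 10⁻⁵², i.e.
never in practice.

### Units and motility calibration

1 pixel = 3 µm; 1 MCS = 27 s (0.3 µm/MCS reference displacement against a
40 µm/h peak fibroblast migration speed; 0.3·3600/40 = 27). 1 day =
3200 MCS. The Metropolis temperature was calibrated so that a single
unconstrained 8 × 8 cell moves ~0.1 pixel/MCS (measured as the mean
per-MCS centre-of-mass displacement over ≥10⁴ MCS and five seeds): with
J(cell, Medium) = 8 and λ_vol = 2, T_m = 4.2 gives 0.101 ± 0.003
pixel/MCS. `scripts/acceptance.py` re-measures this from scratch.

## Diffusible fields

PDGF, CSF1, MMP (proteinase) and an aggregate inflammatory-SASP field obey

```
∂c/∂t = D ∇²c − δ c + S(x, t)
```

solved by forward Euler with a 5-point Laplacian, clamped-index (reflecting)
borders and automatic sub-stepping to satisfy D·Δt ≤ 1/4. Decay is applied
multiplicatively, (1 − δ·Δt) per sub-step, and values are clamped at zero
(the scheme is non-negative within the stability bound; the clamp guards
round-off). The clamped-index Laplacian conserves mass exactly under pure
diffusion, which the tests check to 1 × 10⁻⁸ relative over 1000 steps.
Fields ignore cell boundaries (species diffuse across cells), and secretion
is deposited uniformly over the secreting cell's pixels so a cell's output
does not scale with its size. Concentrations are in arbitrary model units —
only ratios to the behavioural thresholds matter.

Secretion rules: M2 macrophages secrete PDGF; M1 macrophages, and any
macrophage touching ECM, secrete MMP; activated fibroblasts and
myofibroblasts secrete CSF1 only while sharing surface with a macrophage
(contact-dependent growth-factor exchange); myofibroblasts additionally
secrete PDGF (autocrine); fibrogenic-phase senescent cells secrete PDGF
(and produce ECM); fibrolytic-phase and pre-existing inflammatory senescent
cells secrete CSF1, inflammation and MMP.

## Cell behaviour

Growth and mitosis run every MCS. Target volumes grow by the Monod law
G_max·c/(c + c₀) — PDGF-limited for fibroblasts/myofibroblasts,
CSF1-limited for macrophages, sampled at the cell's centre of mass
(nearest pixel, round half up) — gated by contact inhibition: growth
requires R_s = s_medium/s ≥ T_CI, otherwise the target volume is frozen at
the current volume (λ retained) until the cell regains free surface. A cell
reaching twice its original target volume divides along a random line
through its centre of mass; daughters inherit type and state flags and
reset to the original target volume.

All threshold/probability rules run in a behaviour sweep every 500 MCS
(≈0.19 d; 6.4 sweeps/day), evaluated against a snapshot of contact counts
and COM concentrations taken at sweep start, in this order: fragment
culling; macrophage polarization (M1 iff INF(COM) > INF_thr, re-evaluated
each sweep); persistent fibroblast activation (PDGF(COM) > PDGF_f);
myofibroblast differentiation (activated, inside the t = 0 wound mask,
PDGF gate and ECM contact > ECM_thr, probability P_MF per sweep); TIMP-like
inhibition (MMP at each myofibroblast COM reduced by MMP_thr, clamped at
zero); ECM degradation (ECM cells with MMP(COM) > MMP_thr removed); ECM
production (gated fibroblasts spawn ECM_Fib = 2 one-pixel ECM cells on
adjacent Medium, myofibroblasts twice that, fibrogenic senescent cells
ECM_Fib without the PDGF gate); senescence and fate (below); senescent
clearance; background removal (probability 1 − exp(−µ·Δt_sweep) for
activated fibroblasts and macrophages, plus CSF1-withdrawal death for
macrophages with CSF1(COM) < CSF1_thr). Threshold comparisons are strict
(>) except the contact-inhibition gate (≥).

Fate decisions — myofibroblast apoptosis/senescence and secondary
senescence — run on their own slower cadence (every 2000 MCS, 1.6/day).
This reflects that commitment events are rarer than signalling updates;
with per-check probabilities P_SNC = 0.15 (primary senescence) this yields
a ~0.2/day conversion hazard, which spreads the myofibroblast→senescent
transition over days rather than hours and produces the observed gradual
day-4→7 senescent rise. Secondary senescence is evaluated before apoptosis
so paracrine induction is not pre-empted by inflammatory apoptosis:
juxtacrine induction requires contact with a fibrogenic-phase senescent
cell plus PDGF(COM) > SNC_thr; paracrine requires contact with a
fibrolytic-phase (or pre-existing) senescent cell plus INF(COM) > INF_thr.
Apoptosis fires on ECM contact < ECM_thr (tension release) or INF(COM) >
INF_thr; otherwise, if the induction gate is open and ECM contact >
ECM_thr, the cell senesces with probability P_SNC (CCN1-mediated primary
induction; equality with ECM_thr means survival).

### Senescence timing

`t_sen` is configured in units of 1000 MCS; the baseline 12 is 12,000 MCS
= 3.75 days. The gate *opens* at `t_sen` (`t_sen_mode="open_after"`;
primary induction permitted for t ≥ T_SEN), which reproduces the day-4
onset of senescence in healthy healing and, at the delayed setting of 48
(= 15 days), the late-onset fibrotic scenario. The alternative reading —
induction only while t < T_SEN — is available as
`t_sen_mode="closed_before"`. Senescent cells carry a clock; their SASP is
fibrogenic while clock < T_NIS (3 days) and fibrolytic afterwards;
pre-existing inflammatory senescent cells are permanently fibrolytic.
Senescent cells are cleared on macrophage contact (phagocytosis) with
per-sweep probability p_clear, and by an equal-probability
inflammation-mediated route when INF(COM) > INF_thr; p_clear = 0.05 per
sweep (~0.3/day) keeps clearance slower than induction until the
fibrolytic phase attracts macrophages via inflammation chemotaxis, which
places the senescent-cell peak near day 7. The cumulative induction
counters satisfy, at every sample time, inductions (primary + juxtacrine +
paracrine + pre-existing) − clearances = live senescent cells.

## Initial condition and scenarios

The wound is a central square (120 px of 200, 36% of the domain). The
dermal margin is tiled with 8 × 8 fibroblasts checkerboarded with blocks of
one-pixel ECM cells at 50% pixel density — a porous scaffold that cells can
migrate along, not through. The wound holds 30 M2 macrophages on random
non-overlapping slots, plus (pre-existing-senescence scenario only) 12
inflammatory senescent cells whose pixels start with a nonzero inflammation
level. The wound also starts with a uniform CSF1 carry-over (0.08)
representing inflammatory-phase growth factor, which keeps macrophages
alive until activated fibroblasts reach them and contact-gated CSF1 supply
takes over.

Scenarios differ *only* in P_SNC, T_SEN and pre-existing seeding:
`healthy` (P_SNC = 0.15, t_sen = 12), `chronic_high_psnc` (P_SNC = 0.75),
`fibrotic_no_snc` (P_SNC = 0), `fibrotic_delayed` (t_sen = 48 = 15 days),
`chronic_preexisting` (seeded inflammatory senescent cells). Wound closure
is the fraction of the t = 0 wound mask occupied by any cell; its
per-sample difference is the closure rate. End states are classified
against a healthy baseline sampled on the same day grid: fibrotic if final
ECM exceeds baseline by 1.25×; chronic if final ECM falls below 0.70× or
final inflammation or macrophage count exceeds 2× baseline (with a floor of
5% of the baseline's peak inflammation to avoid division by a vanishing
late-time level); healthy otherwise. The factors are package-defined
defaults calibrated against reduced-scale scenario runs: the fibrotic
scenarios (absent and delayed senescence) separate robustly from the
baseline by excess matrix, while the chronic scenarios' day-18 signature —
persistent senescent load, inflammation and macrophages — is weaker at
reduced lattice scale than at full scale, where clearance takes longer to
exhaust the senescent population; a single reduced-scale chronic replicate
can therefore classify as healthy. This is a known limitation of end-state
classification under aggressive down-scaling, not of the rule system.

## Baseline calibration

No external data ship with the package. The baseline constants (contact
energies, temperature, diffusion/decay/secretion rates, thresholds, growth
maxima, P_MF, µ, T_CI and the seeding densities) were calibrated by the
authors of this package against the qualitative landmarks of healthy
healing: free-cell speed ~0.1 pixel/MCS; myofibroblasts rising from day 1
and peaking near day 4; senescent myofibroblasts rising near day 4 and
peaking near day 7; macrophages roughly doubling before plateauing;
matrix rising sharply in the first days, dipping ~0.5× around day 7 when
fibrolytic MMP arrives, then re-equilibrating. Calibration was performed
at 100 × 100 scale and verified at larger scales; the landmark timings are
largely structural (the T_SEN gate plus the 3-day fibrogenic phase set the
two peaks), so they are stable across lattice sizes and seeds within the
tests' ±1-day windows.

## Parameter estimation machinery

`objective_relative_error` scores a simulation against target curves for
six observables (fibroblast, myofibroblast, senescent-myofibroblast and
macrophage counts, ECM amount, wound-closure rate): per observable, the
mean over sample times of |sim − target| / max(|target|, ε) with
ε = 0.05·max|target| + 10⁻¹², averaged over observables. `pso_fit` is a
canonical global-best particle swarm (inertia ω = 0.7, cognitive = social
= 1.5, default swarm 15) with positions clamped to box bounds; the
global-best trace is non-increasing by construction. Threshold estimation
runs each candidate through a reduced-scale simulation with common random
numbers, so simulator-generated targets have a known zero at the true
thresholds; recovery is asserted up to the objective's flat region (a
threshold the dynamics never cross is unidentifiable). The synthetic
calibration curves produced by `generate_calibration_curves` are
parameterized stand-ins (log-normal pulses, logistics, double plateaus)
with the landmark shapes above — they are *not* measurements, and fitting
to them demonstrates the machinery, not biological truth.

## Problem sizes used by the tests

The test suite chooses sizes so each check measures what it needs and no
more: oracle equivalence on ≤6 × 6 lattices; cache coherence at 20 × 20
over 10⁴ MCS; motility at 50 × 50 over 5 × 10⁴ total MCS; the landmark
fixture one 120 × 120, 18-day replicate; scenario-logic checks at 60 × 60
over 6 days; the 5 × 5 sweep cardinality at 32 × 32; threshold recovery at
40 × 40 over 2 days.

## Known limitations

Two dimensions only; a single aggregate inflammation species and a single
ECM type; no epidermis/keratinocytes, no immune cells beyond macrophages;
cells are chemically homogeneous (no intracellular signalling);
myofibroblast de-differentiation to fibroblasts is not modelled (no rule
is defined for it; senescence and apoptosis are the modelled fates);
fibroblast activation is persistent. Field units are arbitrary, so
absolute concentrations are not comparable to assay data — only timing,
counts and ratios are meaningful. Passing tests demonstrate internal
consistency and reproduction of the calibrated landmarks, not validation
against wound-healing measurements.
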