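# isletsim

Stochastic simulation of microscopic tumor spread in prostate-like
organs: an Ising-energy cellular automaton that seeds small detached
tumor foci ("islets"), with tools for resolution transfer, calibration
against islet statistics, and Monte-Carlo tumor-probability maps for
radiation-therapy planning.

## The problem

Prostate tumors infiltrate surrounding tissue as small, roughly
spherical islets that are invisible on clinical imaging; treatment
volumes are therefore drawn with generous margins around the visible
gross tumor volume (GTV), irradiating mostly healthy tissue.  A
generative model of islet formation makes the trade-off quantitative:
given a patient's organ and GTV geometry, what is the probability of
finding tumor in a region we might want to spare?

## The model

The organ is discretised on an isotropic voxel grid; each voxel is
*healthy*, *tumor*, or *boundary* (outside the organ).  A tumor voxel
can **jump** to a face-adjacent healthy voxel, **duplicate** into one,
or **die**.  The propensity of an event of class α ∈ {jump, dup, die} is

    a = (1/τ_α) · exp(−ΔE / k_BT),

where ΔE is the change of a nearest-neighbour Ising energy

    E = −(1/2) Σ_i Σ_⟨j,i⟩ J σ_i σ_j,   σ_i = +1 (tumor), −1 (otherwise),

with J = 1.  The energy acts as a surface tension: detaching a voxel
from a cluster costs energy and is exponentially suppressed, so tumor
masses stay compact and detached fragments are rare, round islets —
matching histology.  Trajectories are sampled exactly with the Gillespie
stochastic simulation algorithm; a segment tree over all candidate
events gives O(log Ne) selection and update per event, so organ-scale
grids with tens of millions of candidate events are practical.

On top of the engine the package provides:

* **Resolution transfer** (`isletsim.scaling`): rules mapping
  (k_BT, τ_jump, τ_dup, τ_die) between grid spacings so diffusion,
  escape rate and growth velocity are preserved; validated by the
  convergence suites in `isletsim.convergence`.
* **Islet analysis** (`isletsim.islets`): 6-connected components,
  equivalent-sphere diameters, the >5 mm GTV split, the 1 mm islet
  filter, and the Kolmogorov (sup-CDF) distance between empirical
  distributions.
* **Calibration** (`isletsim.calibration`): fits the four parameters by
  minimising λ_n·D_K(counts) + D_K(median diameters) with CMA-ES over
  log-parameters.
* **Risk maps** (`isletsim.risk`): Monte-Carlo estimates P_N(d) of tumor
  presence within distance d of an organ at risk, with binomial errors.
* **Synthetic geometry** (`isletsim.geometry`): prostate-like organs,
  multi-lobed GTVs, bladder/rectum-like structures, and cohort
  generation — no clinical data required.

## Worked example

`examples/01_single_simulation.py` builds a reduced organ with a
three-lobed GTV and runs one trajectory of death-biased dynamics:

```
grid (42, 38, 40), GTV voxels: 1164
fired events by kind: {'jump': 2, 'dup': 1675, 'die': 2520}
 islet_id  voxel_count  volume_mm3  d_eq_mm  centroid_x_mm  centroid_y_mm  centroid_z_mm
        0          319      39.875 4.238713        9.71395       9.939655       8.005486
-> 1 islet(s); median equivalent diameter: 4.24 mm
```

The GTV erodes (die events dominate) and one of its lobes pinches off:
a detached focus of 319 voxels ≈ 39.9 mm³, equivalent-sphere diameter
4.24 mm — the kind of millimetre-scale islet reported in resection
specimens.  `examples/05_risk_map.py` turns 64 such samples into a risk
curve near a rectum-like structure:

```
 d_mm  p_tumor   stderr  n_samples
  1.0 0.000000 0.000000         64
  2.0 0.000000 0.000000         64
  3.0 0.375000 0.060515         64
  4.0 0.984375 0.015502         64
 ...
largest distance with tumor probability <= 5%: 2.0 mm
```

P_N(d) rises monotonically with the region size and jumps to 1 where the
region reaches the GTV; under this geometry, tissue within 2 mm of the
rectum-like structure carries ≤5% tumor probability.  The other examples
cover resolution transfer, islet statistics, and calibration.

A `isletsim` command-line interface wraps the same operations
(`simulate`, `analyze`, `rescale`, `convergence`, `calibrate`,
`riskmap`, `synth`); every run writes a manifest with its configuration
and seeds.

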