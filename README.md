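# phaseflux

Cell-cycle-resolved biosynthesis inference for single-cell time-lapse data.

Budding yeast cells do not build all of their biomass at a constant pace:
protein synthesis shows two activity waves per cell cycle (around START
and in mid S/G2/M), while lipid and cell-wall-polysaccharide synthesis
peak only once, in S/G2/M. `phaseflux` implements the full computational
chain needed to measure and propagate such dynamics from single-cell
fluorescence microscopy:

1. **Trace processing** (`tracekit`) — prolate-spheroid volume/surface from
   segmentation ellipse radii, cytokinesis-continuous cycle assembly with
   geometric translation of adjacent-cycle context, LOWESS and
   Savitzky–Golay smoothing, spline/midpoint derivatives, LOWESS-division
   detrending, 2-D-Gaussian flat-field correction.
2. **Phase machinery** (`cyclephase`) — ME/START detection from Whi5 pixel
   statistics, histone-loss karyokinesis calls with local-threshold nucleus
   segmentation, and the piecewise-linear map from time to cycle phase
   anchored at population-mean event timings
   `phi(t) = phi_lo + (phi_hi − phi_lo)(t − t_lo)/(t_hi − t_lo)`.
3. **Biosynthetic activities** (`biosynthrate`) — the maturation-corrected
   reporter production rate
   `r(t) = (t_half/ln2)·A''(t) + A'(t)` with `A = F_smooth · V_smooth`,
   and the stop-and-respond statistic
   `R_c = α(P_c − N(φ_c)) / (max N − min N)`,
   the normalised deviation of a cell's NAD(P)H derivative upon acute
   inhibition from the unperturbed same-phase median — a proxy for the
   inhibited process's momentary activity.
4. **GP summaries** (`gpsummary`) — bounded-RBF + white-noise Gaussian
   process regression of phase-scattered values, and Bayesian/frequentist
   adjudication of oscillatory versus linear shape.
5. **Cell-mass model** (`cellmass`) — an algebraic model
   `estimate(t) = Σ_j (1+h_j) M_j(t) + w·V(t)` fitted to volume × density,
   converting dimensionless activities into absolute rates (pg min⁻¹),
   with composition-constrained least squares and profile-likelihood
   identifiability analysis.
6. **Phase-resolved FBA** (`fluxcycle`) — relative rate contributions
   `c_j(t) = r_j/r_biomass` become cell-cycle-dependent biomass
   stoichiometry (`c_j(t)/c_model_j`, storage pinned to zero); 17
   independent LPs maximise biomass flux under a linear Gibbs-dissipation
   cap, with conversion to absolute fluxes
   `v_cell = 10⁻³ (v/v_biomass)(1/M_biomass) r_biomass` and
   newborn-weighted population yields.
7. **Synthetic experiments** (`synthdata`) — seeded generators for
   reporter/volume populations, perturbation experiments, nucleus/flat-field
   image fixtures and self-consistent mass datasets, each with ground truth,
   so every stage is testable without external data.

## Worked example

```python
import numpy as np
from phaseflux import synthdata
from phaseflux.pipelines import population_activity_profile, stop_and_respond_pattern

# reporter experiment: 20 cells, 2 cycles, 6-min cadence
truth = synthdata.GroundTruth(seed=1)
sim = synthdata.simulate_population(truth, n_cells=20, n_cycles=2)
phases, profile, rows = population_activity_profile(sim, t_half=6.0)
print(np.round(profile, 2))

# stop-and-respond experiment: 200 cells, translation inhibited
pert = synthdata.simulate_perturbation_experiment(
    synthdata.GroundTruth(seed=2, perturbation_gain=0.05),
    n_cells=200, t_switch=330.0, lag=6.0, activity="protein", sign=-1)
res, pattern = stop_and_respond_pattern(pert, seed=0)
print(len(res.kept), res.alpha, np.round(pattern.n_interior_maxima()[1], 3))
```

prints

```
[0.43 0.55 0.76 0.73 0.68 0.48 0.36 0.4  0.49 0.74 0.63 0.58 0.39 0.35
 0.32 0.24 0.33]
133 -1 [0.118 0.578]
```

The first line is the population-mean, min–max-normalised production-rate
profile on 17 phase points: two waves, peaking near phases 0.12 and 0.56
(the generating waveform peaks at 0.15 and 0.60; the Pearson correlation
with the truth is 0.92). The second line says 133 of 138 steadily cycling
cells passed the delay filter, the sign convention `α = −1` was chosen
because the population NAD(P)H level drops at the perturbation, and the
GP-summarised response pattern has two interior maxima at phases 0.118 and
0.578 — the stop-and-respond readout independently recovers the same
two-wave activity.

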