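# Methods

`phaseflux` reimplements, as a tested pipeline over synthetic data, the
computational chain that turns single-cell time-lapse measurements of
budding yeast into cell-cycle-resolved biosynthetic rates and
phase-dependent metabolic flux predictions. This note records the models,
the numerical choices, and the limits of what the synthetic experiments can
demonstrate.

## Cell-cycle phase machinery

A cell cycle is the half-open interval `(ME_i, ME_{i+1}]` between two
mitotic exits (nuclear entry of Whi5). Reference events are ME, START
(Whi5 re-localisation to the cytoplasm), bud emergence (BUD) and the next
ME. The population mean relative timing of each event,
`phi_e = mean[(t_e - t_ME)/(t_nextME - t_ME)]`, anchors a piecewise-linear,
monotone map from absolute time to phase in [0, 1]; the map is exact at the
reference events and invertible within each cycle.

ME/START candidates come from the derivative of the s.d./mean ratio of the
Whi5 reporter pixels: local maxima mark ME, minima mark START, compared
over a symmetric window of 12 points at a 6-min cadence (24 at 3 min).
Candidates within one window of the series boundary are dropped (they
cannot be confirmed), and tie plateaus resolve to the earliest time point.
Karyokinesis is the time of the most negative smoothed derivative of the
summed mother-nucleus histone (Hta2) intensity; the nucleus itself is
segmented by local-mean thresholding (15x15 neighbourhood plus the 30th
percentile of the mother pixels as offset), removal of objects below
25 px at orthogonal connectivity, selection of the object containing the
brightest pixel, and hole filling.

## Geometry and trace processing

Mother and bud are prolate spheroids: volume `(4/3) pi R r^2`, surface
`2 pi r^2 (1 + (R/(r e)) arcsin e)` with `e = sqrt(1 - r^2/R^2)`; the
sphere limit is taken analytically at `e = 0`, and inputs with `r > R` are
swapped with a warning because ellipse fitters do not guarantee order.
Within a cycle the total volume is mother plus bud, with the first
unmeasurable bud frames reconstructed linearly from zero at budding.
Smoothing at cycle edges uses 50 min of adjacent-cycle context translated
down/up by the bud volume at the bounding mitotic exits, which removes the
cytokinesis discontinuity; the translation reads the bud volume at the last
frame at or before the boundary, where the bud is still attached.

LOWESS smoothing is parameterised by a window in points (converted to the
fraction statsmodels expects) with tricube weights and a single plain pass
(no robustness reweighting); it is exact on straight lines for any window.
Default windows: volume 6, surface 8, reporter fluorescence 7 points.
Derivatives use a natural cubic interpolating spline on the
context-extended series, evaluated on the grid and trimmed to the core
cycle — with 50 min of context the boundary condition does not influence
the interior. NAD(P)H detrending divides the raw trace by a wide-window
LOWESS curve and then smooths the ratio with a narrow window.

Savitzky-Golay smoothing (window 7, cubic) is applied piecewise around a
declared discontinuity (the medium switch) and re-merged, so a genuine step
is preserved. Edge handling defaults to fitting the edge window's
polynomial directly (`mode="interp"`): padding with the nearest value
biases the derivative in the first interval of a piece by roughly a third
of the local slope, and the stop-and-respond statistic is read exactly
there. Nearest-value padding remains available as an option.

## Reporter production rate

Reporter abundance is the product of the smoothed mean fluorescence and the
smoothed (translated, context-extended) volume. With first-order
maturation at half-time `t_half` (6 min for sfGFP) the production rate is

    r(t) = (t_half / ln 2) * A''(t) + A'(t),

via the spline derivatives; without maturation correction, `r = A'`.
Negative values are allowed — double differentiation propagates noise.
For population summaries each cycle's rate trace is spline-sampled at 17
evenly spaced phases and min-max normalised; the GP summary regresses the
scattered values against phase with a signal x RBF + white-noise kernel,
attributing all within-phase scatter to noise.

## Stop-and-respond statistic

For each steadily cycling cell (latest pre-switch inter-bud duration within
median +/- s.d. of the population), `P_c` is the smoothed NAD(P)H midpoint
derivative immediately preceding the first severely perturbed frame `t_p`.
The cell's cycle position is the elapsed time since the nearest of
ME/START/BUD plus that event's population mean offset, with cells whose
anchoring event is abnormally delayed rejected. The reference `N(phi)` is
the across-cell median of the unperturbed derivative at the matching
offset from the *second-latest* event of the corresponding kind, and the
response is

    R_c = alpha * (P_c - N(phi_c)) / (max N - min N),

with `alpha = -1` when the population-average NAD(P)H level drops at `t_p`.

One refinement matters numerically: `P_c` is measured at the edge of a
smoothing piece (the trace is split at the switch), while a naive `N` would
be measured with an interior sliding window. The two transfer functions
differ, leaving a phase-locked bias of ~25% of the oscillation amplitude in
`P_c - N` even with no perturbation at all. `N` is therefore evaluated
with an *edge-matched* window: for each query time, a window of frames
positioned relative to the query exactly as the post-switch piece is
positioned relative to the `P_c` read-out. With matched transfer functions
the systematic part cancels and a zero-gain experiment yields a flat
response pattern (GP amplitude < 1% of the oscillation amplitude in the
shipped simulations). Derivatives are midpoint differences throughout,
linearly interpolated where a query falls between midpoints.

## Gaussian-process summaries and shape adjudication

`fit_phase_gp` maximises the log marginal likelihood of
`C * RBF(l in bounds) + White` with deterministic multi-start; the
stop-and-respond pattern uses length-scale bounds of 2-5 imaging steps on
the phase axis, following the protocol. Oscillatory-vs-linear adjudication
reports a Bayesian criterion (difference in maximised log marginal
likelihood against a linear-kernel-plus-constant GP) and a frequentist one
(5-fold cross-validated predictive log density, with the fitted white-noise
level included in the predictive variance); the verdict is the shared
winner or "inconclusive" when they disagree. The RBF length scale is
bounded below at 0.1 of the cycle so the oscillatory model cannot win by
tracking sampling noise.

## Cell-mass model

Total mass over one cycle is modelled as five macromolecule pools plus
hydration water and free water/metabolites:

    estimate(t) = sum_j (1 + h_j) M_j(t) + w V(t),        j in {protein, lipid,
                                                           polysaccharide, RNA, DNA}

with `M_j(t) = M_j(ME) + int_0^t r_j`, trapezoid integration on the grid.
Protein, lipid and polysaccharide rates are `k_j (a_j + b_j)` with measured
dimensionless activities `a_j`, conversion factors `k_j` (pg/min per
activity unit) and vertical translations `b_j` bounded by the activity
uncertainty. DNA synthesis is constant on (BUD, KARYO] and zero elsewhere.
RNA is rRNA plus a constant non-rRNA rate; rRNA is proportional to the
protein rate from 15 min (configurable) before mitotic exit through
budding (wrapping across ME) and constant elsewhere — the model extends the
budding-to-karyokinesis constant branch to the uncovered remainder of the
cycle. Initial masses follow from cycle periodicity,
`M_j(ME) = f_j I_j / (1 - f_j)` with `I_j` the cycle integral of `r_j` and
`f_j` the mother's retained fraction at division (volume fraction for
protein/RNA, surface fraction for lipid/polysaccharide, one genome copy for
DNA). The empirical mass is volume times density; the fit minimises the
unweighted sum of squared differences.

**Identifiability.** The measured one-peak activities (lipid,
polysaccharide) overlap the protein activity's S/G2/M wave, and the rRNA
coupling covers its G1 wave; without further information the conversion
factors are structurally non-identifiable — an exact zero-residual
compensation exists for 25% changes in `k_protein`. What identifies the
absolute rates is the cycle-average composition information: windows on
each component's mean dry-mass fraction enter the fit as linear
inequality constraints (the mean component masses and the mean dry mass
are all linear in the scale parameters). The shipped synthetic datasets
carry windows of 2% relative width around their own true fractions,
matching the precision of careful compositional measurements, together
with translation bounds of +/-0.01 activity units; under these conditions
the median recovery error of `k_j` across seeded datasets is below 5% and
the profile likelihood of `k_protein` is U-shaped. Wider windows degrade
recovery roughly linearly — a genuine property of the inference, not an
implementation artifact.

**Optimisation.** For fixed translations and hydration fractions the
estimate is linear in the remaining parameters, so the fit nests a
constrained non-negative least-squares core (SLSQP, warm-started from the
unconstrained bounded solution) inside a small multi-start bounded outer
search (L-BFGS-B over `b_j`, and over `h_j` when their bounds are not
degenerate; hydration defaults to a fixed 0.3 g water per g macromolecule).
Replicate activity sets are fitted for every combination plus the
replicate average, giving a min-max ensemble band. Profile likelihoods pin
one parameter, re-optimise the rest over a grid, and declare
identifiability when the objective rises above the minimum plus a
chi-square(1) 95% threshold scaled by the residual variance on both sides.
A documented `redundant_scale` diagnostic duplicates the protein column
(an exact degeneracy) to verify that the machinery reports flat profiles.

## Phase-resolved, dissipation-capped FBA

The relative contributions `c_j(t) = r_j / r_biomass` become the biomass
stoichiometry: component `j` enters the biomass reaction with multiplier
`c_j(t)/c_model_j` at each of 17 cycle moments (t = 3, 9, ..., 99 min);
the storage coefficient is zero throughout. Each moment is an independent
quasi-steady-state LP: maximise the biomass flux subject to `S v = 0`,
bounds, and a cap on the Gibbs energy dissipation rate

    g(v) = - sum_exchanged v_i dfG'_i / M_biomass  <=  g_lim,

linear in `v` because the external conditions (hence the transformed
formation energies of the exchanged species) are fixed. The nonconvex
concentration-coupled thermodynamic formulation of the source model (and
its Gibbs-energy regression) is out of scope. Uptakes are negative,
excretions positive. FBA fluxes convert to absolute units by

    v_cell = 1e-3 (v / v_biomass) (1 / M_biomass) r_biomass   [pmol/cell/h],

so the biomass reaction's absolute flux is identically
`r_biomass / (1000 M_biomass)`. Population yields weight the early-G1
moments (t in {3, 9} min) by 79.75/11 — the mean newborn early-G1 duration
over the mature one — before forming mass-yield ratios against glucose.
ATP turnover sums the producing-side fluxes; precursor sinks sum a
configured reaction subset.

The shipped network (`data/toy_network.json`) is a deliberately small
synthetic fixture: ~20 lumped reactions (glucose transport, lumped
glycolysis, fermentation, respiration, NADH oxidation, six component
syntheses with distinct glucose/ATP/NADH costs, a biomass assembly
template and exchanges), exactly mass-balanced from atomic masses, with
literature-scale formation energies on the exchanged species. Its
stoichiometries are illustrative — they are not a published reconstruction
— and absolute flux values from it should not be compared with measured
yeast physiology; the pipeline's contributions (phase-dependent biomass
stoichiometry, the linear dissipation cap, unit conversion, weighted
yields) are network-agnostic.

## Synthetic experiments: what they do and do not show

The generator emulates the statistical structure the analysis assumes:
two-peak (protein) and one-peak (lipid/polysaccharide) activity waveforms
built from wrapped Gaussian bumps; first-order reporter maturation
(half-time 6 min) integrated exactly against the cumulative rate so the
pool balance closes to machine precision; prolate-spheroid growth routed
to the mother before budding and to the bud after, with the bud departing
at mitotic exit and the reporter pools split by the retained volume
fraction so measured concentration stays continuous; NAD(P)H baselines as
periodic cubic splines through control points, with the perturbation
adding a derivative offset proportional to the inhibited activity at the
cell's phase; and additive Gaussian channel noise (2% of the channel mean)
with 1% lognormal radii noise. Event schedules are jittered normal
variates (cycle 102 +/- 6 min; START, BUD, karyokinesis at fixed mean
fractions with 1% jitter); the within-population variance structure of
event timing is free configuration, as no canonical value exists.
The default imaging cadence is 6 min, matching the formulas' time unit
(minutes) throughout.

Not emulated: photophysics and optics, segmentation failure modes,
cell-to-cell interactions, realistic bright-field appearance, cell death,
and the coupling of metabolism back onto growth. Passing recovery tests
therefore demonstrates the correctness and numerical stability of the
inference chain under the assumed noise structure — not robustness to the
full error structure of real microscopy data.

## Problem sizes

The shipped tests and the acceptance script run populations of 10-50 cells
(2 observed cycles each), perturbation experiments of 200 cells, 10-20
seeded datasets per model-selection and mass-model check, and 17-phase LP
sweeps; these sizes were chosen so every recovery property is measurable
with comfortable margins while the whole suite remains a desk-scale
computation.
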