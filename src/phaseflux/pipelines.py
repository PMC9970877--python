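"""End-to-end analysis drivers combining the module stages.

These are the entry points a user runs on a whole experiment: reporter
traces -> population activity profile, and perturbation experiment ->
stop-and-respond activity pattern.
"""

from __future__ import annotations

import numpy as np

from .biosynthrate import cycle_production_rates, minmax_phase_matrix, run_stop_and_respond
from .gpsummary import fit_phase_gp

__all__ = ["population_activity_profile", "stop_and_respond_pattern"]


def population_activity_profile(sim, t_half=6.0, n_phase=17, drop_context_cycles=True):
    """Mean min-max-normalised production-rate profile of a population.

    Runs the full reporter pipeline (cycle assembly, smoothing, abundance,
    maturation-corrected differentiation, phase sampling, min-max rows) on
    every cell of a :class:`~phaseflux.synthdata.PopulationSim`-like object
    and averages the rows.  Interior cycles only by default, since boundary
    cycles lack adjacent-cycle smoothing context.
    """
    rows = []
    for tr, ann in zip(sim.traces, sim.annotations):
        cycles = cycle_production_rates(tr, ann.events, t_half=t_half)
        if drop_context_cycles and len(cycles) > 2:
            cycles = cycles[1:-1]
        _, mat = minmax_phase_matrix(cycles, sim.mean_phases, n_phase=n_phase)
        rows.extend(mat)
    rows = np.asarray(rows)
    phases = np.linspace(0.0, 1.0, n_phase)
    return phases, rows.mean(axis=0), rows


def stop_and_respond_pattern(sim, lengthscale_dt_bounds=(2.0, 5.0), seed=0, n_grid=101):
    """Per-cell responses plus the GP-summarised activity pattern.

    The RBF length-scale bounds follow the protocol's multiples of the
    imaging cadence, expressed here on the relative-phase axis.
    """
    res = run_stop_and_respond(sim.traces, sim.annotations, sim.t_switch, sim.t_p, sim.dt)
    kept = res.kept
    cc = res.deltas["CC"]
    bounds = (lengthscale_dt_bounds[0] * sim.dt / cc, lengthscale_dt_bounds[1] * sim.dt / cc)
    pattern = fit_phase_gp(
        kept.phi_rel.values, kept.R_c.values, lengthscale_bounds=bounds, seed=seed, n_grid=n_grid
    )
    return res, pattern
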