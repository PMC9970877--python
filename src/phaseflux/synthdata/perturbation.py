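"""Simulated stop-and-respond experiments.

Asynchronously cycling cells carry an NAD(P)H-like fluorescence channel
whose baseline is a smooth cell-cycle-periodic oscillation (a periodic
cubic spline through configurable control points).  At the perturbation
time the derivative of each cell's trace jumps by

    sign * gain * activity(phase of the cell at the perturbation)

emulating the acute inhibition of a biosynthetic process whose momentary
activity sets the size of the metabolic response.  The sign is configurable
so that both orientations of the response statistic's sign convention are
exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from ..tracekit import SingleCellTrace
from ..cyclephase import CycleAnnotation
from .population import GroundTruth, _cell_schedule, _phase_of_time

__all__ = ["PerturbationSim", "simulate_perturbation_experiment", "periodic_baseline"]

DEFAULT_BASELINE_POINTS = (
    (0.0, 1.00),
    (0.18, 1.12),
    (0.40, 0.94),
    (0.62, 1.08),
    (0.82, 0.92),
)


def periodic_baseline(points=DEFAULT_BASELINE_POINTS):
    """Periodic cubic spline through (phase, level) control points."""
    pts = sorted(points)
    phi = np.array([p for p, _ in pts] + [pts[0][0] + 1.0])
    val = np.array([v for _, v in pts] + [pts[0][1]])
    spl = CubicSpline(phi, val, bc_type="periodic")
    return lambda phase: spl(np.mod(np.asarray(phase, float), 1.0))


@dataclass
class PerturbationSim:
    """Multi-cell NAD(P)H traces around a perturbation, with ground truth."""

    traces: list
    annotations: list
    t_switch: float
    t_p: float
    dt: float
    sign: int
    truth: GroundTruth
    activity_name: str
    true_phase: np.ndarray        # phase in [0,1] of each cell at t_p
    true_activity: np.ndarray     # activity waveform value at that phase
    baseline: object = field(repr=False, default=None)

    @property
    def baseline_derivative_amplitude(self):
        """max-min of the baseline NAD(P)H time derivative (per minute)."""
        phi = np.linspace(0, 1, 4001)
        lvl = self.baseline(phi)
        d = np.gradient(lvl, phi) / self.truth.cycle_min
        return float(d.max() - d.min())


def simulate_perturbation_experiment(
    truth,
    n_cells,
    t_switch,
    lag,
    dt=6.0,
    sign=-1,
    activity="protein",
    baseline_points=DEFAULT_BASELINE_POINTS,
):
    """Simulate an acute-inhibition experiment on ``n_cells`` cycling cells.

    Parameters
    ----------
    truth : GroundTruth
        ``perturbation_gain`` scales the derivative jump; the waveform named
        by ``activity`` sets its phase dependence.
    t_switch : float
        Arrival time of the perturbing medium (min); cells have cycled since
        well before it so every cell has at least two pre-switch buddings.
    lag : float
        Delay from the switch to the first frame of severe perturbation
        ``t_p``; must be non-negative.
    sign : {-1, +1}
        Direction of the derivative offset (a drop for cycloheximide-like
        perturbations; the analysis pipeline's alpha should recover it).
    """
    if lag < 0:
        raise ValueError("lag must be non-negative")
    if sign not in (-1, 1):
        raise ValueError("sign must be -1 or +1")
    wf = truth.activity_waveforms[activity]
    baseline = periodic_baseline(baseline_points)

    t_switch = round(t_switch / dt) * dt
    t_p = round((t_switch + lag) / dt) * dt
    t_onset = t_p - dt  # the derivative between t_p - dt and t_p already responds
    t_end = t_p + 5 * dt

    seeds = np.random.SeedSequence(truth.seed).spawn(n_cells)
    sim = PerturbationSim(
        traces=[],
        annotations=[],
        t_switch=t_switch,
        t_p=t_p,
        dt=dt,
        sign=sign,
        truth=truth,
        activity_name=activity,
        true_phase=np.empty(n_cells),
        true_activity=np.empty(n_cells),
        baseline=baseline,
    )

    n_cycles = int(np.ceil(t_end / truth.cycle_min)) + 2
    for ci, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        events = _cell_schedule(truth, rng, n_cycles)
        # desynchronise: random shift so phases at t_p are uniform
        shift = -rng.uniform(0.0, truth.cycle_min)
        for k in events:
            events[k] = events[k] + shift

        obs_t = np.arange(0.0, t_end + dt / 2, dt)
        phase = _phase_of_time(obs_t, events, truth.mean_phases)
        phi_p = float(phase[int(round(t_p / dt))])  # t_p lies exactly on the grid
        act = float(wf(phi_p % 1.0))

        F = baseline(phase)
        after = obs_t > t_onset
        F = F + after * (sign * truth.perturbation_gain * act * (obs_t - t_onset))
        F = F + rng.normal(0.0, truth.noise_channel_frac * np.nanmean(np.abs(F)), size=len(F))

        trace = SingleCellTrace(cell_id=f"cell{ci:04d}", time_min=obs_t, channels={"NADPH": F})
        ann = CycleAnnotation(
            cell_id=trace.cell_id,
            events={k: v[(v >= 0) & (v <= t_end)] for k, v in events.items()},
        )
        sim.traces.append(trace)
        sim.annotations.append(ann)
        sim.true_phase[ci] = phi_p % 1.0
        sim.true_activity[ci] = act
    return sim
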