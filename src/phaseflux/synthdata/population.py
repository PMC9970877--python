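"""Forward simulation of single-cell reporter/volume time-lapse experiments.

Each simulated cell runs through stochastic cell cycles (ME, START, BUD,
karyokinesis, next ME), expresses a fluorescent reporter whose production
rate follows a ground-truth activity waveform of cell-cycle phase, and grows
as a prolate spheroid whose volume integrates a volumetric growth waveform.
The reporter matures with first-order kinetics

    dA_im/dt = r(t) - (ln 2 / t_half) * A_im,      dA_mat/dt = (ln 2 / t_half) * A_im,

and the measured mean fluorescence is the mature pool divided by cell
volume.  After budding all growth is routed to the bud, which departs at the
next mitotic exit (cytokinesis discontinuity).  The internal integration
grid is much finer than the imaging cadence so that the emitted ground-truth
rate series can serve as an oracle for the production-rate estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from ..tracekit import SingleCellTrace
from ..cyclephase import CycleAnnotation
from .waveforms import PeriodicWaveform, one_peak_waveform, two_peak_waveform

__all__ = ["GroundTruth", "PopulationSim", "simulate_population"]

LN2 = np.log(2.0)


def _default_waveforms():
    return {
        "protein": two_peak_waveform(),
        "lipid": one_peak_waveform(center=0.6),
        "polysaccharide": one_peak_waveform(center=0.62, width=0.12),
        # volumetric growth: never zero, one broad S/G2/M wave
        "volume": one_peak_waveform(center=0.55, width=0.15, height=0.8, floor=0.6),
    }


@dataclass
class GroundTruth:
    """Generator configuration; the seed fully determines all outputs.

    Event timing defaults reproduce the fast-cycling condition of the
    experiments emulated here: cycle duration ~102 min with START at ~11 min,
    budding at ~33 min and karyokinesis ~15 min before the next mitotic exit.
    The within-population variance of event timings is free configuration
    (``cycle_sd_min``, ``event_jitter``), not a canonical value.
    """

    activity_waveforms: dict = field(default_factory=_default_waveforms)
    cycle_min: float = 102.0
    cycle_sd_min: float = 6.0
    start_frac: float = 11.0 / 102.0
    bud_frac: float = 33.0 / 102.0
    karyo_frac: float = 87.0 / 102.0
    event_jitter: float = 0.01          # s.d. of relative event-timing jitter
    maturation_halftime: float = 6.0    # min
    rate_scale: float = 1.0             # abundance units per min at activity 1
    initial_mature: float = 25.0
    initial_immature: float = 0.0
    growth_per_cycle_fl: float = 28.0
    birth_volume_fl: float = 30.0
    aspect_ratio: float = 1.3
    noise_channel_frac: float = 0.02    # additive Gaussian s.d. / channel mean
    radii_lognorm_sd: float = 0.01      # multiplicative lognormal s.d. on radii
    perturbation_gain: float = 0.05     # NAD(P)H derivative jump per activity unit (fluor min^-1)
    bud_missing_frames: int = 3         # unmeasurable early-bud frames
    seed: int = 0

    def __post_init__(self):
        for name, wf in self.activity_waveforms.items():
            if not isinstance(wf, PeriodicWaveform):
                self.activity_waveforms[name] = PeriodicWaveform(wf, name=name)
        if not 0 < self.start_frac < self.bud_frac < self.karyo_frac < 1:
            raise ValueError("event fractions must satisfy 0 < START < BUD < KARYO < 1")

    @property
    def mean_phases(self):
        return {"ME": 0.0, "START": self.start_frac, "BUD": self.bud_frac, "next ME": 1.0}


def _cell_schedule(truth, rng, n_cycles):
    """Event times for one cell covering ``n_cycles`` observed cycles plus context."""
    total = n_cycles + 2  # one leading and one trailing context cycle
    durations = np.clip(
        rng.normal(truth.cycle_min, truth.cycle_sd_min, size=total), 40.0, None
    )
    me = np.concatenate([[0.0], np.cumsum(durations)])
    events = {"ME": me, "START": [], "BUD": [], "KARYO": []}
    for i in range(total):
        d = durations[i]
        jit = rng.normal(0.0, truth.event_jitter, size=3)
        s = np.clip(truth.start_frac + jit[0], 0.02, truth.bud_frac - 0.02)
        b = np.clip(truth.bud_frac + jit[1], s + 0.02, truth.karyo_frac - 0.02)
        k = np.clip(truth.karyo_frac + jit[2], b + 0.02, 0.98)
        events["START"].append(me[i] + s * d)
        events["BUD"].append(me[i] + b * d)
        events["KARYO"].append(me[i] + k * d)
    for k in ("START", "BUD", "KARYO"):
        events[k] = np.asarray(events[k])
    return events


def _phase_of_time(times, events, mean_phases):
    """Vectorised piecewise-linear phase for times within the event span."""
    me = events["ME"]
    phases = np.full(len(times), np.nan)
    knots_p = [0.0, mean_phases["START"], mean_phases["BUD"], 1.0]
    for i in range(len(me) - 1):
        knots_t = [me[i], events["START"][i], events["BUD"][i], me[i + 1]]
        sel = (times >= me[i]) & (times <= me[i + 1])
        phases[sel] = np.interp(times[sel], knots_t, knots_p)
    return phases


def _integrate_maturation(rate, fine_dt, t_half, a_im0, a_mat0):
    """Exponential-integrator solution of the two-pool maturation model.

    The total pool is the exact cumulative integral of the rate (so
    conservation holds to machine precision); the immature pool uses the
    exact one-step solution with the rate held at its per-step midpoint.
    """
    total = a_im0 + a_mat0 + np.concatenate([[0.0], cumulative_trapezoid(rate, dx=fine_dt)])
    if t_half < 1e-9:
        return np.zeros_like(total), total
    k = LN2 / t_half
    E = np.exp(-k * fine_dt)
    a_im = np.empty(len(rate))
    a_im[0] = a_im0
    r_mid = 0.5 * (rate[:-1] + rate[1:])
    for i in range(len(rate) - 1):
        a_im[i + 1] = a_im[i] * E + r_mid[i] * (1.0 - E) / k
    return a_im, total - a_im


@dataclass
class PopulationSim:
    """Simulated population plus ground truth for oracle comparisons."""

    traces: list
    annotations: list
    truth: GroundTruth
    mean_phases: dict
    true_rate: list          # per cell: production rate on the imaging grid
    true_abundance: list     # per cell: noiseless total reporter abundance
    true_phase: list         # per cell: cell-cycle phase on the imaging grid
    conservation_error: float


def simulate_population(truth, n_cells, n_cycles, dt=6.0, fine_dt=0.05):
    """Simulate ``n_cells`` cells observed for ``n_cycles`` full cycles each.

    Returns a :class:`PopulationSim` whose traces carry the fluorescence
    channel ``"GFP"`` and mother/bud ellipse radii, and whose annotations
    list every ME/START/BUD/KARYO event.  One context cycle before and after
    the observed window is included so cycle assembly can use adjacent data.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    wf_protein = truth.activity_waveforms["protein"]
    wf_volume = truth.activity_waveforms["volume"]

    seeds = np.random.SeedSequence(truth.seed).spawn(n_cells)
    sim = PopulationSim([], [], truth, truth.mean_phases, [], [], [], 0.0)
    max_cons_err = 0.0

    # volumetric gain normalisation: one cycle of the volume waveform integrates
    # to growth_per_cycle_fl at the mean cycle duration
    phi_grid = np.linspace(0, 1, 2001)
    wf_vol_mean = np.trapezoid(wf_volume(phi_grid), phi_grid)
    g_vol = truth.growth_per_cycle_fl / (wf_vol_mean * truth.cycle_min)

    for ci, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        events = _cell_schedule(truth, rng, n_cycles)
        me = events["ME"]
        t_end = me[-1]
        fine_t = np.arange(0.0, t_end + fine_dt / 2, fine_dt)
        phase = _phase_of_time(fine_t, events, truth.mean_phases)

        rate = truth.rate_scale * wf_protein(phase)
        a_im, a_mat = _integrate_maturation(
            rate, fine_dt, truth.maturation_halftime, truth.initial_immature, truth.initial_mature
        )
        a_tot = a_im + a_mat

        # conservation: integral of rate vs total-pool gain per observed cycle
        for me_i, me_j in zip(me[1:-2], me[2:-1]):
            i0, i1 = int(round(me_i / fine_dt)), int(round(me_j / fine_dt))
            gained = a_tot[i1] - a_tot[i0]
            integ = np.trapezoid(rate[i0 : i1 + 1], dx=fine_dt)
            if abs(gained) > 0:
                max_cons_err = max(max_cons_err, abs(integ - gained) / abs(gained))

        # volume: growth routed to mother before BUD, to bud after; bud departs at ME
        growth = np.concatenate(
            [[0.0], cumulative_trapezoid(g_vol * wf_volume(phase), dx=fine_dt)]
        )
        mother_v = np.empty_like(fine_t)
        bud_v = np.zeros_like(fine_t)
        m_current = truth.birth_volume_fl
        for i in range(len(me) - 1):
            sel = (fine_t >= me[i]) & (fine_t <= me[i + 1])
            t_bud = events["BUD"][i]
            g_seg = growth[sel] - np.interp(me[i], fine_t, growth)
            g_at_bud = np.interp(t_bud, fine_t, growth) - np.interp(me[i], fine_t, growth)
            before = fine_t[sel] <= t_bud
            mv = np.where(before, m_current + g_seg, m_current + g_at_bud)
            bv = np.where(before, 0.0, g_seg - g_at_bud)
            mother_v[sel] = mv
            bud_v[sel] = bv
            m_current = m_current + g_at_bud  # bud leaves at next ME

        # at each division the departing bud takes its share of the reporter
        # pools, keeping the measured concentration continuous
        total_v = mother_v + bud_v
        split = np.ones_like(fine_t)
        for me_i in me[1:-1]:
            i_d = int(np.ceil(me_i / fine_dt))
            if 0 < i_d < len(fine_t):
                split[i_d:] *= total_v[i_d] / total_v[i_d - 1]
        a_mat_cell = a_mat * split
        a_tot_cell = a_tot * split

        # sample onto the imaging grid, observing cycles 1..n_cycles (plus context)
        obs_t = np.arange(0.0, t_end - dt / 2, dt)
        idx = np.round(obs_t / fine_dt).astype(int)
        F = a_mat_cell[idx] / total_v[idx]
        F_noisy = F + rng.normal(0.0, truth.noise_channel_frac * F.mean(), size=len(F))

        def radii(vol, rng, ar=truth.aspect_ratio):
            r = np.cbrt(3.0 * vol / (4.0 * np.pi * ar))
            noise = np.exp(rng.normal(0.0, truth.radii_lognorm_sd, size=(2, len(r))))
            return ar * r * noise[0], r * noise[1]

        mR, mr = radii(mother_v[idx], rng)
        bud_obs = bud_v[idx].copy()
        bR = np.full(len(obs_t), np.nan)
        br = np.full(len(obs_t), np.nan)
        has_bud = bud_obs > 0
        if has_bud.any():
            bR[has_bud], br[has_bud] = radii(bud_obs[has_bud], rng)
        # first frames after each budding are unmeasurable
        for t_bud in events["BUD"]:
            blank = has_bud & (obs_t > t_bud) & (obs_t <= t_bud + truth.bud_missing_frames * dt)
            bR[blank] = np.nan
            br[blank] = np.nan

        trace = SingleCellTrace(
            cell_id=f"cell{ci:04d}",
            time_min=obs_t,
            channels={"GFP": F_noisy},
            mother_R=mR,
            mother_r=mr,
            bud_R=bR,
            bud_r=br,
        )
        ann = CycleAnnotation(cell_id=trace.cell_id, events={k: v.copy() for k, v in events.items()})
        sim.traces.append(trace)
        sim.annotations.append(ann)
        # within a cycle the cell's pool production is the lineage rate scaled
        # by the cumulative division splits (constant within each cycle)
        sim.true_rate.append((rate * split)[idx])
        sim.true_abundance.append(a_tot_cell[idx])
        sim.true_phase.append(phase[idx])

    sim.conservation_error = max_cons_err
    return sim
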