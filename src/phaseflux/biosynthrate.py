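"""Dimensionless biosynthetic activity inference from single-cell traces.

Two independent readouts are implemented:

1. **Maturation-corrected reporter production rate.**  Reporter abundance is
   the product of smoothed mean fluorescence and smoothed cell volume; with
   first-order maturation (half-time ``t_half``) the production rate is

       r(t) = (t_half / ln 2) * A''(t) + A'(t),

   with derivatives from a natural cubic spline through the
   context-extended abundance trace.

2. **Stop-and-respond NAD(P)H response.**  Upon acute inhibition of a
   process, each cell's NAD(P)H derivative immediately preceding the first
   severely perturbed frame (``P_c``) is compared with the median derivative
   at the comparable time of the unperturbed preceding cycle (``N(phi)``),
   normalised by the amplitude of ``N``:

       R_c = alpha * (P_c - N(phi_c)) / (max N - min N),

   where ``alpha = -1`` when the population-average NAD(P)H level drops at
   the perturbation and ``+1`` otherwise, so the response is on average
   non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .cyclephase import phase_to_time, time_to_phase
from .tracekit import (
    assemble_continuous_series,
    derivatives,
    lowess_smooth,
    savgol_smooth,
)

__all__ = [
    "production_rate",
    "cycle_production_rates",
    "minmax_phase_matrix",
    "select_steady_cycling_cells",
    "perturbation_phase",
    "normal_derivative_profile",
    "nadph_response",
    "choose_alpha",
    "run_stop_and_respond",
    "nbdg_signal_correction",
    "StopAndRespondResult",
]

LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# reporter production rate
# ---------------------------------------------------------------------------

def production_rate(abundance, times, t_half, correct_maturation=True):
    """Reporter production rate from an abundance series.

    With maturation correction the rate is ``(t_half/ln2) A'' + A'``; without
    it simply ``A'``.  Negative values are permitted (noise propagated by the
    double differentiation).
    """
    if t_half <= 0:
        raise ValueError("t_half must be positive")
    a1 = derivatives(abundance, times=times, order=1, method="spline")
    if not correct_maturation:
        return a1
    a2 = derivatives(abundance, times=times, order=2, method="spline")
    return (t_half / LN2) * a2 + a1


def cycle_production_rates(
    trace,
    events,
    t_half=6.0,
    volume_window=6,
    fluor_window=7,
    channel="GFP",
    context_min=50.0,
    correct_maturation=True,
):
    """Per-cycle production-rate traces for one cell (full reporter pipeline).

    For each complete cycle: assemble the cytokinesis-continuous volume with
    adjacent-cycle context, LOWESS-smooth volume and fluorescence, multiply
    them into the abundance, differentiate, and trim back to the core cycle.

    Returns a list of dicts with ``time``, ``rate``, ``in_cycle`` and
    ``cycle_events``.
    """
    vol_cycles = assemble_continuous_series(trace, events, "volume", context_min=context_min)
    F = trace.channels[channel]
    me = np.asarray(events["ME"], float)
    out = []
    for cyc in vol_cycles:
        t_ext = cyc["time"]
        sel = np.isin(trace.time_min, t_ext)
        f_ext = F[sel]
        v_s = lowess_smooth(cyc["values"], volume_window, times=t_ext).values
        f_s = lowess_smooth(f_ext, fluor_window, times=t_ext).values
        abundance = f_s * v_s
        rate = production_rate(abundance, t_ext, t_half, correct_maturation)
        ev = {"ME": cyc["me_start"], "next ME": cyc["me_end"]}
        for kind in ("START", "BUD"):
            inside = np.asarray(events.get(kind, []), float)
            inside = inside[(inside > cyc["me_start"]) & (inside <= cyc["me_end"])]
            if len(inside):
                ev[kind] = float(inside[0])
        out.append(
            {
                "time": t_ext[cyc["in_cycle"]],
                "rate": rate[cyc["in_cycle"]],
                "in_cycle": cyc["in_cycle"],
                "cycle_events": ev,
            }
        )
    return out


def minmax_phase_matrix(rate_cycles, mean_phases, n_phase=17):
    """Min-max-normalised per-cycle rate matrix on an even phase grid.

    Each cycle's rate trace is interpolated by a cubic spline and sampled at
    ``n_phase`` evenly spaced phases (via the event-anchored phase map), then
    scaled to [0, 1].  A degenerate cycle (max == min) yields a zero row.
    """
    import warnings as _warnings

    phases = np.linspace(0.0, 1.0, n_phase)
    rows = []
    for cyc in rate_cycles:
        ev = cyc["cycle_events"]
        if "START" not in ev or "BUD" not in ev:
            continue
        t_grid = np.array([phase_to_time(p, ev, mean_phases) for p in phases])
        spl = CubicSpline(cyc["time"], cyc["rate"])
        t_grid = np.clip(t_grid, cyc["time"][0], cyc["time"][-1])
        r = spl(t_grid)
        span = r.max() - r.min()
        if span == 0:
            _warnings.warn("degenerate cycle with constant rate; emitting zero row", stacklevel=2)
            rows.append(np.zeros_like(r))
        else:
            rows.append((r - r.min()) / span)
    return phases, np.asarray(rows)


# ---------------------------------------------------------------------------
# stop-and-respond
# ---------------------------------------------------------------------------

@dataclass
class StopAndRespondResult:
    """Per-cell responses plus the population quantities entering them."""

    table: pd.DataFrame
    deltas: dict                 # mean event offsets: START, BUD, CC (min, ME = 0)
    alpha: int
    amplitude: float             # max N - min N over (0, CC]
    normal_profile: object = field(repr=False, default=None)  # callable N(phi_min)

    @property
    def kept(self) -> pd.DataFrame:
        return self.table[self.table.kept]


def select_steady_cycling_cells(annotations, t_switch):
    """Keep steadily cycling cells by their latest pre-switch inter-bud time.

    The duration between the two latest buddings before ``t_switch`` is
    collected across cells; cells within median +/- s.d. of that distribution
    form S1.  Also returns the population mean event offsets (minutes from
    ME): ``START``, ``BUD`` and the mean cycle duration ``CC``.
    """
    durations, info = {}, {}
    for ann in annotations:
        buds = np.asarray(ann.events.get("BUD", []), float)
        buds = buds[buds < t_switch]
        if len(buds) < 2:
            continue
        b1, b2 = buds[-2], buds[-1]
        durations[ann.cell_id] = b2 - b1
        info[ann.cell_id] = (b1, b2, ann)
    if not durations:
        raise ValueError("no cell has two buddings before t_switch")
    vals = np.array(list(durations.values()))
    med, sd = np.median(vals), vals.std(ddof=0)
    s1 = [cid for cid, d in durations.items() if med - sd <= d <= med + sd]

    d_start, d_bud = [], []
    for cid in s1:
        b1, b2, ann = info[cid]
        mes = np.asarray(ann.events.get("ME", []), float)
        starts = np.asarray(ann.events.get("START", []), float)
        mes = mes[(mes > b1) & (mes <= b2)]
        if len(mes) == 0:
            continue
        me = mes[0]
        st = starts[(starts > me) & (starts <= b2)]
        if len(st):
            d_start.append(st[0] - me)
        d_bud.append(b2 - me)
    deltas = {
        "ME": 0.0,
        "START": float(np.mean(d_start)),
        "BUD": float(np.mean(d_bud)),
        "CC": float(np.mean(vals[np.isin(list(durations.keys()), s1)]))
        if len(s1)
        else float(med),
    }
    return s1, deltas


def smoothed_derivative(trace, t_switch, channel="NADPH", window=7, polyorder=3):
    """Savitzky-Golay-smoothed trace derivative at interval midpoints.

    The trace is split at ``t_switch`` (first frame at or after the medium
    switch) and smoothed piecewise so the perturbation step is not blurred.
    """
    t = trace.time_min
    y = trace.channels[channel]
    brk = int(np.searchsorted(t, t_switch))
    smooth = savgol_smooth(y, window=window, polyorder=polyorder, break_index=brk).values
    mid, dy = derivatives(smooth, times=t, method="midpoint")
    return mid, dy


def perturbation_phase(ann, t_p, dt, deltas):
    """Cell-cycle position (minutes from ME-equivalent) at the perturbation.

    The elapsed times since the latest ME/START/BUD at ``t_p - dt/2`` are
    compared; the closest event anchors the cell, and its population mean
    offset converts the elapsed time into minutes from ME.  Cells whose
    anchoring event is abnormally delayed (position exceeding the next
    event's mean timing) are rejected.

    Returns ``(phi_min, event_kind, reason)``; ``phi_min`` is None when the
    cell is rejected and ``reason`` says why.
    """
    t_ref = t_p - 0.5 * dt
    thetas = {}
    for e in ("ME", "START", "BUD"):
        ev = np.asarray(ann.events.get(e, []), float)
        ev = ev[ev <= t_ref]
        if len(ev):
            thetas[e] = t_ref - ev[-1]
    if not thetas:
        return None, None, "no pre-perturbation events"
    e_c = min(thetas, key=thetas.get)
    phi = thetas[e_c] + deltas[e_c]
    if e_c == "ME" and phi > deltas["START"]:
        return None, e_c, "delayed: past mean START while anchored at ME"
    if e_c == "START" and phi > deltas["BUD"]:
        return None, e_c, "delayed: past mean BUD while anchored at START"
    if e_c == "BUD" and phi > deltas["CC"]:
        return None, e_c, "delayed: past mean cycle duration while anchored at BUD"
    return float(phi), e_c, ""


def edge_matched_evaluator(trace, t_switch, t_ref, channel="NADPH", window=7, polyorder=3):
    """Derivative evaluator mirroring the post-switch smoothing geometry.

    ``P_c`` is read from the first interval(s) of the piece that starts at
    the medium switch, so its smoothing transfer function is that of a
    window anchored at a piece edge.  Evaluating the reference (unperturbed)
    derivative with an interior sliding window would leave a systematic,
    phase-locked difference between ``P_c`` and ``N`` even without any
    perturbation.  This evaluator instead smooths, for each query time
    ``tau``, a window of frames positioned relative to ``tau`` exactly as
    the post-switch piece is positioned relative to the ``P_c`` read-out,
    so the two transfer functions cancel in the response difference.
    """
    t = trace.time_min
    y = trace.channels[channel]
    dt = t[1] - t[0]
    i_switch = int(np.searchsorted(t, t_switch))
    p_offset = t_ref - t[i_switch]  # position of the read-out within the piece

    def evaluate(tau):
        ib = int(round((tau - p_offset - t[0]) / dt))
        if ib < 0 or ib + window > len(t):
            return np.nan
        if t[ib + window - 1] >= t_switch:  # window would cross into perturbed data
            return np.nan
        seg_t = t[ib : ib + window]
        seg = savgol_smooth(y[ib : ib + window], window=window, polyorder=polyorder).values
        mid = seg_t[:-1] + dt / 2.0
        dy = np.diff(seg) / dt
        if not (mid[0] - dt / 2 <= tau <= mid[-1] + dt / 2):
            return np.nan
        return float(np.interp(tau, mid, dy))

    return evaluate


def normal_derivative_profile(deriv_map, annotations, deltas, t_switch):
    """Median unperturbed NAD(P)H derivative as a function of cycle position.

    For position ``phi`` (minutes from ME) the across-cell median of the
    smoothed derivative is taken at the matching offset from the
    *second-latest* pre-switch event of the branch's kind: offsets from ME on
    (0, START], from START on (START, BUD], from BUD on (BUD, CC].

    ``deriv_map`` maps cell_id -> either a precomputed midpoint derivative
    series ``(mid_times, values)`` (interpolated at the requested times) or
    a callable ``tau -> derivative`` (e.g. the edge-matched evaluator).

    Returns ``(N, amplitude)`` with ``N`` a vectorised callable and the
    amplitude ``max N - min N`` over (0, CC].
    """
    branches = [
        ("ME", 0.0, deltas["START"]),
        ("START", deltas["START"], deltas["BUD"]),
        ("BUD", deltas["BUD"], deltas["CC"]),
    ]

    def N(phi):
        phi_arr = np.atleast_1d(np.asarray(phi, float))
        out = np.full(phi_arr.shape, np.nan)
        for event, lo, hi in branches:
            sel = (phi_arr > lo) & (phi_arr <= hi)
            if event == "ME":
                sel |= phi_arr <= 0  # clamp degenerate non-positive positions
            if not sel.any():
                continue
            for j in np.nonzero(sel)[0]:
                samples = []
                for cid, deriv in deriv_map.items():
                    ev = np.asarray(annotations[cid].events.get(event, []), float)
                    ev = ev[ev < t_switch]
                    if len(ev) < 2:
                        continue
                    t_eval = ev[-2] + (phi_arr[j] - lo)
                    if callable(deriv):
                        val = deriv(t_eval)
                        if np.isfinite(val):
                            samples.append(val)
                    else:
                        mid, dy = deriv
                        if mid[0] <= t_eval <= mid[-1]:
                            samples.append(np.interp(t_eval, mid, dy))
                if samples:
                    out[j] = np.median(samples)
        return out if np.ndim(phi) else float(out[0])

    grid = np.linspace(1e-6, deltas["CC"], 400)
    vals = N(grid)
    vals = vals[np.isfinite(vals)]
    amplitude = float(vals.max() - vals.min()) if len(vals) else 0.0
    return N, amplitude


def nadph_response(P, N_phi, alpha, amplitude):
    """Normalised NAD(P)H response ``alpha (P - N(phi)) / amplitude``."""
    if amplitude <= 0:
        raise ValueError("degenerate normal profile (zero amplitude)")
    return alpha * (P - N_phi) / amplitude


def choose_alpha(traces, t_p, dt, channel="NADPH"):
    """-1 when the population-average level drops at the perturbation, else +1."""
    before, after = [], []
    for tr in traces:
        t = tr.time_min
        y = tr.channels[channel]
        i_p = int(np.searchsorted(t, t_p))
        if 0 < i_p < len(t):
            before.append(y[i_p - 1])
            after.append(y[i_p])
    return -1 if np.mean(after) < np.mean(before) else 1


def run_stop_and_respond(traces, annotations, t_switch, t_p, dt, channel="NADPH"):
    """End-to-end stop-and-respond analysis.

    Steps: select steadily cycling cells (S1) from pre-switch inter-bud
    times; smooth each NAD(P)H trace piecewise around the switch and take
    midpoint derivatives; read each cell's derivative just before the first
    severely perturbed frame (``P_c``); anchor the cell in the cycle
    (``phi_c``, with delay-based rejection yielding S2); build the median
    normal profile ``N``; and normalise responses by the amplitude of ``N``.
    """
    ann_map = {a.cell_id: a for a in annotations}
    trace_map = {t.cell_id: t for t in traces}
    s1, deltas = select_steady_cycling_cells(annotations, t_switch)

    deriv_map = {
        cid: smoothed_derivative(trace_map[cid], t_switch, channel=channel) for cid in s1
    }
    t_ref_eval = t_p - 0.5 * dt
    ref_map = {
        cid: edge_matched_evaluator(trace_map[cid], t_switch, t_ref_eval, channel=channel)
        for cid in s1
    }
    N, amplitude = normal_derivative_profile(ref_map, ann_map, deltas, t_switch)
    alpha = choose_alpha([trace_map[c] for c in s1], t_p, dt, channel=channel)

    rows = []
    for cid in s1:
        mid, dy = deriv_map[cid]
        t_ref = t_p - 0.5 * dt
        if not (mid[0] <= t_ref <= mid[-1]):
            rows.append((cid, np.nan, None, np.nan, np.nan, np.nan, False, "no derivative at t_p"))
            continue
        P = float(np.interp(t_ref, mid, dy))
        phi, e_c, reason = perturbation_phase(ann_map[cid], t_p, dt, deltas)
        if phi is None:
            rows.append((cid, np.nan, e_c, P, np.nan, np.nan, False, reason))
            continue
        n_val = N(phi)
        if not np.isfinite(n_val):
            rows.append((cid, phi, e_c, P, np.nan, np.nan, False, "normal profile undefined"))
            continue
        R = nadph_response(P, n_val, alpha, amplitude)
        rows.append((cid, phi, e_c, P, n_val, R, True, ""))

    table = pd.DataFrame(
        rows, columns=["cell_id", "phi_min", "E_c", "P_c", "N_phi", "R_c", "kept", "reason"]
    )
    table["phi_rel"] = table.phi_min / deltas["CC"]
    return StopAndRespondResult(
        table=table, deltas=deltas, alpha=alpha, amplitude=amplitude, normal_profile=N
    )


# ---------------------------------------------------------------------------
# glucose-analog uptake correction
# ---------------------------------------------------------------------------

def nbdg_signal_correction(cell_series, pre_switch1_frames, post_switch2_frame, batch_groups):
    """Autofluorescence-subtracted, batch-normalised uptake proxy per cell.

    ``cell_series`` maps cell_id -> fluorescence array; per cell the mean of
    the ``pre_switch1_frames`` indices (autofluorescence before the analog
    pulse) is subtracted from the value at ``post_switch2_frame`` (first
    frame after the pulse was washed out).  Cells are then normalised by the
    median corrected value of their acquisition batch (up to four adjacent
    stage positions imaged back to back), removing the washout-decay offset
    between batches while preserving within-batch ranking.
    """
    corrected = {}
    for cid, series in cell_series.items():
        series = np.asarray(series, float)
        auto = float(np.mean(series[list(pre_switch1_frames)]))
        corrected[cid] = float(series[post_switch2_frame] - auto)
    out = {}
    for batch in batch_groups:
        vals = np.array([corrected[cid] for cid in batch])
        med = np.median(vals)
        for cid, v in zip(batch, vals):
            out[cid] = v / med if med != 0 else np.nan
    return out
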