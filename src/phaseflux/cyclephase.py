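"""Cell-cycle event detection and time-to-phase mapping.

Four reference events delimit and subdivide the cycle: mitotic exit (ME,
nuclear entry of Whi5), START (Whi5 re-localisation to the cytoplasm), bud
emergence (BUD) and the next ME.  Karyokinesis is detected separately from
the rapid loss of mother-nucleus histone (Hta2) signal.  Absolute times are
converted to a phase in [0, 1] by piecewise-linear interpolation between
the population-average relative event timings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_fill_holes, label
from scipy.signal import argrelextrema
from skimage.filters import threshold_local

from .tracekit import derivatives, lowess_smooth

__all__ = [
    "CycleAnnotation",
    "NucleusSegmentation",
    "EVENT_ORDER",
    "detect_whi5_events",
    "segment_nucleus",
    "karyokinesis_time",
    "mean_event_phases",
    "time_to_phase",
]

EVENT_ORDER = ("ME", "START", "BUD", "next ME")


@dataclass
class CycleAnnotation:
    """Per-cell event lists plus optional population mean phases.

    ``events`` maps an event kind ("ME", "START", "BUD", "KARYO") to a
    sorted array of times in minutes.
    """

    cell_id: str = ""
    events: dict = field(default_factory=dict)

    def __post_init__(self):
        for k, v in self.events.items():
            v = np.asarray(v, dtype=float)
            if np.any(np.diff(v) <= 0):
                raise ValueError(f"{k} event list must be strictly increasing")
            self.events[k] = v

    def cycles(self):
        """Complete cycles as dicts of event times with ME=start, next ME=end.

        Only cycles containing all of START and BUD between consecutive MEs
        are returned.
        """
        me = self.events.get("ME", np.array([]))
        out = []
        for me_i, me_j in zip(me[:-1], me[1:]):
            cyc = {"ME": me_i, "next ME": me_j}
            complete = True
            for kind in ("START", "BUD"):
                inside = self.events.get(kind, np.array([]))
                inside = inside[(inside > me_i) & (inside <= me_j)]
                if len(inside) == 0:
                    complete = False
                    break
                cyc[kind] = inside[0]
            karyo = self.events.get("KARYO", np.array([]))
            karyo = karyo[(karyo > me_i) & (karyo <= me_j)]
            if len(karyo):
                cyc["KARYO"] = karyo[0]
            if complete and cyc["ME"] < cyc["START"] < cyc["BUD"] < cyc["next ME"]:
                out.append(cyc)
        return out


@dataclass
class NucleusSegmentation:
    """Mask of the segmented nucleus and summed member-pixel intensity."""

    mask: np.ndarray
    abundance: float

    @property
    def found(self) -> bool:
        return bool(self.mask.any())


# ---------------------------------------------------------------------------
# Whi5 event detection
# ---------------------------------------------------------------------------

def detect_whi5_events(sd_series, mean_series, dt, compare_halfwidth=None):
    """Candidate ME and START times from Whi5 pixel statistics.

    The ratio of the standard deviation to the mean of the mother-cell pixel
    intensities rises when Whi5 concentrates in the nucleus.  Local maxima of
    the ratio's midpoint derivative mark ME, local minima mark START; each
    event is assigned to the grid time point *before* the extremum.  The
    symmetric comparison window is 12 points for ``dt`` = 6 min and 24 for
    ``dt`` = 3 min, scaling as 72 min of context on each side otherwise.
    Ties are broken by the earliest time point.

    Returns dict with sorted arrays under "ME" and "START".
    """
    sd = np.asarray(sd_series, dtype=float)
    mu = np.asarray(mean_series, dtype=float)
    if compare_halfwidth is None:
        compare_halfwidth = {6.0: 12, 3.0: 24}.get(float(dt), max(2, int(round(72.0 / dt))))
    x = int(compare_halfwidth)
    n = len(sd)
    if n <= 2 * x + 1:
        raise ValueError("series too short for the comparison window")
    times = np.arange(n, dtype=float) * dt
    ratio = sd / mu
    mid_t, dratio = derivatives(ratio, times=times, method="midpoint")

    if np.allclose(dratio, dratio[0] if len(dratio) else 0.0):
        return {"ME": np.array([]), "START": np.array([])}

    def _extrema(arr, sign):
        a = sign * arr
        idx = argrelextrema(a, np.greater_equal, order=x)[0]
        # candidates too close to the boundary cannot be confirmed with a
        # full comparison window and are dropped
        idx = idx[(idx >= x) & (idx < len(a) - x)]
        keep = []
        for i in idx:
            lo, hi = max(0, i - x), min(len(a), i + x + 1)
            if not np.any(a[i] > a[lo:hi]):
                continue  # flat plateau, not a genuine extremum
            if keep and i - keep[-1] <= x and np.isclose(a[i], a[keep[-1]]):
                continue  # tie run: earliest time point wins
            keep.append(i)
        return np.array(keep, dtype=int)

    maxima = _extrema(dratio, +1)
    minima = _extrema(dratio, -1)

    # the derivative at midpoint i+0.5 involves points i and i+1; the time
    # point before the extremum is grid index i
    me_times = times[np.clip(maxima, 0, n - 1)]
    start_times = times[np.clip(minima, 0, n - 1)]
    return {"ME": np.sort(me_times), "START": np.sort(start_times)}


# ---------------------------------------------------------------------------
# nucleus segmentation and karyokinesis
# ---------------------------------------------------------------------------

def segment_nucleus(image, mother_mask, block_size=15, offset_percentile=30.0, min_size=25):
    """Segment the mother-cell nucleus by local mean thresholding.

    A pixel is selected when it exceeds the mean of its ``block_size`` x
    ``block_size`` neighbourhood plus the 30th percentile of the mother-mask
    pixel intensities.  Objects smaller than ``min_size`` pixels (orthogonal
    connectivity) are removed; of the survivors, the object containing the
    brightest pixel is kept and its enclosed holes are filled.  The returned
    abundance is the sum of intensities over the final mask.

    Returns a :class:`NucleusSegmentation`; ``found`` is False when no
    object survives (not an exception).
    """
    img = np.asarray(image, dtype=float)
    mask = np.asarray(mother_mask, dtype=bool)
    if not mask.any():
        raise ValueError("mother mask is empty")
    p_off = np.percentile(img[mask], offset_percentile)
    # skimage thresholds at local_mean - offset, so pass the negated offset
    thr = threshold_local(img, block_size=block_size, method="mean", offset=-p_off, mode="nearest")
    selected = (img > thr) & mask

    labels, n_obj = label(selected, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    empty = NucleusSegmentation(mask=np.zeros_like(mask), abundance=0.0)
    if n_obj == 0:
        return empty
    sizes = np.bincount(labels.ravel())
    keep_labels = [i for i in range(1, n_obj + 1) if sizes[i] >= min_size]
    if not keep_labels:
        return empty
    # object containing the brightest selected pixels
    best = max(keep_labels, key=lambda i: img[labels == i].max())
    obj = labels == best
    obj = binary_fill_holes(obj)
    return NucleusSegmentation(mask=obj, abundance=float(img[obj].sum()))


def karyokinesis_time(abundance_series, times=None, smoothing_window=6, dt=None):
    """Time of the steepest drop in mother-nucleus histone abundance.

    The abundance trace is LOWESS-smoothed and spline-differentiated; the
    grid time of the most negative derivative is returned, or None when the
    derivative is nowhere negative (no karyokinesis in the window).
    """
    y = np.asarray(abundance_series, dtype=float)
    if times is None:
        times = np.arange(len(y), dtype=float) * (dt if dt else 1.0)
    times = np.asarray(times, dtype=float)
    smooth = lowess_smooth(y, smoothing_window, times=times).values
    deriv = derivatives(smooth, times=times, method="spline", order=1)
    i = int(np.nanargmin(deriv))
    # require a genuine decrease, not numerical dust on a flat/rising trace
    tol = 1e-9 * (np.nanmax(np.abs(y)) / (times[1] - times[0]) + 1.0)
    if deriv[i] >= -tol:
        return None
    return float(times[i])


# ---------------------------------------------------------------------------
# phase machinery
# ---------------------------------------------------------------------------

def mean_event_phases(cycles):
    """Population-average relative event timings over complete cycles.

    For each cycle the relative timing of event ``e`` is
    ``(t_e - t_ME) / (t_nextME - t_ME)``; the returned value is the plain
    mean over cycles.  ME maps to 0 and next ME to 1 by construction.

    Parameters
    ----------
    cycles : iterable of dict
        Each with keys "ME", "START", "BUD", "next ME" (times in minutes).
    """
    cycles = list(cycles)
    if not cycles:
        raise ValueError("no cycles supplied")
    phases = {}
    for e in EVENT_ORDER:
        vals = []
        for cyc in cycles:
            span = cyc["next ME"] - cyc["ME"]
            if span <= 0:
                raise ValueError("cycle with non-positive duration")
            vals.append((cyc[e] - cyc["ME"]) / span)
        phases[e] = float(np.mean(vals))
    phases["ME"] = 0.0
    phases["next ME"] = 1.0
    return phases


def time_to_phase(t, cycle_events, mean_phases):
    """Map an absolute time inside one cycle to phase in [0, 1].

    Piecewise-linear between consecutive reference events: within segment
    ``[E_i, E_{i+1}]`` the phase interpolates between the population mean
    phases of the two events.  ME itself maps to 0; the domain is the
    half-open interval ``(ME, next ME]`` plus ME.
    """
    t = float(t)
    ev_times = [cycle_events[e] for e in EVENT_ORDER]
    if not all(a < b for a, b in zip(ev_times[:-1], ev_times[1:])):
        raise ValueError("cycle events must be strictly ordered ME < START < BUD < next ME")
    if t < ev_times[0] or t > ev_times[-1]:
        raise ValueError("time outside the cycle")
    if t == ev_times[0]:
        return 0.0
    for e_lo, e_hi in zip(EVENT_ORDER[:-1], EVENT_ORDER[1:]):
        t_lo, t_hi = cycle_events[e_lo], cycle_events[e_hi]
        if t_lo < t <= t_hi:
            p_lo, p_hi = mean_phases[e_lo], mean_phases[e_hi]
            return p_lo + (p_hi - p_lo) * (t - t_lo) / (t_hi - t_lo)
    raise AssertionError("unreachable")


def phase_to_time(phase, cycle_events, mean_phases):
    """Inverse of :func:`time_to_phase` within one cycle."""
    phase = float(phase)
    if phase < 0 or phase > 1:
        raise ValueError("phase outside [0, 1]")
    if phase == 0.0:
        return float(cycle_events["ME"])
    for e_lo, e_hi in zip(EVENT_ORDER[:-1], EVENT_ORDER[1:]):
        p_lo, p_hi = mean_phases[e_lo], mean_phases[e_hi]
        if p_lo < phase <= p_hi:
            t_lo, t_hi = cycle_events[e_lo], cycle_events[e_hi]
            return t_lo + (t_hi - t_lo) * (phase - p_lo) / (p_hi - p_lo)
    raise AssertionError("unreachable")
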