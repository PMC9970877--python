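"""Trace geometry, smoothing, derivative estimation and imaging corrections.

Single-cell time-lapse traces of budding yeast consist of fluorescence
channels plus mother/bud ellipse radii sampled on a regular grid (step
``dt`` minutes).  Every downstream inference stage (production rates,
stop-and-respond statistics, mass-model fitting) consumes the smoothed,
cytokinesis-continuous series produced here.

Conventions
-----------
* Cells are treated as prolate spheroids: volume ``(4/3)*pi*R*r**2`` (fl for
  radii in um) and surface ``2*pi*r**2*(1 + (R/(r*e))*arcsin(e))`` with
  eccentricity ``e = sqrt(1 - r**2/R**2)``.
* A cell cycle is the half-open interval ``(ME_i, ME_{i+1}]`` between two
  mitotic exits.  Total volume is mother plus bud; the bud leaves at
  cytokinesis, producing a discontinuity that is removed by geometric
  translation of adjacent-cycle context before smoothing.
* Missing values are propagated as NaN, never zero-filled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import median_filter
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = [
    "SingleCellTrace",
    "SmoothedSeries",
    "spheroid_geometry",
    "assemble_continuous_series",
    "lowess_smooth",
    "savgol_smooth",
    "derivatives",
    "detrend_by_lowess",
    "flatfield_correct",
]

CAMERA_BASELINE = 500.0  # fixed camera offset counts subtracted before corrections


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SingleCellTrace:
    """One cell's time series on a regular grid.

    Parameters
    ----------
    cell_id : str
    time_min : ndarray
        Strictly increasing, constant step ``dt``.
    channels : dict of str -> ndarray
        Background-corrected mean fluorescence over mother-cell pixels.
    mother_R, mother_r : ndarray
        Major/minor ellipse radii of the mother compartment (um).
    bud_R, bud_r : ndarray
        Bud radii; NaN before budding and on unmeasurable early-bud frames.
    """

    cell_id: str
    time_min: np.ndarray
    channels: dict = field(default_factory=dict)
    mother_R: np.ndarray | None = None
    mother_r: np.ndarray | None = None
    bud_R: np.ndarray | None = None
    bud_r: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.time_min, dtype=float)
        if t.ndim != 1 or len(t) < 2:
            raise ValueError("time_min must be a 1-D grid with >= 2 points")
        steps = np.diff(t)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
            raise ValueError("time grid must be strictly increasing with constant step")
        self.time_min = t

    @property
    def dt(self) -> float:
        return float(self.time_min[1] - self.time_min[0])

    def _geom(self, R, r):
        out_v = np.full(len(self.time_min), np.nan)
        out_s = np.full(len(self.time_min), np.nan)
        ok = np.isfinite(R) & np.isfinite(r)
        if ok.any():
            v, s = spheroid_geometry(np.asarray(R)[ok], np.asarray(r)[ok])
            out_v[ok], out_s[ok] = v, s
        return out_v, out_s

    @property
    def mother_volume(self) -> np.ndarray:
        return self._geom(self.mother_R, self.mother_r)[0]

    @property
    def mother_surface(self) -> np.ndarray:
        return self._geom(self.mother_R, self.mother_r)[1]

    @property
    def bud_volume(self) -> np.ndarray:
        """Bud volume; NaN where the bud is absent or unmeasurable."""
        if self.bud_R is None:
            return np.full(len(self.time_min), np.nan)
        return self._geom(self.bud_R, self.bud_r)[0]

    @property
    def bud_surface(self) -> np.ndarray:
        if self.bud_R is None:
            return np.full(len(self.time_min), np.nan)
        return self._geom(self.bud_R, self.bud_r)[1]


@dataclass
class SmoothedSeries:
    """Smoothing result with provenance (method tag, context used)."""

    values: np.ndarray
    method: str
    extension_used: float = 0.0


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def spheroid_geometry(R, r):
    """Volume (fl) and surface area (um^2) of a prolate spheroid.

    ``R`` is the major and ``r`` the minor radius in um.  Inputs with
    ``r > R`` are swapped with a warning, since ellipse fitters do not
    guarantee the ordering.  At ``R == r`` the sphere limit is returned
    (the surface formula's ``arcsin(e)/e`` factor tends to 1).
    """
    R = np.asarray(R, dtype=float)
    r = np.asarray(r, dtype=float)
    scalar = R.ndim == 0 and r.ndim == 0
    R, r = np.atleast_1d(R), np.atleast_1d(r)
    R, r = np.broadcast_arrays(R, r)
    R, r = R.copy(), r.copy()
    if np.any(R <= 0) or np.any(r <= 0):
        raise ValueError("radii must be positive")
    swapped = r > R
    if swapped.any():
        warnings.warn("minor radius exceeded major radius; swapping", stacklevel=2)
        R[swapped], r[swapped] = r[swapped].copy(), R[swapped].copy()

    volume = (4.0 / 3.0) * np.pi * R * r**2
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.sqrt(np.clip(1.0 - r**2 / R**2, 0.0, 1.0))
        factor = np.where(e > 1e-12, (R / r) * np.arcsin(e) / np.where(e > 1e-12, e, 1.0), 1.0)
    surface = 2.0 * np.pi * r**2 * (1.0 + factor)
    if scalar:
        return float(volume[0]), float(surface[0])
    return volume, surface


# ---------------------------------------------------------------------------
# cycle assembly
# ---------------------------------------------------------------------------

def _interp_early_bud(time, bud, t_bud):
    """Fill NaN bud values between budding and the first measurement.

    The bud is unmeasurable for a few frames after emergence; its volume (or
    surface) is reconstructed by linear interpolation between zero at the
    budding time and the first measured value.
    """
    bud = bud.copy()
    after = time > t_bud
    measured = after & np.isfinite(bud)
    if not measured.any():
        bud[after] = 0.0
        return bud
    i_first = np.nonzero(measured)[0][0]
    t_first, v_first = time[i_first], bud[i_first]
    fill = after & (time < t_first) & ~np.isfinite(bud)
    bud[fill] = v_first * (time[fill] - t_bud) / (t_first - t_bud)
    return bud


def assemble_continuous_series(trace, events, quantity="volume", context_min=50.0):
    """Build per-cycle series extended by translated adjacent-cycle context.

    For each complete cycle ``(ME_i, ME_{i+1}]`` the preceding ``context_min``
    minutes are shifted down by the bud volume at ``ME_i`` and the following
    context up by the bud volume at ``ME_{i+1}``, abolishing the cytokinesis
    discontinuities.  Early-bud NaN frames are linearly interpolated from zero
    at budding.

    Parameters
    ----------
    trace : SingleCellTrace
    events : mapping with keys "ME" and "BUD" -> sorted event times (min)
    quantity : {"volume", "surface"}
    context_min : float
        Adjacent-cycle context, minutes (default 50).

    Returns
    -------
    list of dict with keys ``time``, ``values``, ``me_start``, ``me_end``,
    ``in_cycle`` (boolean mask of the core interval), ``extension_used``.
    """
    if quantity not in ("volume", "surface"):
        raise ValueError("quantity must be 'volume' or 'surface'")
    me = np.asarray(events["ME"], dtype=float)
    buds = np.asarray(events.get("BUD", []), dtype=float)
    if len(me) < 2:
        raise ValueError("need at least two mitotic exits to delimit a cycle")

    time = trace.time_min
    mother = trace.mother_volume if quantity == "volume" else trace.mother_surface
    bud_raw = trace.bud_volume if quantity == "volume" else trace.bud_surface

    # reconstruct the bud series cycle by cycle (zero before each budding)
    bud = np.where(np.isfinite(bud_raw), bud_raw, np.nan)
    filled = np.zeros_like(bud)
    boundaries = np.concatenate([[time[0] - trace.dt], me, [time[-1] + trace.dt]])
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        seg = (time > lo) & (time <= hi)
        if not seg.any():
            continue
        t_bud_candidates = buds[(buds > lo) & (buds <= hi)]
        seg_bud = np.full(seg.sum(), 0.0)
        if len(t_bud_candidates):
            t_bud = t_bud_candidates[0]
            seg_bud = _interp_early_bud(time[seg], bud[seg], t_bud)
            seg_bud[time[seg] <= t_bud] = 0.0
        filled[seg] = seg_bud
    total = mother + filled

    def bud_at(t):
        # bud volume while still attached: last frame at or before t
        idx = np.searchsorted(time, t, side="right") - 1
        return filled[max(idx, 0)]

    out = []
    for me_i, me_j in zip(me[:-1], me[1:]):
        core = (time > me_i) & (time <= me_j)
        if not core.any():
            raise ValueError(f"no data in cycle ({me_i}, {me_j}]")
        pre = (time > me_i - context_min) & (time <= me_i)
        post = (time > me_j) & (time <= me_j + context_min)
        if not pre.any() or not post.any():
            warnings.warn(
                "adjacent-cycle context missing; proceeding unextended on that side",
                stacklevel=2,
            )
        sel = pre | core | post
        vals = total[sel].copy()
        t_sel = time[sel]
        vals[t_sel <= me_i] -= bud_at(me_i)
        vals[t_sel > me_j] += bud_at(me_j)
        out.append(
            {
                "time": t_sel,
                "values": vals,
                "me_start": me_i,
                "me_end": me_j,
                "in_cycle": (t_sel > me_i) & (t_sel <= me_j),
                "extension_used": context_min,
            }
        )
    return out


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def lowess_smooth(series, window_pts, times=None):
    """Locally weighted linear regression (tricube weights, one pass).

    ``window_pts`` is the number of neighbouring points entering each local
    line fit; it is converted internally to the fraction statsmodels expects.
    Exact on straight lines for any window.
    """
    y = np.asarray(series, dtype=float)
    ok = np.isfinite(y)
    if not ok.any():
        raise ValueError("all-missing series")
    n = int(ok.sum())
    window_pts = int(window_pts)
    if window_pts < 3:
        raise ValueError("window_pts must be >= 3")
    window_pts = min(window_pts, n)
    x = np.arange(len(y), dtype=float) if times is None else np.asarray(times, dtype=float)
    frac = window_pts / n
    fitted = _sm_lowess(y[ok], x[ok], frac=frac, it=0, return_sorted=False)
    out = np.full_like(y, np.nan)
    out[ok] = fitted
    return SmoothedSeries(values=out, method=f"lowess(w={window_pts})")


def savgol_smooth(series, window=7, polyorder=3, edge_mode="interp", break_index=None):
    """Savitzky-Golay polynomial smoothing, optionally split at a discontinuity.

    With ``break_index`` the series is smoothed piecewise on
    ``[:break_index]`` and ``[break_index:]`` and re-merged, so that a genuine
    step (e.g. at a medium switch) is not blurred across the boundary.

    The default edge handling fits the edge window's polynomial directly
    (``mode="interp"``, exact for cubics): nearest-value padding biases the
    first-interval derivative by about a third of the local slope, which
    matters because the stop-and-respond statistic reads the derivative in
    the first interval after the split.  Pass ``edge_mode="nearest"`` for
    padded behaviour.
    """
    y = np.asarray(series, dtype=float)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and exceed polyorder")

    def _one(seg):
        if len(seg) == 0:
            return seg
        w = min(window, len(seg) if len(seg) % 2 else len(seg) - 1)
        if w <= polyorder:
            return seg.copy()
        return savgol_filter(seg, w, polyorder, mode=edge_mode)

    if break_index is None:
        out = _one(y)
    else:
        out = np.concatenate([_one(y[:break_index]), _one(y[break_index:])])
    return SmoothedSeries(values=out, method=f"savgol({window},{polyorder})")


# ---------------------------------------------------------------------------
# derivatives
# ---------------------------------------------------------------------------

def derivatives(series, times=None, order=1, method="spline", dt=None):
    """Differentiate a sampled series.

    method="spline"
        Natural cubic interpolating spline differentiated analytically and
        evaluated on the original grid.  Returns an array aligned with the
        input grid.
    method="midpoint"
        Finite difference ``(x[i+1]-x[i])/dt`` assigned to the interval
        midpoints; returns ``(mid_times, values)``.
    """
    y = np.asarray(series, dtype=float)
    if times is None:
        if dt is None:
            dt = 1.0
        times = np.arange(len(y), dtype=float) * dt
    else:
        times = np.asarray(times, dtype=float)
        dt = times[1] - times[0]
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")

    if method == "midpoint":
        if order != 1:
            raise ValueError("midpoint method supports order=1 only")
        mid = times[:-1] + np.diff(times) / 2.0
        return mid, np.diff(y) / np.diff(times)
    if method != "spline":
        raise ValueError("method must be 'spline' or 'midpoint'")
    ok = np.isfinite(y)
    spl = CubicSpline(times[ok], y[ok], bc_type="natural")
    return spl(times, nu=order)


# ---------------------------------------------------------------------------
# detrending
# ---------------------------------------------------------------------------

def detrend_by_lowess(series, window_large, window_small, times=None):
    """Divide a trace by its slow LOWESS trend; then smooth the ratio.

    Used on NAD(P)H autofluorescence: the detrended series fluctuates around
    one, exposing the cell-cycle oscillation free of slow drift.

    Returns ``(detrended, smoothed_detrended)`` as :class:`SmoothedSeries`.
    """
    y = np.asarray(series, dtype=float)
    trend = lowess_smooth(y, window_large, times=times).values
    if np.nanmin(trend) <= 0:
        raise ValueError("LOWESS trend is non-positive; cannot divide")
    detrended = y / trend
    smoothed = lowess_smooth(detrended, window_small, times=times)
    return (
        SmoothedSeries(values=detrended, method=f"detrend(lowess w={window_large})"),
        smoothed,
    )


# ---------------------------------------------------------------------------
# flat-field correction
# ---------------------------------------------------------------------------

def _gauss2d(coords, amp, x0, y0, sx, sy, off):
    x, y = coords
    return (amp * np.exp(-((x - x0) ** 2 / (2 * sx**2) + (y - y0) ** 2 / (2 * sy**2))) + off).ravel()


def flatfield_correct(stack, target_frame, baseline=CAMERA_BASELINE):
    """Correct uneven illumination learned from a frame stack.

    The per-pixel median over the stack (structure-free illumination field)
    is baseline-subtracted and fitted with a 2-D Gaussian ``G``; the target
    frame is corrected as ``(frame - baseline) * max(G) / G``.  If the fit
    diverges, the correction falls back to dividing by the median field
    normalised to its maximum.
    """
    stack = np.asarray(stack, dtype=float)
    frame = np.asarray(target_frame, dtype=float)
    med = np.median(stack, axis=0) - baseline
    ny, nx = med.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    p0 = (float(med.max()), nx / 2, ny / 2, nx, ny, 0.0)
    try:
        popt, _ = curve_fit(_gauss2d, (xx, yy), med.ravel(), p0=p0, maxfev=5000)
        if popt[0] <= 0 or not np.all(np.isfinite(popt)):
            raise RuntimeError("degenerate Gaussian fit")
        field = _gauss2d((xx, yy), *popt).reshape(ny, nx)
    except (RuntimeError, ValueError):
        warnings.warn("2-D Gaussian fit diverged; using median-normalisation fallback", stacklevel=2)
        field = median_filter(med, size=5)
        field = np.where(field > 0, field, np.nan)
        field = np.where(np.isfinite(field), field, np.nanmax(field))
    return (frame - baseline) * field.max() / field
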