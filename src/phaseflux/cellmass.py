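"""Algebraic cell-mass model: dimensionless activities to absolute rates.

The model describes the growth of total cell mass over one cell cycle
``t in (ME, next ME]`` as the sum of five macromolecule pools (protein,
lipid, polysaccharide, RNA, DNA), the water bound in their hydration
shells, and free water plus metabolites scaling with cell volume:

    estimate(t) = sum_j (1 + h_j) M_j(t) + w V(t),
    M_j(t)      = M_j(ME) + integral_0^t r_j dtau          (trapezoid),
    empirical(t)= V(t) rho(t),

and the fit minimises ``sum_t (estimate - empirical)^2``.

Rate assumptions:

* protein / lipid / polysaccharide: ``r_j = k_j (a_j + b_j)`` with the
  measured dimensionless activity ``a_j``, a conversion factor ``k_j``
  (pg min^-1 per activity unit) and a vertical translation ``b_j`` bounded
  by the activity's uncertainty;
* DNA: constant rate on (BUD, KARYO], zero elsewhere;
* RNA = rRNA + non-rRNA; non-rRNA constant; rRNA proportional to the
  protein rate from ``lead`` minutes before mitotic exit through budding
  (wrapping across ME) and constant on the remainder of the cycle;
* initial masses follow from cycle periodicity: the newborn keeps fraction
  ``f_j`` of the division mass (mother volume fraction for protein/RNA,
  mother surface fraction for lipid/polysaccharide, one genome copy for
  DNA), so ``M_j(ME) = f_j I_j / (1 - f_j)`` with ``I_j`` the rate integral
  over the cycle.

Given the translations ``b_j`` and hydration fractions ``h_j``, the mass
estimate is *linear* in the remaining parameters, so the fit splits into a
bounded linear least-squares core and a small bounded outer search — a
robust replacement for a monolithic global solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear, minimize
from scipy.stats import chi2

__all__ = [
    "MassModelConfig",
    "MassModelFit",
    "component_rates",
    "mass_trajectories",
    "empirical_mass",
    "fit_mass_model",
    "profile_likelihood",
    "contributions",
]

COMPONENTS = ("protein", "lipid", "polysaccharide", "RNA", "DNA")
LINEAR_PARAMS = ("k_protein", "k_lipid", "k_polysaccharide", "kappa_rRNA", "c_rRNA", "c_nonrRNA", "r_DNA", "w")


@dataclass
class MassModelConfig:
    """Tunable structure of the cell-mass model.

    All literature-derived quantities (split fractions, hydration, the rRNA
    lead time, composition windows) are configuration, not constants.
    Hydration defaults are a fixed 0.3 g water per g macromolecule; widen
    the bounds to let the fit move them.
    """

    f_volume: float = 0.55        # mother volume fraction at division (protein, RNA)
    f_surface: float = 0.60       # mother surface fraction at division (lipid, polysacch)
    f_dna: float = 0.5            # mother keeps one genome copy
    rrna_lead_min: float = 15.0   # protein-coupled rRNA window starts this long before ME
    b_bounds: tuple = (-0.05, 0.05)
    hydration: dict = field(
        default_factory=lambda: {j: (0.3, 0.3) for j in COMPONENTS}
    )
    # cycle-average dry-mass fraction windows (literature-derived).  These are
    # not cosmetic: the measured one-peak activities (lipid, polysaccharide)
    # overlap the protein activity's S/G2/M wave, so without composition
    # constraints the conversion factors are structurally non-identifiable.
    composition_windows: dict = field(
        default_factory=lambda: {
            "protein": (0.42, 0.52),
            "lipid": (0.06, 0.10),
            "polysaccharide": (0.26, 0.34),
            "RNA": (0.08, 0.14),
            "DNA": (0.002, 0.02),
        }
    )
    n_starts: int = 20
    redundant_scale: bool = False  # diagnostic: duplicate the protein column
    # (degenerate with k_protein) to exercise non-identifiability detection


@dataclass
class MassModelFit:
    """Fitted parameters, trajectories and fit diagnostics."""

    params: dict
    rates: dict
    masses: dict
    estimate: np.ndarray
    empirical: np.ndarray
    times: np.ndarray
    objective: float
    clipped: bool
    config: MassModelConfig
    activities: dict = field(repr=False, default_factory=dict)
    volume: np.ndarray = field(repr=False, default=None)
    events: dict = field(default_factory=dict)
    binding_constraints: list = field(default_factory=list)
    ensemble: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# model pieces
# ---------------------------------------------------------------------------

def _windows(times, events, lead):
    """Boolean masks for the piecewise rate rules (half-open intervals)."""
    t = np.asarray(times, float)
    T = events["next ME"] - events["ME"]
    rel = t - events["ME"]
    bud = events["BUD"] - events["ME"]
    karyo = events["KARYO"] - events["ME"]
    dna = (rel > bud) & (rel <= karyo)
    coupled = (rel <= bud) | (rel > T - lead)
    return dna, coupled


def _cumtrapz(y, t):
    out = np.concatenate([[0.0], np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(t))])
    return out


def component_rates(params, activities, events, times, lead=15.0):
    """Evaluate the five component rates (pg min^-1) on the grid.

    ``params`` holds k_j/b_j for the activity-driven components, the rRNA
    coupling ``gamma`` (rRNA = gamma * protein rate on the coupled window)
    with constant level ``c_rRNA`` elsewhere, the constant non-rRNA rate and
    the constant DNA rate.  Rates are clipped to >= 0; the returned flag
    reports whether clipping was active.
    """
    t = np.asarray(times, float)
    dna_mask, coupled = _windows(t, events, lead)
    raw = {}
    raw["protein"] = params["k_protein"] * (activities["protein"] + params["b_protein"])
    raw["lipid"] = params["k_lipid"] * (activities["lipid"] + params["b_lipid"])
    raw["polysaccharide"] = params["k_polysaccharide"] * (
        activities["polysaccharide"] + params["b_polysaccharide"]
    )
    r_rrna = np.where(
        coupled,
        params.get("gamma", 0.0) * raw["protein"],
        params.get("c_rRNA", 0.0),
    )
    raw["RNA"] = r_rrna + params.get("c_nonrRNA", 0.0)
    raw["DNA"] = np.where(dna_mask, params.get("r_DNA", 0.0), 0.0)

    clipped = any(np.any(v < -1e-12) for v in raw.values())
    rates = {j: np.clip(v, 0.0, None) for j, v in raw.items()}
    return rates, clipped


def mass_trajectories(rates, times, split_fractions, hydration, volume, w):
    """Integrate rates into masses and form the total mass estimate.

    Initial masses follow the periodicity closure
    ``M_j(ME) = f_j I_j / (1 - f_j)``.
    """
    t = np.asarray(times, float)
    masses = {}
    for j, r in rates.items():
        I = _cumtrapz(r, t)
        f = split_fractions[j]
        m0 = f * I[-1] / (1.0 - f) if f < 1.0 else 0.0
        masses[j] = m0 + I
    estimate = sum((1.0 + hydration[j]) * masses[j] for j in masses) + w * np.asarray(volume, float)
    return masses, estimate


def empirical_mass(volume, density):
    """Pointwise product of volume (fl) and density (pg/fl) -> mass (pg)."""
    return np.asarray(volume, float) * np.asarray(density, float)


def contributions(rates):
    """Total biomass rate and relative contributions c_j = r_j / r_biomass.

    Where the total rate vanishes the contributions are NaN and flagged.
    """
    r_total = sum(rates.values())
    out = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for j, r in rates.items():
            out[j] = np.where(r_total > 0, r / np.where(r_total > 0, r_total, 1.0), np.nan)
    return r_total, out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _split_fractions(cfg):
    return {
        "protein": cfg.f_volume,
        "RNA": cfg.f_volume,
        "lipid": cfg.f_surface,
        "polysaccharide": cfg.f_surface,
        "DNA": cfg.f_dna,
    }


def _design_matrix(b, h, activities, volume, events, times, cfg):
    """Columns of the estimate's linear expansion for fixed (b, h)."""
    t = np.asarray(times, float)
    dna_mask, coupled = _windows(t, events, cfg.rrna_lead_min)
    fr = _split_fractions(cfg)

    def pool_column(series, f):
        I = _cumtrapz(series, t)
        return f * I[-1] / (1.0 - f) + I

    a_p = activities["protein"] + b[0]
    a_l = activities["lipid"] + b[1]
    a_s = activities["polysaccharide"] + b[2]

    cols = {
        "k_protein": (1 + h["protein"]) * pool_column(a_p, fr["protein"]),
        "k_lipid": (1 + h["lipid"]) * pool_column(a_l, fr["lipid"]),
        "k_polysaccharide": (1 + h["polysaccharide"]) * pool_column(a_s, fr["polysaccharide"]),
        "kappa_rRNA": (1 + h["RNA"]) * pool_column(np.where(coupled, a_p, 0.0), fr["RNA"]),
        "c_rRNA": (1 + h["RNA"]) * pool_column(np.where(coupled, 0.0, 1.0), fr["RNA"]),
        "c_nonrRNA": (1 + h["RNA"]) * pool_column(np.ones_like(t), fr["RNA"]),
        "r_DNA": (1 + h["DNA"]) * pool_column(dna_mask.astype(float), fr["DNA"]),
        "w": np.asarray(volume, float),
    }
    if cfg.redundant_scale:
        cols["redundant_scale"] = cols["k_protein"].copy()
    return cols


_PARAM_COMPONENT = {
    "k_protein": "protein",
    "redundant_scale": "protein",
    "k_lipid": "lipid",
    "k_polysaccharide": "polysaccharide",
    "kappa_rRNA": "RNA",
    "c_rRNA": "RNA",
    "c_nonrRNA": "RNA",
    "r_DNA": "DNA",
}


def _assemble_params(linear, b):
    params = {
        "k_protein": linear.get("k_protein", 0.0),
        "k_lipid": linear.get("k_lipid", 0.0),
        "k_polysaccharide": linear.get("k_polysaccharide", 0.0),
        "b_protein": b[0],
        "b_lipid": b[1],
        "b_polysaccharide": b[2],
        "c_rRNA": linear.get("c_rRNA", 0.0),
        "c_nonrRNA": linear.get("c_nonrRNA", 0.0),
        "r_DNA": linear.get("r_DNA", 0.0),
        "w": linear.get("w", 0.0),
    }
    kp = params["k_protein"] + linear.get("redundant_scale", 0.0)
    params["k_protein"] = kp
    params["gamma"] = linear.get("kappa_rRNA", 0.0) / kp if kp > 0 else 0.0
    return params


def _solve_linear(b, h, activities, volume, density, events, times, cfg, fixed=None):
    """Scale-parameter subproblem: non-negative least squares with linear
    cycle-average composition constraints, for fixed translations/hydration.

    The mean mass of component ``j`` and the mean dry mass are both linear in
    the scale parameters, so each composition window yields two linear
    inequalities; the constrained quadratic programme is solved with SLSQP
    warm-started from the unconstrained bounded solution.
    """
    cols = _design_matrix(b, h, activities, volume, events, times, cfg)
    target = empirical_mass(volume, density)
    names = [n for n in cols if not (fixed and n in fixed)]
    A = np.column_stack([cols[n] for n in names])
    rhs = target.copy()
    if fixed:
        for n, v in fixed.items():
            rhs = rhs - v * cols[n]

    res0 = lsq_linear(A, rhs, bounds=(0.0, np.inf))
    x0 = res0.x

    windows = cfg.composition_windows or {}
    if not windows:
        x = dict(zip(names, x0))
        if fixed:
            x.update(fixed)
        resid = A @ x0 - rhs
        return x, float(resid @ resid), []

    # per-parameter mean component-mass weights: mean_t(column)/(1+h_j)
    all_names = list(cols)
    mass_weight = {}
    for n in all_names:
        jc = _PARAM_COMPONENT.get(n)
        mass_weight[n] = 0.0 if jc is None else float(np.mean(cols[n])) / (1.0 + h[jc])
    comp_weight = {
        j: np.array(
            [mass_weight[n] if _PARAM_COMPONENT.get(n) == j else 0.0 for n in names]
        )
        for j in COMPONENTS
    }
    dry_weight = sum(comp_weight.values())
    offset = {j: 0.0 for j in COMPONENTS}
    dry_offset = 0.0
    if fixed:
        for n, v in fixed.items():
            jc = _PARAM_COMPONENT.get(n)
            if jc is not None:
                offset[jc] += mass_weight[n] * v
                dry_offset += mass_weight[n] * v

    G_rows, g_rhs, labels = [], [], []
    for j, (lo, hi) in windows.items():
        # mean M_j - hi * mean dry <= 0   and   lo * mean dry - mean M_j <= 0
        G_rows.append(comp_weight[j] - hi * dry_weight)
        g_rhs.append(-(offset[j] - hi * dry_offset))
        labels.append(f"{j} fraction <= {hi}")
        G_rows.append(lo * dry_weight - comp_weight[j])
        g_rhs.append(-(lo * dry_offset - offset[j]))
        labels.append(f"{j} fraction >= {lo}")
    G = np.vstack(G_rows)
    g_rhs = np.asarray(g_rhs)

    AtA = A.T @ A
    Atb = A.T @ rhs

    def f(x):
        r = A @ x - rhs
        return float(r @ r)

    def grad(x):
        return 2.0 * (AtA @ x - Atb)

    cons = [
        {"type": "ineq", "fun": lambda x, i=i: g_rhs[i] - G[i] @ x, "jac": lambda x, i=i: -G[i]}
        for i in range(len(g_rhs))
    ]
    res = minimize(
        f,
        np.clip(x0, 0.0, None),
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, None)] * len(names),
        constraints=cons,
        options={"maxiter": 300, "ftol": 1e-12},
    )
    xv = res.x
    binding = [labels[i] for i in range(len(g_rhs)) if g_rhs[i] - G[i] @ xv < 1e-8]
    x = dict(zip(names, xv))
    if fixed:
        x.update(fixed)
    return x, f(xv), binding


def fit_mass_model(activities, volume, density, events, config=None, seed=0, fixed=None):
    """Fit the cell-mass model by nested optimisation.

    Outer: multi-start bounded search over the vertical translations (and
    hydration fractions when their bounds are not degenerate).  Inner:
    non-negative linear least squares over the conversion factors, constant
    rates and water coefficient.  When replicate activity measurements are
    supplied (lists of arrays per component), the fit is repeated for every
    replicate combination plus the replicate-averaged input; the averaged
    fit is returned with the combination fits attached as ``ensemble``.

    Parameters
    ----------
    activities : dict
        "protein"/"lipid"/"polysaccharide" -> activity array on the grid,
        or list of replicate arrays.
    volume, density : arrays on the grid ``activities["times"]``.
    events : dict with ME, START, BUD, KARYO, next ME (minutes).
    fixed : dict, optional
        Pin named linear parameters (used by the profile likelihood).
    """
    cfg = config or MassModelConfig()
    times = np.asarray(activities["times"], float)

    reps = {j: activities[j] for j in ("protein", "lipid", "polysaccharide")}
    is_replicated = any(isinstance(v, (list, tuple)) for v in reps.values())
    if is_replicated:
        from itertools import product as _product

        lists = {j: (v if isinstance(v, (list, tuple)) else [v]) for j, v in reps.items()}
        combos = list(_product(*[range(len(lists[j])) for j in ("protein", "lipid", "polysaccharide")]))
        ensemble = []
        for combo in combos:
            acts = {
                "times": times,
                "protein": np.asarray(lists["protein"][combo[0]], float),
                "lipid": np.asarray(lists["lipid"][combo[1]], float),
                "polysaccharide": np.asarray(lists["polysaccharide"][combo[2]], float),
            }
            ensemble.append(fit_mass_model(acts, volume, density, events, cfg, seed=seed, fixed=fixed))
        avg = {
            "times": times,
            **{j: np.mean(np.asarray(lists[j], float), axis=0) for j in lists},
        }
        main = fit_mass_model(avg, volume, density, events, cfg, seed=seed, fixed=fixed)
        main.ensemble = ensemble
        return main

    acts = {j: np.asarray(reps[j], float) for j in reps}

    h_bounds = [cfg.hydration[j] for j in COMPONENTS]
    h_free = [i for i, (lo, hi) in enumerate(h_bounds) if hi > lo]
    b_lo, b_hi = cfg.b_bounds

    def unpack(theta):
        b = theta[:3]
        h = {j: lo for j, (lo, hi) in zip(COMPONENTS, h_bounds)}
        for slot, i in enumerate(h_free):
            h[COMPONENTS[i]] = theta[3 + slot]
        return b, h

    def outer_obj(theta):
        b, h = unpack(theta)
        _, obj, _ = _solve_linear(b, h, acts, volume, density, events, times, cfg, fixed=fixed)
        return obj

    rng = np.random.default_rng(seed)
    bounds = [(b_lo, b_hi)] * 3 + [h_bounds[i] for i in h_free]
    starts = [np.array([0.0] * 3 + [np.mean(h_bounds[i]) for i in h_free])]
    for _ in range(cfg.n_starts - 1):
        starts.append(np.array([rng.uniform(lo, hi) for lo, hi in bounds]))

    best = None
    for x0 in starts:
        res = minimize(outer_obj, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    b, h = unpack(best.x)
    linear, obj, binding = _solve_linear(b, h, acts, volume, density, events, times, cfg, fixed=fixed)
    params = _assemble_params(linear, b)
    params.update({f"h_{j}": h[j] for j in COMPONENTS})
    rates, clipped = component_rates(params, acts, events, times, cfg.rrna_lead_min)
    masses, estimate = mass_trajectories(
        rates, times, _split_fractions(cfg), h, volume, params["w"]
    )
    return MassModelFit(
        params=params,
        rates=rates,
        masses=masses,
        estimate=estimate,
        empirical=empirical_mass(volume, density),
        times=times,
        objective=obj,
        clipped=clipped,
        config=cfg,
        activities=acts,
        volume=np.asarray(volume, float),
        events=dict(events),
        binding_constraints=binding,
    )


def profile_likelihood(fit, param_name, grid, density=None, threshold=None):
    """Profile the least-squares objective over one parameter.

    For each grid value the parameter is pinned and all others re-optimised.
    The parameter is judged identifiable when the profile rises above
    ``objective_min + threshold`` on both sides of its minimum within the
    grid; the default threshold is the 95% chi-square(1) quantile scaled by
    the residual variance (objective / (n - p)).
    """
    cfg = fit.config
    times = fit.times
    vol = fit.volume
    dens = fit.empirical / vol if density is None else np.asarray(density, float)
    acts = {"times": times, **fit.activities}

    objs = []
    for val in grid:
        refit = fit_mass_model(
            acts, vol, dens, fit.events, cfg, fixed={param_name: float(val)}
        )
        objs.append(refit.objective)
    objs = np.asarray(objs)

    n = len(times)
    p = len(LINEAR_PARAMS) + 3
    if threshold is None:
        s2 = max(fit.objective / max(n - p, 1), 1e-12)
        threshold = s2 * chi2.ppf(0.95, 1)
    i_min = int(np.argmin(objs))
    crossed_left = np.any(objs[: i_min + 1] > objs.min() + threshold)
    crossed_right = np.any(objs[i_min:] > objs.min() + threshold)
    verdict = "identifiable" if (crossed_left and crossed_right) else "non-identifiable"
    return {
        "grid": np.asarray(grid, float),
        "objective": objs,
        "threshold": float(threshold),
        "verdict": verdict,
    }
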