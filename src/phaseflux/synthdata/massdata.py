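"""Self-consistent synthetic datasets for the cell-mass model.

A dataset consists of dimensionless activity traces, a volume trajectory, a
density trajectory (so that empirical mass = estimate + measurement noise),
the event times, the generating parameters, and a composition-window
configuration centred on the dataset's own cycle-average dry-mass fractions
— emulating a compositional measurement of stated precision, which is what
makes the conversion factors identifiable (the one-peak lipid and
polysaccharide activities overlap the protein activity's S/G2/M wave, so
without composition information the scale split between them is free).
"""

from __future__ import annotations

import numpy as np

from ..cellmass import (
    COMPONENTS,
    MassModelConfig,
    _split_fractions,
    component_rates,
    mass_trajectories,
)
from .waveforms import one_peak_waveform, two_peak_waveform

__all__ = ["simulate_mass_dataset"]

BASE_PARAMS = {
    "k_protein": 0.075,      # pg min^-1 per activity unit
    "k_lipid": 0.018,
    "k_polysaccharide": 0.065,
    "b_protein": 0.005,
    "b_lipid": -0.005,
    "b_polysaccharide": 0.0,
    "gamma": 0.12,           # rRNA coupling to the protein rate
    "c_rRNA": 0.008,         # pg min^-1, constant branch
    "c_nonrRNA": 0.003,
    "r_DNA": 0.0015,
    "w": 0.72,               # pg fl^-1 free water + metabolites
}


def simulate_mass_dataset(
    seed=0,
    dt=3.0,
    cycle_min=102.0,
    events=None,
    k_jitter=0.08,
    noise_pg=0.1,
    composition_rel_precision=0.02,
    b_bounds=(-0.01, 0.01),
    hydration=0.3,
):
    """One seeded self-consistent cell-mass dataset with known parameters.

    Conversion factors and the water coefficient are jittered around
    realistic yeast values (protein ~48%, polysaccharide ~30%, RNA ~11%,
    lipid ~8% of dry mass); the empirical mass is the model's own estimate
    plus ``noise_pg`` Gaussian noise.  The returned config's composition
    windows are the dataset's true mean fractions +/- the stated halfwidth.
    """
    rng = np.random.default_rng(seed)
    if events is None:
        events = {
            "ME": 0.0,
            "START": 11.0,
            "BUD": 33.0,
            "KARYO": cycle_min - 15.0,
            "next ME": cycle_min,
        }
    t = np.arange(0.0, cycle_min + dt / 2, dt)

    wf_p = two_peak_waveform()
    wf_l = one_peak_waveform(center=0.60)
    wf_s = one_peak_waveform(center=0.62, width=0.12)
    phases = t / cycle_min
    acts = {
        "times": t,
        "protein": wf_p(phases),
        "lipid": wf_l(phases),
        "polysaccharide": wf_s(phases),
    }

    params = dict(BASE_PARAMS)
    for k in ("k_protein", "k_lipid", "k_polysaccharide"):
        params[k] *= 1.0 + rng.uniform(-k_jitter, k_jitter)
    params["w"] *= 1.0 + rng.uniform(-0.03, 0.03)

    cfg = MassModelConfig(b_bounds=b_bounds, hydration={j: (hydration, hydration) for j in COMPONENTS})
    rates, _ = component_rates(params, acts, events, t, cfg.rrna_lead_min)

    wf_vol = one_peak_waveform(center=0.55, width=0.15, height=0.8, floor=0.6)
    gv = wf_vol(phases)
    V = 30.0 + np.concatenate([[0.0], np.cumsum(0.5 * (gv[1:] + gv[:-1]) * np.diff(t))]) * 0.39

    h = {j: hydration for j in COMPONENTS}
    masses, estimate = mass_trajectories(rates, t, _split_fractions(cfg), h, V, params["w"])
    dry = sum(masses.values())
    fractions = {j: float(np.mean(masses[j]) / np.mean(dry)) for j in COMPONENTS}
    cfg.composition_windows = {
        j: (f * (1.0 - composition_rel_precision), f * (1.0 + composition_rel_precision))
        for j, f in fractions.items()
    }

    empirical = estimate + rng.normal(0.0, noise_pg, len(t))
    return {
        "activities": acts,
        "volume": V,
        "density": empirical / V,
        "events": events,
        "config": cfg,
        "true_params": params,
        "true_rates": rates,
        "true_masses": masses,
        "true_estimate": estimate,
        "fractions": fractions,
    }
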