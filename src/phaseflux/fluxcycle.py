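"""Phase-resolved, dissipation-capped flux balance analysis.

The cell-cycle-dependent relative contributions of the biosynthetic
processes (from the cell-mass model) become the stoichiometric coefficients
of the corresponding components in the biomass reaction: at cycle moment
``t`` component ``j`` enters with coefficient ``c_j(t) / c_model_j`` (and
the storage coefficient is zero throughout, reflecting negligible reserve
carbohydrate production on high glucose).  At each of the default 17
moments ``T = {3, 9, ..., 99}`` min a quasi-steady-state LP maximises the
biomass flux subject to ``S v = 0``, reaction bounds and a cap on the
cellular Gibbs energy dissipation rate

    g(v) = - sum_{exchanged i} v_i * dfG'_i / M_biomass  <=  g_lim,

which is linear in the fluxes because the external conditions (and thus the
transformed formation energies of the exchanged species) are held fixed.
FBA fluxes (mmol (mmol biomass)^-1 h^-1) are converted to absolute
single-cell fluxes via the total biomass synthesis rate:

    v_cell = 1e-3 * (v / v_biomass) * (1 / M_biomass) * r_biomass  [pmol cell^-1 h^-1].

The shipped network is a deliberately small, synthetic, thermodynamically
annotated fixture (see ``data/toy_network.json``); its stoichiometries are
illustrative, not a published reconstruction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import linprog

__all__ = [
    "ThermoNetwork",
    "PhaseFluxSolution",
    "load_toy_network",
    "phase_biomass_coefficients",
    "solve_phase_fba",
    "solve_cycle",
    "convert_flux_units",
    "newborn_weighted_yield",
    "metabolite_turnover",
    "precursor_sink",
    "exchange_mass_closure",
    "DEFAULT_PHASES",
]

DEFAULT_PHASES = np.arange(3.0, 100.0, 6.0)  # 17 moments, min


@dataclass
class ThermoNetwork:
    """Reduced metabolic network with thermodynamic annotation.

    ``metabolites`` maps id -> {mass (g/mol), dfG (kJ/mol or None),
    exchanged (bool)}; ``reactions`` is a list of dicts with ``id``,
    ``stoich`` (metabolite -> coefficient), ``lb``, ``ub`` and ``kind``
    (internal / exchange / synthesis / biomass).
    """

    metabolites: dict
    reactions: list
    c_model: dict
    component_species: dict
    M_biomass: float
    g_lim: float
    name: str = ""

    @classmethod
    def from_json(cls, path_or_dict):
        d = path_or_dict
        if not isinstance(d, dict):
            with open(path_or_dict) as f:
                d = json.load(f)
        net = cls(
            metabolites=d["metabolites"],
            reactions=d["reactions"],
            c_model=d["c_model"],
            component_species=d["component_species"],
            M_biomass=float(d["M_biomass"]),
            g_lim=float(d["g_lim"]),
            name=d.get("name", ""),
        )
        net.validate()
        return net

    @property
    def reaction_ids(self):
        return [r["id"] for r in self.reactions]

    def reaction(self, rid):
        for r in self.reactions:
            if r["id"] == rid:
                return r
        raise KeyError(rid)

    def validate(self, tol=1e-6):
        """Check mass balance of every non-exchange, non-biomass reaction.

        The biomass assembly reaction is excluded because its product's
        molar mass is composition-dependent (it equals the coefficient-
        weighted component mass at each phase).
        """
        if self.g_lim <= 0:
            raise ValueError("g_lim must be positive")
        if sum(self.c_model.values()) > 1.0 + 1e-9:
            raise ValueError("model composition fractions exceed 1")
        for r in self.reactions:
            if r["kind"] in ("exchange", "biomass"):
                continue
            bal = sum(c * self.metabolites[mid]["mass"] for mid, c in r["stoich"].items())
            if abs(bal) > tol:
                raise ValueError(f"reaction {r['id']} violates mass balance by {bal:.3g}")

    def stoichiometric_matrix(self, biomass_coeffs=None):
        """Dense S (metabolites x reactions); biomass columns optionally rescaled.

        ``biomass_coeffs`` maps component name -> multiplier applied to that
        component's term in the biomass assembly reaction.
        """
        met_ids = list(self.metabolites)
        met_idx = {mid: i for i, mid in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(self.reactions)))
        comp_of_species = {v: k for k, v in self.component_species.items()}
        for j, r in enumerate(self.reactions):
            for mid, c in r["stoich"].items():
                coef = c
                if r["kind"] == "biomass" and biomass_coeffs and mid in comp_of_species:
                    coef = c * biomass_coeffs[comp_of_species[mid]]
                S[met_idx[mid], j] = coef
        return met_ids, S


def load_toy_network():
    """The packaged synthetic reduced network."""
    with resources.files("phaseflux").joinpath("data/toy_network.json").open() as f:
        return ThermoNetwork.from_json(json.load(f))


# ---------------------------------------------------------------------------
# phase-dependent biomass stoichiometry
# ---------------------------------------------------------------------------

def phase_biomass_coefficients(contrib, c_model, phases=None):
    """Per-phase biomass-reaction multipliers ``c_j(t) / c_model_j``.

    ``contrib`` maps component -> array of relative contributions over the
    phase moments (summing to 1 at each moment); storage is pinned to zero.
    Returns a list of dicts, one per phase.
    """
    names = [j for j in c_model if j != "storage"]
    n = len(next(iter(contrib.values())))
    if phases is not None and len(phases) != n:
        raise ValueError("phases and contributions length mismatch")
    out = []
    for i in range(n):
        coefs = {j: float(contrib[j][i]) / c_model[j] for j in names}
        coefs["storage"] = 0.0
        out.append(coefs)
    return out


# ---------------------------------------------------------------------------
# LP solve
# ---------------------------------------------------------------------------

@dataclass
class PhaseFluxSolution:
    """One phase's FBA solution."""

    t: float
    fluxes: pd.Series             # mmol (mmol biomass)^-1 h^-1
    v_biomass: float
    dissipation: float            # J gDW^-1 h^-1
    status: str
    biomass_coeffs: dict = field(default_factory=dict)
    network: ThermoNetwork = field(repr=False, default=None)
    fluxes_cell: pd.Series = None  # pmol cell^-1 h^-1, set by solve_cycle

    @property
    def ok(self):
        return self.status == "optimal"


def _dissipation_row(net):
    """Coefficients of the linear dissipation g(v) = row . v (J gDW^-1 h^-1)."""
    row = np.zeros(len(net.reactions))
    for j, r in enumerate(net.reactions):
        if r["kind"] != "exchange":
            continue
        for mid, c in r["stoich"].items():
            dfG = net.metabolites[mid].get("dfG")
            if dfG is None:
                continue
            # exchange written as "met ->": flux v means -v*c of met leaves the system
            row[j] += -c * dfG
    return -row / net.M_biomass  # g = -sum(v_export * dfG)/M


def solve_phase_fba(net, biomass_coeffs=None, g_lim=None, t=0.0):
    """Maximise biomass flux under S v = 0, bounds and the dissipation cap.

    ``biomass_coeffs`` rescales the component terms of the biomass assembly
    reaction (see :func:`phase_biomass_coefficients`); ``g_lim`` overrides
    the network's cap (pass ``np.inf`` for plain FBA).
    """
    g_lim = net.g_lim if g_lim is None else float(g_lim)
    met_ids, S = net.stoichiometric_matrix(biomass_coeffs)
    n = len(net.reactions)
    lb = np.array([r["lb"] for r in net.reactions], float)
    ub = np.array([r["ub"] for r in net.reactions], float)
    i_bio = net.reaction_ids.index("BIOMASS")
    c = np.zeros(n)
    c[i_bio] = -1.0

    g_row = _dissipation_row(net)
    A_ub, b_ub = None, None
    if np.isfinite(g_lim):
        A_ub = g_row.reshape(1, -1)
        b_ub = np.array([g_lim])

    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if res.status == 3:
        raise ValueError("LP unbounded: the network must bound uptake fluxes")
    status = "optimal" if res.status == 0 else f"infeasible ({res.message})"
    v = res.x if res.x is not None else np.full(n, np.nan)
    fluxes = pd.Series(v, index=net.reaction_ids)
    return PhaseFluxSolution(
        t=t,
        fluxes=fluxes,
        v_biomass=float(fluxes["BIOMASS"]) if res.status == 0 else np.nan,
        dissipation=float(g_row @ v) if res.status == 0 else np.nan,
        status=status,
        biomass_coeffs=dict(biomass_coeffs or {}),
        network=net,
    )


def convert_flux_units(v_fba, v_biomass_fba, M_biomass, r_biomass):
    """FBA flux units -> absolute pmol cell^-1 h^-1.

    ``v_cell = 1e-3 * (v_fba / v_biomass_fba) * (1 / M_biomass) * r_biomass``
    with ``r_biomass`` in pg cell^-1 h^-1 and ``M_biomass`` in g/mmol.  The
    biomass reaction's own absolute flux is identically
    ``r_biomass / (1000 * M_biomass)``.
    """
    if np.any(np.asarray(v_biomass_fba) <= 0):
        raise ValueError("biomass flux must be positive to convert units")
    return 1e-3 * (v_fba / v_biomass_fba) * (1.0 / M_biomass) * r_biomass


def solve_cycle(net, contrib, r_biomass, phases=DEFAULT_PHASES, g_lim=None):
    """Independent per-phase LPs over the cycle with absolute-unit conversion.

    ``contrib`` maps component -> contributions at ``phases``; ``r_biomass``
    is the total biomass synthesis rate at those phases (pg min^-1 per cell;
    converted internally to pg h^-1).
    """
    coeff_list = phase_biomass_coefficients(contrib, net.c_model, phases)
    r_biomass = np.asarray(r_biomass, float) * 60.0  # pg/min -> pg/h
    sols = []
    for t, coefs, r_b in zip(phases, coeff_list, r_biomass):
        sol = solve_phase_fba(net, coefs, g_lim=g_lim, t=float(t))
        if sol.ok and sol.v_biomass > 0:
            sol.fluxes_cell = convert_flux_units(
                sol.fluxes, sol.v_biomass, net.M_biomass, r_b
            )
        sols.append(sol)
    return sols


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def newborn_weighted_yield(solutions, met_exchange, glc_exchange="EX_glc", phase_weights=None):
    """Cycle-average mass yield of an exchanged metabolite w.r.t. glucose.

    ``Y = sum_t[v_met(t) M_met w(t)] / (-sum_t[v_glc(t) M_glc w(t)])`` with
    weights ``w(t)`` defaulting to the newborn correction: early-G1 moments
    (t in {3, 9} min) weighted by 79.75/11 (mean newborn early-G1 duration
    over the mature one), all other moments weighted 1.
    """
    if phase_weights is None:
        phase_weights = {3.0: 79.75 / 11.0, 9.0: 79.75 / 11.0}
    net = solutions[0].network

    def species_mass(rid):
        st = net.reaction(rid)["stoich"]
        (mid,) = st.keys()
        return net.metabolites[mid]["mass"]

    m_met, m_glc = species_mass(met_exchange), species_mass(glc_exchange)
    num = den = 0.0
    for sol in solutions:
        v = sol.fluxes_cell if sol.fluxes_cell is not None else sol.fluxes
        w = phase_weights.get(float(sol.t), 1.0)
        num += float(v[met_exchange]) * m_met * w
        den += -float(v[glc_exchange]) * m_glc * w
    if den <= 0:
        raise ValueError("no glucose uptake in the supplied solutions")
    return num / den


def metabolite_turnover(solution, met, threshold=None):
    """Production-side turnover of a metabolite plus per-reaction fluxes.

    Turnover is the sum of ``S_im * v_i`` over reactions producing ``met``
    (at steady state the consumer sum is its negative).  With ``threshold``
    the per-reaction table is restricted to |flux| above it.
    """
    net = solution.network
    v = solution.fluxes_cell if solution.fluxes_cell is not None else solution.fluxes
    per_rxn = {}
    for r in net.reactions:
        coef = r["stoich"].get(met, 0.0)
        if coef:
            per_rxn[r["id"]] = coef * float(v[r["id"]])
    turnover = sum(x for x in per_rxn.values() if x > 0)
    if threshold is not None:
        per_rxn = {k: x for k, x in per_rxn.items() if abs(x) > threshold}
    return turnover, per_rxn


def precursor_sink(solution, met, reaction_ids):
    """Summed flux of a precursor into a configured set of sink reactions."""
    net = solution.network
    v = solution.fluxes_cell if solution.fluxes_cell is not None else solution.fluxes
    return sum(net.reaction(rid)["stoich"].get(met, 0.0) * float(v[rid]) for rid in reaction_ids)


def exchange_mass_closure(solution):
    """Net mass crossing the boundary (g per flux unit); ~0 at steady state.

    The biomass drain uses the composition-dependent effective molar mass
    (coefficient-weighted component masses plus the assembly byproducts).
    """
    net = solution.network
    v = solution.fluxes
    total = 0.0
    for r in net.reactions:
        if r["kind"] != "exchange":
            continue
        (mid,) = r["stoich"].keys()
        mass = net.metabolites[mid]["mass"]
        if mid == "biomass" and solution.biomass_coeffs:
            bio = net.reaction("BIOMASS")
            comp_of_species = {s: j for j, s in net.component_species.items()}
            mass = 0.0
            for sp, c in bio["stoich"].items():
                if sp in comp_of_species:
                    mass += -c * solution.biomass_coeffs[comp_of_species[sp]] * net.metabolites[sp]["mass"]
        total += r["stoich"][mid] * float(v[r["id"]]) * mass
    return -total
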