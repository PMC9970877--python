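"""Phase-resolved dissipation-capped FBA on the shipped reduced network."""

import json
from importlib import resources

import numpy as np
import pytest
from scipy.optimize import linprog

from phaseflux.fluxcycle import (
    DEFAULT_PHASES,
    ThermoNetwork,
    convert_flux_units,
    exchange_mass_closure,
    load_toy_network,
    metabolite_turnover,
    newborn_weighted_yield,
    phase_biomass_coefficients,
    precursor_sink,
    solve_cycle,
    solve_phase_fba,
)


@pytest.fixture(scope="module")
def net():
    return load_toy_network()


@pytest.fixture(scope="module")
def reference_solution(net):
    return solve_phase_fba(net, g_lim=np.inf)


def independent_plain_fba(raw):
    """Straight-line plain-FBA LP assembled directly from the network JSON."""
    met_ids = list(raw["metabolites"])
    ridx = {r["id"]: j for j, r in enumerate(raw["reactions"])}
    S = np.zeros((len(met_ids), len(raw["reactions"])))
    for j, r in enumerate(raw["reactions"]):
        for mid, c in r["stoich"].items():
            S[met_ids.index(mid), j] = c
    c_obj = np.zeros(len(raw["reactions"]))
    c_obj[ridx["BIOMASS"]] = -1.0
    bounds = [(r["lb"], r["ub"]) for r in raw["reactions"]]
    res = linprog(c_obj, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    assert res.status == 0
    return -res.fun


class TestNetwork:
    def test_loads_and_validates(self, net):
        assert net.M_biomass == pytest.approx(0.966)
        assert net.g_lim == pytest.approx(12.3)

    def test_mass_imbalance_detected(self, net):
        with resources.files("phaseflux").joinpath("data/toy_network.json").open() as f:
            raw = json.load(f)
        raw["reactions"][11]["stoich"]["glc_c"] = -1.5  # corrupt glycolysis
        with pytest.raises(ValueError, match="mass balance"):
            ThermoNetwork.from_json(raw)


class TestPhaseCoefficients:
    def test_reference_composition_gives_unit_coefficients(self, net):
        contrib = {j: np.array([v]) for j, v in net.c_model.items() if j != "storage"}
        total = sum(v[0] for v in contrib.values())
        contrib = {j: v / total for j, v in contrib.items()}
        coefs = phase_biomass_coefficients(contrib, net.c_model)[0]
        for j, v in coefs.items():
            if j == "storage":
                assert v == 0.0
            else:
                assert v == pytest.approx(1.0 / total, rel=1e-12)

    def test_ratio_arithmetic_and_storage_zero(self, net):
        contrib = {
            "protein": np.array([0.6]),
            "lipid": np.array([0.08]),
            "polysaccharide": np.array([0.2]),
            "RNA": np.array([0.11]),
            "DNA": np.array([0.01]),
        }
        coefs = phase_biomass_coefficients(contrib, net.c_model)[0]
        assert coefs["protein"] == pytest.approx(0.6 / 0.45)
        assert coefs["storage"] == 0.0


class TestSolve:
    def test_steady_state_and_dissipation_cap(self, net):
        sol = solve_phase_fba(net, g_lim=200.0)
        _, S = net.stoichiometric_matrix(sol.biomass_coeffs or None)
        assert np.max(np.abs(S @ sol.fluxes.values)) < 1e-8
        assert sol.dissipation <= 200.0 + 1e-6

    def test_slack_cap_matches_independent_plain_lp(self, net, reference_solution):
        with resources.files("phaseflux").joinpath("data/toy_network.json").open() as f:
            raw = json.load(f)
        oracle = independent_plain_fba(raw)
        assert reference_solution.v_biomass == pytest.approx(oracle, abs=1e-8)

    def test_biomass_nondecreasing_in_cap(self, net):
        caps = [5.0, 12.3, 50.0, 200.0, 1000.0, 5000.0]
        v = [solve_phase_fba(net, g_lim=g).v_biomass for g in caps]
        assert all(b >= a - 1e-9 for a, b in zip(v, v[1:]))

    def test_zero_like_cap_stops_growth(self, net):
        sol = solve_phase_fba(net, g_lim=1e-9)
        assert sol.v_biomass == pytest.approx(0.0, abs=1e-6)

    def test_composition_shifts_oxygen_demand(self, net):
        # lipid synthesis consumes far more NADH and oxygen-linked redox per
        # gram than protein synthesis in this network, so a lipid-heavy
        # biomass at the same dissipation cap draws different O2
        heavy_lipid = {"protein": [0.40], "lipid": [0.20], "polysaccharide": [0.25], "RNA": [0.13], "DNA": [0.02]}
        heavy_prot = {"protein": [0.60], "lipid": [0.05], "polysaccharide": [0.20], "RNA": [0.13], "DNA": [0.02]}
        sols = {}
        for name, contrib in (("lipid", heavy_lipid), ("protein", heavy_prot)):
            contrib = {j: np.array(v) for j, v in contrib.items()}
            coefs = phase_biomass_coefficients(contrib, net.c_model)[0]
            sol = solve_phase_fba(net, coefs, g_lim=300.0)
            sols[name] = sol.fluxes["EX_o2"] / sol.v_biomass
        assert sols["lipid"] != pytest.approx(sols["protein"], rel=1e-6)

    def test_exchange_mass_closure(self, net):
        contrib = {"protein": np.array([0.5]), "lipid": np.array([0.08]),
                   "polysaccharide": np.array([0.28]), "RNA": np.array([0.13]), "DNA": np.array([0.01])}
        coefs = phase_biomass_coefficients(contrib, net.c_model)[0]
        sol = solve_phase_fba(net, coefs, g_lim=500.0)
        assert abs(exchange_mass_closure(sol)) < 1e-6


class TestUnitConversion:
    def test_printed_arithmetic(self):
        v = convert_flux_units(1.0, 1.0, 0.966, 9.66)
        assert v == pytest.approx(1e-3 * (1 / 0.966) * 9.66)

    def test_linearity_in_biomass_rate(self, reference_solution):
        sol = reference_solution
        v1 = convert_flux_units(sol.fluxes, sol.v_biomass, 0.966, 10.0)
        v2 = convert_flux_units(sol.fluxes, sol.v_biomass, 0.966, 20.0)
        assert np.allclose(v2.values, 2.0 * v1.values)

    def test_matches_symbolic_oracle_on_random_solution(self):
        r = np.random.default_rng(0)
        v = r.uniform(-5, 5, 10)
        vb, M, rb = 0.7, 0.966, 12.0
        expect = 1e-3 * (v / vb) * (1 / M) * rb
        assert np.allclose(convert_flux_units(v, vb, M, rb), expect)

    def test_biomass_identity(self, reference_solution):
        sol = reference_solution
        rb = 8.5
        v_cell = convert_flux_units(sol.fluxes, sol.v_biomass, 0.966, rb)
        assert v_cell["BIOMASS"] == pytest.approx(rb / (1000 * 0.966), abs=1e-12)

    def test_zero_biomass_flux_rejected(self):
        with pytest.raises(ValueError):
            convert_flux_units(np.ones(3), 0.0, 0.966, 1.0)


class TestYieldsAndAggregates:
    def _two_phase_solutions(self, net):
        contrib = {j: np.array([v, v]) for j, v in
                   {"protein": 0.5, "lipid": 0.08, "polysaccharide": 0.28, "RNA": 0.13, "DNA": 0.01}.items()}
        return solve_cycle(net, contrib, r_biomass=np.array([0.1, 0.2]),
                           phases=np.array([3.0, 51.0]), g_lim=500.0)

    def test_constant_fluxes_make_yield_weight_independent(self, net):
        contrib = {j: np.array([v, v]) for j, v in
                   {"protein": 0.5, "lipid": 0.08, "polysaccharide": 0.28, "RNA": 0.13, "DNA": 0.01}.items()}
        sols = solve_cycle(net, contrib, r_biomass=np.array([0.1, 0.1]),
                           phases=np.array([3.0, 51.0]), g_lim=500.0)
        y1 = newborn_weighted_yield(sols, "EX_etoh")
        y2 = newborn_weighted_yield(sols, "EX_etoh", phase_weights={})
        assert y1 == pytest.approx(y2, rel=1e-9)

    def test_glucose_self_yield_is_minus_one(self, net):
        sols = self._two_phase_solutions(net)
        assert newborn_weighted_yield(sols, "EX_glc") == pytest.approx(-1.0, abs=1e-9)

    def test_two_phase_yield_matches_hand_computation(self, net):
        sols = self._two_phase_solutions(net)
        w = {3.0: 79.75 / 11.0}
        m_et = sols[0].network.metabolites["etoh_e"]["mass"]
        m_gl = sols[0].network.metabolites["glc_e"]["mass"]
        num = sum(float(s.fluxes_cell["EX_etoh"]) * m_et * w.get(float(s.t), 1.0) for s in sols)
        den = -sum(float(s.fluxes_cell["EX_glc"]) * m_gl * w.get(float(s.t), 1.0) for s in sols)
        assert newborn_weighted_yield(sols, "EX_etoh", phase_weights=w) == pytest.approx(num / den, rel=1e-12)

    def test_turnover_production_equals_consumption(self, net):
        sol = solve_phase_fba(net, g_lim=500.0)
        turnover, per_rxn = metabolite_turnover(sol, "atp")
        produced = sum(x for x in per_rxn.values() if x > 0)
        consumed = -sum(x for x in per_rxn.values() if x < 0)
        assert turnover == pytest.approx(produced)
        assert produced == pytest.approx(consumed, abs=1e-8)

    def test_turnover_matches_matrix_product_oracle(self, net):
        sol = solve_phase_fba(net, g_lim=500.0)
        met_ids, S = net.stoichiometric_matrix()
        i = met_ids.index("atp")
        contrib_vec = S[i] * sol.fluxes.values
        assert metabolite_turnover(sol, "atp")[0] == pytest.approx(contrib_vec[contrib_vec > 0].sum(), abs=1e-9)

    def test_precursor_sink_sums_configured_reactions(self, net):
        sol = solve_phase_fba(net, g_lim=500.0)
        sink = precursor_sink(sol, "glc_c", ["PROT_syn", "LIP_syn", "PS_syn"])
        expect = sum(net.reaction(r)["stoich"]["glc_c"] * sol.fluxes[r]
                     for r in ("PROT_syn", "LIP_syn", "PS_syn"))
        assert sink == pytest.approx(expect, abs=1e-12)


class TestDefaultPhases:
    def test_seventeen_moments(self):
        assert len(DEFAULT_PHASES) == 17
        assert DEFAULT_PHASES[0] == 3.0 and DEFAULT_PHASES[-1] == 99.0
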