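"""Production-rate estimator and stop-and-respond statistic components."""

import numpy as np
import pandas as pd
import pytest

from phaseflux.biosynthrate import (
    choose_alpha,
    minmax_phase_matrix,
    nadph_response,
    nbdg_signal_correction,
    normal_derivative_profile,
    perturbation_phase,
    production_rate,
    select_steady_cycling_cells,
    smoothed_derivative,
)
from phaseflux.cyclephase import CycleAnnotation
from phaseflux.tracekit import SingleCellTrace


class TestProductionRate:
    def test_constant_abundance_zero_rate(self):
        t = np.arange(0, 120, 6.0)
        r = production_rate(np.full(len(t), 7.0), t, t_half=6.0)
        assert np.allclose(r, 0.0, atol=1e-9)

    def test_linear_abundance_recovers_slope(self):
        t = np.arange(0, 120, 6.0)
        r = production_rate(3.0 * t + 1.0, t, t_half=6.0)
        assert np.allclose(r, 3.0, atol=1e-8)
        r_nc = production_rate(3.0 * t + 1.0, t, t_half=6.0, correct_maturation=False)
        assert np.allclose(r_nc, 3.0, atol=1e-8)

    def test_nonpositive_halftime_rejected(self):
        with pytest.raises(ValueError):
            production_rate(np.ones(10), np.arange(10.0), t_half=0.0)


class TestMinmaxMatrix:
    def _cycles(self, values):
        t = np.arange(0.0, 102.1, 6.0)
        return [
            {
                "time": t,
                "rate": values,
                "cycle_events": {"ME": 0.0, "START": 11.0, "BUD": 33.0, "next ME": 102.0},
            }
        ]

    def test_rows_span_zero_to_one(self):
        t = np.arange(0.0, 102.1, 6.0)
        mp = {"ME": 0.0, "START": 11 / 102, "BUD": 33 / 102, "next ME": 1.0}
        _, mat = minmax_phase_matrix(self._cycles(np.sin(t / 20) + 2), mp)
        assert mat.shape == (1, 17)
        assert mat.min() == pytest.approx(0.0) and mat.max() == pytest.approx(1.0)

    def test_monotone_trace_gives_monotone_row(self):
        t = np.arange(0.0, 102.1, 6.0)
        mp = {"ME": 0.0, "START": 11 / 102, "BUD": 33 / 102, "next ME": 1.0}
        _, mat = minmax_phase_matrix(self._cycles(t * 0.1), mp)
        assert np.all(np.diff(mat[0]) >= -1e-9)

    def test_degenerate_cycle_yields_zero_row_with_warning(self):
        t = np.arange(0.0, 102.1, 6.0)
        mp = {"ME": 0.0, "START": 11 / 102, "BUD": 33 / 102, "next ME": 1.0}
        with pytest.warns(UserWarning):
            _, mat = minmax_phase_matrix(self._cycles(np.full(len(t), 2.0)), mp)
        assert np.allclose(mat[0], 0.0)


class TestCellSelection:
    def _ann(self, cid, buds, mes=(), starts=()):
        return CycleAnnotation(cell_id=cid, events={"ME": np.array(mes), "START": np.array(starts), "BUD": np.array(buds)})

    def test_identical_durations_all_kept(self):
        anns = [self._ann(f"c{i}", [10.0 + i, 110.0 + i]) for i in range(5)]
        s1, deltas = select_steady_cycling_cells(anns, t_switch=300.0)
        assert len(s1) == 5
        assert deltas["CC"] == pytest.approx(100.0)

    def test_outlier_beyond_one_sd_excluded(self):
        buds = [[0.0, 100.0 + d] for d in (0.0, 1.0, -1.0, 0.5, 40.0)]
        anns = [self._ann(f"c{i}", b) for i, b in enumerate(buds)]
        s1, _ = select_steady_cycling_cells(anns, t_switch=300.0)
        assert "c4" not in s1

    def test_membership_matches_brute_force(self):
        r = np.random.default_rng(8)
        durations = r.normal(100, 10, 30)
        anns = [self._ann(f"c{i}", [50.0, 50.0 + d]) for i, d in enumerate(durations)]
        s1, _ = select_steady_cycling_cells(anns, t_switch=400.0)
        med, sd = np.median(durations), durations.std()
        expect = {f"c{i}" for i, d in enumerate(durations) if med - sd <= d <= med + sd}
        assert set(s1) == expect


class TestPerturbationPhase:
    DELTAS = {"ME": 0.0, "START": 11.0, "BUD": 30.0, "CC": 100.0}

    def _ann(self, me=(), start=(), bud=()):
        return CycleAnnotation(cell_id="c", events={"ME": np.array(me), "START": np.array(start), "BUD": np.array(bud)})

    def test_bud_anchor_arithmetic(self):
        # perturbation read-out 2 min after the latest budding, mean BUD offset 30
        ann = self._ann(me=[200.0], start=[211.0], bud=[230.0])
        phi, e_c, reason = perturbation_phase(ann, t_p=235.0, dt=6.0, deltas=self.DELTAS)
        assert e_c == "BUD" and phi == pytest.approx(32.0)

    def test_me_anchor_kept_when_within_mean_start(self):
        ann = self._ann(me=[227.0], start=[170.0], bud=[150.0])
        phi, e_c, reason = perturbation_phase(ann, t_p=235.0, dt=6.0, deltas=self.DELTAS)
        assert e_c == "ME" and phi == pytest.approx(5.0) and reason == ""

    def test_delayed_bud_anchor_rejected(self):
        ann = self._ann(me=[100.0], start=[111.0], bud=[130.0])
        phi, e_c, reason = perturbation_phase(ann, t_p=235.0, dt=6.0, deltas=self.DELTAS)
        assert phi is None and e_c == "BUD" and "delayed" in reason

    def test_no_events_rejected_with_reason(self):
        phi, e_c, reason = perturbation_phase(self._ann(), 235.0, 6.0, self.DELTAS)
        assert phi is None and reason == "no pre-perturbation events"


class TestNormalProfile:
    def test_shared_periodic_trace_reproduces_its_derivative(self):
        # every cell carries the same pure cosine; N(phi) must equal its
        # derivative at the same cycle offset
        dt, T = 6.0, 96.0
        t = np.arange(0.0, 5 * T, dt)
        y = 2.0 + 0.5 * np.sin(2 * np.pi * t / T)
        traces = {}
        anns = {}
        for i in range(5):
            cid = f"c{i}"
            traces[cid] = SingleCellTrace(cell_id=cid, time_min=t, channels={"NADPH": y})
            anns[cid] = CycleAnnotation(
                cell_id=cid,
                events={
                    "ME": np.arange(0.0, 5 * T, T),
                    "START": np.arange(11.0, 5 * T, T),
                    "BUD": np.arange(30.0, 5 * T, T),
                },
            )
        deltas = {"ME": 0.0, "START": 11.0, "BUD": 30.0, "CC": T}
        t_switch = 4 * T
        deriv_map = {cid: smoothed_derivative(traces[cid], t_switch) for cid in traces}
        N, amp = normal_derivative_profile(deriv_map, anns, deltas, t_switch)
        w = 2 * np.pi / T
        for phi in (5.0, 20.0, 50.0, 80.0):
            expect = 0.5 * w * np.cos(w * phi)
            assert N(phi) == pytest.approx(expect, abs=0.2 * 0.5 * w + 1e-4)
        assert amp == pytest.approx(2 * 0.5 * w, rel=0.25)

    def test_median_robust_to_minority_corruption(self):
        dt, T = 6.0, 96.0
        t = np.arange(0.0, 5 * T, dt)
        y = 2.0 + 0.5 * np.sin(2 * np.pi * t / T)
        traces, anns = {}, {}
        for i in range(7):
            cid = f"c{i}"
            yy = y + (100.0 if i < 3 else 0.0) * np.sin(t / 7.0)  # corrupt 3 of 7
            traces[cid] = SingleCellTrace(cell_id=cid, time_min=t, channels={"NADPH": yy})
            anns[cid] = CycleAnnotation(
                cell_id=cid,
                events={
                    "ME": np.arange(0.0, 5 * T, T),
                    "START": np.arange(11.0, 5 * T, T),
                    "BUD": np.arange(30.0, 5 * T, T),
                },
            )
        deltas = {"ME": 0.0, "START": 11.0, "BUD": 30.0, "CC": T}
        deriv_clean = {c: smoothed_derivative(traces[c], 4 * T) for c in list(traces)[3:]}
        deriv_all = {c: smoothed_derivative(traces[c], 4 * T) for c in traces}
        N_clean, _ = normal_derivative_profile(deriv_clean, anns, deltas, 4 * T)
        N_all, _ = normal_derivative_profile(deriv_all, anns, deltas, 4 * T)
        for phi in (10.0, 40.0, 70.0):
            assert N_all(phi) == pytest.approx(N_clean(phi), abs=1e-9)


class TestResponse:
    def test_null_response_and_arithmetic(self):
        assert nadph_response(0.3, 0.3, alpha=-1, amplitude=2.0) == 0.0
        assert nadph_response(-0.2, 0.3, alpha=-1, amplitude=2.0) == pytest.approx(0.25)

    def test_zero_amplitude_rejected(self):
        with pytest.raises(ValueError):
            nadph_response(0.1, 0.0, alpha=1, amplitude=0.0)

    def test_alpha_sign_follows_population_drop(self):
        t = np.arange(0.0, 60.0, 6.0)
        drop = SingleCellTrace(cell_id="a", time_min=t, channels={"NADPH": np.where(t < 30, 1.0, 0.5)})
        rise = SingleCellTrace(cell_id="b", time_min=t, channels={"NADPH": np.where(t < 30, 1.0, 1.5)})
        assert choose_alpha([drop], 30.0, 6.0) == -1
        assert choose_alpha([rise], 30.0, 6.0) == 1


class TestNbdgCorrection:
    def test_autofluorescence_cancels_and_equal_batch_normalises_to_one(self):
        series = {f"c{i}": np.array([3.0, 3.0, 3.0, 3.0, 3.0, 0.0, 8.0]) for i in range(4)}
        out = nbdg_signal_correction(series, range(5), 6, [list(series)])
        assert all(v == pytest.approx(1.0) for v in out.values())

    def test_zero_uptake_corrects_to_zero(self):
        series = {"c0": np.array([2.0, 2.0, 2.0, 2.0, 2.0, 0.0, 2.0]),
                  "c1": np.array([1.0, 1.0, 1.0, 1.0, 1.0, 0.0, 4.0])}
        out = nbdg_signal_correction(series, range(5), 6, [["c0", "c1"]])
        assert out["c0"] == pytest.approx(0.0)

    def test_batch_offset_equalised_ranking_preserved(self):
        r = np.random.default_rng(1)
        base = r.uniform(1.0, 3.0, 6)
        batch1 = {f"a{i}": np.array([0.5] * 5 + [0.0, 0.5 + base[i]]) for i in range(3)}
        batch2 = {f"b{i}": np.array([0.5] * 5 + [0.0, 0.5 + 2.0 * base[3 + i]]) for i in range(3)}
        out = nbdg_signal_correction({**batch1, **batch2}, range(5), 6, [list(batch1), list(batch2)])
        v1 = [out[k] for k in batch1]
        v2 = [out[k] for k in batch2]
        assert np.median(v1) == pytest.approx(np.median(v2))
        assert np.argsort(v1).tolist() == np.argsort(base[:3]).tolist()
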