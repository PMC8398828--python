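"""Sampling correction, permeability estimation, transport metrics, TEER gate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ussingkit import (
    CompartmentAmounts,
    CompoundKinetics,
    CompoundSpec,
    ExperimentDesign,
    KineticParams,
    MeasurementModel,
    TEERTrace,
    apply_measurement,
    correct_sampling,
    estimate_papp,
    mfi,
    papp_from_slope,
    q_dep,
    q_dep_extract,
    q_perm,
    simulate_kinetics,
    simulate_teer,
    teer_gate,
    transport_index,
)
from ussingkit.scenarios import papp_recovery_scenario


def amounts(d0=700.0, dend=0.0, mem=0.0, acc=0.0, cid="cpd", chamber=1):
    return CompartmentAmounts(cid, chamber, d0, dend, mem, acc)


class TestCorrectSampling:
    def test_zero_everywhere(self):
        times = np.array([0.0, 10.0, 20.0])
        q, eq = correct_sampling(times, np.zeros(3), 7.0, 0.4)
        assert np.all(q == 0) and np.all(eq == 0)

    def test_constant_concentration_accumulates_aliquots(self):
        times = np.array([0.0, 10.0])
        q, eq = correct_sampling(times, np.array([1.0, 1.0]), 7.0, 0.4)
        assert q[-1] == pytest.approx(7.4)
        assert eq[-1] == pytest.approx(7.4 / 7.0)

    def test_matches_simulator_removal_ledger(self):
        """Corrected cumulative amounts equal truth: in-acceptor + removed."""
        design = ExperimentDesign()
        compounds = [CompoundSpec(id="cpd", mz=417.1181, rt=2.2, mw=416.4,
                                  initial_donor_conc=100.0)]
        kin = KineticParams(rates={"cpd": CompoundKinetics(papp_true=5e-6)})
        state = simulate_kinetics(design, compounds, kin)
        conc = state.sampled_acceptor_conc[0]
        q, _ = correct_sampling(np.asarray(design.sampling_times), conc,
                                design.acceptor_volume, design.acceptor_aliquot)
        # at the final time nothing has been withdrawn there yet
        truth = (state.sampled_acceptor_conc[0, -1] * design.acceptor_volume
                 + state.removed_acceptor[0, -2])
        assert q[-1] == pytest.approx(truth, rel=5e-3)

    def test_aliquot_larger_than_volume_rejected(self):
        with pytest.raises(ValueError):
            correct_sampling(np.array([0.0, 10.0]), np.array([1.0, 1.0]), 0.4, 7.0)


class TestEstimatePapp:
    def test_slope_to_papp_formula(self):
        design = ExperimentDesign()
        assert papp_from_slope(1.8e-5, design, 100.0) == pytest.approx(1.0e-6)

    def test_zero_slope_gives_zero(self):
        design = ExperimentDesign()
        times = np.asarray(design.sampling_times)
        fit = estimate_papp(times, np.zeros_like(times), design, 100.0, correct=False)
        assert fit.mean == 0.0

    def test_insufficient_window_points_rejected(self):
        design = ExperimentDesign()
        with pytest.raises(ValueError, match="3 sampling points"):
            estimate_papp(np.array([0.0, 50.0, 100.0]), np.zeros(3), design, 100.0)

    def test_nonpositive_c0_rejected(self):
        with pytest.raises(ValueError, match="C0"):
            papp_from_slope(1e-5, ExperimentDesign(), 0.0)

    @pytest.mark.parametrize("papp_true", [0.5e-6, 1e-6, 2.5e-6, 5e-6, 10e-6])
    def test_noise_free_recovery_across_grid(self, papp_true):
        scenario = papp_recovery_scenario(papp_true, 100.0)
        state = scenario.simulate()
        times = np.asarray(scenario.design.sampling_times)
        conc = state.sampled_acceptor_conc
        fit = estimate_papp(times, conc, scenario.design, 100.0)
        assert fit.mean == pytest.approx(papp_true, rel=0.02)

    def test_noisy_recovery_with_four_chambers(self):
        scenario = papp_recovery_scenario(2.61e-6, 25.724)
        model = MeasurementModel(noise_cv=0.05, seed=20, lod_height=0.0)
        table = scenario.measure(model)
        times = np.asarray(scenario.design.sampling_times)
        fid = "F001"
        conc = np.array([
            [table.height(fid, f"acceptor_t{t:g}_r{ch}") / model.response_factor
             for t in times]
            for ch in range(1, 5)
        ])
        c0 = np.mean([table.height(fid, f"donor_t0_r{ch}") / model.response_factor
                      for ch in range(1, 5)])
        fit = estimate_papp(times, conc, scenario.design, float(c0))
        assert fit.mean == pytest.approx(2.61e-6, rel=0.10)

    def test_uncorrected_mode_underestimates(self):
        """Skipping the withdrawal correction biases the slope downward."""
        scenario = papp_recovery_scenario(5e-6, 100.0)
        state = scenario.simulate()
        times = np.asarray(scenario.design.sampling_times)
        conc = state.sampled_acceptor_conc
        corrected = estimate_papp(times, conc, scenario.design, 100.0, correct=True)
        naive = estimate_papp(times, conc, scenario.design, 100.0, correct=False)
        assert naive.mean < corrected.mean


class TestTransportMetrics:
    def test_q_dep_forced_arithmetic(self):
        assert q_dep(amounts(d0=700.0, mem=3.29)) == pytest.approx(0.47)
        assert q_dep(amounts(d0=700.0, mem=4.41)) == pytest.approx(0.63)

    def test_q_perm_zero_acceptor(self):
        a = amounts(d0=700.0, mem=3.29, acc=0.0)
        assert q_perm(a) == 0.0
        assert transport_index(a) == q_dep(a)

    @settings(max_examples=50, deadline=None)
    @given(d0=st.floats(1e-3, 1e4), mem=st.floats(0, 1e3), acc=st.floats(0, 1e3))
    def test_ti_is_sum_identity(self, d0, mem, acc):
        a = amounts(d0=d0, mem=mem, acc=acc)
        assert transport_index(a) == pytest.approx(q_dep(a) + q_perm(a), rel=1e-12)

    def test_q_dep_extract_forced_arithmetic(self):
        # membrane 0.6145 nmol vs donor-end 1.544 uM x 7 mL = 10.808 nmol
        a = amounts(dend=10.808, mem=0.6145)
        assert q_dep_extract(a) == pytest.approx(5.38, abs=0.005)

    def test_q_dep_extract_symmetry_and_edges(self):
        assert q_dep_extract(amounts(dend=5.0, mem=5.0)) == pytest.approx(50.0)
        assert q_dep_extract(amounts(dend=5.0, mem=0.0)) == 0.0
        with pytest.raises(ValueError):
            q_dep_extract(amounts(dend=0.0, mem=0.0))

    @settings(max_examples=50, deadline=None)
    @given(dend=st.floats(0, 1e3), mem=st.floats(0, 1e3))
    def test_q_dep_extract_bounded(self, dend, mem):
        if dend + mem <= 0:
            return
        v = q_dep_extract(amounts(dend=dend, mem=mem))
        assert 0.0 <= v <= 100.0

    def test_mfi_formula_and_edges(self):
        met = amounts(d0=0.0, dend=10.0, mem=2.0, acc=0.0, cid="met")
        assert mfi(met, 100.0) == pytest.approx(12.0)
        empty = amounts(d0=0.0, cid="met")
        assert mfi(empty, 100.0) == 0.0
        with pytest.raises(ValueError):
            mfi(met, 0.0)

    def test_zero_initial_amount_rejected(self):
        with pytest.raises(ValueError):
            q_dep(amounts(d0=0.0, mem=1.0))


class TestTeerGate:
    def _trace(self, values, chamber=1):
        values = np.asarray(values, dtype=float)
        return TEERTrace(chamber, np.arange(values.size, dtype=float), values)

    def test_constant_forty_viable(self):
        rep = teer_gate([self._trace([40.0] * 101)])[0]
        assert rep.viable and rep.min_teer == 40.0

    def test_single_dip_below_threshold_excludes(self):
        values = [40.0] * 101
        values[60] = 14.0
        rep = teer_gate([self._trace(values)])[0]
        assert not rep.viable

    def test_exactly_at_threshold_remains_viable(self):
        rep = teer_gate([self._trace([15.0] * 101)])[0]
        assert rep.viable

    def test_simulated_decaying_chamber_is_gated(self):
        design = ExperimentDesign()
        dying = simulate_teer(design, baseline=20.0, decay_rate=0.005, chamber=2)
        healthy = simulate_teer(design, baseline=40.0, chamber=1)
        reports = teer_gate([healthy, dying])
        assert [r.viable for r in reports] == [True, False]
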