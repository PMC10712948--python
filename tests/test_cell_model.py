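import numpy as np
import pytest

from arraxis import _ord
from arraxis.cell_model import (
    BASELINE_RESCALING,
    APTrace,
    ConductanceMultipliers,
    PacingProtocol,
    SolverSettings,
    SurrogateSpec,
    build_scaled_parameters,
    simulate_ap,
    surrogate_simulate,
)
from arraxis.ead_detector import classify_cell, detect_peaks

from conftest import ECTOPIC_POINT


class TestConductanceMultipliers:
    def test_log_round_trip(self):
        m = ConductanceMultipliers(2.0, 0.5, 1.0, 3.0)
        assert ConductanceMultipliers.from_log(m.log()).as_tuple() == pytest.approx(
            m.as_tuple()
        )

    @pytest.mark.parametrize("bad", [0.0, -1.0, np.nan, np.inf])
    def test_non_positive_rejected(self, bad):
        with pytest.raises(ValueError):
            ConductanceMultipliers(gCaL=bad)


class TestBuildScaledParameters:
    def test_baseline_rescaling_applied_once(self):
        p = build_scaled_parameters(ConductanceMultipliers())
        assert p[_ord.P_GKS] == pytest.approx(8.09 * _ord.BASE_PARAMS[_ord.P_GKS])
        assert p[_ord.P_GKR] == pytest.approx(1.17 * _ord.BASE_PARAMS[_ord.P_GKR])
        assert p[_ord.P_PCA] == pytest.approx(3.57 * _ord.BASE_PARAMS[_ord.P_PCA])
        assert p[_ord.P_GNCX] == pytest.approx(3.05 * _ord.BASE_PARAMS[_ord.P_GNCX])
        assert p[_ord.P_PNAK] == pytest.approx(1.91 * _ord.BASE_PARAMS[_ord.P_PNAK])
        assert p[_ord.P_GNAL] == pytest.approx(1.7 * _ord.BASE_PARAMS[_ord.P_GNAL])

    def test_cell_multiplier_composes_on_top(self):
        p = build_scaled_parameters(ConductanceMultipliers(gCaL=2.0))
        base = build_scaled_parameters(ConductanceMultipliers())
        assert p[_ord.P_PCA] == pytest.approx(2.0 * 3.57 * _ord.BASE_PARAMS[_ord.P_PCA])
        # all other parameters untouched
        others = [i for i in range(_ord.N_PARAMS) if i != _ord.P_PCA]
        assert np.allclose(p[others], base[others])

    def test_multiplicative_composition_commutes(self):
        a = (1.7, 0.4, 2.0, 0.9)
        b = (0.5, 3.0, 0.25, 1.1)
        ab = tuple(x * y for x, y in zip(a, b))
        assert np.allclose(
            build_scaled_parameters(ab),
            build_scaled_parameters(tuple(x * y for x, y in zip(b, a))),
        )
        # applying a then b equals applying their product
        pa = build_scaled_parameters(a)
        idx = [_ord.P_PCA, _ord.P_GKR, _ord.P_GNAL, _ord.P_GKS]
        pab = pa.copy()
        for i, g in zip(idx, b):
            pab[i] *= g
        assert np.allclose(pab, build_scaled_parameters(ab))

    def test_extreme_domain_multiplier(self):
        p = build_scaled_parameters((1.0, np.exp(-3.0), 1.0, 1.0))
        assert p[_ord.P_GKR] == pytest.approx(
            np.exp(-3.0) * 1.17 * _ord.BASE_PARAMS[_ord.P_GKR]
        )


class TestSimulateAP:
    def test_baseline_is_benign(self, baseline_trace):
        assert classify_cell(baseline_trace).label == "benign"
        assert baseline_trace.vm.min() > -95.0
        assert 20.0 < baseline_trace.vm.max() < 60.0

    def test_unstimulated_cell_stays_at_rest(self):
        protocol = PacingProtocol(
            stim_amplitude=-1e-12, equilibration_beats=2, recorded_beats=4
        )
        trace = simulate_ap(ConductanceMultipliers(), protocol)
        assert trace.vm.max() - trace.vm.min() < 2.0
        assert np.all(trace.vm < -80.0)

    def test_consecutive_beats_near_periodic(self, baseline_trace):
        cl = int(baseline_trace.protocol.cycle_length)
        beats = baseline_trace.vm.reshape(4, cl)
        for k in range(3):
            assert np.max(np.abs(beats[k + 1] - beats[k])) < 1.0

    def test_deterministic(self, short_protocol, baseline_trace):
        again = simulate_ap(ConductanceMultipliers(), short_protocol)
        assert np.array_equal(again.vm, baseline_trace.vm)

    def test_reduced_ikr_enhanced_ical_is_ectopic(self):
        protocol = PacingProtocol(equilibration_beats=150, recorded_beats=4)
        trace = simulate_ap(ECTOPIC_POINT, protocol)
        assert classify_cell(trace).ectopic

    def test_solvers_agree_at_baseline(self, baseline_trace, short_protocol):
        lsoda = simulate_ap(
            ConductanceMultipliers(),
            short_protocol,
            SolverSettings(method="lsoda"),
        )
        # pointwise agreement away from the upstroke; the steep upstroke
        # shifts by a fraction of a sample between integrators
        d = np.abs(lsoda.vm - baseline_trace.vm)
        assert np.mean(d) < 0.25
        assert np.percentile(d, 99) < 2.0

    def test_invalid_protocol_rejected(self):
        with pytest.raises(ValueError):
            PacingProtocol(cycle_length=0.3, stim_duration=0.5)
        with pytest.raises(ValueError):
            SolverSettings(abs_tol=-1.0)


class TestTraceIO:
    def test_csv_round_trip(self, tmp_path, baseline_trace):
        path = tmp_path / "trace.csv"
        baseline_trace.to_csv(path)
        back = APTrace.from_csv(path)
        assert np.allclose(back.time, baseline_trace.time)
        assert np.allclose(back.vm, baseline_trace.vm, atol=1e-6)
        assert back.protocol.cycle_length == 1000.0


class TestProtocolConfig:
    def test_key_value_file(self, tmp_path):
        from arraxis.cell_model import load_protocol_config

        cfg = tmp_path / "protocol.cfg"
        cfg.write_text(
            "# pacing\ncycle_length = 800\nequilibration_beats = 50\n"
            "method = lsoda\nabs_tol = 1e-4\n"
        )
        protocol, solver = load_protocol_config(cfg)
        assert protocol.cycle_length == 800.0
        assert protocol.equilibration_beats == 50
        assert protocol.stim_amplitude == -70.0  # default preserved
        assert solver.method == "lsoda"
        assert solver.abs_tol == 1e-4

    def test_unknown_key_rejected(self, tmp_path):
        from arraxis.cell_model import load_protocol_config

        cfg = tmp_path / "bad.cfg"
        cfg.write_text("voltage_clamp = 1\n")
        with pytest.raises(ValueError, match="unknown key"):
            load_protocol_config(cfg)


class TestSurrogate:
    def test_rule_controls_ead_presence(self):
        spec = SurrogateSpec(b0=-1.0, b=(1.0, -1.0, 0.0, 0.0))
        ect = surrogate_simulate((np.exp(1.5), 1.0, 1.0, 1.0), spec=spec)
        ben = surrogate_simulate((1.0, 1.0, 1.0, 1.0), spec=spec)
        # ectopic trace has a secondary peak above -50 mV in every beat
        lab = classify_cell(ect)
        assert lab.ectopic and all(lab.beat_flags)
        assert not classify_cell(ben).ectopic
        assert len(detect_peaks(ben)) == 4

    def test_trace_geometry(self):
        trace = surrogate_simulate((1.0, 1.0, 1.0, 1.0))
        assert trace.vm[0] == pytest.approx(-88.0, abs=1.0)
        assert trace.vm.max() < 40.0
        assert len(trace.time) == 4000

    def test_temperature_softens_boundary(self):
        spec = SurrogateSpec(b0=0.0, b=(1.0, 0.0, 0.0, 0.0), temperature=1.0)
        rng = np.random.default_rng(0)
        from arraxis.cell_model import surrogate_label

        labels = [surrogate_label([0.0, 0, 0, 0], spec, rng) for _ in range(400)]
        frac = np.mean(labels)
        assert 0.4 < frac < 0.6  # p = 0.5 on the boundary
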