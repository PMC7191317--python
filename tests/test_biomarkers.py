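import numpy as np
import pytest

from atriagp.biomarkers import (
    detect_activations,
    extract_biomarkers,
    plausibility_filter,
)
from atriagp.cell_models import PacingProtocol, Trace, simulate_toy_ap


class TestTriangularOracle:
    """Closed forms on the triangular action potential (amplitude 100 mV)."""

    def test_apd_values(self, triangle_trace):
        vec = extract_biomarkers(triangle_trace, 0)
        assert vec.APD_90 == pytest.approx(450.0, abs=0.5)
        assert vec.APD_50 == pytest.approx(250.0, abs=0.5)

    def test_plateau_voltages_linear(self, triangle_trace):
        vec = extract_biomarkers(triangle_trace, 0)
        # V(t) = 20 - 0.2 t with APD_90 = 450
        assert vec.V_20 == pytest.approx(20.0 - 0.2 * 90.0, abs=0.2)
        assert vec.V_40 == pytest.approx(20.0 - 0.2 * 180.0, abs=0.2)
        assert vec.V_80 == pytest.approx(20.0 - 0.2 * 360.0, abs=0.2)

    def test_rest_and_peak(self, triangle_trace):
        vec = extract_biomarkers(triangle_trace, 0)
        assert vec.RestV_m == pytest.approx(-80.0)
        assert vec.V_max == pytest.approx(20.0, abs=0.1)

    def test_apd_monotone_in_repolarization_fraction(self, triangle_trace):
        t, v = triangle_trace.time, triangle_trace.voltage
        vec = extract_biomarkers(triangle_trace, 0)
        assert vec.APD_50 < vec.APD_90


class TestToyRecovery:
    def test_generating_parameters_recovered(self, toy_defaults):
        """Extraction on the toy generator recovers its parameters to < 1%."""
        tr = simulate_toy_ap(toy_defaults, PacingProtocol(n_beats=3))
        vec = extract_biomarkers(tr, -1)
        vals = toy_defaults.values
        assert vec.RestV_m == pytest.approx(vals["rest_V"], rel=0.01)
        assert vec.V_max == pytest.approx(vals["peak_V"], rel=0.01, abs=0.3)
        assert vec.Ca_min == pytest.approx(vals["Ca_base"], rel=0.01)
        from atriagp.cell_models import toy_apd

        di_s1 = 1000.0 - toy_apd(vals, 1.0)
        assert vec.APD_90 == pytest.approx(toy_apd(vals, 0.9, di_s1), rel=0.01)

    def test_constant_diastole_rest_exact(self, toy_defaults):
        tr = simulate_toy_ap(toy_defaults, PacingProtocol(n_beats=2))
        vec = extract_biomarkers(tr, -1)
        assert vec.RestV_m == -80.0


class TestActivationDetection:
    def test_two_stimuli_two_activations(self, toy_defaults):
        tr = simulate_toy_ap(toy_defaults, PacingProtocol(n_beats=2))
        acts = detect_activations(tr)
        assert acts.n_captured == 2
        assert np.all(np.abs(acts.captured - tr.stim_times) < 10.0)
        assert acts.spontaneous.size == 0

    def test_spontaneous_upstroke_reported(self):
        """An upstroke with no stimulus at t=500 ms counts as pacemaking."""
        t = np.arange(0.0, 1000.0, 0.5)
        v = np.full_like(t, -80.0)
        up = (t >= 0) & (t < 200)
        v[up] = np.where(t[up] < 2, -80 + 50 * t[up], 20.0 - 0.5 * (t[up] - 2))
        sp = (t >= 500) & (t < 700)
        v[sp] = np.where(t[sp] < 502, -80 + 50 * (t[sp] - 500), 20.0 - 0.5 * (t[sp] - 502))
        tr = Trace(t, v, np.full_like(t, 1e-4), np.array([0.0]), np.array([0.0]))
        acts = detect_activations(tr)
        assert acts.n_captured == 1
        assert acts.spontaneous.size == 1
        assert abs(acts.spontaneous[0] - 500.0) < 10.0

    def test_no_capture_flagged(self):
        t = np.arange(0.0, 500.0, 0.5)
        v = np.full_like(t, -80.0)
        tr = Trace(t, v, np.full_like(t, 1e-4), np.array([0.0]), np.array([np.nan]))
        vec = extract_biomarkers(tr, 0)
        assert "no_capture" in vec.flags


def _toy_trace(toy_defaults, **overrides):
    pa = toy_defaults.replace(**overrides) if overrides else toy_defaults
    return simulate_toy_ap(pa, PacingProtocol(n_beats=3))


class TestPlausibilityFilter:
    def test_healthy_run_kept(self, toy_defaults):
        rec = plausibility_filter(_toy_trace(toy_defaults))
        assert rec.keep and rec.reasons == ()

    def test_depolarized_rest_excluded(self, toy_defaults):
        """A resting potential of -59 mV crosses the -60 mV threshold."""
        rec = plausibility_filter(_toy_trace(toy_defaults, rest_V=-59.0))
        assert not rec.keep
        assert "depolarized_rest" in rec.reasons

    def test_long_apd_excluded(self, toy_defaults):
        # APD_90 just over 600 ms (apd_scale chosen so 0.9^q * T + t_up > 600)
        rec = plausibility_filter(
            _toy_trace(toy_defaults, apd_scale=830.0, restitution_slope=1e-6)
        )
        assert not rec.keep
        assert "long_apd" in rec.reasons

    def test_five_percent_alternans_rule_arithmetic(self):
        # |300 - 310| / 310 = 3.2% keeps; the same pair scaled to >5% excludes
        assert abs(300.0 - 310.0) / 310.0 < 0.05
        assert abs(290.0 - 310.0) / 310.0 > 0.05

    def test_filter_is_deterministic_and_idempotent(self, toy_defaults):
        tr = _toy_trace(toy_defaults)
        r1 = plausibility_filter(tr)
        r2 = plausibility_filter(tr)
        assert r1 == r2

    def test_incomplete_run_excluded(self, toy_defaults):
        tr = simulate_toy_ap(toy_defaults, PacingProtocol(n_beats=1))
        rec = plausibility_filter(tr)
        assert not rec.keep
        assert "incomplete" in rec.reasons
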