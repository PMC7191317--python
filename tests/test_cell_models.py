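import numpy as np
import pytest

from atriagp.biomarkers import extract_biomarkers
from atriagp.cell_models import (
    PacingProtocol,
    SolverSettings,
    simulate,
    simulate_toy_ap,
    toy_apd,
)


class TestProtocolBookkeeping:
    def test_stimulus_times_are_multiples_of_cycle_length(self, crn_short_trace):
        assert np.allclose(crn_short_trace.stim_times, [0.0, 1000.0, 2000.0])

    def test_forty_beat_toy_protocol(self, toy_defaults):
        tr = simulate_toy_ap(toy_defaults, PacingProtocol(n_beats=40))
        assert np.allclose(tr.stim_times, np.arange(40) * 1000.0)

    def test_invalid_protocols_rejected(self):
        with pytest.raises(ValueError):
            PacingProtocol(cl=-1.0)
        with pytest.raises(ValueError):
            PacingProtocol(n_beats=0)

    def test_unknown_parameter_rejected(self, crn_defaults):
        with pytest.raises(ValueError):
            crn_defaults.replace(G_bogus=1.0)

    def test_maleckar_stimulus_density(self, mal_defaults):
        """A 750 pA, 6 ms stimulus: current density 750/C_m pA/pF."""
        tr = simulate(mal_defaults, PacingProtocol(n_beats=1))
        proto = tr.meta["protocol"]
        assert proto["stim_amplitude_pA"] == 750.0
        assert proto["stim_duration_ms"] == 6.0
        cm = mal_defaults.values["C_m"]
        assert 750.0 / cm == pytest.approx(15.0)


class TestPublishedPhysiology:
    """Steady-state biomarkers against the published model behavior."""

    def test_courtemanche_resting_potential_and_apd(self, crn_defaults):
        tr = simulate(crn_defaults, PacingProtocol(n_beats=6))
        vec = extract_biomarkers(tr, -1)
        assert vec.RestV_m == pytest.approx(-81.2, abs=1.5)
        assert 270.0 < vec.APD_90 < 330.0
        assert 150.0 < vec.dVdt_max < 260.0
        assert 10.0 < vec.V_max < 35.0

    def test_courtemanche_calcium_transient_range(self, crn_defaults):
        tr = simulate(crn_defaults, PacingProtocol(n_beats=6))
        vec = extract_biomarkers(tr, -1)
        assert 0.5e-4 < vec.Ca_min < 2.5e-4
        assert 3e-4 < vec.Ca_max < 1.5e-3

    def test_maleckar_resting_potential(self, mal_defaults):
        tr = simulate(mal_defaults, PacingProtocol(n_beats=6))
        vec = extract_biomarkers(tr, -1)
        assert -82.0 < vec.RestV_m < -70.0
        assert 100.0 < vec.APD_90 < 300.0


class TestSolverContracts:
    def test_determinism(self, crn_defaults):
        a = simulate(crn_defaults, PacingProtocol(n_beats=2))
        b = simulate(crn_defaults, PacingProtocol(n_beats=2))
        assert np.array_equal(a.time, b.time)
        assert np.array_equal(a.voltage, b.voltage)

    def test_intracellular_na_k_fixed(self, crn_short_trace):
        y_end = crn_short_trace.meta["final_state"]
        assert y_end[16] == 11.17
        assert y_end[17] == 139.0

    def test_tolerance_convergence(self, crn_defaults):
        """10x tighter tolerances move the final-beat APD_90 by < 0.5 ms."""
        loose = simulate(crn_defaults, PacingProtocol(n_beats=3))
        tight = simulate(
            crn_defaults, PacingProtocol(n_beats=3),
            SolverSettings(rtol=1e-7, atol=1e-7),
        )
        a = extract_biomarkers(loose, -1).APD_90
        b = extract_biomarkers(tight, -1).APD_90
        assert abs(a - b) < 0.5

    def test_hybrid_agrees_with_bdf_reference(self, crn_defaults):
        """The production integrator matches LSODA at the same tolerances."""
        hyb = simulate(crn_defaults, PacingProtocol(n_beats=2))
        ref = simulate(
            crn_defaults, PacingProtocol(n_beats=2), SolverSettings(method="lsoda")
        )
        a = extract_biomarkers(hyb, -1)
        b = extract_biomarkers(ref, -1)
        assert abs(a.APD_90 - b.APD_90) < 0.5
        assert abs(a.RestV_m - b.RestV_m) < 0.1

    def test_s1s2_timing_contract(self, crn_defaults):
        di = 150.0
        tr = simulate(crn_defaults, PacingProtocol(n_beats=3, s2_di=di))
        apd90_s1 = extract_biomarkers(tr, -2).APD_90
        expected = tr.stim_times[-2] + apd90_s1 + 10.0 + di
        assert tr.stim_times[-1] == pytest.approx(expected, abs=1.0)


class TestToyModel:
    def test_rest_and_peak_recovered(self, toy_defaults):
        tr = simulate_toy_ap(toy_defaults, PacingProtocol(n_beats=2))
        vec = extract_biomarkers(tr, -1)
        assert vec.RestV_m == pytest.approx(-80.0, abs=1e-9)
        assert vec.V_max == pytest.approx(20.0, abs=0.5)

    def test_apd_scale_doubles_apd90(self, toy_defaults):
        base = extract_biomarkers(
            simulate_toy_ap(toy_defaults, PacingProtocol(n_beats=2)), -1
        ).APD_90
        doubled = extract_biomarkers(
            simulate_toy_ap(
                toy_defaults.replace(apd_scale=600.0), PacingProtocol(cl=2000.0, n_beats=2)
            ),
            -1,
        ).APD_90
        assert doubled == pytest.approx(2 * base, rel=0.02)

    def test_restitution_monotone_in_di(self, toy_defaults):
        vals = dict(toy_defaults.values)
        apds = [toy_apd(vals, 0.9, di) for di in (50, 150, 250, 350, 450)]
        assert np.all(np.diff(apds) > 0)

    def test_s1s2_apd_shorter_at_short_di(self, toy_defaults):
        short = extract_biomarkers(
            simulate_toy_ap(toy_defaults, PacingProtocol(n_beats=3, s2_di=60.0)), -1
        ).APD_90
        long = extract_biomarkers(
            simulate_toy_ap(toy_defaults, PacingProtocol(n_beats=3, s2_di=440.0)), -1
        ).APD_90
        assert short < long

    def test_invalid_toy_parameters_rejected(self, toy_defaults):
        with pytest.raises(ValueError):
            simulate_toy_ap(toy_defaults.replace(apd_scale=-1.0), PacingProtocol(n_beats=1))
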