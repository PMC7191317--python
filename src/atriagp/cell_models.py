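"""Deterministic simulators for human atrial myocyte models.

Two biophysically detailed models are implemented: the Courtemanche et al.
(1998) model and the Maleckar et al. (2009) extension of the Nygren et al.
(1998) model, each transcribed from the published equation sets with two
stabilising modifications: intracellular Na+ and K+ are held at their default
initial values (11.17 / 139.00 mM) in the Courtemanche model, and the
acetylcholine-activated K+ current is zero in the Maleckar model.

A closed-form "toy" action-potential generator is also provided so that the
downstream design -> biomarker -> emulator -> sensitivity pipeline can be
exercised in milliseconds with analytically known ground truth.

Simulation uses an adaptive second-order Rush-Larsen integrator compiled
with numba (exponential gate updates remove the fast Na-gate stiffness at
rest); the default tolerances are rtol = atol = 1e-6 with the maximum step
capped at 0.5 ms.  An embedded Cash-Karp Runge-Kutta path and a BDF-type
reference path (scipy LSODA) are kept for solver cross-checks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from numba import njit

from .design import build_input_space

__all__ = [
    "ParameterAssignment",
    "PacingProtocol",
    "SolverSettings",
    "Trace",
    "SimulationError",
    "simulate",
    "simulate_toy_ap",
    "toy_apd",
]

F = 96.4867  # C/mmol
R = 8.3143   # J/(mol K)
T = 310.0    # K
RTF = R * T / F  # ~26.71 mV


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails or the state leaves the finite range."""


@dataclass(frozen=True)
class ParameterAssignment:
    """Raw parameter values for one model, in the units of the input table.

    Unlisted model constants stay at their published defaults.  ``values``
    must cover every input of the model's Stage-1 input space; use
    :meth:`defaults` and :meth:`replace` for partial overrides.
    """

    model: str
    values: Mapping[str, float]

    @classmethod
    def defaults(cls, model: str) -> "ParameterAssignment":
        space = build_input_space(model, 1)
        return cls(model, dict(zip(space.names, space.central.tolist())))

    def replace(self, **overrides: float) -> "ParameterAssignment":
        space = build_input_space(self.model, 1)
        unknown = set(overrides) - set(space.names)
        if unknown:
            raise ValueError(f"unknown parameter(s) for {self.model}: {sorted(unknown)}")
        vals = dict(self.values)
        vals.update(overrides)
        return ParameterAssignment(self.model, vals)

    def vector(self) -> np.ndarray:
        space = build_input_space(self.model, 1)
        missing = [n for n in space.names if n not in self.values]
        if missing:
            raise ValueError(f"missing parameter(s) for {self.model}: {missing}")
        v = np.array([float(self.values[n]) for n in space.names])
        positive = space.central > 0
        if np.any(v[positive] <= 0):
            bad = [n for n, p, x in zip(space.names, positive, v) if p and x <= 0]
            raise ValueError(f"parameters must be strictly positive: {bad}")
        return v

    def __post_init__(self) -> None:
        self.vector()  # validate names/positivity eagerly


@dataclass(frozen=True)
class PacingProtocol:
    """S1 (and optional S1-S2) pacing.

    ``cl`` is the S1 cycle length in ms and ``n_beats`` the number of S1
    stimuli.  If ``s2_di`` is given, a single S2 stimulus follows the last
    S1 at ``last S1 onset + APD90(last S1) + s2_offset + s2_di``.
    Stimulus amplitude/duration defaults are per model: an inward current of
    2,000 pA for 2 ms (Courtemanche) and 750/C_m pA/pF for 6 ms (Maleckar).
    """

    cl: float = 1000.0
    n_beats: int = 40
    s2_di: float | None = None
    s2_offset: float = 10.0
    stim_amplitude: float | None = None  # pA (total inward current), None = model default
    stim_duration: float | None = None   # ms, None = model default

    def __post_init__(self) -> None:
        if self.cl <= 0:
            raise ValueError("cycle length must be positive")
        if self.n_beats < 1:
            raise ValueError("at least one S1 beat is required")
        if self.s2_di is not None and not (0.0 < self.s2_di <= 2000.0):
            raise ValueError("S2 diastolic interval out of range")


@dataclass(frozen=True)
class SolverSettings:
    rtol: float = 1e-6
    atol: float = 1e-6
    max_step: float = 0.5  # ms
    method: str = "adaptive-rl"  # "adaptive-rk" and "lsoda" are cross-check paths

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0 or self.max_step <= 0:
            raise ValueError("solver tolerances and max step must be positive")


@dataclass
class Trace:
    """Simulated time course of one run."""

    time: np.ndarray          # ms, strictly increasing
    voltage: np.ndarray       # mV
    calcium: np.ndarray       # mM (intracellular [Ca2+]i)
    stim_times: np.ndarray    # ms, one entry per delivered stimulus
    activation_times: np.ndarray  # ms, time of max dV/dt after each stimulus
    model: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("trace time must be strictly increasing")
        if not np.all(np.isfinite(self.voltage)):
            raise ValueError("trace voltage contains non-finite values")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_ms": self.time, "V_mV": self.voltage, "Ca_mM": self.calcium}
        )

    def export_csv(self, path, sidecar: bool = True) -> None:
        self.to_frame().to_csv(path, index=False)
        if sidecar:
            side = {
                "model": self.model,
                "stim_times_ms": self.stim_times.tolist(),
                **{k: v for k, v in self.meta.items() if _jsonable(v)},
            }
            with open(str(path) + ".json", "w") as fh:
                json.dump(side, fh, indent=2)


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


# ---------------------------------------------------------------------------
# Courtemanche et al. 1998 right-hand side (time in ms, V in mV, conc in mM)
# ---------------------------------------------------------------------------
# state: 0 V, 1 m, 2 h, 3 j, 4 oa, 5 oi, 6 ua, 7 ui, 8 xr, 9 xs, 10 d, 11 f,
#        12 fca, 13 u, 14 v, 15 w, 16 Nai, 17 Ki, 18 Cai, 19 Caup, 20 Carel
# params (design.py Stage-1 order):
#  0 G_Na 1 G_K1 2 G_to 3 fG_Kur 4 G_Kr 5 G_Ks 6 G_CaL 7 G_bNa 8 G_bCa
#  9 i_NaK_max 10 i_NaCa_max 11 i_pCa_max 12 K_rel 13 tau_tr 14 i_up_max
# 15 K_up 16 C_m 17 Na_o 18 K_o 19 Ca_o

CRN_N_STATES = 21

_CRN_VCELL = 20100.0   # um^3
_CRN_VI = 13668.0
_CRN_VUP = 1109.52
_CRN_VREL = 96.48


def courtemanche_initial_state() -> np.ndarray:
    return np.array(
        [
            -81.18, 2.908e-3, 9.649e-1, 9.775e-1, 3.043e-2, 9.992e-1,
            4.966e-3, 9.986e-1, 3.296e-5, 1.869e-2, 1.367e-4, 9.996e-1,
            7.755e-1, 0.0, 1.0, 9.992e-1, 11.17, 139.0, 1.013e-4,
            1.488, 1.488,
        ]
    )



@njit(cache=True, inline="always")
def _exp(x):
    """exp with overflow saturation (trial solver stages can be wild)."""
    if x > 700.0:
        return 1.7976931348623157e308
    return math.exp(x)


@njit(cache=True, fastmath=False)
def _crn_rates(t, y, p, istim, ginf, itau, dy):
    """Gate targets/rates (ginf, 1/tau) and non-gate derivatives.

    States with itau[i] > 0 are Hodgkin-Huxley gates obeying
    dy/dt = (ginf - y)/tau; for those dy[i] is not written here.
    State values are clamped to a wide physical bracket before rate
    evaluation so that rejected trial stages cannot overflow.
    """
    V = y[0]
    if V > 500.0:
        V = 500.0
    elif V < -500.0:
        V = -500.0
    m = y[1]; h = y[2]; jj = y[3]
    oa = y[4]; oi = y[5]; ua = y[6]; ui = y[7]
    xr = y[8]; xs = y[9]; d = y[10]; f = y[11]; fca = y[12]
    u = y[13]; vv = y[14]; w = y[15]
    Nai = y[16]; Ki = y[17]; Cai = y[18]; Caup = y[19]; Carel = y[20]

    gNa = p[0]; gK1 = p[1]; gto = p[2]; fGKur = p[3]; gKr = p[4]; gKs = p[5]
    gCaL = p[6]; gbNa = p[7]; gbCa = p[8]; iNaKmax = p[9]; iNaCamax = p[10]
    ipCamax = p[11]; Krel = p[12]; tautr = p[13]; iupmax = p[14]; Kup = p[15]
    Cm = p[16]; Nao = p[17]; Ko = p[18]; Cao = p[19]

    if Cai < 1e-10:
        Cai = 1e-10

    ENa = RTF * math.log(Nao / Nai)
    EK = RTF * math.log(Ko / Ki)
    ECa = 0.5 * RTF * math.log(Cao / Cai)

    # fast Na+ current
    INa = Cm * gNa * m * m * m * h * jj * (V - ENa)
    dV1 = V + 47.13
    if abs(dV1) < 1e-10:
        am = 3.2
    else:
        am = 0.32 * dV1 / (1.0 - _exp(-0.1 * dV1))
    bm = 0.08 * _exp(-V / 11.0)
    if V >= -40.0:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + _exp(-(V + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.3 * _exp(-2.535e-7 * V) / (1.0 + _exp(-0.1 * (V + 32.0)))
    else:
        ah = 0.135 * _exp(-(V + 80.0) / 6.8)
        bh = 3.56 * _exp(0.079 * V) + 3.1e5 * _exp(0.35 * V)
        aj = (
            (-1.2714e5 * _exp(0.2444 * V) - 3.474e-5 * _exp(-0.04391 * V))
            * (V + 37.78)
            / (1.0 + _exp(0.311 * (V + 79.23)))
        )
        bj = 0.1212 * _exp(-0.01052 * V) / (1.0 + _exp(-0.1378 * (V + 40.14)))

    # inward rectifier
    IK1 = Cm * gK1 * (V - EK) / (1.0 + _exp(0.07 * (V + 80.0)))

    # transient outward
    Ito = Cm * gto * oa * oa * oa * oi * (V - EK)
    KQ10 = 3.0
    a_oa = 0.65 / (_exp(-(V + 10.0) / 8.5) + _exp(-(V - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + _exp((V + 82.0) / 17.0))
    tau_oa = 1.0 / ((a_oa + b_oa) * KQ10)
    oa_inf = 1.0 / (1.0 + _exp(-(V + 20.47) / 17.54))
    a_oi = 1.0 / (18.53 + _exp((V + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + _exp(-(V + 1.26) / 7.44))
    tau_oi = 1.0 / ((a_oi + b_oi) * KQ10)
    oi_inf = 1.0 / (1.0 + _exp((V + 43.1) / 5.3))

    # ultra-rapid delayed rectifier (Kv1.5); fGKur scales the conductance
    gKur = 0.005 + 0.05 / (1.0 + _exp(-(V - 15.0) / 13.0))
    IKur = Cm * fGKur * gKur * ua * ua * ua * ui * (V - EK)
    a_ua = 0.65 / (_exp(-(V + 10.0) / 8.5) + _exp(-(V - 30.0) / 59.0))
    b_ua = 0.65 / (2.5 + _exp((V + 82.0) / 17.0))
    tau_ua = 1.0 / ((a_ua + b_ua) * KQ10)
    ua_inf = 1.0 / (1.0 + _exp(-(V + 30.3) / 9.6))
    a_ui = 1.0 / (21.0 + _exp(-(V - 185.0) / 28.0))
    b_ui = _exp((V - 158.0) / 16.0)
    tau_ui = 1.0 / ((a_ui + b_ui) * KQ10)
    ui_inf = 1.0 / (1.0 + _exp((V - 99.45) / 27.48))

    # rapid delayed rectifier
    IKr = Cm * gKr * xr * (V - EK) / (1.0 + _exp((V + 15.0) / 22.4))
    dV2 = V + 14.1
    if abs(dV2) < 1e-10:
        a_xr = 0.0015
    else:
        a_xr = 0.0003 * dV2 / (1.0 - _exp(-dV2 / 5.0))
    dV3 = V - 3.3328
    if abs(dV3) < 1e-10:
        b_xr = 7.3898e-5 * 5.1237
    else:
        b_xr = 7.3898e-5 * dV3 / (_exp(dV3 / 5.1237) - 1.0)
    tau_xr = 1.0 / (a_xr + b_xr)
    xr_inf = 1.0 / (1.0 + _exp(-dV2 / 6.5))

    # slow delayed rectifier
    IKs = Cm * gKs * xs * xs * (V - EK)
    dV4 = V - 19.9
    if abs(dV4) < 1e-10:
        a_xs = 0.00068
        b_xs = 0.000315
    else:
        a_xs = 4e-5 * dV4 / (1.0 - _exp(-dV4 / 17.0))
        b_xs = 3.5e-5 * dV4 / (_exp(dV4 / 9.0) - 1.0)
    tau_xs = 0.5 / (a_xs + b_xs)
    xs_inf = 1.0 / math.sqrt(1.0 + _exp(-dV4 / 12.7))

    # L-type Ca2+ current
    ICaL = Cm * gCaL * d * f * fca * (V - 65.0)
    dV5 = V + 10.0
    if abs(dV5) < 1e-10:
        tau_d = 1.0 / (0.035 * 6.24 * 2.0)  # limit 2.289
    else:
        e5 = _exp(-dV5 / 6.24)
        tau_d = (1.0 - e5) / (0.035 * dV5 * (1.0 + e5))
    d_inf = 1.0 / (1.0 + _exp(-dV5 / 8.0))
    tau_f = 9.0 / (0.0197 * _exp(-0.0337 * 0.0337 * dV5 * dV5) + 0.02)
    f_inf = 1.0 / (1.0 + _exp((V + 28.0) / 6.9))
    fca_inf = 1.0 / (1.0 + Cai / 0.00035)
    tau_fca = 2.0

    # pumps and exchangers
    sigma = (_exp(Nao / 67.3) - 1.0) / 7.0
    fNaK = 1.0 / (
        1.0
        + 0.1245 * _exp(-0.1 * V / RTF)
        + 0.0365 * sigma * _exp(-V / RTF)
    )
    INaK = (
        Cm * iNaKmax * fNaK * (1.0 / (1.0 + (10.0 / Nai) ** 1.5)) * Ko / (Ko + 1.5)
    )
    g = 0.35
    expg = _exp(g * V / RTF)
    expg1 = _exp((g - 1.0) * V / RTF)
    INaCa = (
        Cm
        * iNaCamax
        * (expg * Nai ** 3 * Cao - expg1 * Nao ** 3 * Cai)
        / (
            (87.5 ** 3 + Nao ** 3)
            * (1.38 + Cao)
            * (1.0 + 0.1 * expg1)
        )
    )
    IpCa = Cm * ipCamax * Cai / (0.0005 + Cai)
    IbNa = Cm * gbNa * (V - ENa)
    IbCa = Cm * gbCa * (V - ECa)

    # SR release / uptake (concentration fluxes in mM/ms)
    Irel = Krel * u * u * vv * w * (Carel - Cai)
    Iup = iupmax / (1.0 + Kup / Cai)
    Iupleak = iupmax * Caup / 15.0
    Itr = (Caup - Carel) / tautr

    Fn = 1e3 * (
        1e-15 * _CRN_VREL * Irel
        - 1e-15 / (2.0 * F) * (0.5 * ICaL - 0.2 * INaCa)
    )
    ex = _exp(-(Fn - 3.4175e-13) / 13.67e-16)
    u_inf = 1.0 / (1.0 + ex)
    tau_u = 8.0
    v_inf = 1.0 - 1.0 / (1.0 + _exp(-(Fn - 6.835e-14) / 13.67e-16))
    tau_v = 1.91 + 2.09 / (1.0 + ex)
    w_inf = 1.0 - 1.0 / (1.0 + _exp(-(V - 40.0) / 17.0))
    dV6 = V - 7.9
    if abs(dV6) < 1e-10:
        tau_w = 6.0 * 0.2 / 1.3
    else:
        e6 = _exp(-dV6 / 5.0)
        tau_w = 6.0 * (1.0 - e6) / ((1.0 + 0.3 * e6) * dV6)

    Iion = (
        INa + IK1 + Ito + IKur + IKr + IKs + ICaL + IpCa + INaK + INaCa + IbNa + IbCa
    )
    dy[0] = -(Iion + istim) / Cm

    itau[1] = am + bm; ginf[1] = am / itau[1]
    itau[2] = ah + bh; ginf[2] = ah / itau[2]
    itau[3] = aj + bj; ginf[3] = aj / itau[3]
    itau[4] = 1.0 / tau_oa; ginf[4] = oa_inf
    itau[5] = 1.0 / tau_oi; ginf[5] = oi_inf
    itau[6] = 1.0 / tau_ua; ginf[6] = ua_inf
    itau[7] = 1.0 / tau_ui; ginf[7] = ui_inf
    itau[8] = 1.0 / tau_xr; ginf[8] = xr_inf
    itau[9] = 1.0 / tau_xs; ginf[9] = xs_inf
    itau[10] = 1.0 / tau_d; ginf[10] = d_inf
    itau[11] = 1.0 / tau_f; ginf[11] = f_inf
    itau[12] = 1.0 / tau_fca; ginf[12] = fca_inf
    itau[13] = 1.0 / tau_u; ginf[13] = u_inf
    itau[14] = 1.0 / tau_v; ginf[14] = v_inf
    itau[15] = 1.0 / tau_w; ginf[15] = w_inf

    # intracellular Na+/K+ held constant (stabilising modification)
    dy[16] = 0.0
    dy[17] = 0.0

    B1 = (2.0 * INaCa - IpCa - ICaL - IbCa) / (2.0 * F * _CRN_VI) + (
        _CRN_VUP * (Iupleak - Iup) + Irel * _CRN_VREL
    ) / _CRN_VI
    B2 = (
        1.0
        + 0.07 * 0.0005 / ((Cai + 0.0005) * (Cai + 0.0005))
        + 0.05 * 0.00238 / ((Cai + 0.00238) * (Cai + 0.00238))
    )
    dy[18] = B1 / B2
    dy[19] = Iup - Iupleak - Itr * _CRN_VREL / _CRN_VUP
    dy[20] = (Itr - Irel) / (1.0 + 10.0 * 0.8 / ((Carel + 0.8) * (Carel + 0.8)))


@njit(cache=True)
def _crn_currents(t, y, p):
    """Selected membrane currents (pA): IKur, ICaL, IKr (for mechanism plots)."""
    V = y[0]
    ua = y[6]; ui = y[7]; xr = y[8]; d = y[10]; f = y[11]; fca = y[12]
    Ki = y[17]
    Cm = p[16]; Ko = p[18]
    EK = RTF * math.log(Ko / Ki)
    gKur = 0.005 + 0.05 / (1.0 + _exp(-(V - 15.0) / 13.0))
    IKur = Cm * p[3] * gKur * ua ** 3 * ui * (V - EK)
    ICaL = Cm * p[6] * d * f * fca * (V - 65.0)
    IKr = Cm * p[4] * xr * (V - EK) / (1.0 + _exp((V + 15.0) / 22.4))
    return IKur, ICaL, IKr


# ---------------------------------------------------------------------------
# Maleckar et al. 2009 (Nygren-family) right-hand side
# (internally time in seconds, V in mV, currents in pA, conc in mM)
# ---------------------------------------------------------------------------
# state: 0 V, 1 m, 2 h1, 3 h2, 4 dL, 5 fL1, 6 fL2, 7 r, 8 s, 9 a_ur, 10 i_ur,
#        11 n, 12 pa, 13 Nai, 14 Ki, 15 Cai, 16 Cad, 17 Caup, 18 Carel,
#        19 Nac, 20 Kc, 21 Cac, 22 OC, 23 OTC, 24 OTMgC, 25 OTMgMg, 26 OCalse,
#        27 F1, 28 F2
# params (design.py Stage-1 order):
#  0 P_Na 1 G_K1 2 G_t 3 G_Kur 4 G_Kr 5 G_Ks 6 G_CaL 7 G_bNa 8 G_bCa
#  9 i_NaK_max 10 K_NaCa 11 i_pCa_max 12 alpha_rel 13 tau_tr 14 i_up_max
# 15 K_cyca 16 K_srca 17 K_xcs 18 C_m 19 Na_o 20 K_o 21 Ca_o

MAL_N_STATES = 29

_MAL_VOLI = 0.005884       # nL
_MAL_VOLC = 0.136 * 0.005884
_MAL_VOLD = 0.02 * 0.005884
_MAL_VOLREL = 0.0000441
_MAL_VOLUP = 0.0003969
_MAL_TAU_NA = 14.3         # s
_MAL_TAU_K = 10.0
_MAL_TAU_CA = 24.7
_MAL_TAU_DI = 0.01
_MAL_MGI = 2.5
_MAL_PHI_NA_EN = -1.68     # pA electroneutral Na+ influx

# Nygren-family unit system: F in C/mol with volumes in nL gives pA<->mM/s
# conversions directly; T = 306.15 K.
_MAL_F = 96487.0
_MAL_RTF = 8314.0 * 306.15 / 96487.0  # ~26.38 mV


def maleckar_initial_state() -> np.ndarray:
    return np.array(
        [
            -74.2525, 3.2017e-3, 0.8814, 0.8742, 1.3e-5, 0.9986, 0.9986,
            1.0678e-3, 0.949, 3.67e-4, 0.9673, 4.8357e-3, 1.0e-4,
            8.5547, 129.435, 6.729e-5, 7.2495e-5, 0.6646, 0.6465,
            130.011, 5.3581, 1.8147, 0.0275, 0.0133, 0.1961, 0.7094,
            0.4369, 0.4284, 0.0028,
        ]
    )


@njit(cache=True, fastmath=False)
def _mal_rates(t, y, p, istim, ginf, itau, dy):
    V = y[0]
    if V > 500.0:
        V = 500.0
    elif V < -500.0:
        V = -500.0
    m = y[1]; h1 = y[2]; h2 = y[3]
    dL = y[4]; fL1 = y[5]; fL2 = y[6]
    r = y[7]; s = y[8]; aur = y[9]; iur = y[10]
    n = y[11]; pa = y[12]
    Nai = y[13]; Ki = y[14]; Cai = y[15]; Cad = y[16]
    Caup = y[17]; Carel = y[18]
    Nac = y[19]; Kc = y[20]; Cac = y[21]
    OC = y[22]; OTC = y[23]; OTMgC = y[24]; OTMgMg = y[25]; OCalse = y[26]
    F1 = y[27]; F2 = y[28]

    PNa = p[0]; gK1 = p[1]; gt = p[2]; gKur = p[3]; gKr = p[4]; gKs = p[5]
    gCaL = p[6]; gbNa = p[7]; gbCa = p[8]; iNaKmax = p[9]; kNaCa = p[10]
    ipCamax = p[11]; arel = p[12]; tautr = p[13]; iupmax = p[14]
    Kcyca = p[15]; Ksrca = p[16]; Kxcs = p[17]; Cm = p[18]
    Nab = p[19]; Kb = p[20]; Cab = p[21]

    if Cai < 1e-10:
        Cai = 1e-10
    if Cad < 1e-10:
        Cad = 1e-10
    if Nai < 1e-6:
        Nai = 1e-6
    if Ki < 1e-6:
        Ki = 1e-6
    if Nac < 1e-6:
        Nac = 1e-6
    if Kc < 1e-6:
        Kc = 1e-6
    if Cac < 1e-10:
        Cac = 1e-10
    if Carel < 0.0:
        Carel = 0.0
    if Caup < 0.0:
        Caup = 0.0

    ENa = _MAL_RTF * math.log(Nac / Nai)
    EK = _MAL_RTF * math.log(Kc / Ki)
    ECa = 0.5 * _MAL_RTF * math.log(Cac / Cai)

    # fast Na+ current (GHK-like, permeability formulation);
    # V/(exp(V/_MAL_RTF) - 1) -> _MAL_RTF as V -> 0
    hh = 0.9 * h1 + 0.1 * h2
    if abs(V) < 1e-7:
        drive = _MAL_RTF
    else:
        drive = V / (_exp(V / _MAL_RTF) - 1.0)
    INa = (
        PNa * m ** 3 * hh * Nac * _MAL_F / _MAL_RTF * drive
        * (_exp((V - ENa) / _MAL_RTF) - 1.0)
    )
    m_inf = 1.0 / (1.0 + _exp(-(V + 27.12) / 8.21))
    tau_m = 4.2e-5 * _exp(-(((V + 25.57) / 28.8) ** 2)) + 2.4e-5
    h_inf = 1.0 / (1.0 + _exp((V + 63.6) / 5.3))
    tau_h1 = 0.03 / (1.0 + _exp((V + 35.1) / 3.2)) + 0.0003
    tau_h2 = 0.12 / (1.0 + _exp((V + 35.1) / 3.2)) + 0.003

    # L-type Ca2+ current
    fca = Cad / (Cad + 0.025)
    ICaL = gCaL * dL * (fca * fL1 + (1.0 - fca) * fL2) * (V - 60.0)
    dL_inf = 1.0 / (1.0 + _exp(-(V + 9.0) / 5.8))
    tau_dL = 0.0027 * _exp(-(((V + 35.0) / 30.0) ** 2)) + 0.002
    fL_inf = 1.0 / (1.0 + _exp((V + 27.4) / 7.1))
    tau_fL1 = 0.161 * _exp(-(((V + 40.0) / 14.4) ** 2)) + 0.01
    tau_fL2 = 1.3323 * _exp(-(((V + 40.0) / 14.2) ** 2)) + 0.0626

    # transient outward K+ current
    It = gt * r * s * (V - EK)
    r_inf = 1.0 / (1.0 + _exp(-(V - 1.0) / 11.0))
    tau_r = 0.0035 * _exp(-((V / 30.0) ** 2)) + 0.0015
    s_inf = 1.0 / (1.0 + _exp((V + 40.5) / 11.5))
    tau_s = 0.025635 * _exp(-(((V + 52.45) / 15.8827) ** 2)) + 0.01414

    # ultra-rapid K+ current (Kv1.5)
    IKur = gKur * aur * iur * (V - EK)
    aur_inf = 1.0 / (1.0 + _exp(-(V + 6.0) / 8.6))
    tau_aur = 0.009 / (1.0 + _exp((V + 5.0) / 12.0)) + 0.0005
    iur_inf = 1.0 / (1.0 + _exp((V + 7.5) / 10.0))
    tau_iur = 0.59 / (1.0 + _exp((V + 60.0) / 10.0)) + 3.05

    # delayed rectifiers
    IKs = gKs * n * (V - EK)
    n_inf = 1.0 / (1.0 + _exp(-(V - 19.9) / 12.7))
    tau_n = 0.7 + 0.4 * _exp(-(((V - 20.0) / 20.0) ** 2))
    pip = 1.0 / (1.0 + _exp((V + 55.0) / 24.0))
    IKr = gKr * pa * pip * (V - EK)
    pa_inf = 1.0 / (1.0 + _exp(-(V + 15.0) / 6.0))
    tau_pa = 0.03118 + 0.21718 * _exp(-(((V + 20.1376) / 22.1996) ** 2))

    # inward rectifier
    IK1 = (
        gK1
        * Kc ** 0.4457
        * (V - EK)
        / (1.0 + _exp(1.5 * (V - EK + 3.6) / _MAL_RTF))
    )

    # background, pump and exchanger currents
    IbNa = gbNa * (V - ENa)
    IbCa = gbCa * (V - ECa)
    INaK = (
        iNaKmax
        * Kc
        / (Kc + 1.0)
        * Nai ** 1.5
        / (Nai ** 1.5 + 11.0 ** 1.5)
        * (V + 150.0)
        / (V + 200.0)
    )
    ICaP = ipCamax * Cai / (Cai + 0.0002)
    gam = 0.45
    INaCa = (
        kNaCa
        * (
            Nai ** 3 * Cac * _exp(gam * V / _MAL_RTF)
            - Nac ** 3 * Cai * _exp((gam - 1.0) * V / _MAL_RTF)
        )
        / (1.0 + 0.0003 * (Nac ** 3 * Cai + Nai ** 3 * Cac))
    )

    # diadic space exchange and SR fluxes (currents in pA)
    Idi = (Cad - Cai) * 2.0 * _MAL_F * _MAL_VOLD / _MAL_TAU_DI
    Iup = (
        iupmax
        * (Cai / Kcyca - Kxcs * Kxcs * Caup / Ksrca)
        / ((Cai + Kcyca) / Kcyca + Kxcs * (Caup + Ksrca) / Ksrca)
    )
    Itr = (Caup - Carel) * 2.0 * _MAL_F * _MAL_VOLREL / tautr
    Irel = arel * (F2 / (F2 + 0.25)) ** 2 * (Carel - Cai)

    r_act = 203.8 * (
        (Cai / (Cai + 0.0003)) ** 4 + (Cad / (Cad + 0.003)) ** 4
    )
    r_inact = 33.96 + 339.6 * (Cai / (Cai + 0.0003)) ** 4

    # buffer occupancies (rates per second)
    dOC = 2.0e5 * Cai * (1.0 - OC) - 476.0 * OC
    dOTC = 7.84e4 * Cai * (1.0 - OTC) - 392.0 * OTC
    dOTMgC = 2.0e5 * Cai * (1.0 - OTMgC - OTMgMg) - 6.6 * OTMgC
    dOTMgMg = 2.0e3 * _MAL_MGI * (1.0 - OTMgC - OTMgMg) - 666.0 * OTMgMg
    dOCalse = 480.0 * Carel * (1.0 - OCalse) - 400.0 * OCalse

    Iion = (
        INa + ICaL + It + IKur + IK1 + IKr + IKs + IbNa + IbCa + INaK + ICaP + INaCa
    )
    dy[0] = -1000.0 * (Iion + istim) / Cm  # mV/s

    itau[1] = 1.0 / tau_m; ginf[1] = m_inf
    itau[2] = 1.0 / tau_h1; ginf[2] = h_inf
    itau[3] = 1.0 / tau_h2; ginf[3] = h_inf
    itau[4] = 1.0 / tau_dL; ginf[4] = dL_inf
    itau[5] = 1.0 / tau_fL1; ginf[5] = fL_inf
    itau[6] = 1.0 / tau_fL2; ginf[6] = fL_inf
    itau[7] = 1.0 / tau_r; ginf[7] = r_inf
    itau[8] = 1.0 / tau_s; ginf[8] = s_inf
    itau[9] = 1.0 / tau_aur; ginf[9] = aur_inf
    itau[10] = 1.0 / tau_iur; ginf[10] = iur_inf
    itau[11] = 1.0 / tau_n; ginf[11] = n_inf
    itau[12] = 1.0 / tau_pa; ginf[12] = pa_inf

    dy[13] = -(INa + IbNa + 3.0 * INaK + 3.0 * INaCa + _MAL_PHI_NA_EN) / (
        _MAL_VOLI * _MAL_F
    )
    dy[14] = -(It + IKur + IK1 + IKr + IKs - 2.0 * INaK) / (_MAL_VOLI * _MAL_F)
    dy[15] = -(-Idi + IbCa + ICaP - 2.0 * INaCa + Iup - Irel) / (
        2.0 * _MAL_VOLI * _MAL_F
    ) - (0.045 * dOC + 0.08 * dOTC + 0.16 * dOTMgC)
    dy[16] = -(ICaL + Idi) / (2.0 * _MAL_VOLD * _MAL_F)
    dy[17] = (Iup - Itr) / (2.0 * _MAL_VOLUP * _MAL_F)
    dy[18] = (Itr - Irel) / (2.0 * _MAL_VOLREL * _MAL_F) - 31.0 * dOCalse

    dy[19] = (Nab - Nac) / _MAL_TAU_NA + (
        INa + IbNa + 3.0 * INaK + 3.0 * INaCa + _MAL_PHI_NA_EN
    ) / (_MAL_VOLC * _MAL_F)
    dy[20] = (Kb - Kc) / _MAL_TAU_K + (It + IKur + IK1 + IKr + IKs - 2.0 * INaK) / (
        _MAL_VOLC * _MAL_F
    )
    dy[21] = (Cab - Cac) / _MAL_TAU_CA + (ICaL + IbCa + ICaP - 2.0 * INaCa) / (
        2.0 * _MAL_VOLC * _MAL_F
    )

    dy[22] = dOC
    dy[23] = dOTC
    dy[24] = dOTMgC
    dy[25] = dOTMgMg
    dy[26] = dOCalse
    dy[27] = 0.815 * (1.0 - F1 - F2) - r_act * F1
    dy[28] = r_act * F1 - r_inact * F2


@njit(cache=True)
def _mal_currents(t, y, p):
    """Selected membrane currents (pA): IKur, ICaL, IKr."""
    V = y[0]
    dL = y[4]; fL1 = y[5]; fL2 = y[6]
    aur = y[9]; iur = y[10]; pa = y[12]
    Ki = y[14]; Cad = y[16]; Kc = y[20]
    EK = _MAL_RTF * math.log(Kc / Ki)
    fca = Cad / (Cad + 0.025)
    IKur = p[3] * aur * iur * (V - EK)
    ICaL = p[6] * dL * (fca * fL1 + (1.0 - fca) * fL2) * (V - 60.0)
    pip = 1.0 / (1.0 + _exp((V + 55.0) / 24.0))
    IKr = p[4] * pa * pip * (V - EK)
    return IKur, ICaL, IKr


# ---------------------------------------------------------------------------
# Adaptive embedded Cash-Karp Runge-Kutta integrator (compiled per RHS)
# ---------------------------------------------------------------------------


def _make_integrator(rhs):
    @njit(cache=True)
    def integrate(y0, t0, t1, params, istim, rtol, atol, max_step, h0):
        """Integrate rhs from t0 to t1 with constant stimulus current.

        Returns (status, times, V, Ca_index_placeholder, y_end, h_last,
        n_recorded).  Recorded points are the accepted steps (step <=
        max_step), starting at t0.
        """
        nst = y0.shape[0]
        cap = 4096
        ts = np.empty(cap)
        ys = np.empty((cap, nst))
        y = y0.copy()
        t = t0
        ts[0] = t
        ys[0, :] = y
        nrec = 1

        k1 = np.empty(nst); k2 = np.empty(nst); k3 = np.empty(nst)
        k4 = np.empty(nst); k5 = np.empty(nst); k6 = np.empty(nst)
        ytmp = np.empty(nst)
        y5 = np.empty(nst)
        errv = np.empty(nst)

        h = min(h0, max_step, t1 - t0)
        if h <= 0.0:
            h = min(max_step, t1 - t0)
        hmin = 1e-10
        status = 0

        rhs(t, y, params, istim, k1)
        while t < t1 - 1e-12:
            if h > max_step:
                h = max_step
            if t + h > t1:
                h = t1 - t

            # Cash-Karp tableau
            for i in range(nst):
                ytmp[i] = y[i] + h * 0.2 * k1[i]
            rhs(t + 0.2 * h, ytmp, params, istim, k2)
            for i in range(nst):
                ytmp[i] = y[i] + h * (3.0 / 40.0 * k1[i] + 9.0 / 40.0 * k2[i])
            rhs(t + 0.3 * h, ytmp, params, istim, k3)
            for i in range(nst):
                ytmp[i] = y[i] + h * (0.3 * k1[i] - 0.9 * k2[i] + 1.2 * k3[i])
            rhs(t + 0.6 * h, ytmp, params, istim, k4)
            for i in range(nst):
                ytmp[i] = y[i] + h * (
                    -11.0 / 54.0 * k1[i]
                    + 2.5 * k2[i]
                    - 70.0 / 27.0 * k3[i]
                    + 35.0 / 27.0 * k4[i]
                )
            rhs(t + h, ytmp, params, istim, k5)
            for i in range(nst):
                ytmp[i] = y[i] + h * (
                    1631.0 / 55296.0 * k1[i]
                    + 175.0 / 512.0 * k2[i]
                    + 575.0 / 13824.0 * k3[i]
                    + 44275.0 / 110592.0 * k4[i]
                    + 253.0 / 4096.0 * k5[i]
                )
            rhs(t + 0.875 * h, ytmp, params, istim, k6)

            errnorm = 0.0
            ok = True
            for i in range(nst):
                y5i = y[i] + h * (
                    37.0 / 378.0 * k1[i]
                    + 250.0 / 621.0 * k3[i]
                    + 125.0 / 594.0 * k4[i]
                    + 512.0 / 1771.0 * k6[i]
                )
                y4i = y[i] + h * (
                    2825.0 / 27648.0 * k1[i]
                    + 18575.0 / 48384.0 * k3[i]
                    + 13525.0 / 55296.0 * k4[i]
                    + 277.0 / 14336.0 * k5[i]
                    + 0.25 * k6[i]
                )
                y5[i] = y5i
                if not math.isfinite(y5i):
                    ok = False
                    break
                sc = atol + rtol * max(abs(y[i]), abs(y5i))
                e = (y5i - y4i) / sc
                errv[i] = e
                errnorm += e * e
            if ok:
                errnorm = math.sqrt(errnorm / nst)

            if ok and errnorm <= 1.0:
                t = t + h
                for i in range(nst):
                    y[i] = y5[i]
                if nrec == cap:
                    ts2 = np.empty(cap * 2)
                    ys2 = np.empty((cap * 2, nst))
                    ts2[:cap] = ts
                    ys2[:cap, :] = ys
                    ts = ts2
                    ys = ys2
                    cap *= 2
                ts[nrec] = t
                ys[nrec, :] = y
                nrec += 1
                rhs(t, y, params, istim, k1)
                if errnorm > 1e-14:
                    fac = 0.9 * errnorm ** (-0.2)
                    if fac > 5.0:
                        fac = 5.0
                    h *= fac
                else:
                    h *= 5.0
            else:
                if not ok:
                    h *= 0.1
                else:
                    fac = 0.9 * errnorm ** (-0.25)
                    if fac < 0.1:
                        fac = 0.1
                    h *= fac
                if h < hmin:
                    status = 1
                    break

        return status, ts[:nrec], ys[:nrec, :], y, h, nrec

    return integrate


CRN_GATE_SLICE = (1, 16)   # states 1..15 are Hodgkin-Huxley gates
MAL_GATE_SLICE = (1, 13)   # states 1..12


def _make_rhs(rates, nst):
    @njit(cache=True)
    def rhs(t, y, p, istim, dy):
        ginf = np.empty(nst)
        itau = np.zeros(nst)
        rates(t, y, p, istim, ginf, itau, dy)
        for i in range(nst):
            if itau[i] > 0.0:
                dy[i] = (ginf[i] - y[i]) * itau[i]
    return rhs


_crn_rhs = _make_rhs(_crn_rates, CRN_N_STATES)
_mal_rhs = _make_rhs(_mal_rates, MAL_N_STATES)
_crn_integrate = _make_integrator(_crn_rhs)
_mal_integrate = _make_integrator(_mal_rhs)


def _make_hybrid_integrator(rates, nst, dvdt_switch):
    """Adaptive integrator combining Rush-Larsen and Cash-Karp steps.

    Below ``V_SWITCH`` (diastole / late repolarization) the fast Na-gate
    kinetics make the system stiff while the solution is smooth: gates are
    advanced with exact exponential (Rush-Larsen) updates using midpoint
    rates and the remaining states with the explicit midpoint rule, with an
    embedded first-order error estimate.  Above ``V_SWITCH`` (upstroke and
    plateau) the gates are active and a fifth-order Cash-Karp step with
    embedded fourth-order error estimate is cheaper at tight tolerances.
    """
    V_SWITCH = -55.0          # mV
    DVDT_SWITCH = dvdt_switch  # |dV/dt| (per RHS time unit) forcing high order

    @njit(cache=True)
    def integrate(y0, t0, t1, params, istim, rtol, atol, max_step, h0):
        cap = 4096
        ts = np.empty(cap)
        ys = np.empty((cap, nst))
        y = y0.copy()
        t = t0
        ts[0] = t
        ys[0, :] = y
        nrec = 1

        ginf0 = np.empty(nst); itau0 = np.zeros(nst); dy0 = np.zeros(nst)
        ginfm = np.empty(nst); itaum = np.zeros(nst); dym = np.zeros(nst)
        gtmp = np.empty(nst); ttmp = np.zeros(nst)
        ym = np.empty(nst); y2 = np.empty(nst)
        k1 = np.empty(nst); k2 = np.empty(nst); k3 = np.empty(nst)
        k4 = np.empty(nst); k5 = np.empty(nst); k6 = np.empty(nst)

        h = min(h0, max_step, t1 - t0)
        if h <= 0.0:
            h = min(max_step, t1 - t0)
        hmin = 1e-10
        status = 0

        while t < t1 - 1e-12:
            if h > max_step:
                h = max_step
            if t + h > t1:
                h = t1 - t

            ok = True
            errnorm = 0.0
            rates(t, y, params, istim, ginf0, itau0, dy0)
            if y[0] < V_SWITCH and abs(dy0[0]) < DVDT_SWITCH:
                # --- Rush-Larsen / midpoint step -------------------------
                for i in range(nst):
                    if itau0[i] > 0.0:
                        ym[i] = ginf0[i] + (y[i] - ginf0[i]) * math.exp(
                            -0.5 * h * itau0[i]
                        )
                    else:
                        ym[i] = y[i] + 0.5 * h * dy0[i]
                rates(t + 0.5 * h, ym, params, istim, ginfm, itaum, dym)
                for i in range(nst):
                    if itaum[i] > 0.0:
                        y2i = ginfm[i] + (y[i] - ginfm[i]) * math.exp(-h * itaum[i])
                        y1i = ginf0[i] + (y[i] - ginf0[i]) * math.exp(-h * itau0[i])
                    else:
                        y2i = y[i] + h * dym[i]
                        y1i = y[i] + h * dy0[i]
                    if not math.isfinite(y2i):
                        ok = False
                        break
                    y2[i] = y2i
                    sc = atol + rtol * max(abs(y[i]), abs(y2i))
                    e = (y2i - y1i) / sc
                    errnorm += e * e
                expo = -0.5
            else:
                # --- Cash-Karp 4(5) step ---------------------------------
                for i in range(nst):
                    if itau0[i] > 0.0:
                        k1[i] = (ginf0[i] - y[i]) * itau0[i]
                    else:
                        k1[i] = dy0[i]
                for i in range(nst):
                    ym[i] = y[i] + h * 0.2 * k1[i]
                rates(t + 0.2 * h, ym, params, istim, gtmp, ttmp, k2)
                for i in range(nst):
                    if ttmp[i] > 0.0:
                        k2[i] = (gtmp[i] - ym[i]) * ttmp[i]
                    ttmp[i] = 0.0
                for i in range(nst):
                    ym[i] = y[i] + h * (3.0 / 40.0 * k1[i] + 9.0 / 40.0 * k2[i])
                rates(t + 0.3 * h, ym, params, istim, gtmp, ttmp, k3)
                for i in range(nst):
                    if ttmp[i] > 0.0:
                        k3[i] = (gtmp[i] - ym[i]) * ttmp[i]
                    ttmp[i] = 0.0
                for i in range(nst):
                    ym[i] = y[i] + h * (0.3 * k1[i] - 0.9 * k2[i] + 1.2 * k3[i])
                rates(t + 0.6 * h, ym, params, istim, gtmp, ttmp, k4)
                for i in range(nst):
                    if ttmp[i] > 0.0:
                        k4[i] = (gtmp[i] - ym[i]) * ttmp[i]
                    ttmp[i] = 0.0
                for i in range(nst):
                    ym[i] = y[i] + h * (
                        -11.0 / 54.0 * k1[i]
                        + 2.5 * k2[i]
                        - 70.0 / 27.0 * k3[i]
                        + 35.0 / 27.0 * k4[i]
                    )
                rates(t + h, ym, params, istim, gtmp, ttmp, k5)
                for i in range(nst):
                    if ttmp[i] > 0.0:
                        k5[i] = (gtmp[i] - ym[i]) * ttmp[i]
                    ttmp[i] = 0.0
                for i in range(nst):
                    ym[i] = y[i] + h * (
                        1631.0 / 55296.0 * k1[i]
                        + 175.0 / 512.0 * k2[i]
                        + 575.0 / 13824.0 * k3[i]
                        + 44275.0 / 110592.0 * k4[i]
                        + 253.0 / 4096.0 * k5[i]
                    )
                rates(t + 0.875 * h, ym, params, istim, gtmp, ttmp, k6)
                for i in range(nst):
                    if ttmp[i] > 0.0:
                        k6[i] = (gtmp[i] - ym[i]) * ttmp[i]
                    ttmp[i] = 0.0
                for i in range(nst):
                    y5i = y[i] + h * (
                        37.0 / 378.0 * k1[i]
                        + 250.0 / 621.0 * k3[i]
                        + 125.0 / 594.0 * k4[i]
                        + 512.0 / 1771.0 * k6[i]
                    )
                    y4i = y[i] + h * (
                        2825.0 / 27648.0 * k1[i]
                        + 18575.0 / 48384.0 * k3[i]
                        + 13525.0 / 55296.0 * k4[i]
                        + 277.0 / 14336.0 * k5[i]
                        + 0.25 * k6[i]
                    )
                    if not math.isfinite(y5i):
                        ok = False
                        break
                    y2[i] = y5i
                    sc = atol + rtol * max(abs(y[i]), abs(y5i))
                    e = (y5i - y4i) / sc
                    errnorm += e * e
                expo = -0.2
            if ok:
                errnorm = math.sqrt(errnorm / nst)

            if ok and errnorm <= 1.0:
                t = t + h
                for i in range(nst):
                    y[i] = y2[i]
                if nrec == cap:
                    ts2 = np.empty(cap * 2)
                    ys2 = np.empty((cap * 2, nst))
                    ts2[:cap] = ts
                    ys2[:cap, :] = ys
                    ts = ts2
                    ys = ys2
                    cap *= 2
                ts[nrec] = t
                ys[nrec, :] = y
                nrec += 1
                if errnorm > 1e-14:
                    fac = 0.9 * errnorm ** expo
                    if fac > 5.0:
                        fac = 5.0
                    h *= fac
                else:
                    h *= 5.0
            else:
                if not ok:
                    h *= 0.1
                else:
                    fac = 0.9 * errnorm ** (expo * 1.25)
                    if fac < 0.1:
                        fac = 0.1
                    h *= fac
                if h < hmin:
                    status = 1
                    break

        return status, ts[:nrec], ys[:nrec, :], y, h, nrec

    return integrate


_crn_rl_integrate = _make_hybrid_integrator(_crn_rates, CRN_N_STATES, 0.5)
_mal_rl_integrate = _make_hybrid_integrator(_mal_rates, MAL_N_STATES, 500.0)


# ---------------------------------------------------------------------------
# scipy LSODA reference path (BDF-type, used for solver cross-checks)
# ---------------------------------------------------------------------------


def _lsoda_segments(rhs, y0, segments, params, rtol, atol, max_step):
    from scipy.integrate import solve_ivp

    times, volts, cals = [], [], []
    y = np.asarray(y0, dtype=float)
    dy = np.empty_like(y)

    def f(t, yy, stim):
        rhs(t, yy, params, stim, dy)
        return dy.copy()

    for (t0, t1, stim) in segments:
        sol = solve_ivp(
            f, (t0, t1), y, method="LSODA", args=(stim,),
            rtol=rtol, atol=atol, max_step=max_step, dense_output=False,
        )
        if not sol.success:
            raise SimulationError(f"LSODA failed on [{t0}, {t1}]: {sol.message}")
        times.append(sol.t)
        volts.append(sol.y[0])
        cals.append(sol.y)
        y = sol.y[:, -1].copy()
    return times, cals, y


# ---------------------------------------------------------------------------
# public simulate()
# ---------------------------------------------------------------------------

_MODEL_TABLES = {
    "courtemanche": {
        "rhs": _crn_rhs,
        "integrate": None,  # filled below
        "integrate_rl": None,
        "initial": courtemanche_initial_state,
        "cai_index": 18,
        "time_scale": 1.0,   # RHS time unit in ms
        "stim_amp": 2000.0,  # pA inward
        "stim_dur": 2.0,     # ms
    },
    "maleckar": {
        "rhs": _mal_rhs,
        "integrate": None,
        "integrate_rl": None,
        "initial": maleckar_initial_state,
        "cai_index": 15,
        "time_scale": 1e-3,  # RHS time unit in s; trace times in ms
        "stim_amp": 750.0,
        "stim_dur": 6.0,
    },
}
_MODEL_TABLES["courtemanche"]["integrate"] = _crn_integrate
_MODEL_TABLES["maleckar"]["integrate"] = _mal_integrate
_MODEL_TABLES["courtemanche"]["integrate_rl"] = _crn_rl_integrate
_MODEL_TABLES["maleckar"]["integrate_rl"] = _mal_rl_integrate


def _run_segment(model, y, t0_ms, t1_ms, pvec, stim_pA, solver, h_last):
    tab = _MODEL_TABLES[model]
    scale = tab["time_scale"]
    if solver.method == "adaptive-rl":
        integrate = tab["integrate_rl"]
    elif solver.method == "adaptive-rk":
        integrate = tab["integrate"]
    elif solver.method != "lsoda":
        raise ValueError(f"unknown solver method {solver.method!r}")
    if solver.method == "lsoda":
        times, states, y_end = _lsoda_segments(
            tab["rhs"], y, [(t0_ms * scale, t1_ms * scale, stim_pA)],
            pvec, solver.rtol, solver.atol, solver.max_step * scale,
        )
        t = times[0] / scale
        ys = states[0].T
        return t, ys, y_end, h_last
    status, t, ys, y_end, h, _ = integrate(
        y, t0_ms * scale, t1_ms * scale, pvec, stim_pA,
        solver.rtol, solver.atol, solver.max_step * scale,
        h_last if h_last > 0 else solver.max_step * scale * 0.01,
    )
    if status != 0 or not np.all(np.isfinite(y_end)):
        raise SimulationError(
            f"{model} solver failure in segment [{t0_ms:.1f}, {t1_ms:.1f}] ms"
        )
    return t / scale, ys, y_end, h


def _apd90_online(t, v, stim_time):
    """APD90 of the beat stimulated at stim_time, from the trace so far.

    Uses the same conventions as the biomarker extractor: the activation is
    the maximum dV/dt within 50 ms of the stimulus, the resting potential
    is the mean over [activation-110, activation-100] ms, and the 90%
    repolarization level references the beat's own amplitude.
    """
    sel = t >= stim_time - 120.0
    tt, vv = t[sel], v[sel]
    win = (tt >= stim_time) & (tt <= stim_time + 50.0)
    if win.sum() < 3:
        return None
    dv = np.gradient(vv, tt)
    idx = np.where(win)[0]
    act = float(tt[idx[np.argmax(dv[idx])]])
    rest_sel = (tt >= act - 110.0) & (tt <= act - 100.0)
    rest = float(vv[rest_sel].mean()) if rest_sel.any() else float(vv[0])
    post = tt >= act
    if post.sum() < 3:
        return None
    vmax = float(vv[post].max())
    level = vmax - 0.9 * (vmax - rest)
    imax = np.argmax(vv[post])
    tpost, vpost = tt[post][imax:], vv[post][imax:]
    below = np.where(vpost <= level)[0]
    if below.size == 0:
        return None
    k = below[0]
    if k == 0:
        return float(tpost[0] - act)
    t_cross = tpost[k - 1] + (level - vpost[k - 1]) / (vpost[k] - vpost[k - 1]) * (
        tpost[k] - tpost[k - 1]
    )
    return float(t_cross - act)


def simulate(
    params: ParameterAssignment,
    protocol: PacingProtocol = PacingProtocol(),
    solver: SolverSettings = SolverSettings(),
    record_currents: bool = False,
) -> Trace:
    """Run one pacing protocol and return the full voltage/Ca2+ trace.

    S1 stimuli are delivered at ``t = 0, cl, 2*cl, ...``.  For an S1-S2
    protocol the S2 stimulus is delivered at ``last S1 onset + APD90(last
    S1) + offset + DI``; APD90 is measured online from the developing trace.
    """
    if params.model == "toy":
        return simulate_toy_ap(params, protocol)
    if params.model not in _MODEL_TABLES:
        raise ValueError(f"unknown model {params.model!r}")

    tab = _MODEL_TABLES[params.model]
    pvec = params.vector()
    stim_amp = protocol.stim_amplitude if protocol.stim_amplitude is not None else tab["stim_amp"]
    stim_dur = protocol.stim_duration if protocol.stim_duration is not None else tab["stim_dur"]
    istim = -abs(stim_amp)  # inward (depolarizing) current in pA

    y = tab["initial"]().copy()
    cl, nb = protocol.cl, protocol.n_beats
    ts_all: list[np.ndarray] = []
    ys_all: list[np.ndarray] = []
    stim_times = []
    h_last = -1.0

    def push(t, ys):
        if ts_all and t.size and abs(t[0] - ts_all[-1][-1]) < 1e-12:
            t = t[1:]
            ys = ys[1:]
        if t.size:
            ts_all.append(t)
            ys_all.append(ys)

    for b in range(nb):
        onset = b * cl
        stim_times.append(onset)
        t, ys, y, h_last = _run_segment(
            params.model, y, onset, onset + stim_dur, pvec, istim, solver, h_last
        )
        push(t, ys)
        if protocol.s2_di is not None and b == nb - 1:
            break
        t, ys, y, h_last = _run_segment(
            params.model, y, onset + stim_dur, onset + cl, pvec, 0.0, solver, h_last
        )
        push(t, ys)

    if protocol.s2_di is not None:
        onset = (nb - 1) * cl
        t_now = onset + stim_dur
        apd90 = None
        chunk = 25.0
        # integrate the final S1 beat in chunks until its APD90 is known
        while t_now < onset + 700.0 and apd90 is None:
            t, ys, y, h_last = _run_segment(
                params.model, y, t_now, t_now + chunk, pvec, 0.0, solver, h_last
            )
            push(t, ys)
            t_now += chunk
            tcat = np.concatenate([a for a in ts_all[-40:]])
            vcat = np.concatenate([a[:, 0] for a in ys_all[-40:]])
            apd90 = _apd90_online(tcat, vcat, onset)
        if apd90 is None:
            apd90 = 700.0  # failed to repolarize; flagged downstream
        t_s2 = onset + apd90 + protocol.s2_offset + protocol.s2_di
        if t_s2 > t_now:
            t, ys, y, h_last = _run_segment(
                params.model, y, t_now, t_s2, pvec, 0.0, solver, h_last
            )
            push(t, ys)
        stim_times.append(t_s2)
        t, ys, y, h_last = _run_segment(
            params.model, y, t_s2, t_s2 + stim_dur, pvec, istim, solver, h_last
        )
        push(t, ys)
        t, ys, y, h_last = _run_segment(
            params.model, y, t_s2 + stim_dur, t_s2 + cl, pvec, 0.0, solver, h_last
        )
        push(t, ys)

    time = np.concatenate(ts_all)
    states = np.vstack(ys_all)
    voltage = states[:, 0]
    calcium = states[:, tab["cai_index"]]
    if not np.all(np.isfinite(voltage)):
        bad = time[~np.isfinite(voltage)][0]
        raise SimulationError(f"{params.model} produced non-finite voltage at t={bad:.2f} ms")

    stim_times = np.asarray(stim_times, dtype=float)
    activation_times = _activation_after_stimuli(time, voltage, stim_times)

    meta: dict = {
        "protocol": {
            "cl": cl, "n_beats": nb, "s2_di": protocol.s2_di,
            "stim_amplitude_pA": stim_amp, "stim_duration_ms": stim_dur,
        },
        "solver": {"rtol": solver.rtol, "atol": solver.atol,
                   "max_step": solver.max_step, "method": solver.method},
        "parameters": dict(params.values),
        "final_state": y,
    }
    if record_currents:
        cur = _crn_currents if params.model == "courtemanche" else _mal_currents
        ikur = np.empty(time.size); ical = np.empty(time.size); ikr = np.empty(time.size)
        for i in range(time.size):
            ikur[i], ical[i], ikr[i] = cur(time[i], states[i], pvec)
        meta["currents"] = {"I_Kur": ikur, "I_CaL": ical, "I_Kr": ikr}

    return Trace(time, voltage, calcium, stim_times, activation_times,
                 model=params.model, meta=meta)


def _activation_after_stimuli(time, voltage, stim_times, window=100.0):
    acts = []
    dv = np.gradient(voltage, time)
    for st in stim_times:
        sel = (time >= st) & (time <= st + window)
        if sel.sum() < 3:
            acts.append(np.nan)
            continue
        idx = np.where(sel)[0]
        acts.append(float(time[idx[np.argmax(dv[idx])]]))
    return np.asarray(acts)


# ---------------------------------------------------------------------------
# toy action-potential generator (closed form)
# ---------------------------------------------------------------------------
#
# Per beat, with activation at the stimulus time t0:
#   upstroke:      V = rest + (peak - rest) * (t - t0)/t_up  on [t0, t0 + t_up]
#                  with t_up = (peak - rest)/upstroke_slope
#   repolarization V = peak - (peak - rest) * ((t - t0 - t_up)/T)^(1/q)
#                  on (t0 + t_up, t0 + t_up + T], then V = rest
# where T = apd_scale * (1 - restitution_slope * exp(-DI/100)) and q =
# plateau_shape (> 1 gives a plateau).  APD at x% repolarization is then
# exactly t_up + (x/100)^q * T.  The Ca2+ transient is a smooth pulse from
# Ca_base to Ca_base + Ca_amp peaking shortly after the upstroke.

_TOY_RESTITUTION_TAU = 100.0  # ms


def toy_apd(values: Mapping[str, float], frac: float, di: float | None = None) -> float:
    """Closed-form APD at repolarization fraction ``frac`` (e.g. 0.9)."""
    t_up = (values["peak_V"] - values["rest_V"]) / values["upstroke_slope"]
    T = values["apd_scale"]
    if di is not None:
        T = T * (1.0 - values["restitution_slope"] * math.exp(-di / _TOY_RESTITUTION_TAU))
    return t_up + frac ** values["plateau_shape"] * T


def _toy_beat(tloc, vals, T):
    rest = vals["rest_V"]; peak = vals["peak_V"]
    amp = peak - rest
    t_up = amp / vals["upstroke_slope"]
    q = vals["plateau_shape"]
    v = np.full_like(tloc, rest)
    up = (tloc >= 0) & (tloc <= t_up)
    v[up] = rest + amp * tloc[up] / t_up
    rep = (tloc > t_up) & (tloc <= t_up + T)
    v[rep] = peak - amp * ((tloc[rep] - t_up) / T) ** (1.0 / q)
    ca = vals["Ca_base"] + vals["Ca_amp"] * np.clip(
        (tloc - t_up) / (0.6 * T), 0.0, None
    ) * np.exp(1.0 - np.clip((tloc - t_up) / (0.6 * T), 0.0, None))
    ca[tloc < t_up] = vals["Ca_base"]
    ca[tloc > t_up + 2.0 * T] = vals["Ca_base"]
    return v, ca


def simulate_toy_ap(
    params: ParameterAssignment,
    protocol: PacingProtocol = PacingProtocol(),
    dt: float = 0.5,
) -> Trace:
    """Closed-form toy action potentials; every biomarker is analytic."""
    if params.model != "toy":
        raise ValueError("simulate_toy_ap requires a toy ParameterAssignment")
    vals = {k: float(v) for k, v in params.values.items()}
    if vals["apd_scale"] <= 0:
        raise ValueError("toy APD scale must be positive")
    if not (0.0 <= vals["restitution_slope"] < 1.0):
        raise ValueError("restitution slope must be in [0, 1)")

    cl, nb = protocol.cl, protocol.n_beats
    stim_times = [b * cl for b in range(nb)]
    # steady-state DI implied by the S1 train
    T1 = vals["apd_scale"]
    t_up = (vals["peak_V"] - vals["rest_V"]) / vals["upstroke_slope"]
    di_s1 = cl - (t_up + T1)
    T_s1 = vals["apd_scale"] * (
        1.0 - vals["restitution_slope"] * math.exp(-max(di_s1, 1.0) / _TOY_RESTITUTION_TAU)
    )

    segs_t, segs_v, segs_c = [], [], []
    for b, st in enumerate(stim_times):
        tloc = np.arange(0.0, cl, dt)
        v, ca = _toy_beat(tloc, vals, T_s1)
        segs_t.append(tloc + st)
        segs_v.append(v)
        segs_c.append(ca)

    if protocol.s2_di is not None:
        apd90_s1 = t_up + 0.9 ** vals["plateau_shape"] * T_s1
        t_s2 = stim_times[-1] + apd90_s1 + protocol.s2_offset + protocol.s2_di
        # truncate the final S1 cycle at the S2 onset
        last_t = segs_t[-1]
        keep = last_t < t_s2
        segs_t[-1] = last_t[keep]
        segs_v[-1] = segs_v[-1][keep]
        segs_c[-1] = segs_c[-1][keep]
        T_s2 = vals["apd_scale"] * (
            1.0 - vals["restitution_slope"] * math.exp(-protocol.s2_di / _TOY_RESTITUTION_TAU)
        )
        tloc = np.arange(0.0, cl, dt)
        v, ca = _toy_beat(tloc, vals, T_s2)
        segs_t.append(tloc + t_s2)
        segs_v.append(v)
        segs_c.append(ca)
        stim_times = stim_times + [t_s2]

    time = np.concatenate(segs_t)
    voltage = np.concatenate(segs_v)
    calcium = np.concatenate(segs_c)
    stim_arr = np.asarray(stim_times, dtype=float)
    acts = stim_arr + 0.5 * t_up  # max slope occurs within the linear upstroke
    meta = {
        "protocol": {"cl": cl, "n_beats": nb, "s2_di": protocol.s2_di},
        "parameters": vals,
        "toy_T_s1": T_s1,
    }
    return Trace(time, voltage, calcium, stim_arr, acts, model="toy", meta=meta)
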