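"""Action-potential and Ca2+-transient biomarkers, and the plausibility filter.

Eleven outputs characterize each simulator run, all taken from the final
analyzed beat: maximum upstroke slope dV/dt_max, peak voltage V_max, the
plateau/repolarization voltages V_20..V_80 (measured at 20..80% of APD_90
after the upstroke), APD_50 and APD_90 (durations to 50%/90% repolarization
of the amplitude), the resting potential RestV_m (mean voltage over a 10 ms
window 100 ms before the upstroke), and the Ca2+ transient extrema Ca_min
and Ca_max over the beat's cycle.

Runs showing unphysiological behavior are excluded from emulator design
data: pacemaking activity (spontaneous upstrokes outside stimulus windows),
a depolarized resting potential (> -60 mV), a long action potential
(APD_90 > 600 ms, which also covers failure to repolarize), or APD
alternans (the final beat pair differing by more than 5%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cell_models import Trace

__all__ = [
    "BIOMARKER_NAMES",
    "BiomarkerVector",
    "Activations",
    "ExclusionRecord",
    "detect_activations",
    "extract_biomarkers",
    "plausibility_filter",
]

BIOMARKER_NAMES = (
    "dVdt_max", "V_max", "V_20", "V_40", "V_60", "V_80",
    "APD_50", "APD_90", "RestV_m", "Ca_min", "Ca_max",
)

STIM_WINDOW = 50.0       # ms after a stimulus within which an upstroke counts as captured
SPONT_DVDT_MIN = 5.0     # mV/ms threshold for a spontaneous upstroke
REST_DEPOLARIZED = -60.0  # mV
APD90_LONG = 600.0       # ms
ALTERNANS_FRACTION = 0.05


@dataclass(frozen=True)
class BiomarkerVector:
    dVdt_max: float
    V_max: float
    V_20: float
    V_40: float
    V_60: float
    V_80: float
    APD_50: float
    APD_90: float
    RestV_m: float
    Ca_min: float
    Ca_max: float
    flags: tuple[str, ...] = ()

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in BIOMARKER_NAMES])

    def __post_init__(self) -> None:
        ok = np.isfinite(self.as_array()).all()
        if ok and not self.flags:
            if not (self.APD_50 < self.APD_90):
                raise ValueError("APD_50 must be smaller than APD_90")
            if self.Ca_min > self.Ca_max:
                raise ValueError("Ca_min must not exceed Ca_max")
            if not (self.V_max > self.RestV_m):
                raise ValueError("V_max must exceed RestV_m")


@dataclass(frozen=True)
class Activations:
    """Upstrokes split into stimulus-captured and spontaneous events."""

    captured: np.ndarray     # one entry per stimulus; NaN = no capture
    spontaneous: np.ndarray  # times of upstrokes outside stimulus windows

    @property
    def n_captured(self) -> int:
        return int(np.isfinite(self.captured).sum())


def _dvdt(trace: Trace) -> np.ndarray:
    return np.gradient(trace.voltage, trace.time)


def detect_activations(trace: Trace, window: float = STIM_WINDOW) -> Activations:
    """Locate genuine upstrokes: per-stimulus capture plus spontaneous events.

    The activation time of a captured beat is the time of maximum dV/dt in
    the ``window`` ms after its stimulus.  Upstrokes outside every stimulus
    window (dV/dt above ``SPONT_DVDT_MIN`` with a depolarized excursion)
    are reported separately as spontaneous, i.e. pacemaking.
    """
    t, v = trace.time, trace.voltage
    dv = _dvdt(trace)
    captured = np.full(trace.stim_times.size, np.nan)
    for k, st in enumerate(trace.stim_times):
        sel = (t >= st) & (t <= st + window)
        if sel.sum() < 3:
            continue
        idx = np.where(sel)[0]
        j = idx[np.argmax(dv[idx])]
        # genuine capture: substantial upstroke and depolarization relative
        # to the pre-stimulus voltage
        vref = v[max(idx[0] - 1, 0)]
        if dv[j] > 1.0 and v[idx].max() > vref + 10.0:
            captured[k] = t[j]

    in_window = np.zeros(t.size, dtype=bool)
    for st in trace.stim_times:
        in_window |= (t >= st - 1.0) & (t <= st + window)
    cand = np.where((dv > SPONT_DVDT_MIN) & ~in_window)[0]
    spont = []
    last = -np.inf
    for j in cand:
        if t[j] - last < 2.0 * window:
            continue
        seg = (t >= t[j]) & (t <= t[j] + window)
        if v[seg].max() > v[j] + 10.0:
            spont.append(t[j])
            last = t[j]
    return Activations(captured, np.asarray(spont))


def _interp_crossing(t0, v0, t1, v1, level):
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def extract_biomarkers(trace: Trace, beat: int = -1) -> BiomarkerVector:
    """Extract the 11 outputs from one beat of a trace.

    ``beat`` indexes the trace's stimuli (negative values count from the
    end; the default is the final beat, the one analyzed in both the S1 and
    S1-S2 protocols).  APD_x is the time from the activation (maximum
    dV/dt) to the first subsequent crossing of
    ``V_max - x% * (V_max - RestV_m)``, with linear interpolation between
    samples; V_p is the voltage at ``activation + p% * APD_90``.
    """
    nstim = trace.stim_times.size
    b = beat % nstim
    acts = detect_activations(trace)
    act = acts.captured[b]
    flags: list[str] = []
    if not np.isfinite(act):
        return BiomarkerVector(*([np.nan] * 11), flags=("no_capture",))

    t, v, ca = trace.time, trace.voltage, trace.calcium
    cyc_start = trace.stim_times[b]
    cyc_end = trace.stim_times[b + 1] if b + 1 < nstim else t[-1]

    # resting potential: 10 ms window ending 100 ms before the upstroke
    w0, w1 = act - 110.0, act - 100.0
    if w0 < t[0]:
        w0, w1 = t[0], min(t[0] + 10.0, act)
    rest_sel = (t >= w0) & (t <= w1)
    rest = float(v[rest_sel].mean()) if rest_sel.any() else float(v[0])

    dv = _dvdt(trace)
    up_sel = (t >= cyc_start) & (t <= act + STIM_WINDOW)
    dvdt_max = float(dv[up_sel].max())

    cyc = (t >= cyc_start) & (t <= cyc_end)
    post = (t >= act) & (t <= cyc_end)
    tp, vp = t[post], v[post]
    imax = int(np.argmax(vp))
    vmax = float(vp[imax])
    amp = vmax - rest

    def apd(frac):
        level = vmax - frac * amp
        seg_t, seg_v = tp[imax:], vp[imax:]
        below = np.where(seg_v <= level)[0]
        if below.size == 0:
            return np.nan
        k = int(below[0])
        if k == 0:
            return float(seg_t[0] - act)
        tc = _interp_crossing(seg_t[k - 1], seg_v[k - 1], seg_t[k], seg_v[k], level)
        return float(tc - act)

    apd50 = apd(0.5)
    apd90 = apd(0.9)
    if not np.isfinite(apd90):
        flags.append("failure_to_repolarize")

    def v_at(frac_of_apd90):
        if not np.isfinite(apd90):
            return np.nan
        return float(np.interp(act + frac_of_apd90 * apd90, t, v))

    camin = float(ca[cyc].min())
    camax = float(ca[cyc].max())

    return BiomarkerVector(
        dVdt_max=dvdt_max,
        V_max=vmax,
        V_20=v_at(0.2),
        V_40=v_at(0.4),
        V_60=v_at(0.6),
        V_80=v_at(0.8),
        APD_50=apd50,
        APD_90=apd90,
        RestV_m=rest,
        Ca_min=camin,
        Ca_max=camax,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class ExclusionRecord:
    keep: bool
    reasons: tuple[str, ...]
    beat_indices: tuple[int, ...]
    apd90_pair: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.keep and not self.reasons:
            raise ValueError("an excluded run must carry at least one reason")


def plausibility_filter(
    trace: Trace,
    final_biomarkers: BiomarkerVector | None = None,
    activations: Activations | None = None,
) -> ExclusionRecord:
    """Apply the design-data exclusion criteria to one run.

    A run is excluded if it shows pacemaking activity, a resting potential
    above -60 mV, APD_90 above 600 ms (failure to repolarize counts as a
    long action potential), or if the APD_90 of the final beat pair differs
    by more than 5% (alternans; the later beat is the denominator).  Runs
    missing the required beats are excluded as ``incomplete``.

    The filter judges the model's steady S1 behavior.  In an S1-S2 run the
    resting-potential and APD criteria are therefore evaluated on the final
    S1 beat and the alternans pair on the last two S1 beats: a premature S2
    beat legitimately shows a shortened APD, and its pre-stimulus window
    overlaps the previous repolarization at short diastolic intervals, so
    the S2 beat's own biomarkers are restitution measurements rather than
    evidence of pathology (a non-repolarizing S2 still excludes the run).
    """
    if activations is None:
        activations = detect_activations(trace)
    nstim = trace.stim_times.size
    if nstim < 2 or activations.n_captured < 2:
        return ExclusionRecord(False, ("incomplete",), ())
    if final_biomarkers is None:
        final_biomarkers = extract_biomarkers(trace, -1)
    is_s1s2 = trace.meta.get("protocol", {}).get("s2_di") is not None
    if is_s1s2 and nstim >= 3:
        steady = extract_biomarkers(trace, -2)   # final S1 beat
        prev = extract_biomarkers(trace, -3)
    else:
        steady = final_biomarkers
        prev = extract_biomarkers(trace, -2)

    reasons: list[str] = []
    if activations.spontaneous.size > 0:
        reasons.append("pacemaking")
    if np.isfinite(steady.RestV_m) and steady.RestV_m > REST_DEPOLARIZED:
        reasons.append("depolarized_rest")
    a_pair = steady.APD_90
    a_prev = prev.APD_90
    if not np.isfinite(a_pair) or a_pair > APD90_LONG or not np.isfinite(
        final_biomarkers.APD_90
    ):
        reasons.append("long_apd")
    if np.isfinite(a_pair) and np.isfinite(a_prev):
        if abs(a_prev - a_pair) / a_pair > ALTERNANS_FRACTION:
            reasons.append("alternans")
    elif "long_apd" not in reasons:
        reasons.append("long_apd")  # the pair is unusable: no repolarization
    pair = (float(a_prev), float(a_pair))
    return ExclusionRecord(
        keep=not reasons,
        reasons=tuple(reasons),
        beat_indices=(nstim - 2, nstim - 1),
        apd90_pair=pair,
    )
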