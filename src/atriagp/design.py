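"""Input-space definitions and Latin-hypercube experimental designs.

The sensitivity analysis varies maximum conductances, pump/exchanger rates,
Ca2+-handling parameters, cell capacitance and extracellular concentrations
of two human atrial cell models around their published defaults.  Each input
is varied over ``central * (1 +/- fraction)`` with fraction 0.50 for most
inputs, 0.25 for G_K1 and C_m, and 0.10 for extracellular concentrations,
and is affinely mapped to [0, 1] for emulation.  Stage 1 uses the full input
list; Stage 2 keeps only the inputs that dominate action-potential shape and
adds the diastolic interval (DI) of a final S2 beat as an extra input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InputSpec",
    "InputSpace",
    "DesignMatrix",
    "build_input_space",
    "normalize",
    "denormalize",
    "latin_hypercube",
    "PRINTED_RANGE_AUDIT",
]

# Sensitivity-analysis variance classes on the normalized [0,1] scale:
# +/-50% inputs -> 0.02, +/-25% inputs (G_K1, C_m) -> 0.04,
# +/-10% inputs (extracellular concentrations) -> 0.1.
_VARIANCE_BY_FRACTION = {0.50: 0.02, 0.25: 0.04, 0.10: 0.1}


@dataclass(frozen=True)
class InputSpec:
    """One uncertain model input.

    Parameters
    ----------
    name : str
        Input name (matches the cell-model parameter name).
    central : float
        Default (central) value in the model's own units.
    fraction : float
        Half-range as a fraction of the central value (0.50, 0.25 or 0.10).
    units : str
        Units of the raw value.
    variance : float
        Variance assigned to this input, in normalized units, when it is
        treated as uncertain in the sensitivity analysis.
    """

    name: str
    central: float
    fraction: float
    units: str
    variance: float

    @property
    def low(self) -> float:
        # min/max keeps low < high for negative central values (toy rest_V)
        return min(self.central * (1.0 - self.fraction), self.central * (1.0 + self.fraction))

    @property
    def high(self) -> float:
        return max(self.central * (1.0 - self.fraction), self.central * (1.0 + self.fraction))

    def __post_init__(self) -> None:
        if not (self.low < self.central < self.high):
            raise ValueError(f"degenerate range for input {self.name!r}")
        if self.variance <= 0:
            raise ValueError(f"variance must be > 0 for input {self.name!r}")


def _spec(name, central, fraction, units, variance=None) -> InputSpec:
    if variance is None:
        variance = _VARIANCE_BY_FRACTION[fraction]
    return InputSpec(name, central, fraction, units, variance)


# The diastolic interval input of Stage 2 is a protocol input with an
# absolute range of 50-450 ms; it is expressed here through an equivalent
# central value and fraction (250 ms +/- 80%) and carries the default
# variance class of the widely varied inputs.
_DI_SPEC = InputSpec("DI", 250.0, 0.8, "ms", 0.02)

_COURTEMANCHE_STAGE1: tuple[InputSpec, ...] = (
    _spec("G_Na", 7.8, 0.50, "nS/pF"),
    _spec("G_K1", 0.09, 0.25, "nS/pF"),
    _spec("G_to", 0.1652, 0.50, "nS/pF"),
    _spec("fG_Kur", 1.0, 0.50, "dimensionless"),
    _spec("G_Kr", 0.0294, 0.50, "nS/pF"),
    _spec("G_Ks", 0.1294, 0.50, "nS/pF"),
    _spec("G_CaL", 0.1237, 0.50, "nS/pF"),
    _spec("G_bNa", 0.000674, 0.50, "nS/pF"),
    _spec("G_bCa", 0.001131, 0.50, "nS/pF"),
    _spec("i_NaK_max", 0.5993, 0.50, "pA/pF"),
    _spec("i_NaCa_max", 1600.0, 0.50, "pA/pF"),
    _spec("i_pCa_max", 0.275, 0.50, "pA/pF"),
    # The published Courtemanche SR release rate constant is 30 /ms; the
    # design table's printed central value carries a decimal slip (0.30).
    _spec("K_rel", 30.0, 0.50, "1/ms"),
    _spec("tau_tr", 180.0, 0.50, "ms"),
    _spec("i_up_max", 0.005, 0.50, "mM/ms"),
    _spec("K_up", 0.00092, 0.50, "mM"),
    _spec("C_m", 100.0, 0.25, "pF"),
    _spec("Na_o", 140.0, 0.10, "mM"),
    _spec("K_o", 5.4, 0.10, "mM"),
    _spec("Ca_o", 1.8, 0.10, "mM"),
)

_MALECKAR_STAGE1: tuple[InputSpec, ...] = (
    _spec("P_Na", 0.0018, 0.50, "nL/s"),
    _spec("G_K1", 3.1, 0.25, "nS"),
    _spec("G_t", 8.25, 0.50, "nS"),
    _spec("G_Kur", 2.25, 0.50, "nS"),
    _spec("G_Kr", 0.5, 0.50, "nS"),
    _spec("G_Ks", 1.0, 0.50, "nS"),
    _spec("G_CaL", 6.75, 0.50, "nS"),
    _spec("G_bNa", 0.0605, 0.50, "nS"),
    _spec("G_bCa", 0.0590, 0.50, "nS"),
    _spec("i_NaK_max", 68.55, 0.50, "pA"),
    _spec("K_NaCa", 0.0750, 0.50, "pA/mM^4"),
    _spec("i_pCa_max", 4.0, 0.50, "pA"),
    _spec("alpha_rel", 200000.0, 0.50, "pA/mM"),
    _spec("tau_tr", 0.01, 0.50, "s"),
    _spec("i_up_max", 2800.0, 0.50, "pA"),
    _spec("K_cyca", 0.0003, 0.50, "mM"),
    _spec("K_srca", 0.5, 0.50, "mM"),
    _spec("K_xcs", 0.4, 0.50, "dimensionless"),
    _spec("C_m", 50.0, 0.25, "pF"),
    _spec("Na_o", 140.0, 0.10, "mM"),
    _spec("K_o", 5.4, 0.10, "mM"),
    _spec("Ca_o", 1.8, 0.10, "mM"),
)

# Closed-form toy action-potential generator (see cell_models.simulate_toy_ap).
_TOY_STAGE1: tuple[InputSpec, ...] = (
    _spec("rest_V", -80.0, 0.10, "mV", 0.1),
    _spec("peak_V", 20.0, 0.50, "mV"),
    _spec("upstroke_slope", 200.0, 0.50, "mV/ms"),
    _spec("apd_scale", 300.0, 0.50, "ms"),
    _spec("plateau_shape", 3.0, 0.50, "dimensionless"),
    _spec("Ca_base", 0.0001, 0.50, "mM"),
    _spec("Ca_amp", 0.0005, 0.50, "mM"),
    _spec("restitution_slope", 0.3, 0.50, "dimensionless"),
)

# Stage-2 subsets: inputs whose Stage-1 first-order index on action-potential
# shape/duration outputs exceeds 0.1, with Na-channel, extracellular and
# Ca2+-store inputs deliberately excluded.
_STAGE2_SUBSETS: dict[str, tuple[str, ...]] = {
    "courtemanche": (
        "G_K1", "G_to", "fG_Kur", "G_CaL", "G_bCa",
        "i_NaK_max", "i_NaCa_max", "i_pCa_max",
    ),
    "maleckar": ("G_K1", "G_t", "G_Kur", "G_CaL", "G_bCa", "i_NaK_max", "C_m"),
    "toy": ("apd_scale", "plateau_shape", "peak_V"),
}

_STAGE1_SPACES: dict[str, tuple[InputSpec, ...]] = {
    "courtemanche": _COURTEMANCHE_STAGE1,
    "maleckar": _MALECKAR_STAGE1,
    "toy": _TOY_STAGE1,
}

# Endpoints as printed in the source design table, recorded verbatim for
# audit.  Several rows are internally inconsistent with their percentage
# column (marked); ranges used by this package are always computed from the
# percentage rule central*(1 +/- fraction).
PRINTED_RANGE_AUDIT: tuple[tuple[str, str, float, float, bool], ...] = (
    ("courtemanche", "G_Na", 5.85, 11.70, False),
    ("courtemanche", "G_K1", 0.045, 0.018, True),
    ("courtemanche", "G_to", 0.0826, 0.0330, True),
    ("courtemanche", "K_rel", 0.15, 0.45, True),
    ("maleckar", "G_bNa", 0.303, 0.909, True),
    ("maleckar", "i_up_max", 1400.0, 4300.0, True),
)


@dataclass(frozen=True)
class InputSpace:
    """Ordered collection of uncertain inputs for one model and stage."""

    model: str
    stage: int
    specs: tuple[InputSpec, ...]
    fixed: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("input names must be unique")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    @property
    def dim(self) -> int:
        return len(self.specs)

    @property
    def low(self) -> np.ndarray:
        return np.array([s.low for s in self.specs])

    @property
    def high(self) -> np.ndarray:
        return np.array([s.high for s in self.specs])

    @property
    def central(self) -> np.ndarray:
        return np.array([s.central for s in self.specs])

    @property
    def variances(self) -> np.ndarray:
        return np.array([s.variance for s in self.specs])

    def spec(self, name: str) -> InputSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": self.model,
                "stage": self.stage,
                "inputs": [
                    {
                        "name": s.name,
                        "central": s.central,
                        "fraction": s.fraction,
                        "low": s.low,
                        "high": s.high,
                        "units": s.units,
                        "variance": s.variance,
                    }
                    for s in self.specs
                ],
                "fixed": dict(self.fixed),
            },
            indent=2,
        )


def build_input_space(model: str, stage: int = 1) -> InputSpace:
    """Return the input space for ``model`` ('courtemanche' | 'maleckar' | 'toy').

    Stage 1 spans every listed input.  Stage 2 keeps the action-potential
    shaping subset plus the diastolic interval DI (range 50-450 ms); all
    other Stage-1 inputs are recorded as fixed at their central value.
    """
    if model not in _STAGE1_SPACES:
        raise ValueError(f"unknown model {model!r}")
    stage1 = _STAGE1_SPACES[model]
    if stage == 1:
        return InputSpace(model, 1, stage1)
    if stage == 2:
        keep = _STAGE2_SUBSETS[model]
        specs = tuple(s for s in stage1 if s.name in keep) + (_DI_SPEC,)
        fixed = {s.name: s.central for s in stage1 if s.name not in keep}
        return InputSpace(model, 2, specs, fixed)
    raise ValueError(f"stage must be 1 or 2, got {stage!r}")


def _raw_vector(space: InputSpace, raw) -> np.ndarray:
    if isinstance(raw, Mapping):
        mapping = raw
    elif hasattr(raw, "values") and isinstance(getattr(raw, "values"), Mapping):
        mapping = raw.values  # ParameterAssignment-like
    else:
        arr = np.asarray(raw, dtype=float)
        if arr.shape != (space.dim,):
            raise ValueError("raw vector length does not match input space")
        return arr
    missing = [n for n in space.names if n not in mapping]
    if missing:
        raise KeyError(f"missing inputs: {missing}")
    return np.array([float(mapping[n]) for n in space.names])


def normalize(space: InputSpace, raw, clip: bool = True) -> np.ndarray:
    """Map raw input values onto the [0, 1] design scale (low->0, high->1).

    Values outside [low, high] are clamped (with a warning) unless
    ``clip=False``.
    """
    x = _raw_vector(space, raw)
    z = (x - space.low) / (space.high - space.low)
    if clip and ((z < 0).any() or (z > 1).any()):
        import warnings

        bad = [space.names[i] for i in np.where((z < 0) | (z > 1))[0]]
        warnings.warn(f"inputs outside design range clamped: {bad}")
        z = np.clip(z, 0.0, 1.0)
    return z


def denormalize(space: InputSpace, z: Sequence[float]) -> dict[str, float]:
    """Inverse of :func:`normalize`: [0,1] vector -> raw value mapping."""
    z = np.asarray(z, dtype=float)
    if z.shape != (space.dim,):
        raise ValueError("normalized vector length does not match input space")
    x = space.low + z * (space.high - space.low)
    return dict(zip(space.names, x.tolist()))


@dataclass(frozen=True)
class DesignMatrix:
    """N x P matrix of normalized design points in [0, 1]."""

    X: np.ndarray
    names: tuple[str, ...]
    seed: int
    optimize_iters: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=list(self.names))

    def raw_frame(self, space: InputSpace) -> pd.DataFrame:
        raw = space.low + self.X * (space.high - space.low)
        return pd.DataFrame(raw, columns=list(self.names))


def _lhc_candidate(rng: np.random.Generator, n: int, p: int) -> np.ndarray:
    # one point per stratum [k/n, (k+1)/n) per column
    u = rng.uniform(size=(n, p))
    X = np.empty((n, p))
    for j in range(p):
        X[:, j] = (rng.permutation(n) + u[:, j]) / n
    return X


def min_pairwise_distance(X: np.ndarray) -> float:
    from scipy.spatial.distance import pdist

    return float(pdist(X).min())


def latin_hypercube(
    n: int,
    space: InputSpace | int,
    seed: int = 0,
    optimize_iters: int = 50,
) -> DesignMatrix:
    """Maximin-optimized Latin hypercube on [0, 1]^P.

    ``optimize_iters`` candidate stratified designs are drawn and the one
    with the greatest minimum pairwise distance is kept.  Deterministic for
    a fixed seed.
    """
    if n < 2:
        raise ValueError("a design needs at least 2 runs")
    if isinstance(space, InputSpace):
        p, names = space.dim, tuple(space.names)
    else:
        p, names = int(space), tuple(f"x{i + 1}" for i in range(int(space)))
    optimize_iters = max(1, int(optimize_iters))
    rng = np.random.default_rng(seed)
    best, best_d = None, -np.inf
    for _ in range(optimize_iters):
        X = _lhc_candidate(rng, n, p)
        d = min_pairwise_distance(X)
        if d > best_d:
            best, best_d = X, d
    return DesignMatrix(best, names, seed, optimize_iters)
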