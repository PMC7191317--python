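"""Synthetic benchmarks with analytically known variance decompositions.

Two kinds of ground truth stand in for expensive cell-model simulations
when exercising the design -> emulator -> sensitivity pipeline:

* analytic test functions on [0, 1]^P whose first-order and total-effect
  Sobol indices under an independent Gaussian input measure are known in
  closed form (linear and pure-interaction families), each able to
  self-validate against the Monte-Carlo oracle; and

* toy action-potential design data: Latin-hypercube samples of the toy
  generator's parameters pushed through the closed-form simulator and the
  biomarker extractor, with known monotone effect directions, optionally
  with planted pathological runs that the plausibility filter must remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import biomarkers as bm
from .cell_models import PacingProtocol, ParameterAssignment, simulate_toy_ap
from .design import InputSpace, build_input_space, latin_hypercube
from .sensitivity import UncertainInputs, mc_oracle

__all__ = [
    "AnalyticFunction",
    "make_linear_function",
    "make_interaction_function",
    "generate_toy_design_data",
    "ToyDesignData",
]


@dataclass(frozen=True)
class AnalyticFunction:
    """Evaluable map [0,1]^P -> scalar with known Sobol indices."""

    f: Callable[[np.ndarray], np.ndarray]
    S: np.ndarray
    ST: np.ndarray
    measure: UncertainInputs
    note: str = ""

    @property
    def dim(self) -> int:
        return self.S.size

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.f(np.atleast_2d(np.asarray(X, dtype=float)))

    def self_validate(self, n: int = 100_000, seed: int = 0, k_se: float = 3.0):
        """Check the stored indices against the Monte-Carlo oracle."""
        est = mc_oracle(self.f, self.measure, n=n, seed=seed)
        ok_s = np.all(np.abs(est["S"] - self.S) <= k_se * est["S_se"] + 1e-9)
        ok_t = np.all(np.abs(est["ST"] - self.ST) <= k_se * est["ST_se"] + 1e-9)
        if not (ok_s and ok_t):
            raise AssertionError(
                f"stored indices disagree with MC oracle: {self.note}\n"
                f"S={self.S} vs {est['S']} (se {est['S_se']})\n"
                f"ST={self.ST} vs {est['ST']} (se {est['ST_se']})"
            )
        return est


def make_linear_function(
    coeffs, intercept: float = 0.0, measure: UncertainInputs | None = None
) -> AnalyticFunction:
    """f(x) = intercept + sum a_p x_p: S_w = a_w^2 v_w / sum(a^2 v), S_Tw = S_w."""
    a = np.asarray(coeffs, dtype=float)
    if np.all(a == 0):
        raise ValueError("at least one coefficient must be nonzero")
    if measure is None:
        measure = UncertainInputs.uniform(a.size)
    v = measure.variances
    contrib = a**2 * v
    S = contrib / contrib.sum()

    def f(X):
        return intercept + np.atleast_2d(X) @ a

    return AnalyticFunction(f, S, S.copy(), measure, note=f"linear a={a.tolist()}")


def make_interaction_function(
    centers=(0.5, 0.5), measure: UncertainInputs | None = None
) -> AnalyticFunction:
    """f(x) = prod_p (x_p - mu_p): all S_w = 0; S_Tw = 1 for two inputs.

    When the centers coincide with the measure means, every conditional
    expectation E[f | x_w] vanishes, so the whole variance is interaction.
    For P inputs S_Tw = 1 - Var[prod_{p != w}(x_p - mu_p)] / Var[f] = 1.
    """
    c = np.asarray(centers, dtype=float)
    if measure is None:
        measure = UncertainInputs.uniform(c.size)
    if not np.allclose(measure.means, c):
        raise ValueError("interaction centers must equal the measure means")
    P = c.size
    S = np.zeros(P)
    ST = np.ones(P)

    def f(X):
        return np.prod(np.atleast_2d(X) - c, axis=1)

    return AnalyticFunction(f, S, ST, measure, note=f"interaction centers={c.tolist()}")


@dataclass
class ToyDesignData:
    """Paired toy design inputs and biomarker outputs with ground truth."""

    space: InputSpace
    X: np.ndarray                   # N x P normalized inputs (all runs)
    Y: np.ndarray                   # N x 11 biomarkers (NaN where unmeasurable)
    keep: np.ndarray                # boolean mask of runs passing the filter
    reasons: list[tuple[str, ...]]  # per-run exclusion reasons
    planted_bad: np.ndarray         # boolean: runs constructed to be pathological
    effect_signs: dict = field(default_factory=dict)

    @property
    def X_kept(self) -> np.ndarray:
        return self.X[self.keep]

    @property
    def Y_kept(self) -> np.ndarray:
        return self.Y[self.keep]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        xf = pd.DataFrame(self.X, columns=self.space.names)
        yf = pd.DataFrame(self.Y, columns=list(bm.BIOMARKER_NAMES))
        ef = pd.DataFrame(
            {
                "keep": self.keep,
                "reasons": ["|".join(r) for r in self.reasons],
                "planted_bad": self.planted_bad,
            }
        )
        return xf, yf, ef


# Known monotone effect directions of the toy generator's parameters on the
# extracted biomarkers (+1 increase, -1 decrease); the basis of
# parameter-recovery assertions downstream.
TOY_EFFECT_SIGNS = {
    ("apd_scale", "APD_90"): +1,
    ("apd_scale", "APD_50"): +1,
    ("peak_V", "V_max"): +1,
    ("rest_V", "RestV_m"): +1,
    ("upstroke_slope", "dVdt_max"): +1,
    ("Ca_base", "Ca_min"): +1,
    ("Ca_amp", "Ca_max"): +1,
}


def generate_toy_design_data(
    space: InputSpace | None = None,
    n: int = 100,
    seed: int = 0,
    n_beats: int = 4,
    cl: float = 1000.0,
    planted_bad_fraction: float = 0.0,
    s2_di: float | None = None,
) -> ToyDesignData:
    """LHC design -> toy simulation -> biomarkers -> plausibility filter.

    ``planted_bad_fraction`` converts that fraction of the runs into
    deliberately pathological parameter draws (resting potential above the
    -60 mV exclusion threshold) to exercise the filter.
    """
    if space is None:
        space = build_input_space("toy", 1)
    design = latin_hypercube(n, space, seed=seed)
    X = design.X.copy()
    rng = np.random.default_rng(seed + 1)
    n_bad = int(round(planted_bad_fraction * n))
    bad_idx = rng.choice(n, size=n_bad, replace=False) if n_bad else np.array([], int)
    planted = np.zeros(n, dtype=bool)
    planted[bad_idx] = True

    di_col = space.names.index("DI") if "DI" in space.names else None
    Y = np.full((n, len(bm.BIOMARKER_NAMES)), np.nan)
    keep = np.zeros(n, dtype=bool)
    reasons: list[tuple[str, ...]] = []
    for i in range(n):
        raw = dict(zip(space.names, (space.low + X[i] * (space.high - space.low))))
        raw.update(space.fixed)
        di = raw.pop("DI", None) if di_col is not None else s2_di
        toy_defaults = build_input_space("toy", 1)
        vals = {nm: raw.get(nm, c) for nm, c in zip(toy_defaults.names, toy_defaults.central)}
        if planted[i]:
            vals["rest_V"] = -50.0  # depolarized rest: must be filtered out
        pa = ParameterAssignment("toy", vals)
        proto = PacingProtocol(cl=cl, n_beats=n_beats, s2_di=di)
        tr = simulate_toy_ap(pa, proto)
        vec = bm.extract_biomarkers(tr, -1)
        Y[i] = vec.as_array()
        rec = bm.plausibility_filter(tr, final_biomarkers=vec)
        keep[i] = rec.keep
        reasons.append(rec.reasons)

    return ToyDesignData(
        space=space, X=X, Y=Y, keep=keep, reasons=reasons,
        planted_bad=planted, effect_signs=dict(TOY_EFFECT_SIGNS),
    )
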