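"""End-to-end orchestration of the two-stage emulation workflow.

Stage 1: a maximin Latin-hypercube design over the full input space, one
40-beat simulation per design point at a 1,000 ms cycle length, biomarker
extraction from the final beat, the plausibility filter, one GP emulator
per output trained on the kept runs, validation on an independent run set,
and variance-based + regression-based sensitivity tables.

Stage 2: the same workflow over the reduced input space (the strongest
action-potential-shaping inputs plus the diastolic interval DI of a final
S2 beat, delivered after 39 S1 beats); the S2 beat is the one analyzed.

Also here: the targeted verification experiment scaling the ultra-rapid
K+ conductance G_Kur to 50%/150% of its default, and the principal-
component summary of output dimensionality.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import biomarkers as bm
from .cell_models import (
    PacingProtocol,
    ParameterAssignment,
    SimulationError,
    SolverSettings,
    simulate,
)
from .design import InputSpace, build_input_space, latin_hypercube
from .emulator import GPEmulator, ValidationReport, train, validate
from .regression import RegressionIndices, compare_indices, regression_indices
from .sensitivity import SensitivityResult, UncertainInputs, sensitivity_table

__all__ = [
    "StageConfig",
    "DesignData",
    "StageBundle",
    "run_design",
    "run_stage",
    "train_emulators",
    "gkur_experiment",
    "pca_outputs",
]

log = logging.getLogger("atriagp.pipeline")


@dataclass(frozen=True)
class StageConfig:
    model: str = "courtemanche"
    stage: int = 1
    n_design: int | None = None       # defaults: 300 (Stage 1) / 200 (Stage 2)
    n_validation: int | None = None   # defaults: 150 (Stage 1) / 100 (Stage 2)
    cl: float = 1000.0
    n_beats: int = 40                 # S1 count; Stage 2 runs 39 S1 + S2
    seed: int = 0
    outdir: str | None = None
    outputs: tuple[str, ...] = bm.BIOMARKER_NAMES
    restarts: int = 10
    solver: SolverSettings = field(default_factory=SolverSettings)

    def resolved(self) -> "StageConfig":
        nd = self.n_design if self.n_design is not None else (300 if self.stage == 1 else 200)
        nv = self.n_validation if self.n_validation is not None else (150 if self.stage == 1 else 100)
        space = build_input_space(self.model, self.stage)
        if nd <= space.dim + 2:
            raise ValueError("n_design must exceed the input dimension + 2")
        return StageConfig(
            self.model, self.stage, nd, nv, self.cl, self.n_beats,
            self.seed, self.outdir, self.outputs, self.restarts, self.solver,
        )


@dataclass
class DesignData:
    """Paired normalized design inputs and biomarker outputs for N runs."""

    space: InputSpace
    X: np.ndarray                   # N x P normalized
    Y: np.ndarray                   # N x M biomarkers (NaN where unmeasurable)
    keep: np.ndarray                # plausibility-filter mask
    reasons: list[tuple[str, ...]]
    seed: int

    @property
    def X_kept(self) -> np.ndarray:
        return self.X[self.keep]

    @property
    def Y_kept(self) -> np.ndarray:
        return self.Y[self.keep]

    @property
    def n_excluded(self) -> int:
        return int((~self.keep).sum())

    def output_column(self, name: str) -> np.ndarray:
        return self.Y_kept[:, bm.BIOMARKER_NAMES.index(name)]

    def frames(self):
        xf = pd.DataFrame(self.X, columns=self.space.names)
        raw = self.space.low + self.X * (self.space.high - self.space.low)
        rf = pd.DataFrame(raw, columns=[f"{n}_raw" for n in self.space.names])
        yf = pd.DataFrame(self.Y, columns=list(bm.BIOMARKER_NAMES))
        ef = pd.DataFrame(
            {"keep": self.keep, "reasons": ["|".join(r) for r in self.reasons]}
        )
        return xf, rf, yf, ef


def _protocol_for(space: InputSpace, raw: dict, config: StageConfig) -> PacingProtocol:
    if space.stage == 2:
        di = raw["DI"]
        return PacingProtocol(cl=config.cl, n_beats=config.n_beats - 1, s2_di=di)
    return PacingProtocol(cl=config.cl, n_beats=config.n_beats)


def run_design(
    config: StageConfig,
    n: int,
    seed: int,
    optimize_iters: int = 50,
) -> DesignData:
    """Sample a maximin LHC and simulate/filter every design point."""
    space = build_input_space(config.model, config.stage)
    design = latin_hypercube(n, space, seed=seed, optimize_iters=optimize_iters)
    X = design.X
    Y = np.full((n, len(bm.BIOMARKER_NAMES)), np.nan)
    keep = np.zeros(n, dtype=bool)
    reasons: list[tuple[str, ...]] = []
    tally: dict[str, int] = {}
    for i in range(n):
        raw = dict(zip(space.names, space.low + X[i] * (space.high - space.low)))
        proto = _protocol_for(space, raw, config)
        raw.pop("DI", None)
        raw.update(space.fixed)
        params = ParameterAssignment(config.model, raw)
        try:
            tr = simulate(params, proto, config.solver)
        except SimulationError as exc:
            log.warning("run %d failed: %s", i, exc)
            keep[i] = False
            reasons.append(("incomplete",))
            tally["incomplete"] = tally.get("incomplete", 0) + 1
            continue
        vec = bm.extract_biomarkers(tr, -1)
        Y[i] = vec.as_array()
        rec = bm.plausibility_filter(tr, final_biomarkers=vec)
        keep[i] = rec.keep
        reasons.append(rec.reasons)
        for r in rec.reasons:
            tally[r] = tally.get(r, 0) + 1
    log.info(
        "%s stage %d: %d/%d runs kept (exclusions: %s)",
        config.model, config.stage, int(keep.sum()), n, tally or "none",
    )
    return DesignData(space, X, Y, keep, reasons, seed)


def train_emulators(
    data: DesignData,
    outputs=bm.BIOMARKER_NAMES,
    restarts: int = 10,
    seed: int = 0,
) -> dict[str, GPEmulator]:
    """One GP emulator per requested output, trained on the kept runs."""
    ems = {}
    for k, name in enumerate(outputs):
        y = data.output_column(name)
        em = train(data.X_kept, y, restarts=restarts, seed=seed + 1000 * k)
        best = max(e["loglik"] for e in em.training_log)
        log.info("emulator %s: best loglik %.2f over %d restarts", name, best, restarts)
        ems[name] = em
    return ems


@dataclass
class StageBundle:
    """Everything one stage produces, in memory."""

    config: StageConfig
    design: DesignData
    validation: DesignData
    emulators: dict[str, GPEmulator]
    validation_reports: dict[str, ValidationReport]
    sensitivity: dict[str, SensitivityResult]
    regression: RegressionIndices
    comparison: pd.DataFrame

    def sensitivity_frames(self):
        s = pd.DataFrame(
            {o: r.signed_s1 for o, r in self.sensitivity.items()},
            index=list(next(iter(self.sensitivity.values())).inputs),
        ).T
        st = pd.DataFrame(
            {o: r.st for o, r in self.sensitivity.items()},
            index=list(next(iter(self.sensitivity.values())).inputs),
        ).T
        inter = pd.DataFrame(
            {o: r.interaction for o, r in self.sensitivity.items()},
            index=list(next(iter(self.sensitivity.values())).inputs),
        ).T
        return s, st, inter

    def validation_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "output": list(self.validation_reports),
                "MAPE_percent": [r.mape for r in self.validation_reports.values()],
                "median_ISE": [r.median_ise for r in self.validation_reports.values()],
                "n_validation": [r.n_validation for r in self.validation_reports.values()],
            }
        )


def run_stage(config: StageConfig) -> StageBundle:
    """Design -> simulate -> filter -> train -> validate -> sensitivity."""
    config = config.resolved()
    space = build_input_space(config.model, config.stage)
    log.info("stage %d for %s: %d design + %d validation runs",
             config.stage, config.model, config.n_design, config.n_validation)
    design = run_design(config, config.n_design, seed=config.seed)
    validation = run_design(config, config.n_validation, seed=config.seed + 7919)

    ems = train_emulators(design, config.outputs, restarts=config.restarts,
                          seed=config.seed)
    reports = {}
    for name, em in ems.items():
        Xv = validation.X_kept
        yv = validation.output_column(name)
        ok = np.isfinite(yv)
        reports[name] = validate(em, Xv[ok], yv[ok])

    u = UncertainInputs.from_space(space)
    sens = {name: sensitivity_table(em, u, output=name) for name, em in ems.items()}

    finite = np.all(np.isfinite(design.Y_kept), axis=1)
    reg = regression_indices(
        design.X_kept[finite],
        design.Y_kept[finite][:, [bm.BIOMARKER_NAMES.index(o) for o in config.outputs]],
        input_names=space.names,
        output_names=config.outputs,
    )
    comp = compare_indices(sens, reg)

    bundle = StageBundle(config, design, validation, ems, reports, sens, reg, comp)
    if config.outdir:
        write_bundle(bundle, Path(config.outdir))
    return bundle


def write_bundle(bundle: StageBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config
    tag = f"{cfg.model}_stage{cfg.stage}"
    for label, data in (("design", bundle.design), ("validation", bundle.validation)):
        xf, rf, yf, ef = data.frames()
        pd.concat([xf, rf, yf, ef], axis=1).to_csv(
            outdir / f"{tag}_{label}.csv", index=False
        )
    for name, em in bundle.emulators.items():
        em.save(outdir / f"{tag}_emulator_{name}.json")
    bundle.validation_frame().to_csv(outdir / f"{tag}_validation.csv", index=False)
    s, st, inter = bundle.sensitivity_frames()
    s.to_csv(outdir / f"{tag}_first_order_signed.csv")
    st.to_csv(outdir / f"{tag}_total_effect.csv")
    inter.to_csv(outdir / f"{tag}_interaction.csv")
    bundle.regression.frame().to_csv(outdir / f"{tag}_regression_B.csv")
    bundle.comparison.to_csv(outdir / f"{tag}_S_vs_B2.csv", index=False)
    curves = []
    for name, res in bundle.sensitivity.items():
        for c in res.main_effects:
            curves.append(pd.DataFrame({
                "output": name, "input": c.input, "grid": c.grid,
                "expectation": c.expectation,
            }))
    pd.concat(curves, ignore_index=True).to_csv(
        outdir / f"{tag}_main_effects.csv", index=False
    )
    meta = {
        "model": cfg.model, "stage": cfg.stage, "seed": cfg.seed,
        "n_design": cfg.n_design, "n_validation": cfg.n_validation,
        "n_excluded_design": bundle.design.n_excluded,
        "n_excluded_validation": bundle.validation.n_excluded,
    }
    (outdir / f"{tag}_meta.json").write_text(json.dumps(meta, indent=2))


def gkur_experiment(
    model: str,
    scales=(0.5, 1.0, 1.5),
    n_beats: int = 40,
    cl: float = 1000.0,
    solver: SolverSettings = SolverSettings(),
):
    """Scale the ultra-rapid K+ conductance and compare final-beat APD_90.

    Returns a dict with a summary frame (scale vs APD_90) and, per scale,
    the final-beat traces of the mechanistically relevant currents I_Kur,
    I_CaL and I_Kr.
    """
    gkur_name = "fG_Kur" if model == "courtemanche" else "G_Kur"
    base = ParameterAssignment.defaults(model)
    rows = []
    currents = {}
    for s in scales:
        pa = base.replace(**{gkur_name: base.values[gkur_name] * s})
        tr = simulate(pa, PacingProtocol(cl=cl, n_beats=n_beats), solver,
                      record_currents=True)
        vec = bm.extract_biomarkers(tr, -1)
        rows.append({"scale": s, "APD_90": vec.APD_90, "APD_50": vec.APD_50,
                     "V_max": vec.V_max, "RestV_m": vec.RestV_m})
        final = tr.time >= tr.stim_times[-1]
        currents[s] = pd.DataFrame({
            "time_ms": tr.time[final] - tr.stim_times[-1],
            "V_mV": tr.voltage[final],
            "I_Kur": tr.meta["currents"]["I_Kur"][final],
            "I_CaL": tr.meta["currents"]["I_CaL"][final],
            "I_Kr": tr.meta["currents"]["I_Kr"][final],
        })
    return {"model": model, "summary": pd.DataFrame(rows), "currents": currents}


def pca_outputs(Y: np.ndarray, threshold: float = 0.95) -> pd.DataFrame:
    """Principal components of the standardized output matrix.

    Eigendecomposition of the output correlation matrix (kept runs only);
    the returned frame lists each component's variance fraction, the
    cumulative fraction, and carries ``n95`` (components needed to reach
    the threshold) as an attribute.
    """
    Y = np.asarray(Y, dtype=float)
    ok = np.all(np.isfinite(Y), axis=1)
    Y = Y[ok]
    sd = Y.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant output column; correlation matrix undefined")
    C = np.corrcoef(Y, rowvar=False)
    evals = np.linalg.eigvalsh(C)[::-1]
    frac = evals / evals.sum()
    cum = np.cumsum(frac)
    out = pd.DataFrame(
        {"component": np.arange(1, evals.size + 1), "eigenvalue": evals,
         "variance_fraction": frac, "cumulative_fraction": cum}
    )
    out.attrs["n95"] = int(np.searchsorted(cum, threshold) + 1)
    out.attrs["threshold"] = threshold
    return out
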