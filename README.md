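# atriagp

Gaussian-process emulation, variance-based sensitivity analysis and
uncertainty quantification for biophysically detailed models of the human
atrial action potential.

## The problem

Models of the cardiac action potential are systems of stiff, non-linear
ODEs with dozens of parameters — maximum channel conductances, pump and
exchanger rates, Ca²⁺-handling constants, cell capacitance, extracellular
ion concentrations.  Many of these quantities vary from cell to cell, and
how that variability propagates into the action potential is hard to see
from the equations.  `atriagp` makes the question quantitative for two
widely used human atrial myocyte models, the **Courtemanche** model and
the **Maleckar** (Nygren-family) model:

1. sample the parameter space with a maximin Latin hypercube, each input
   scaled to `[0, 1]` over `central × (1 ± 0.5)` (±25% for `G_K1` and
   `C_m`, ±10% for extracellular concentrations);
2. simulate 40 paced beats per sample (cycle length 1,000 ms) and reduce
   each run to 11 biomarkers: `dV/dt_max`, `V_max`, `V_20…V_80`,
   `APD_50`, `APD_90`, `RestV_m`, `Ca_min`, `Ca_max`, discarding runs with
   pacemaking, a resting potential above −60 mV, `APD_90` > 600 ms, or
   APD alternans;
3. train one Gaussian-process emulator per biomarker,
   `f_e(x) = h(x)ᵀβ + g(x)` with a linear mean and RBF covariance
   `c(x,x′) = exp[−Σ_p (x_p−x′_p)²/δ_p²]`, fitting `δ` by restricted
   maximum likelihood (weak priors on `β`, `σ²`; fixed nugget 10⁻⁷;
   best of 10 restarts);
4. compute, in closed form under independent Gaussian input measures,
   the first-order Sobol index `S_w = Var[E(f_e|x_w)]/Var[f_e]`, the
   total-effect index `S_Tw = 1 − Var[E(f_e|x_{~w})]/Var[f_e]`, signed
   main-effect curves, output-uncertainty sweeps and (in Stage 2, which
   adds the diastolic interval of an S2 beat as an input) APD restitution
   surfaces with emulator credible bands.

A closed-form "toy" action-potential generator with analytically known
biomarkers, plus linear/pure-interaction test functions with known Sobol
decompositions, make the whole pipeline testable in seconds.

## Worked example

```python
from atriagp.pipeline import StageConfig, run_stage

bundle = run_stage(StageConfig(model="toy", stage=1, n_design=100,
                               n_validation=40, seed=5, n_beats=3))
print(bundle.validation_frame().head(3).to_string(index=False))
s, st, inter = bundle.sensitivity_frames()
print(s.abs().idxmax(axis=1).loc[["APD_90", "V_max", "Ca_max"]])
```

prints

```
  output  MAPE_percent  median_ISE  n_validation
dVdt_max      2.351381    0.511052            40
   V_max     17.744620    0.511052            40
    V_20      1.014628    1.766673            40
APD_90     apd_scale
V_max         peak_V
Ca_max        Ca_amp
dtype: object
```

— each toy emulator is validated on 40 held-out runs (MAPE: mean absolute
prediction error as % of the validation mean; ISE: error standardized by
the posterior predictive s.d.), and the largest first-order index for each
biomarker lands on the parameter that generated it: the APD scale for
`APD_90`, the peak voltage for `V_max`, the transient amplitude for
`Ca_max`.

The same workflow for the real cell model is one call away
(`run_stage(StageConfig(model="courtemanche", stage=1, seed=1))`, roughly
ten minutes of CPU), or from the shell:

```
atriagp stage1 --model courtemanche --seed 1 --outdir out/
atriagp gkur --model maleckar
```

The `gkur` command reproduces the targeted verification experiment: halving
the ultra-rapid K⁺ conductance lengthens the action potential in the
Maleckar model but slightly shortens it in the Courtemanche model, because
the two models balance the plateau currents `I_Kur`, `I_CaL` and `I_Kr`
differently.

## Layout

| module | contents |
| --- | --- |
| `atriagp.cell_models` | Courtemanche and Maleckar ODE right-hand sides (numba), hybrid Rush-Larsen/Runge-Kutta integrator, S1 and S1-S2 pacing, toy AP generator |
| `atriagp.design` | input-space tables, `[0,1]` normalization, maximin Latin hypercubes |
| `atriagp.biomarkers` | the 11 outputs and the plausibility filter |
| `atriagp.emulator` | linear-mean RBF GP, restricted-likelihood training, MAPE/ISE validation |
| `atriagp.sensitivity` | closed-form Sobol indices, main effects, MC oracle, uncertainty sweeps, restitution surfaces |
| `atriagp.regression` | standardized multivariate regression indices, S ≈ B² comparison |
| `atriagp.synthetic` | analytic benchmark functions, toy design-data generation |
| `atriagp.pipeline` | Stage-1/Stage-2 orchestration, G_Kur experiment, output PCA |
| `atriagp.plotting` | optional heatmap / main-effect / surface figures (``plot`` extra) |
| `atriagp.cli` | `atriagp` command-line interface |

See `docs/methods.md` for the modeling and numerical choices.
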