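"""Standardized multivariate linear-regression sensitivity indices.

A complementary, regression-based view of sensitivity: with design inputs
X (N x P) and outputs Y (N x M) both z-scored column-wise, the coefficient
matrix B (P x M) of the linear model Y = X B measures how many standard
deviations each output moves per standard deviation of each input.  For
near-additive simulators the first-order variance-based index satisfies
S_w ~ B_w^2, which this module's comparison table quantifies.

The default estimator is ordinary multivariate least squares on the
standardized matrices; a latent-component partial-least-squares mode is
available behind a flag for methodological comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "RegressionIndices",
    "standardize",
    "regression_indices",
    "compare_indices",
]


def standardize(M: np.ndarray, ddof: int = 1):
    """Z-score columns (sample s.d., N-1 denominator).

    Returns (Z, means, sds).  A constant column is an error: it carries no
    information and would divide by zero.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    means = M.mean(axis=0)
    sds = M.std(axis=0, ddof=ddof)
    if np.any(sds == 0):
        bad = np.where(sds == 0)[0].tolist()
        raise ValueError(f"constant column(s) cannot be standardized: {bad}")
    return (M - means) / sds, means, sds


@dataclass(frozen=True)
class RegressionIndices:
    B: np.ndarray                  # P x M standardized coefficients
    input_names: tuple[str, ...]
    output_names: tuple[str, ...]
    x_means: np.ndarray
    x_sds: np.ndarray
    y_means: np.ndarray
    y_sds: np.ndarray
    mode: str = "ols"

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.B, index=list(self.input_names),
                            columns=list(self.output_names))


def regression_indices(
    X: np.ndarray,
    Y: np.ndarray,
    input_names=None,
    output_names=None,
    mode: str = "ols",
    n_components: int | None = None,
) -> RegressionIndices:
    """Fit B in Y = X B on standardized design data.

    ``mode='ols'`` (default) is the plain multivariate least-squares
    solution; ``mode='pls'`` uses latent-component partial least squares
    (``n_components`` defaults to min(P, 10)).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("X and Y must have the same number of runs")
    if n <= p:
        raise ValueError("need more runs than inputs for a least-squares fit")
    Zx, xm, xs = standardize(X)
    Zy, ym, ysd = standardize(Y)
    if mode == "ols":
        rank = np.linalg.matrix_rank(Zx)
        if rank < p:
            _, R = np.linalg.qr(Zx)
            collinear = np.where(np.abs(np.diag(R)) < 1e-8)[0].tolist()
            raise ValueError(f"design inputs are rank deficient (columns {collinear})")
        B, *_ = np.linalg.lstsq(Zx, Zy, rcond=None)
    elif mode == "pls":
        from sklearn.cross_decomposition import PLSRegression

        nc = n_components if n_components is not None else min(p, 10)
        pls = PLSRegression(n_components=nc, scale=False)
        pls.fit(Zx, Zy)
        B = pls.coef_.T  # sklearn stores (M, P)
    else:
        raise ValueError("mode must be 'ols' or 'pls'")
    inames = tuple(input_names) if input_names is not None else tuple(
        f"x{i + 1}" for i in range(p)
    )
    onames = tuple(output_names) if output_names is not None else tuple(
        f"y{j + 1}" for j in range(Y.shape[1])
    )
    return RegressionIndices(B, inames, onames, xm, xs, ym, ysd, mode=mode)


def compare_indices(sens_results, reg: RegressionIndices) -> pd.DataFrame:
    """Tabulate S_w against B^2 per (input, output) with rank correlations.

    ``sens_results`` is a mapping output name -> SensitivityResult (inputs
    must be ordered as in ``reg``).  The returned frame carries one row per
    input x output with columns S, B, B^2, plus the per-output Spearman
    rank correlation between S and B^2.
    """
    rows = []
    for j, out in enumerate(reg.output_names):
        res = sens_results[out]
        if tuple(res.inputs) != tuple(reg.input_names):
            raise ValueError(f"input ordering mismatch for output {out!r}")
        b = reg.B[:, j]
        s = res.s1
        if s.size > 1 and np.std(s) > 0 and np.std(b**2) > 0:
            rho = float(spearmanr(s, b**2).statistic)
        else:
            rho = np.nan
        for i, name in enumerate(reg.input_names):
            rows.append(
                {
                    "output": out,
                    "input": name,
                    "S": float(s[i]),
                    "B": float(b[i]),
                    "B2": float(b[i] ** 2),
                    "rank_corr_S_B2": rho,
                }
            )
    return pd.DataFrame(rows)
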