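"""Bulk deconvolution by Nu-SVR against a marker signature and positive-Lasso imputation.

For each bulk sample, expression of the marker genes is regressed on the
signature matrix with linear-kernel Nu-SVR over a grid of Nu values; the fit
with the smallest mean squared error between predicted and observed expression
wins.  Negative coefficients are clipped to zero and the remainder normalized
to a simplex, giving per-state proportions.  State-specific expression is
recovered from many bulk samples by an L1-penalized non-negative regression of
each gene on the estimated proportion matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso
from sklearn.svm import NuSVR

from .markers import MarkerSet
from .matrix import ExpressionMatrix

DEFAULT_NU_GRID = (0.25, 0.5, 0.75)
DEFAULT_ALPHA = 1e-4


@dataclass
class SignatureMatrix:
    """Marker gene x state mean expression used as the regression design."""

    values: pd.DataFrame
    space: str = "logTPM"
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise ValueError("signature needs at least 2 states")
        zero = (self.values == 0).all(axis=1)
        if zero.any():
            raise ValueError(f"all-zero signature row for gene {zero.idxmax()!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def states(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ProportionEstimate:
    proportions: pd.DataFrame  # sample x state, rows on the simplex
    chosen_nu: pd.Series
    fit_mse: pd.Series
    raw_coefficients: pd.DataFrame


@dataclass
class ImputedExpression:
    values: pd.DataFrame  # gene x state, all entries >= 0
    alpha: float


def build_signature(
    matrix: ExpressionMatrix, labels: pd.Series, markers: MarkerSet
) -> SignatureMatrix:
    """Mean expression of each marker gene within each state."""
    genes = markers.all_genes()
    missing = [g for g in genes if g not in matrix.values.index]
    if missing:
        raise KeyError(f"marker gene not present in matrix: {missing[0]!r}")
    labels = labels.reindex(matrix.observations)
    if labels.isna().any():
        raise ValueError("labels missing for some observations")
    sub = matrix.values.loc[genes]
    sig = sub.T.groupby(labels).mean().T
    sig = sig[sorted(sig.columns)]
    return SignatureMatrix(values=sig, space=matrix.space, provenance=f"top{markers.top_n}")


def deconvolve_sample(
    bulk_profile: np.ndarray | pd.Series,
    signature: SignatureMatrix,
    nu_grid: tuple[float, ...] = DEFAULT_NU_GRID,
    standardize: bool = True,
) -> tuple[np.ndarray, float, float, np.ndarray]:
    """Estimate state proportions for one bulk profile.

    Returns (proportions, chosen_nu, mse, raw_beta).  Nu is selected by the smallest MSE
    of predicted vs observed marker expression; coefficients are clipped at
    zero and normalized to sum to one.  With ``standardize`` the profile and
    the signature matrix are z-scored before regression (the CIBERSORT
    convention), which keeps the fit scale-free.
    """
    y = np.asarray(bulk_profile, dtype=float).ravel()
    X = signature.values.to_numpy(dtype=float)
    if y.shape[0] != X.shape[0]:
        raise ValueError(
            f"bulk profile length ({y.shape[0]}) does not match signature genes ({X.shape[0]})"
        )
    if standardize:
        sd_y = y.std()
        if sd_y == 0:
            raise ValueError("constant bulk profile cannot be standardized")
        y = (y - y.mean()) / sd_y
        X = (X - X.mean()) / X.std()
    best: tuple[float, float, np.ndarray] | None = None
    for nu in nu_grid:
        model = NuSVR(kernel="linear", nu=nu, C=1.0)
        model.fit(X, y)
        mse = float(np.mean((model.predict(X) - y) ** 2))
        if best is None or mse < best[0]:
            best = (mse, float(nu), model.coef_.ravel().copy())
    assert best is not None
    mse, chosen_nu, beta = best
    clipped = np.clip(beta, 0.0, None)
    total = clipped.sum()
    if total <= 0:
        raise ValueError("unresolvable mixture: all Nu-SVR coefficients non-positive")
    return clipped / total, chosen_nu, mse, beta


def deconvolve_matrix(
    bulk: ExpressionMatrix,
    signature: SignatureMatrix,
    nu_grid: tuple[float, ...] = DEFAULT_NU_GRID,
    space: str = "log",
) -> ProportionEstimate:
    """Deconvolve every bulk sample independently, in input order.

    ``space`` selects the regression value space: ``"log"`` uses the matrices
    as given (log2(TPM+1)); ``"linear"`` reverses the log transform of both
    bulk and signature first, matching physical mixing of linear abundances.
    """
    if space not in ("log", "linear"):
        raise ValueError(f"space must be 'log' or 'linear', got {space!r}")
    sub = bulk.subset_genes(signature.genes)
    if space == "linear":
        if sub.space == "logTPM":
            sub = ExpressionMatrix(np.exp2(sub.values) - 1.0, space="TPM")
        sig_vals = signature.values
        if signature.space == "logTPM":
            sig_vals = np.exp2(sig_vals) - 1.0
        signature = SignatureMatrix(sig_vals, space="TPM", provenance=signature.provenance)
    props, nus, mses, raws = [], [], [], []
    for sample in sub.observations:
        try:
            p, nu, mse, raw = deconvolve_sample(sub.values[sample], signature, nu_grid)
        except ValueError as err:
            raise ValueError(f"sample {sample!r}: {err}") from err
        props.append(p)
        nus.append(nu)
        mses.append(mse)
        raws.append(raw)
    states = signature.states
    samples = sub.observations
    return ProportionEstimate(
        proportions=pd.DataFrame(props, index=samples, columns=states),
        chosen_nu=pd.Series(nus, index=samples, name="nu"),
        fit_mse=pd.Series(mses, index=samples, name="mse"),
        raw_coefficients=pd.DataFrame(raws, index=samples, columns=states),
    )


def impute_state_expression(
    bulk: ExpressionMatrix,
    proportions: ProportionEstimate | pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
) -> ImputedExpression:
    """Per-gene positive Lasso of bulk expression on the state-proportion design.

    No intercept; non-negative coefficients give the imputed per-state
    expression of each gene in the value space of ``bulk``.
    """
    P = proportions.proportions if isinstance(proportions, ProportionEstimate) else proportions
    P = P.reindex(bulk.observations)
    if P.isna().any().any():
        raise ValueError("proportions missing for some bulk samples")
    design = P.to_numpy(dtype=float)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn("proportion matrix is rank-deficient; imputed values may be unstable")
    Y = bulk.to_numpy()  # genes x samples
    model = Lasso(alpha=alpha, fit_intercept=False, positive=True, max_iter=10_000)
    coefs = np.empty((bulk.n_genes, design.shape[1]))
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*convergence.*")
        for g in range(bulk.n_genes):
            model.fit(design, Y[g])
            coefs[g] = model.coef_
    return ImputedExpression(
        values=pd.DataFrame(coefs, index=bulk.genes, columns=list(P.columns)),
        alpha=alpha,
    )
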