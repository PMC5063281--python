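"""Linear generalized estimating equations with exchangeable working correlation.

This is a from-scratch marginal (population-averaged) linear model for
clustered data.  The working covariance of a cluster of size n is

    V = phi * [(1 - rho) I + rho J],

whose inverse has the closed form

    V^-1 = (1/phi) * [ I/(1-rho) - rho J / ((1-rho)(1 - rho + n rho)) ],

so every cluster contribution reduces to cross-products of cluster sums and
no per-cluster matrix inversion is needed.  Estimation alternates a
generalized-least-squares update of beta with moment re-estimation of
(rho, phi) from the residuals; inference uses the robust sandwich covariance
A^-1 B A^-1.

The public surface follows the model/results idiom: construct an
:class:`ExchangeableGEE` from a design (or raw arrays), call :meth:`fit`, and
read estimates, robust standard errors, confidence intervals and the summary
table off the returned :class:`GEEResults`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrix
from .errors import DegreesOfFreedomError, SchemaError, SingularDesignError

__all__ = ["ExchangeableGEE", "GEEResults", "estimate_rho_phi", "sandwich_covariance", "Z_975"]

logger = logging.getLogger(__name__)

Z_975 = 1.959964  # large-sample two-sided 95% normal quantile

_RHO_MAX = 0.99  # keeps the working covariance positive definite


def _group_codes(cluster_ids: np.ndarray) -> tuple[np.ndarray, int]:
    _, codes = np.unique(np.asarray(cluster_ids, dtype=object), return_inverse=True)
    return codes.astype(np.intp), int(codes.max()) + 1 if len(codes) else 0


def estimate_rho_phi(
    residuals: np.ndarray,
    cluster_ids: np.ndarray,
    p: int,
) -> tuple[float, float]:
    """Moment estimates of the exchangeable correlation and scale.

    phi = sum(r^2) / (N - p); rho = mean within-cluster pairwise residual
    product over phi, with an (npairs - p) degrees-of-freedom correction,
    floored at 0 and clamped below 0.99.
    """
    r = np.asarray(residuals, dtype=float)
    codes, n_groups = _group_codes(np.asarray(cluster_ids))
    N = r.size
    if N <= p:
        raise DegreesOfFreedomError(f"need more observations ({N}) than parameters ({p})")
    phi = float(r @ r) / (N - p)
    sizes = np.bincount(codes, minlength=n_groups)
    npairs = float((sizes * (sizes - 1) // 2).sum())
    if npairs == 0:
        logger.info("all clusters are singletons; exchangeable rho set to 0")
        return 0.0, phi
    if phi == 0.0:
        return 0.0, 0.0
    sums = np.bincount(codes, weights=r, minlength=n_groups)
    sq = np.bincount(codes, weights=r * r, minlength=n_groups)
    pair_sum = float(((sums * sums) - sq).sum()) / 2.0
    denom = npairs - p
    if denom <= 0:
        denom = npairs
    rho = pair_sum / denom / phi
    return float(min(max(rho, 0.0), _RHO_MAX)), phi


def _fit_arrays(
    X: np.ndarray,
    y: np.ndarray,
    codes: np.ndarray,
    n_groups: int,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> dict:
    """Lean array-level fit shared by the model class and the resampling loops.

    ``codes`` must be integer cluster labels in [0, n_groups).
    """
    N, p = X.shape
    if N <= p:
        raise DegreesOfFreedomError(f"need more observations ({N}) than parameters ({p})")
    XtX = X.T @ X
    Xty = X.T @ y
    # rank check once, with a helpful message
    rank = np.linalg.matrix_rank(XtX)
    if rank < p:
        u, s, vt = np.linalg.svd(XtX)
        dependent = np.where(np.abs(vt[rank:]).max(axis=0) > 1e-8)[0].tolist()
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} < {p}); "
            f"columns involved: {dependent}",
            dependent_columns=dependent,
        )

    sizes = np.bincount(codes, minlength=n_groups).astype(float)
    col_scale = np.sqrt((X * X).mean(axis=0))
    col_scale[col_scale == 0.0] = 1.0
    y_scale = max(1.0, float(np.std(y)))

    rho, phi = 0.0, 1.0
    beta = np.linalg.solve(XtX, Xty)
    converged = False
    iterations = 0
    for iteration in range(1, maxiter + 1):
        iterations = iteration
        r = y - X @ beta
        rho, phi = estimate_rho_phi(r, codes, p)
        if phi == 0.0:  # perfect fit; nothing left to iterate on
            converged = True
            break
        # GLS update under the current working correlation (phi cancels)
        if rho == 0.0:
            A_corr = XtX
            b = Xty
        else:
            Sx = np.zeros((n_groups, p))
            np.add.at(Sx, codes, X)
            Sy = np.bincount(codes, weights=y, minlength=n_groups)
            c = rho / (1.0 - rho + sizes * rho)  # per-cluster shrink factor
            A_corr = (XtX - (Sx * c[:, None]).T @ Sx) / (1.0 - rho)
            b = (Xty - Sx.T @ (c * Sy)) / (1.0 - rho)
        new_beta = np.linalg.solve(A_corr, b)
        step = np.max(np.abs(new_beta - beta) * col_scale)
        beta = new_beta
        if step < tol * y_scale:
            converged = True
            break
    if not converged:
        warnings.warn("GEE did not converge within the iteration cap", RuntimeWarning)

    # final working parameters and covariance pieces at the converged beta
    r = y - X @ beta
    rho, phi = estimate_rho_phi(r, codes, p)
    if rho == 0.0:
        A_corr = XtX
    else:
        Sx = np.zeros((n_groups, p))
        np.add.at(Sx, codes, X)
        c = rho / (1.0 - rho + sizes * rho)
        A_corr = (XtX - (Sx * c[:, None]).T @ Sx) / (1.0 - rho)

    # per-cluster score pieces u_g = X_g' Vc^-1 r_g (correlation part only)
    if rho == 0.0:
        U = np.zeros((n_groups, p))
        np.add.at(U, codes, X * r[:, None])
    else:
        Sx = np.zeros((n_groups, p))
        np.add.at(Sx, codes, X)
        Sr = np.bincount(codes, weights=r, minlength=n_groups)
        Xr = np.zeros((n_groups, p))
        np.add.at(Xr, codes, X * r[:, None])
        c = rho / (1.0 - rho + sizes * rho)
        U = (Xr - Sx * (c * Sr)[:, None]) / (1.0 - rho)

    A_corr_inv = np.linalg.inv(A_corr)
    B = U.T @ U
    robust_cov = A_corr_inv @ B @ A_corr_inv  # phi cancels in the sandwich
    naive_cov = phi * A_corr_inv
    score_norm = float(np.max(np.abs(U.sum(axis=0)))) if phi > 0 else 0.0
    return {
        "beta": beta,
        "rho": rho,
        "phi": phi,
        "robust_cov": robust_cov,
        "naive_cov": naive_cov,
        "iterations": iterations,
        "converged": converged,
        "n_obs": N,
        "n_clusters": n_groups,
        "score_norm": score_norm,
    }


def sandwich_covariance(
    design: DesignMatrix,
    beta: np.ndarray,
    rho: float,
    phi: float,
) -> np.ndarray:
    """Robust covariance A^-1 B A^-1 at given working parameters.

    A = sum_i X_i' V_i^-1 X_i and B = sum_i X_i' V_i^-1 r_i r_i' V_i^-1 X_i
    with V_i = phi[(1-rho)I + rho J]; the scale phi cancels in the sandwich.
    """
    X = design.values
    y = design.outcome
    codes, n_groups = _group_codes(design.cluster_ids)
    N, p = X.shape
    r = y - X @ np.asarray(beta, dtype=float)
    sizes = np.bincount(codes, minlength=n_groups).astype(float)
    Sx = np.zeros((n_groups, p))
    np.add.at(Sx, codes, X)
    Xr = np.zeros((n_groups, p))
    np.add.at(Xr, codes, X * r[:, None])
    c = rho / (1.0 - rho + sizes * rho)
    Sr = np.bincount(codes, weights=r, minlength=n_groups)
    A_corr = (X.T @ X - (Sx * c[:, None]).T @ Sx) / (1.0 - rho)
    U = (Xr - Sx * (c * Sr)[:, None]) / (1.0 - rho)
    try:
        A_inv = np.linalg.inv(A_corr)
    except np.linalg.LinAlgError as err:
        raise SingularDesignError(f"working information matrix is singular: {err}") from err
    return A_inv @ (U.T @ U) @ A_inv


class ExchangeableGEE:
    """Marginal linear model for clustered outcomes.

    Parameters
    ----------
    endog : array-like
        Outcome vector (here: annualized change in 6MWD, m/year).
    exog : array-like, shape (n, p)
        Design matrix including the intercept column.
    groups : array-like
        Cluster labels (one patient = one cluster).
    exog_names : sequence of str, optional
        Column names; positional defaults are generated when omitted.
    """

    def __init__(self, endog, exog, groups, exog_names=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        self.groups = np.asarray(groups, dtype=object)
        if self.exog.shape[0] != self.endog.shape[0] or len(self.groups) != len(self.endog):
            raise SchemaError("endog, exog and groups must have matching length")
        if exog_names is None:
            exog_names = [f"x{j}" for j in range(self.exog.shape[1])]
        if len(exog_names) != self.exog.shape[1]:
            raise SchemaError("exog_names length must match the design width")
        self.exog_names = list(exog_names)
        self.design: DesignMatrix | None = None

    @classmethod
    def from_design(cls, design: DesignMatrix) -> "ExchangeableGEE":
        model = cls(design.outcome, design.values, design.cluster_ids, design.column_names)
        model.design = design
        return model

    @classmethod
    def from_intervals(cls, intervals, spec, **encode_kwargs) -> "ExchangeableGEE":
        from .design import encode_model_matrix

        return cls.from_design(encode_model_matrix(intervals, spec, **encode_kwargs))

    def fit(self, tol: float = 1e-8, maxiter: int = 100) -> "GEEResults":
        codes, n_groups = _group_codes(self.groups)
        state = _fit_arrays(self.exog, self.endog, codes, n_groups, tol=tol, maxiter=maxiter)
        return GEEResults(self, state)


@dataclass
class GEEResults:
    """Fit results: coefficients, working correlation, robust inference."""

    model: ExchangeableGEE
    _state: dict

    def __post_init__(self) -> None:
        names = self.model.exog_names
        self.params = pd.Series(self._state["beta"], index=names, name="coefficient")
        self.rho = float(self._state["rho"])
        self.phi = float(self._state["phi"])
        self.cov_robust = pd.DataFrame(self._state["robust_cov"], index=names, columns=names)
        self.cov_naive = pd.DataFrame(self._state["naive_cov"], index=names, columns=names)
        self.n_obs = int(self._state["n_obs"])
        self.n_clusters = int(self._state["n_clusters"])
        self.iterations = int(self._state["iterations"])
        self.converged = bool(self._state["converged"])

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.clip(np.diag(self.cov_robust.to_numpy()), 0.0, None)),
            index=self.params.index,
            name="robust_se",
        )

    @property
    def pvalues(self) -> pd.Series:
        se = self.bse.to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, self.params.to_numpy() / se, np.inf)
        return pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=self.params.index, name="p")

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = Z_975 if alpha == 0.05 else stats.norm.ppf(1.0 - alpha / 2.0)
        est, se = self.params.to_numpy(), self.bse.to_numpy()
        return pd.DataFrame(
            {"lower": est - z * se, "upper": est + z * se}, index=self.params.index
        )

    def predict(self, design=None) -> np.ndarray:
        """Marginal predictions X @ beta for a design (default: fitting data)."""
        if design is None:
            X = self.model.exog
        elif isinstance(design, DesignMatrix):
            if design.column_names != self.model.exog_names:
                raise SchemaError(
                    f"design columns {design.column_names} do not match fit "
                    f"columns {self.model.exog_names}"
                )
            X = design.values
        else:
            X = np.atleast_2d(np.asarray(design, dtype=float))
            if X.shape[1] != len(self.model.exog_names):
                raise SchemaError("prediction design width does not match the fit")
        return X @ self.params.to_numpy()

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.predict()

    def coefficient_table(self) -> pd.DataFrame:
        """Estimates, robust SEs, 95% CIs, normal p-values and stars."""
        ci = self.conf_int()
        p = self.pvalues
        stars = pd.Series(
            np.select(
                [p < 0.001, p < 0.01, p < 0.05],
                ["***", "**", "*"],
                default="",
            ),
            index=p.index,
        )
        return pd.DataFrame(
            {
                "estimate": self.params,
                "robust_se": self.bse,
                "ci_lower": ci["lower"],
                "ci_upper": ci["upper"],
                "p_value": p,
                "": stars,
            }
        )

    def summary(self) -> str:
        spec = self.model.design.spec.name if self.model.design and self.model.design.spec else "GEE"
        head = (
            f"{spec}: linear GEE, exchangeable working correlation\n"
            f"  clusters: {self.n_clusters}   observations: {self.n_obs}\n"
            f"  rho = {self.rho:.4f}   scale = {self.phi:.2f}   "
            f"iterations = {self.iterations}   converged = {self.converged}\n"
        )
        table = self.coefficient_table().to_string(float_format=lambda v: f"{v:10.4f}")
        return head + table + "\n(*: p<0.05, **: p<0.01, ***: p<0.001; robust SEs)"

    def to_json(self, path=None) -> str:
        payload = {
            "model": self.model.design.spec.name if self.model.design and self.model.design.spec else None,
            "coefficients": self.params.to_dict(),
            "robust_se": self.bse.to_dict(),
            "conf_int": {k: list(v) for k, v in self.conf_int().T.to_dict("list").items()},
            "p_values": self.pvalues.to_dict(),
            "rho": self.rho,
            "phi": self.phi,
            "convergence": {
                "converged": self.converged,
                "iterations": self.iterations,
                "n_clusters": self.n_clusters,
                "n_obs": self.n_obs,
            },
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text
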