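"""Generalized estimating equations with an exchangeable working correlation.

Population-averaged linear model for clustered outcomes (here: one cluster
per participant, one row per participant-day, outcome in percentage
points).  Identity link, Gaussian variance function.  Estimation iterates

1. a generalized least-squares update of the coefficients given the working
   correlation ``alpha``, using the closed-form inverse of the exchangeable
   correlation matrix, and
2. moment estimation of ``alpha`` and the dispersion ``phi`` from
   standardized residuals (Liang-Zeger estimators: ``phi`` with denominator
   N - p, ``alpha`` with denominator Npairs - p),

until the largest coefficient change falls below a tolerance.  Inference
uses the robust (sandwich) covariance; a Mancl-DeRouen bias-corrected
sandwich is available for small numbers of clusters.

The estimating-equation fixed point does not depend on ``phi``; only
``alpha`` and the naive covariance do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["ExchangeableGEE", "ExchangeableGEEResults", "SingularDesignError"]

_ALPHA_EPS = 1e-6


class SingularDesignError(ValueError):
    """The design matrix is rank-deficient; names the collinear columns."""


class ExchangeableGEE:
    """Identity-link GEE model with exchangeable within-cluster correlation.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Outcome vector.
    exog : array-like, shape (n, p)
        Design matrix including the intercept column.
    groups : array-like, shape (n,)
        Cluster labels (participant identifiers).
    exog_names : sequence of str, optional
        Column names for the design matrix.
    """

    def __init__(self, endog, exog, groups, exog_names=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or len(self.endog) != self.exog.shape[0]:
            raise ValueError("endog and exog shapes are inconsistent")
        groups = np.asarray(groups)
        if len(groups) != len(self.endog):
            raise ValueError("groups length does not match endog")
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{j}" for j in range(self.exog.shape[1])]
        )
        if len(self.exog_names) != self.exog.shape[1]:
            raise ValueError("exog_names length does not match exog columns")

        # stable cluster partition (order of first appearance)
        _, first_idx = np.unique(groups, return_index=True)
        labels = groups[np.sort(first_idx)]
        self.group_labels = list(labels)
        self._index_lists = [np.flatnonzero(groups == g) for g in self.group_labels]
        if len(self.group_labels) < 2:
            raise ValueError("at least 2 clusters are required")
        self._check_rank()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str, predictors, group: str):
        """Build the model from a tidy DataFrame; an intercept is prepended."""
        predictors = list(predictors)
        X = np.column_stack(
            [np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in predictors]
        )
        return cls(
            data[outcome].to_numpy(dtype=float),
            X,
            data[group].to_numpy(),
            exog_names=["intercept"] + predictors,
        )

    # ------------------------------------------------------------------
    def _check_rank(self) -> None:
        q, r = np.linalg.qr(self.exog)
        diag = np.abs(np.diag(r))
        tol = max(self.exog.shape) * np.finfo(float).eps * (diag.max() or 1.0)
        bad = [self.exog_names[j] for j in np.flatnonzero(diag < tol)]
        if bad:
            raise SingularDesignError(f"collinear design columns: {bad}")

    @staticmethod
    def _solve_exchangeable(alpha: float, block: np.ndarray) -> np.ndarray:
        """R(alpha)^{-1} @ block for an exchangeable correlation matrix.

        Uses R^{-1}x = x/(1-a) - a/((1-a)(1+a(k-1))) * sum(x) per column.
        """
        k = block.shape[0]
        c = alpha / ((1.0 - alpha) * (1.0 + alpha * (k - 1)))
        return block / (1.0 - alpha) - c * block.sum(axis=0, keepdims=True)

    def _gls_beta(self, alpha: float) -> np.ndarray:
        p = self.exog.shape[1]
        A = np.zeros((p, p))
        b = np.zeros(p)
        for idx in self._index_lists:
            X = self.exog[idx]
            y = self.endog[idx]
            RiX = self._solve_exchangeable(alpha, X)
            A += X.T @ RiX
            b += RiX.T @ y
        return np.linalg.solve(A, b)

    def _moments(self, beta: np.ndarray) -> tuple[float, float]:
        """Moment estimates (phi, alpha) from residuals at beta."""
        p = self.exog.shape[1]
        n = len(self.endog)
        resid = self.endog - self.exog @ beta
        ssr = float(resid @ resid)
        phi = ssr / (n - p)
        cross = 0.0
        npairs = 0.0
        for idx in self._index_lists:
            e = resid[idx]
            cross += (e.sum() ** 2 - float(e @ e)) / 2.0
            k = len(e)
            npairs += 0.5 * k * (k - 1)
        alpha = cross / (phi * (npairs - p))
        return phi, alpha

    def _clip_alpha(self, alpha: float) -> float:
        kmax = max(len(idx) for idx in self._index_lists)
        lo = -1.0 / (kmax - 1) + _ALPHA_EPS if kmax > 1 else 0.0
        return float(np.clip(alpha, lo, 1.0 - _ALPHA_EPS))

    def fit(
        self,
        maxiter: int = 100,
        tol: float = 1e-8,
        update_alpha: bool = True,
        start_alpha: float = 0.0,
        small_sample: bool = False,
    ) -> "ExchangeableGEEResults":
        """Fit the model.

        ``update_alpha=False`` freezes the working correlation at
        ``start_alpha`` (0 gives the independence working model, whose
        coefficient solution is ordinary least squares).  ``small_sample``
        switches the reported covariance to the Mancl-DeRouen bias-corrected
        sandwich, appropriate when the number of clusters is small.
        """
        alpha = self._clip_alpha(start_alpha)
        beta = self._gls_beta(alpha)
        phi, _ = self._moments(beta)
        converged = not update_alpha
        n_iter = 0
        if update_alpha:
            for n_iter in range(1, maxiter + 1):
                phi, alpha_new = self._moments(beta)
                alpha = self._clip_alpha(alpha_new)
                beta_new = self._gls_beta(alpha)
                delta = float(np.max(np.abs(beta_new - beta)))
                beta = beta_new
                if delta < tol:
                    converged = True
                    break
        cov_robust, cov_naive = self._covariances(beta, alpha, phi)
        cov_used = (
            self._mancl_derouen(beta, alpha) if small_sample else cov_robust
        )
        return ExchangeableGEEResults(
            model=self,
            params=beta,
            cov_robust=cov_used,
            cov_naive=cov_naive,
            alpha=alpha,
            scale=phi,
            converged=converged,
            n_iter=n_iter,
            small_sample=small_sample,
        )

    def _covariances(self, beta, alpha, phi):
        p = self.exog.shape[1]
        B = np.zeros((p, p))
        M = np.zeros((p, p))
        resid = self.endog - self.exog @ beta
        for idx in self._index_lists:
            X = self.exog[idx]
            RiX = self._solve_exchangeable(alpha, X)
            B += X.T @ RiX
            g = RiX.T @ resid[idx]
            M += np.outer(g, g)
        Binv = np.linalg.inv(B)
        return Binv @ M @ Binv, phi * Binv

    def _mancl_derouen(self, beta, alpha):
        """Bias-corrected sandwich: residuals inflated by (I - H_i)^{-1}."""
        p = self.exog.shape[1]
        B = np.zeros((p, p))
        resid = self.endog - self.exog @ beta
        blocks = []
        for idx in self._index_lists:
            X = self.exog[idx]
            RiX = self._solve_exchangeable(alpha, X)
            B += X.T @ RiX
            blocks.append((X, RiX, resid[idx]))
        Binv = np.linalg.inv(B)
        M = np.zeros((p, p))
        for X, RiX, e in blocks:
            H = X @ Binv @ RiX.T  # X_i B^{-1} X_i' R_i^{-1}
            e_adj = np.linalg.solve(np.eye(len(e)) - H, e)
            g = RiX.T @ e_adj
            M += np.outer(g, g)
        return Binv @ M @ Binv


@dataclass
class ExchangeableGEEResults:
    """Estimates, robust uncertainties and diagnostics of a fitted GEE."""

    model: ExchangeableGEE
    params: np.ndarray
    cov_robust: np.ndarray
    cov_naive: np.ndarray
    alpha: float
    scale: float
    converged: bool
    n_iter: int
    small_sample: bool = False

    @property
    def exog_names(self) -> list[str]:
        return self.model.exog_names

    @property
    def bse(self) -> np.ndarray:
        """Robust (sandwich) standard errors."""
        return np.sqrt(np.diag(self.cov_robust))

    @property
    def n_clusters(self) -> int:
        return len(self.model.group_labels)

    @property
    def nobs(self) -> int:
        return len(self.model.endog)

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        """Two-sided Wald p-values with a Normal reference."""
        return 2 * norm.sf(np.abs(self.zvalues))

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        z = norm.ppf(0.5 + level / 2)
        return np.column_stack(
            [self.params - z * self.bse, self.params + z * self.bse]
        )

    def params_series(self) -> pd.Series:
        return pd.Series(self.params, index=self.exog_names)

    def to_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "estimate": self.params,
                "robust_se": self.bse,
                "ci95_low": ci[:, 0],
                "ci95_high": ci[:, 1],
                "p_value": self.pvalues,
            },
            index=self.exog_names,
        )

    def to_dict(self) -> dict:
        frame = self.to_frame()
        return {
            "coefficients": {
                name: {
                    "estimate": float(row["estimate"]),
                    "robust_se": float(row["robust_se"]),
                    "ci95": [float(row["ci95_low"]), float(row["ci95_high"])],
                    "p_value": float(row["p_value"]),
                }
                for name, row in frame.iterrows()
            },
            "alpha_hat": float(self.alpha),
            "scale": float(self.scale),
            "n_clusters": self.n_clusters,
            "n_obs": self.nobs,
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "small_sample_correction": bool(self.small_sample),
        }

    def summary(self) -> str:
        frame = self.to_frame()
        lines = [
            "Exchangeable GEE (identity link, Gaussian variance)",
            f"  clusters: {self.n_clusters}   observations: {self.nobs}",
            f"  working correlation alpha: {self.alpha:.4f}   "
            f"dispersion: {self.scale:.4f}",
            f"  converged: {self.converged} (iterations: {self.n_iter})"
            + ("   [Mancl-DeRouen covariance]" if self.small_sample else ""),
            "",
            f"  {'':<16}{'coef':>10}{'rob.SE':>10}{'[0.025':>10}{'0.975]':>10}"
            f"{'p':>8}",
        ]
        for name, row in frame.iterrows():
            lines.append(
                f"  {name:<16}{row['estimate']:>10.3f}{row['robust_se']:>10.3f}"
                f"{row['ci95_low']:>10.3f}{row['ci95_high']:>10.3f}"
                f"{row['p_value']:>8.3f}"
            )
        return "\n".join(lines)
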