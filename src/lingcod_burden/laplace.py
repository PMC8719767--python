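"""Laplace-approximated maximum likelihood for negative-binomial mixed models.

The model: counts y_i ~ NB2(mu_i, theta) with

    log mu_i = offset_i + x_i' beta + z_i' b,      b ~ N(0, Sigma(phi)),

where b stacks every random effect (nested intercepts and/or correlated
per-group slope vectors) and Sigma is block diagonal.  The marginal
likelihood integral over b is approximated at the joint mode:

    log L(beta, theta, phi) ~= l(y | b_hat) - 0.5 b_hat' Sigma^-1 b_hat
                               + 0.5 log|Sigma^-1| - 0.5 log|H|,

with H = Z' W Z + Sigma^-1 the negative Hessian of the joint log-density at
b_hat.  Estimation is a nested scheme: inner damped Newton iterations to the
joint random-effect mode (the objective is strictly concave in b, so the
mode is unique), outer bounded quasi-Newton (L-BFGS-B) over beta, log theta
and the log-Cholesky parameters of Sigma.  Positivity of theta and of the
variance components is enforced by optimizing on the log scale.

Z is sparse (a handful of nonzeros per observation), so each Newton step
costs one sparse product plus one dense Cholesky of the q x q matrix H.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from scipy.special import digamma

from .nb import nb_log_pmf_unchecked, nb_score_eta, nb_neg_hess_eta

_ETA_CLIP = 40.0  # guards exp() during line search; never active at a mode


def _encode_labels(labels) -> tuple[np.ndarray, list]:
    codes, uniques = pd.factorize(np.asarray(labels), sort=False)
    if (codes < 0).any():
        raise ValueError("random-effect grouping labels may not be missing")
    return codes, list(uniques)


@dataclass
class ScalarIntercept:
    """A random intercept per level of one grouping factor; one sd parameter."""

    name: str
    labels: np.ndarray  # length n_obs, group label per observation

    def __post_init__(self) -> None:
        self.codes, self.levels = _encode_labels(self.labels)
        self.n_levels = len(self.levels)
        self.n_cols = self.n_levels
        self.n_params = 1

    def z_entries(self, col0: int):
        rows = np.arange(len(self.codes))
        return rows, col0 + self.codes, np.ones(len(self.codes))

    def precision_blocks(self, params: np.ndarray):
        (log_sd,) = params
        prec = np.exp(-2.0 * log_sd)
        logdet_sigma = 2.0 * log_sd * self.n_levels
        return ("diagonal", np.full(self.n_cols, prec)), logdet_sigma

    def covariance(self, params: np.ndarray) -> np.ndarray:
        return np.array([[np.exp(2.0 * params[0])]])

    def default_params(self) -> np.ndarray:
        return np.array([np.log(0.3)])

    def param_bounds(self) -> list[tuple[float, float]]:
        return [(-8.0, 4.0)]


@dataclass
class CorrelatedSlopes:
    """A correlated k-vector of random coefficients per level of a factor.

    ``covariates`` is n_obs x k: the within-level design each coefficient
    multiplies (first column usually all ones for the intercept).  The k x k
    covariance is parameterized by its Cholesky factor, log diagonal first,
    then the strict lower triangle row-major.
    """

    name: str
    labels: np.ndarray
    covariates: np.ndarray
    slope_names: Sequence[str]

    def __post_init__(self) -> None:
        self.codes, self.levels = _encode_labels(self.labels)
        self.covariates = np.asarray(self.covariates, dtype=float)
        self.k = self.covariates.shape[1]
        if len(self.slope_names) != self.k:
            raise ValueError("slope_names length must match covariate columns")
        self.n_levels = len(self.levels)
        self.n_cols = self.n_levels * self.k
        self.n_params = self.k + self.k * (self.k - 1) // 2

    def z_entries(self, col0: int):
        n = len(self.codes)
        rows = np.repeat(np.arange(n), self.k)
        cols = (col0 + self.codes[:, None] * self.k + np.arange(self.k)[None, :]).ravel()
        vals = self.covariates.ravel()
        return rows, cols, vals

    def _chol(self, params: np.ndarray) -> np.ndarray:
        L = np.zeros((self.k, self.k))
        L[np.diag_indices(self.k)] = np.exp(params[: self.k])
        idx = self.k
        for i in range(1, self.k):
            for j in range(i):
                L[i, j] = params[idx]
                idx += 1
        return L

    def precision_blocks(self, params: np.ndarray):
        L = self._chol(params)
        # Sigma = L L'; block precision via Cholesky (stable for small k)
        prec = cho_solve((L, True), np.eye(self.k))
        prec = 0.5 * (prec + prec.T)
        logdet_sigma = 2.0 * float(np.sum(params[: self.k])) * self.n_levels
        return ("block", prec, self.n_levels), logdet_sigma

    def covariance(self, params: np.ndarray) -> np.ndarray:
        L = self._chol(params)
        return L @ L.T

    def default_params(self) -> np.ndarray:
        p = np.full(self.n_params, 0.0)
        p[: self.k] = np.log(0.3)
        return p

    def param_bounds(self) -> list[tuple[float, float]]:
        return [(-8.0, 4.0)] * self.k + [(-10.0, 10.0)] * (self.n_params - self.k)


@dataclass
class LaplaceFit:
    """Raw optimizer output for a Laplace NB mixed-model fit."""

    beta: np.ndarray
    theta: float
    term_params: list[np.ndarray]
    loglik: float
    converged: bool
    n_outer_iter: int
    message: str
    beta_cov: np.ndarray
    random_modes: list[np.ndarray]  # per term: (n_levels, k) conditional modes
    random_cond_sd: list[np.ndarray]  # per term: matching conditional sds
    term_covariances: list[np.ndarray]


class LaplaceNBModel:
    """Negative-binomial mixed model with a Laplace-approximated likelihood.

    Parameters
    ----------
    y : observation-level counts
    X : observation-level fixed-effect matrix (includes the intercept column)
    offset : observation-level offset added to the linear predictor
    terms : random-effect structure; may be empty, in which case the model
        is an ordinary NB regression and the "approximation" is exact.
    """

    def __init__(self, y, X, offset=None, terms: Sequence = ()):  # noqa: D401
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        if self.y.shape[0] != self.n:
            raise ValueError("y and X row counts differ")
        self.offset = (
            np.zeros(self.n) if offset is None else np.asarray(offset, dtype=float)
        )
        self.terms = list(terms)
        self.q = sum(t.n_cols for t in self.terms)
        self._col0 = np.cumsum([0] + [t.n_cols for t in self.terms])[:-1]
        if self.q:
            rows, cols, vals = [], [], []
            for t, c0 in zip(self.terms, self._col0):
                r, c, v = t.z_entries(c0)
                rows.append(r), cols.append(c), vals.append(v)
            self.Z = sp.csr_matrix(
                (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                shape=(self.n, self.q),
            )
        else:
            self.Z = None
        self._b_warm = np.zeros(self.q)

    # -- parameter packing -------------------------------------------------
    @property
    def n_params(self) -> int:
        return self.p + 1 + sum(t.n_params for t in self.terms)

    def pack(self, beta, log_theta, term_params: Sequence[np.ndarray]) -> np.ndarray:
        parts = [np.asarray(beta, dtype=float), [log_theta]]
        parts += [np.asarray(tp, dtype=float) for tp in term_params]
        return np.concatenate([np.atleast_1d(p) for p in parts])

    def unpack(self, x: np.ndarray):
        beta = x[: self.p]
        log_theta = x[self.p]
        term_params, i = [], self.p + 1
        for t in self.terms:
            term_params.append(x[i : i + t.n_params])
            i += t.n_params
        return beta, log_theta, term_params

    # -- precision assembly ------------------------------------------------
    def _precision(self, term_params):
        """Sparse block-diagonal precision of b, plus log|Sigma|."""
        blocks, logdet_sigma = [], 0.0
        for t, tp in zip(self.terms, term_params):
            spec, ld = t.precision_blocks(tp)
            logdet_sigma += ld
            if spec[0] == "diagonal":
                blocks.append(sp.diags(spec[1]))
            else:
                _, prec, n_levels = spec
                blocks.append(sp.block_diag([prec] * n_levels))
        P = sp.block_diag(blocks, format="csr") if blocks else None
        return P, logdet_sigma

    # -- inner problem -----------------------------------------------------
    def _joint_neglogpost(self, b, beta, theta, P):
        eta = np.clip(self.offset + self.X @ beta + (self.Z @ b), -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        nll = -float(np.sum(nb_log_pmf_unchecked(self.y, mu, theta)))
        return nll + 0.5 * float(b @ (P @ b)), mu

    def _inner_mode(self, beta, theta, P, b0, gtol=1e-8, max_iter=50):
        """Damped Newton to the joint mode of all random effects."""
        b = b0.copy()
        f, mu = self._joint_neglogpost(b, beta, theta, P)
        H_chol = None
        for _ in range(max_iter):
            s = nb_score_eta(self.y, mu, theta)
            grad = -(self.Z.T @ s) + P @ b
            if np.max(np.abs(grad)) < gtol:
                break
            w = nb_neg_hess_eta(self.y, mu, theta)
            H = (self.Z.T @ self.Z.multiply(w[:, None])).toarray() + P.toarray()
            H_chol = cho_factor(H, lower=True)
            step = -cho_solve(H_chol, grad)
            t_ls = 1.0
            for _ in range(30):
                f_new, mu_new = self._joint_neglogpost(b + t_ls * step, beta, theta, P)
                if f_new <= f + 1e-12:
                    break
                t_ls *= 0.5
            b = b + t_ls * step
            f, mu = f_new, mu_new
        # refresh curvature at the final point
        w = nb_neg_hess_eta(self.y, mu, theta)
        H = (self.Z.T @ self.Z.multiply(w[:, None])).toarray() + P.toarray()
        H_chol = cho_factor(H, lower=True)
        return b, f, mu, w, H_chol

    # -- marginal likelihood -----------------------------------------------
    def marginal_loglik(self, beta, theta, term_params: Sequence[np.ndarray] = ()):
        """Laplace-approximated marginal log-likelihood at given parameters."""
        beta = np.asarray(beta, dtype=float)
        if not self.terms:
            eta = np.clip(self.offset + self.X @ beta, -_ETA_CLIP, _ETA_CLIP)
            return float(np.sum(nb_log_pmf_unchecked(self.y, np.exp(eta), theta)))
        P, logdet_sigma = self._precision(term_params)
        b, f, _, _, H_chol = self._inner_mode(beta, theta, P, self._b_warm)
        self._b_warm = b
        logdet_H = 2.0 * float(np.sum(np.log(np.diag(H_chol[0]))))
        return -f - 0.5 * logdet_sigma - 0.5 * logdet_H

    def _neg_marginal(self, x: np.ndarray) -> float:
        beta, log_theta, term_params = self.unpack(x)
        val = self.marginal_loglik(beta, np.exp(log_theta), term_params)
        if not np.isfinite(val):
            return 1e12
        return -val

    def _neg_loglik_grad_plain(self, x: np.ndarray):
        """Exact objective and gradient for the random-effect-free model."""
        beta, log_theta = x[: self.p], x[self.p]
        theta = np.exp(log_theta)
        eta = np.clip(self.offset + self.X @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        ll = float(np.sum(nb_log_pmf_unchecked(self.y, mu, theta)))
        g_beta = self.X.T @ nb_score_eta(self.y, mu, theta)
        dll_dtheta = np.sum(
            digamma(self.y + theta) - digamma(theta)
            + np.log(theta) - np.log(theta + mu)
            + 1.0 - (self.y + theta) / (theta + mu)
        )
        grad = np.concatenate([g_beta, [theta * dll_dtheta]])
        if not np.isfinite(ll):
            return 1e12, np.zeros_like(x)
        return -ll, -grad

    # -- fitting -----------------------------------------------------------
    def _initial_point(self, x0=None, fix_theta=None):
        if x0 is not None:
            return np.asarray(x0, dtype=float)
        beta0 = np.zeros(self.p)
        # intercept from the mean response rate
        mean_rate = max(np.mean(self.y / np.exp(np.clip(self.offset, -50, 50))), 1e-3)
        beta0[0] = np.log(mean_rate)
        log_theta0 = 0.0 if fix_theta is None else np.log(fix_theta)
        return self.pack(beta0, log_theta0, [t.default_params() for t in self.terms])

    def fit(
        self,
        x0: Optional[np.ndarray] = None,
        fix_theta: Optional[float] = None,
        outer_tol: float = 1e-6,
        max_outer_iter: int = 200,
        compute_uncertainty: bool = True,
    ) -> LaplaceFit:
        """Maximize the Laplace marginal likelihood.

        ``outer_tol`` is the relative function tolerance of the outer
        quasi-Newton loop; ``fix_theta`` pins the dispersion (useful for
        Poisson-limit checks).  Non-convergence is flagged on the result,
        never raised.
        """
        x = self._initial_point(x0, fix_theta)
        bounds = [(None, None)] * self.p
        if fix_theta is not None:
            lt = float(np.log(fix_theta))
            bounds.append((lt, lt))
            x[self.p] = lt
        else:
            bounds.append((-6.0, 16.0))
        for t in self.terms:
            bounds.extend(t.param_bounds())

        self._b_warm = np.zeros(self.q)
        if not self.terms:
            res = minimize(
                self._neg_loglik_grad_plain,
                x,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={
                    # exact ML with analytic gradients is cheap: converge hard
                    "ftol": min(outer_tol, 1e-12),
                    "gtol": 1e-9,
                    "maxiter": max(max_outer_iter, 500),
                },
            )
        else:
            res = minimize(
                self._neg_marginal,
                x,
                jac="3-point",
                method="L-BFGS-B",
                bounds=bounds,
                options={
                    "ftol": outer_tol,
                    "gtol": 1e-6,
                    "maxiter": max_outer_iter,
                    "eps": 1e-6,
                },
            )
        beta, log_theta, term_params = self.unpack(res.x)
        theta = float(np.exp(log_theta))
        loglik = -float(res.fun)
        return self._assemble_fit(
            beta, theta, term_params, loglik, bool(res.success), int(res.nit),
            str(res.message), compute_uncertainty,
        )

    def _assemble_fit(
        self, beta, theta, term_params, loglik, converged, nit, message,
        compute_uncertainty,
    ) -> LaplaceFit:
        modes, cond_sds, covs = [], [], []
        if self.terms:
            P, _ = self._precision(term_params)
            b, _, mu, w, H_chol = self._inner_mode(beta, theta, P, self._b_warm)
            self._b_warm = b
            if compute_uncertainty:
                Hinv_diag = np.diag(cho_solve(H_chol, np.eye(self.q)))
            else:
                Hinv_diag = np.full(self.q, np.nan)
            for t, c0 in zip(self.terms, self._col0):
                k = getattr(t, "k", 1)
                modes.append(b[c0 : c0 + t.n_cols].reshape(t.n_levels, k))
                cond_sds.append(
                    np.sqrt(Hinv_diag[c0 : c0 + t.n_cols]).reshape(t.n_levels, k)
                )
            covs = [t.covariance(tp) for t, tp in zip(self.terms, term_params)]
            if compute_uncertainty:
                WX = w[:, None] * self.X
                A = self.X.T @ WX
                B = WX.T @ self.Z  # p x q
                beta_cov = np.linalg.pinv(A - B @ cho_solve(H_chol, B.T))
            else:
                beta_cov = np.full((self.p, self.p), np.nan)
        else:
            eta = np.clip(self.offset + self.X @ beta, -_ETA_CLIP, _ETA_CLIP)
            mu = np.exp(eta)
            w = nb_neg_hess_eta(self.y, mu, theta)
            beta_cov = (
                np.linalg.pinv(self.X.T @ (w[:, None] * self.X))
                if compute_uncertainty
                else np.full((self.p, self.p), np.nan)
            )
        return LaplaceFit(
            beta=np.asarray(beta, dtype=float),
            theta=theta,
            term_params=[np.asarray(tp, dtype=float) for tp in term_params],
            loglik=loglik,
            converged=converged,
            n_outer_iter=nit,
            message=message,
            beta_cov=beta_cov,
            random_modes=modes,
            random_cond_sd=cond_sds,
            term_covariances=covs,
        )
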