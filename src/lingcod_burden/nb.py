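"""NB2 negative-binomial log-likelihood and its derivatives on the log-link scale.

Parameterization (NB2): for count y with mean mu and dispersion theta > 0,

    Var(y) = mu + mu^2 / theta,

so theta -> infinity recovers the Poisson.  All model code works with the
linear predictor eta = log(mu); first and second derivatives with respect to
eta are what the Laplace machinery needs.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln


def nb_log_pmf(count, mean, theta):
    """NB2 log probability mass.

    Accepts scalars or arrays (broadcast).  ``mean`` may be 0, in which case
    the mass is a point mass at zero.  Negative counts or non-positive theta
    are domain errors.
    """
    y = np.asarray(count, dtype=float)
    mu = np.asarray(mean, dtype=float)
    th = np.asarray(theta, dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("count must be a non-negative integer")
    if np.any(th <= 0):
        raise ValueError("theta must be > 0")
    if np.any(mu < 0):
        raise ValueError("mean must be >= 0")

    y, mu, th = np.broadcast_arrays(y, mu, th)
    out = np.empty(y.shape, dtype=float)
    zero_mu = mu == 0
    # mean 0: P(y=0)=1, P(y>0)=0
    out[zero_mu] = np.where(y[zero_mu] == 0, 0.0, -np.inf)
    m = ~zero_mu
    ym, mum, thm = y[m], mu[m], th[m]
    out[m] = (
        gammaln(ym + thm)
        - gammaln(thm)
        - gammaln(ym + 1)
        + thm * (np.log(thm) - np.log(thm + mum))
        + ym * (np.log(mum) - np.log(thm + mum))
    )
    if out.ndim == 0:
        return float(out)
    return out


def nb_score_eta(y, mu, theta):
    """d log-pmf / d eta with eta = log mu."""
    return y - (y + theta) * mu / (mu + theta)


def nb_neg_hess_eta(y, mu, theta):
    """-(d^2 log-pmf / d eta^2); strictly positive, so eta-concavity holds."""
    return (y + theta) * theta * mu / (mu + theta) ** 2


def nb_loglik(y, eta, theta, offset=0.0):
    """Sum of NB2 log-pmf at linear predictor eta (+ offset)."""
    mu = np.exp(eta + offset)
    return float(np.sum(nb_log_pmf_unchecked(y, mu, theta)))


def nb_log_pmf_unchecked(y, mu, theta):
    """Fast path without validation, for inner optimization loops."""
    return (
        gammaln(y + theta)
        - gammaln(theta)
        - gammaln(y + 1)
        + theta * (np.log(theta) - np.log(theta + mu))
        + y * (np.log(np.maximum(mu, 1e-300)) - np.log(theta + mu))
    )


def sample_nb(rng: np.random.Generator, mean, theta):
    """Draw NB2 counts via the gamma-Poisson mixture (numerically safe for
    very large theta, where the draw degenerates to Poisson)."""
    mean = np.asarray(mean, dtype=float)
    lam = rng.gamma(shape=theta, scale=mean / theta)
    return rng.poisson(lam)
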