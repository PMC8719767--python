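"""Parasite community composition: Bray-Curtis dissimilarities and
permutational MANOVA with sequential (Type-I) sums of squares.

The dissimilarity matrix D is squared and Gower-centered,

    G = -0.5 * J D^2 J,    J = I - 11'/n,

and each term's sequential SS is tr(H_k G) - tr(H_{k-1} G) where H_k is the
hat matrix of the cumulative design through term k (McArdle-Anderson
partitioning).  Pseudo-F compares a term's mean square to the residual mean
square of the full model; p-values come from free (unrestricted) permutation
of observation labels, with the observed statistic included in the null set
((count + 1)/(n_perm + 1)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


@dataclass
class DissimilarityMatrix:
    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("values must be square and match labels")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("dissimilarities must lie in [0, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)


def bray_curtis(u, v) -> float:
    """Bray-Curtis dissimilarity sum|u-v| / sum(u+v) between count vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    if np.any(u < 0) or np.any(v < 0):
        raise ValueError("entries must be non-negative")
    if u.sum() == 0 and v.sum() == 0:
        raise ValueError("Bray-Curtis is undefined when both vectors are all-zero")
    return float(np.abs(u - v).sum() / (u + v).sum())


def community_dissimilarity(
    counts_wide: pd.DataFrame, metric: str = "braycurtis"
) -> tuple[DissimilarityMatrix, list]:
    """Pairwise dissimilarities between fish from a fish x taxon matrix.

    Fish with all-zero parasite vectors are excluded first (the distance is
    undefined for them); the excluded ids are returned for logging.
    ``metric`` is ``braycurtis`` on raw counts (default) or ``jaccard`` on
    presence/absence.
    """
    totals = counts_wide.sum(axis=1)
    excluded = list(counts_wide.index[totals == 0])
    kept = counts_wide.loc[totals > 0]
    if len(kept) < 2:
        raise ValueError("need at least 2 fish with non-zero parasite vectors")
    if metric == "braycurtis":
        dm = squareform(pdist(kept.to_numpy(dtype=float), metric="braycurtis"))
    elif metric == "jaccard":
        dm = squareform(pdist(kept.to_numpy(dtype=float) > 0, metric="jaccard"))
    else:
        raise ValueError("metric must be 'braycurtis' or 'jaccard'")
    return DissimilarityMatrix(list(kept.index), dm), excluded


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _term_columns(values: np.ndarray, continuous: bool) -> np.ndarray:
    if continuous:
        return np.asarray(values, dtype=float)[:, None]
    codes, levels = pd.factorize(values)
    # full dummy expansion; rank handled via the projector
    return (codes[:, None] == np.arange(len(levels))[None, :]).astype(float)


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X.T @ X) @ X.T


def permanova(
    dist: DissimilarityMatrix,
    factors: pd.DataFrame,
    term_order: Optional[Sequence[str]] = None,
    continuous: Sequence[str] = ("depth",),
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Sequential-SS PERMANOVA over an ordered list of terms.

    ``factors`` carries one column per term, aligned with ``dist.labels``;
    columns named in ``continuous`` enter as single-df covariates, the rest
    as categorical factors.  Returns the standard table: df, sequential SS,
    pseudo-F, R^2 and permutation p per term, plus residual and total rows.
    A term absorbing all residual df yields an undefined (NaN) pseudo-F.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if len(factors) != dist.n:
        raise ValueError("factors and dissimilarity matrix must align")
    terms = list(term_order) if term_order is not None else list(factors.columns)
    n = dist.n
    G = _gower_center(dist.values)
    ss_total = float(np.trace(G))

    # cumulative hat matrices: intercept-only, then +term1, +term1+term2, ...
    X = np.ones((n, 1))
    hats, dfs = [_hat(X)], []
    for t in terms:
        cols = _term_columns(factors[t].to_numpy(), t in continuous)
        X = np.column_stack([X, cols])
        H = _hat(X)
        dfs.append(int(np.round(np.trace(H) - np.trace(hats[-1]))))
        hats.append(H)
    df_res = n - int(np.round(np.trace(hats[-1])))

    def seq_stats(g: np.ndarray):
        tr = [float(np.sum(h * g)) for h in hats]  # tr(HG), H symmetric
        ss = np.diff(tr)
        ss_res = float(np.trace(g)) - tr[-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            ms_res = ss_res / df_res if df_res > 0 else np.nan
            f = np.array(
                [
                    (ss[k] / dfs[k]) / ms_res if dfs[k] > 0 and df_res > 0 and ms_res > 0
                    else np.nan
                    for k in range(len(terms))
                ]
            )
        return ss, ss_res, f

    ss_obs, ss_res, f_obs = seq_stats(G)

    rng = np.random.default_rng([seed, 104729])
    count_ge = np.zeros(len(terms))
    n_valid = np.zeros(len(terms))
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        _, _, f_perm = seq_stats(G[np.ix_(perm, perm)])
        for k in range(len(terms)):
            if np.isfinite(f_obs[k]) and np.isfinite(f_perm[k]):
                n_valid[k] += 1
                if f_perm[k] >= f_obs[k] - 1e-12:
                    count_ge[k] += 1
    with np.errstate(invalid="ignore"):
        pvals = (count_ge + 1) / (n_valid + 1)
    pvals = np.where(np.isfinite(f_obs), pvals, np.nan)

    rows = []
    for k, t in enumerate(terms):
        rows.append(
            {
                "term": t,
                "df": dfs[k],
                "ss": ss_obs[k],
                "pseudo_F": f_obs[k],
                "R2": ss_obs[k] / ss_total if ss_total > 0 else np.nan,
                "p": pvals[k],
            }
        )
    rows.append(
        {"term": "Residual", "df": df_res, "ss": ss_res, "pseudo_F": np.nan,
         "R2": ss_res / ss_total if ss_total > 0 else np.nan, "p": np.nan}
    )
    rows.append(
        {"term": "Total", "df": n - 1, "ss": ss_total, "pseudo_F": np.nan,
         "R2": 1.0, "p": np.nan}
    )
    return pd.DataFrame(rows)
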