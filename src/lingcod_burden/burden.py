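"""Parasite-burden mixed model: per-taxon counts vs depth, sex, color and
their interaction, with nested host random intercepts (fish within sampling
location within sampling region), a correlated per-taxon random vector for
the sex x color response, and a log total-length offset.

Reported fixed-effect terms use treatment contrasts referenced at
sex = female, color = blue, so coefficients read as ``sex[male]``,
``color[brown]`` and ``sex[male]*color[brown]``; Wald z = estimate/SE with a
two-sided standard-normal p-value, and no degrees-of-freedom correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import ModelDesign, ScalingMetadata, build_fixed_matrix, compute_vif, encode_sex_color
from .laplace import CorrelatedSlopes, LaplaceNBModel, ScalarIntercept
from .records import HostRecord, ParasiteCountTable, hosts_to_frame

INTERACTION = "sex[male]*color[brown]"


@dataclass
class FitOptions:
    """Optimizer controls for the burden model.

    ``x0`` warm-starts the outer optimizer from a packed parameter vector of
    a previous fit on the same design (used heavily by the permutation test,
    where each replicate differs from the observed data only in relabeled
    colors).  ``outer_tol`` is the relative outer tolerance; simulation
    studies may loosen it.
    """

    outer_tol: float = 1e-6
    max_outer_iter: int = 200
    x0: Optional[np.ndarray] = None
    fix_theta: Optional[float] = None
    compute_uncertainty: bool = True
    vif_warn_threshold: float = 5.0


@dataclass
class BurdenFitResult:
    """Fitted burden model: Table-1-style fixed effects plus the random part."""

    fixed_effects: pd.DataFrame  # term, estimate, se, z, p
    theta: float
    variance_components: dict
    taxon_modes: pd.DataFrame  # taxon_id, term, mode, cond_sd
    loglik: float
    converged: bool
    scaling_metadata: dict
    vif: Optional[pd.Series]
    n_obs: int
    design: ModelDesign
    packed_params: np.ndarray = field(repr=False, default=None)
    messages: list = field(default_factory=list)

    def coefficient(self, term: str) -> float:
        row = self.fixed_effects.loc[self.fixed_effects["term"] == term]
        if row.empty:
            raise KeyError(f"term {term!r} not in fitted model")
        return float(row["estimate"].iloc[0])


def wald_z(estimate: float, se: float) -> float:
    """Wald statistic estimate/SE (two-sided normal reference)."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    return estimate / se


def blue_to_brown_ratio(
    fit: Union[BurdenFitResult, Mapping[str, float]], sex: str
) -> float:
    """Multiplicative burden ratio of blue relative to brown fish of a sex.

    With brown as the non-reference color level, the blue:brown mean ratio is
    exp(-(color[brown] + interaction)) for males and exp(-color[brown]) for
    females; values above 1 mean blue fish carry more parasites.
    """
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    get = fit.coefficient if isinstance(fit, BurdenFitResult) else fit.__getitem__
    try:
        color = float(get("color[brown]"))
        inter = float(get(INTERACTION)) if sex == "male" else 0.0
    except KeyError as exc:
        raise KeyError(f"fit lacks required term: {exc}") from exc
    return float(np.exp(-(color + inter)))


def _obs_table(hosts, counts) -> tuple[pd.DataFrame, pd.DataFrame]:
    hosts_df = hosts if isinstance(hosts, pd.DataFrame) else hosts_to_frame(hosts)
    counts_df = counts.frame if isinstance(counts, ParasiteCountTable) else counts
    n_fish = hosts_df["fish_id"].nunique()
    taxa = pd.unique(counts_df["taxon_id"])
    if len(counts_df) != n_fish * len(taxa):
        raise ValueError(
            "count table must contain every (fish, taxon) pair exactly once; "
            "use read_count_table() to complete the grid with structural zeros"
        )
    if counts_df.duplicated(["fish_id", "taxon_id"]).any():
        raise ValueError("duplicate (fish, taxon) rows in count table")
    obs = counts_df.merge(hosts_df, on="fish_id", how="left", validate="m:1")
    if obs["region"].isna().any():
        bad = obs.loc[obs["region"].isna(), "fish_id"].iloc[0]
        raise ValueError(f"count table references unknown fish_id {bad!r}")
    if obs[["sex", "color"]].isna().any().any():
        raise ValueError("burden model requires definitive sex and color for every fish")
    return obs.reset_index(drop=True), hosts_df


def build_burden_model(
    hosts, counts, design: ModelDesign
) -> tuple[LaplaceNBModel, list[str], dict, pd.DataFrame]:
    """Assemble the observation-level Laplace model for the burden analysis."""
    obs, hosts_df = _obs_table(hosts, counts)

    X_host, names, depth_meta = build_fixed_matrix(
        obs.drop_duplicates("fish_id").set_index("fish_id"), design
    )
    host_index = {fid: i for i, fid in enumerate(obs["fish_id"].drop_duplicates())}
    rows = obs["fish_id"].map(host_index).to_numpy()
    X = X_host[rows]

    offset = (
        np.log(obs["total_length_cm"].to_numpy(dtype=float))
        if design.use_offset
        else np.zeros(len(obs))
    )

    terms = []
    if "region" in design.nested_terms:
        terms.append(ScalarIntercept("region", obs["region"].to_numpy()))
    if "location" in design.nested_terms:
        # qualify by region so identically named sites in two regions stay distinct
        loc = (obs["region"].astype(str) + ":" + obs["location"].astype(str)).to_numpy()
        terms.append(ScalarIntercept("location", loc))
    if "fish" in design.nested_terms:
        terms.append(ScalarIntercept("fish", obs["fish_id"].to_numpy()))
    if design.taxon_structure != "none":
        ind = encode_sex_color(obs, design)
        if design.taxon_structure == "full":
            cov = np.column_stack(
                [
                    np.ones(len(obs)),
                    ind["sex[male]"],
                    ind["color[brown]"],
                    ind[INTERACTION],
                ]
            )
        else:
            cov = np.column_stack([np.ones(len(obs)), ind[INTERACTION]])
        terms.append(
            CorrelatedSlopes(
                "taxon", obs["taxon_id"].to_numpy(), cov, design.taxon_slope_names
            )
        )

    model = LaplaceNBModel(obs["count"].to_numpy(dtype=float), X, offset, terms)
    meta = {"depth": depth_meta} if depth_meta is not None else {}
    return model, names, meta, obs


def fit_burden_model(
    hosts, counts, design: Optional[ModelDesign] = None,
    fit_options: Optional[FitOptions] = None,
) -> BurdenFitResult:
    """Fit the parasite-burden NB mixed model by Laplace-approximated ML.

    The VIF collinearity check runs first on the non-intercept fixed-effect
    columns; values above the threshold raise a warning, never an abort.
    Non-convergence is flagged on the result with parameters still reported.
    """
    design = design or ModelDesign()
    opts = fit_options or FitOptions()
    model, names, scaling_meta, obs = build_burden_model(hosts, counts, design)

    messages: list[str] = []
    vif = None
    if model.X.shape[1] > 2:
        host_X = obs.drop_duplicates("fish_id")
        X_host, _, _ = build_fixed_matrix(host_X.set_index("fish_id"), design)
        vif = compute_vif(X_host[:, 1:], names[1:])
        high = vif[vif > opts.vif_warn_threshold]
        if len(high):
            msg = f"VIF above {opts.vif_warn_threshold}: {high.to_dict()}"
            messages.append(msg)
            warnings.warn(msg)

    raw = model.fit(
        x0=opts.x0,
        fix_theta=opts.fix_theta,
        outer_tol=opts.outer_tol,
        max_outer_iter=opts.max_outer_iter,
        compute_uncertainty=opts.compute_uncertainty,
    )

    se = np.sqrt(np.maximum(np.diag(raw.beta_cov), 0.0))
    z = np.where(se > 0, raw.beta / np.where(se > 0, se, 1.0), np.nan)
    fixed = pd.DataFrame(
        {
            "term": names,
            "estimate": raw.beta,
            "se": se,
            "z": z,
            "p": 2.0 * norm.sf(np.abs(z)),
        }
    )

    variance_components: dict = {}
    taxon_modes = pd.DataFrame(columns=["taxon_id", "term", "mode", "cond_sd"])
    for term, cov, modes, csd in zip(
        model.terms, raw.term_covariances, raw.random_modes, raw.random_cond_sd
    ):
        if isinstance(term, ScalarIntercept):
            sd = float(np.sqrt(cov[0, 0]))
            variance_components[f"sd_{term.name}"] = sd
            if sd < 1e-3:
                messages.append(f"variance component for {term.name} fitted at boundary (~0)")
        else:
            slope_names = list(term.slope_names)
            variance_components["taxon_cov"] = pd.DataFrame(
                cov, index=slope_names, columns=slope_names
            )
            if np.any(np.sqrt(np.diag(cov)) < 1e-3):
                messages.append("taxon covariance fitted at or near the boundary (singular)")
            taxon_modes = pd.DataFrame(
                {
                    "taxon_id": np.repeat(term.levels, term.k),
                    "term": np.tile(slope_names, term.n_levels),
                    "mode": modes.ravel(),
                    "cond_sd": csd.ravel(),
                }
            )

    if not raw.converged:
        messages.append(f"outer optimizer did not converge: {raw.message}")

    return BurdenFitResult(
        fixed_effects=fixed,
        theta=raw.theta,
        variance_components=variance_components,
        taxon_modes=taxon_modes,
        loglik=raw.loglik,
        converged=raw.converged,
        scaling_metadata=scaling_meta,
        vif=vif,
        n_obs=model.n,
        design=design,
        packed_params=model.pack(raw.beta, np.log(raw.theta), raw.term_params),
        messages=messages,
    )


def extract_taxon_effects(fit: BurdenFitResult) -> pd.DataFrame:
    """Per-taxon sex x color interaction slopes with conditional SDs.

    Each taxon's total slope is the fixed interaction coefficient plus that
    taxon's conditional-mode deviation; output is ordered by total slope,
    ready for a caterpillar plot.  A taxon covariance fitted at zero yields
    all-zero deviations and is flagged via the fit's messages.
    """
    if fit.design.taxon_structure == "none":
        raise ValueError("fit has no taxon random term")
    sub = fit.taxon_modes[fit.taxon_modes["term"] == INTERACTION]
    if sub.empty:
        raise ValueError("fitted taxon structure lacks an interaction slope")
    fixed_int = fit.coefficient(INTERACTION)
    out = pd.DataFrame(
        {
            "taxon_id": sub["taxon_id"].to_numpy(),
            "deviation": sub["mode"].to_numpy(),
            "total_slope": fixed_int + sub["mode"].to_numpy(),
            "cond_sd": sub["cond_sd"].to_numpy(),
        }
    )
    return out.sort_values("total_slope").reset_index(drop=True)
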