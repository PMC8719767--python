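"""Body-condition indices and their mixed-model analyses.

Fulton's K = mass / length^3 (bare ratio, kg/cm^3; no display multiplier by
default) and the hepatosomatic index HSI = liver mass / body mass, fourth-
root transformed before modelling to improve normality.  Each index is
modelled as depth + sex + color + sex:color with nested random intercepts
for sampling location within sampling region, fitted by maximum likelihood
(statsmodels MixedLM provides the Gaussian LMM engine).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import ModelDesign, build_fixed_matrix, scale_plus_two
from .records import HostRecord, hosts_to_frame


@dataclass
class ConditionRecord:
    """Condition indices for one fish."""

    fish_id: str
    fultons_k: float
    hsi: float
    hsi_transformed: float


def fultons_k(total_mass: float, total_length: float, display_multiplier: float = 1.0) -> float:
    """Fulton's condition factor, mass / length^3.

    No scaling constant is applied by default; ``display_multiplier`` is an
    optional cosmetic factor (e.g. 1e5) left at 1.
    """
    if total_mass <= 0:
        raise ValueError("total_mass must be positive")
    if total_length <= 0:
        raise ValueError("total_length must be positive")
    return display_multiplier * total_mass / total_length**3


def hepatosomatic_index(liver_mass: float, body_mass: float, transform: bool = False) -> float:
    """Liver-to-body mass ratio; fourth root when ``transform`` is set."""
    if body_mass <= 0:
        raise ValueError("body_mass must be positive")
    if liver_mass < 0:
        raise ValueError("liver_mass must be non-negative")
    if liver_mass >= body_mass:
        raise ValueError("liver_mass must be smaller than body_mass")
    ratio = liver_mass / body_mass
    return ratio**0.25 if transform else ratio


def condition_records(hosts: Sequence[HostRecord]) -> list[ConditionRecord]:
    out = []
    for h in hosts:
        k = fultons_k(h.total_mass_kg, h.total_length_cm)
        hsi = hepatosomatic_index(h.liver_mass_kg, h.total_mass_kg)
        out.append(ConditionRecord(h.fish_id, k, hsi, hsi**0.25))
    return out


def flag_outliers(
    hosts: Sequence[HostRecord], max_k_fold: float = 10.0
) -> tuple[list[HostRecord], list[HostRecord], list[str]]:
    """Partition hosts into (kept, flagged) by an implausible Fulton's K.

    A record is flagged when its K exceeds ``max_k_fold`` times the median K
    across all records — the signature of a mis-recorded body mass.  Nothing
    is silently dropped: every exclusion is returned as a log line naming
    the fish.
    """
    if len(hosts) < 2:
        raise ValueError("outlier flagging needs at least 2 records (median undefined)")
    ks = np.array([fultons_k(h.total_mass_kg, h.total_length_cm) for h in hosts])
    median_k = float(np.median(ks))
    kept, flagged, log = [], [], []
    for h, k in zip(hosts, ks):
        if k > max_k_fold * median_k:
            flagged.append(h)
            log.append(
                f"excluded fish {h.fish_id}: Fulton's K {k:.3g} exceeds "
                f"{max_k_fold:g} x median ({median_k:.3g})"
            )
        else:
            kept.append(h)
    return kept, flagged, log


@dataclass
class ConditionFitResult:
    """Table-2-style summary for one condition model."""

    response: str
    fixed_effects: pd.DataFrame  # term, estimate, se, z, p (analysis scale)
    variance_components: dict
    converged: bool
    scaling_metadata: dict
    n_obs: int
    messages: list


def _response_vector(hosts_df: pd.DataFrame, response: str) -> np.ndarray:
    mass = hosts_df["total_mass_kg"].to_numpy(float)
    length = hosts_df["total_length_cm"].to_numpy(float)
    liver = hosts_df["liver_mass_kg"].to_numpy(float)
    if response == "fultons_k":
        return mass / length**3
    if response == "hsi":
        return (liver / mass) ** 0.25  # fourth-root transform
    raise ValueError("response must be 'fultons_k' or 'hsi'")


def fit_condition_model(
    hosts,
    response: str = "hsi",
    design: Optional[ModelDesign] = None,
    zero_variance: bool = False,
) -> ConditionFitResult:
    """Fit a Gaussian LMM for a condition index by maximum likelihood.

    Random intercepts: sampling location nested within sampling region.
    ``zero_variance=True`` constrains both variance components to 0, which
    reduces the fit to ordinary least squares exactly (used as a closed-form
    oracle check).  Non-convergence is flagged, not raised.
    """
    design = design or ModelDesign(taxon_structure="none", nested_terms=("region", "location"))
    hosts_df = hosts if isinstance(hosts, pd.DataFrame) else hosts_to_frame(hosts)
    if hosts_df["sex"].nunique() < 2 or hosts_df["color"].nunique() < 2:
        raise ValueError("need at least 2 levels each of sex and color")

    y = _response_vector(hosts_df, response)
    X, names, depth_meta = build_fixed_matrix(hosts_df, design)
    meta = {"depth": depth_meta} if depth_meta is not None else {}
    messages: list[str] = []

    if zero_variance:
        import statsmodels.api as sm

        ols = sm.OLS(y, X).fit()
        est, se = ols.params, ols.bse
        z = est / se
        fixed = pd.DataFrame(
            {"term": names, "estimate": est, "se": se, "z": z, "p": 2 * norm.sf(np.abs(z))}
        )
        return ConditionFitResult(
            response=response,
            fixed_effects=fixed,
            variance_components={"sd_region": 0.0, "sd_location": 0.0},
            converged=True,
            scaling_metadata=meta,
            n_obs=len(y),
            messages=["variance components constrained to 0 (OLS)"],
        )

    import statsmodels.formula.api as smf

    data = pd.DataFrame(X[:, 1:], columns=["depth_s", "male", "brown", "male_brown"][: X.shape[1] - 1])
    if not design.include_depth:
        data = pd.DataFrame(X[:, 1:], columns=["male", "brown", "male_brown"])
    data["y"] = y
    data["region"] = hosts_df["region"].to_numpy()
    data["location"] = (
        hosts_df["region"].astype(str) + ":" + hosts_df["location"].astype(str)
    ).to_numpy()
    rhs = " + ".join(c for c in data.columns if c not in ("y", "region", "location"))

    # standardize the response for the optimizer (Fulton's K is ~1e-5 in
    # kg/cm^3, far below MixedLM's comfortable scale) and undo afterwards
    y_scale = float(np.std(y, ddof=1))
    if y_scale == 0.0:
        y_scale = 1.0
    data["y"] = (data["y"] - float(np.mean(y))) / y_scale

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(
                f"y ~ {rhs}",
                data,
                groups="region",
                re_formula="1",
                vc_formula={"location": "0 + C(location)"},
            )
            fit = model.fit(reml=False, method=["lbfgs", "powell"], maxiter=500)
            converged = bool(getattr(fit, "converged", True))
        except Exception as exc:  # keep the contract: flag, don't raise
            messages.append(f"mixed-model fit failed ({exc}); falling back to OLS")
            return fit_condition_model(hosts_df, response, design, zero_variance=True)

    keep = [n for n in fit.params.index if not n.endswith("Var")]
    est = fit.params[keep].to_numpy() * y_scale
    se = fit.bse[keep].to_numpy() * y_scale
    est[keep.index("Intercept")] += float(np.mean(y))
    z = est / se
    pretty = {"Intercept": "(Intercept)", "depth_s": "depth", "male": "sex[male]",
              "brown": "color[brown]", "male_brown": "sex[male]*color[brown]"}
    fixed = pd.DataFrame(
        {
            "term": [pretty.get(n, n) for n in keep],
            "estimate": est,
            "se": se,
            "z": z,
            "p": 2 * norm.sf(np.abs(z)),
        }
    )
    vc = {
        "sd_region": float(np.sqrt(max(fit.cov_re.iloc[0, 0], 0.0))) * y_scale,
        "sd_location": (
            float(np.sqrt(max(fit.vcomp[0], 0.0))) * y_scale if len(fit.vcomp) else 0.0
        ),
        "sd_residual": float(np.sqrt(fit.scale)) * y_scale,
    }
    if not converged:
        messages.append("mixed-model optimizer reported non-convergence")
    return ConditionFitResult(
        response=response,
        fixed_effects=fixed,
        variance_components=vc,
        converged=converged,
        scaling_metadata=meta,
        n_obs=len(y),
        messages=messages,
    )
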