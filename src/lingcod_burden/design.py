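"""Model design: fixed-effect matrices, the scale-then-add-2 convention, VIF.

The burden and condition models share one fixed-effect structure
(depth + sex + color + sex:color) with treatment contrasts referenced at
sex = female, color = blue, so the reported terms are ``sex[male]``,
``color[brown]`` and ``sex[male]*color[brown]``.  Numeric predictors are
standardized as (x - mean)/sd + 2 (sample sd, n-1 denominator); the shift
keeps values positive and leaves slopes interpretable per 1 sd.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

FIXED_TERMS = ("depth", "sex[male]", "color[brown]", "sex[male]*color[brown]")


@dataclass(frozen=True)
class ScalingMetadata:
    """Mean/sd used in scale_plus_two, retained for back-transformation."""

    mean: float
    sd: float
    shift: float = 2.0

    def forward(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / self.sd + self.shift

    def invert(self, z):
        return (np.asarray(z, dtype=float) - self.shift) * self.sd + self.mean

    def slope_to_original(self, slope_scaled: float) -> float:
        """A slope per 1 scaled unit becomes slope/sd per original unit."""
        return slope_scaled / self.sd


def scale_plus_two(values) -> tuple[np.ndarray, ScalingMetadata]:
    """Standardize then add 2: (x - mean)/sd + 2, sd with n-1 denominator.

    Raises ValueError on a constant vector (degenerate scale).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("scale_plus_two expects a 1-d vector")
    if x.size < 2:
        raise ValueError("need at least 2 values to scale")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError("degenerate scale: input vector is constant")
    meta = ScalingMetadata(mean=mean, sd=sd)
    return meta.forward(x), meta


@dataclass
class ModelDesign:
    """Specification of the parasite-burden mixed model.

    Fixed part: intercept + scaled depth + sex[male] + color[brown] +
    sex[male]*color[brown], with the log total length (cm) offset whose
    coefficient is fixed at 1 and never estimated.  Random part: nested
    intercepts for fish within sampling location within sampling region, and
    a correlated per-taxon random vector.

    ``taxon_structure``:
      * ``"full"``    — (intercept, sex, color, interaction) per taxon, 4x4
                        covariance (the model formula's ``(1+sex*color|taxon)``);
      * ``"reduced"`` — (intercept, interaction) per taxon, 2x2 covariance,
                        offered for stability on small fixtures;
      * ``"none"``    — no taxon term.
    """

    include_depth: bool = True
    include_sex_color: bool = True
    nested_terms: Sequence[str] = ("region", "location", "fish")
    taxon_structure: str = "full"
    use_offset: bool = True
    sex_reference: str = "female"
    color_reference: str = "blue"

    def __post_init__(self) -> None:
        if self.taxon_structure not in ("full", "reduced", "none"):
            raise ValueError("taxon_structure must be 'full', 'reduced' or 'none'")
        allowed = {"region", "location", "fish"}
        if not set(self.nested_terms) <= allowed:
            raise ValueError(f"nested_terms must be a subset of {sorted(allowed)}")
        if not self.include_sex_color and self.taxon_structure == "full":
            raise ValueError("full taxon structure requires the sex/color fixed terms")

    @property
    def taxon_slope_names(self) -> tuple[str, ...]:
        if self.taxon_structure == "full":
            return ("intercept", "sex[male]", "color[brown]", "sex[male]*color[brown]")
        if self.taxon_structure == "reduced":
            return ("intercept", "sex[male]*color[brown]")
        return ()

    def fixed_term_names(self) -> list[str]:
        names = ["(Intercept)"]
        if self.include_depth:
            names.append("depth")
        if self.include_sex_color:
            names += ["sex[male]", "color[brown]", "sex[male]*color[brown]"]
        return names


def encode_sex_color(hosts: pd.DataFrame, design: ModelDesign) -> pd.DataFrame:
    """Treatment-coded indicator columns for sex, color and their product."""
    sex = hosts["sex"].astype(str)
    color = hosts["color"].astype(str)
    male = (sex != design.sex_reference).astype(float)
    brown = (color != design.color_reference).astype(float)
    return pd.DataFrame(
        {
            "sex[male]": male.to_numpy(),
            "color[brown]": brown.to_numpy(),
            "sex[male]*color[brown]": (male * brown).to_numpy(),
        },
        index=hosts.index,
    )


def build_fixed_matrix(
    hosts: pd.DataFrame, design: ModelDesign
) -> tuple[np.ndarray, list[str], Optional[ScalingMetadata]]:
    """Host-level fixed-effect design matrix (one row per fish).

    Returns (X_host, term names, depth scaling metadata or None).
    """
    cols = [np.ones(len(hosts))]
    names = ["(Intercept)"]
    depth_meta: Optional[ScalingMetadata] = None
    if design.include_depth:
        scaled, depth_meta = scale_plus_two(hosts["depth_m"].to_numpy())
        cols.append(scaled)
        names.append("depth")
    if design.include_sex_color:
        ind = encode_sex_color(hosts, design)
        for name in ("sex[male]", "color[brown]", "sex[male]*color[brown]"):
            cols.append(ind[name].to_numpy())
            names.append(name)
    return np.column_stack(cols), names, depth_meta


def compute_vif(design_matrix: np.ndarray, names: Optional[Sequence[str]] = None) -> pd.Series:
    """Variance inflation factors, VIF_j = 1/(1 - R^2_j).

    ``design_matrix`` holds the non-intercept fixed-effect columns; each
    column is regressed (with an intercept) on all the others.  Exact linear
    dependence is reported as ``inf`` rather than raised, since the check is
    a diagnostic: values above 5 warrant a warning, never an abort.
    """
    X = np.asarray(design_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least two columns to compute VIF")
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    out = {}
    for j in range(p):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        if ss_tot == 0.0:
            out[names[j]] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[names[j]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")
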