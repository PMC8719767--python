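"""Contingency-table analysis of blue-morph frequency by sex."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .records import HostRecord


@dataclass
class SexColorTable:
    """2x2 counts, rows (female, male) x columns (blue, brown)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (2, 2):
            raise ValueError("SexColorTable needs a 2x2 array")
        if np.any(c < 0) or np.any(c != np.floor(c)):
            raise ValueError("cells must be non-negative integers")
        if c.sum() == 0:
            raise ValueError("table total must be positive")
        self.counts = c.astype(int)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=["female", "male"], columns=["blue", "brown"]
        )


def chi_squared_test(
    table: SexColorTable, continuity_correction: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on the 2x2 table.

    No Yates correction by default (large-sample design); enable it via the
    flag.  A zero row or column margin is a degenerate table and an error.
    """
    c = table.counts
    if np.any(c.sum(axis=0) == 0) or np.any(c.sum(axis=1) == 0):
        raise ValueError("degenerate table: a margin is zero")
    stat, p, dof, _ = chi2_contingency(c, correction=continuity_correction)
    return float(stat), int(dof), float(p)


def morph_frequency_summary(hosts: Sequence[HostRecord]) -> dict:
    """Per-sex blue proportions plus the underlying 2x2 table.

    Fish without a definitive sex and color are excluded; the exclusion
    count is reported (not silently dropped).  A sample with only one sex
    yields a single-row summary and a warning message instead of a table.
    """
    if len(hosts) == 0:
        raise ValueError("empty host table")
    definitive = [h for h in hosts if h.is_definitive()]
    n_excluded = len(hosts) - len(definitive)
    messages = []
    if n_excluded:
        messages.append(f"excluded {n_excluded} fish without definitive sex/color")

    rows = []
    table = np.zeros((2, 2), dtype=int)
    for sex_i, sex in enumerate(("female", "male")):
        of_sex = [h for h in definitive if h.sex == sex]
        n_blue = sum(1 for h in of_sex if h.color == "blue")
        n_brown = len(of_sex) - n_blue
        table[sex_i, 0], table[sex_i, 1] = n_blue, n_brown
        if of_sex:
            rows.append(
                {
                    "sex": sex,
                    "n": len(of_sex),
                    "n_blue": n_blue,
                    "blue_proportion": n_blue / len(of_sex),
                }
            )
    summary = pd.DataFrame(rows)
    result: dict = {
        "summary": summary,
        "n_excluded": n_excluded,
        "messages": messages,
    }
    if (table.sum(axis=1) > 0).all():
        result["table"] = SexColorTable(table)
    else:
        messages.append("only one sex present; chi-squared table not formed")
        result["table"] = None
    return result
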