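"""Core data containers: sampled hosts and the long-format parasite count table.

A *host* is one sampled lingcod with its hierarchy labels (sampling region,
sampling location within region) and morphometrics.  Parasite counts are kept
long-format — one row per (fish, taxon) pair, zeros included — because the
burden model treats every (fish, taxon) cell as one observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

SEXES = ("female", "male")
COLORS = ("blue", "brown")

HOST_COLUMNS = [
    "fish_id",
    "region",
    "location",
    "depth_m",
    "sex",
    "color",
    "total_length_cm",
    "total_mass_kg",
    "liver_mass_kg",
]


@dataclass
class HostRecord:
    """One sampled fish.

    ``gonad_mass_kg`` is carried for completeness but unused by any analysis
    here.  ``sex`` / ``color`` may be None for fish that could not be
    definitively classified; such fish are excluded (with a logged count)
    wherever a definitive label is required.
    """

    fish_id: str
    region: str
    location: str
    depth_m: float
    sex: Optional[str]
    color: Optional[str]
    total_length_cm: float
    total_mass_kg: float
    liver_mass_kg: float
    gonad_mass_kg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex is not None and self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES} or None, got {self.sex!r}")
        if self.color is not None and self.color not in COLORS:
            raise ValueError(f"color must be one of {COLORS} or None, got {self.color!r}")
        if self.depth_m < 0:
            raise ValueError(f"fish {self.fish_id}: negative depth {self.depth_m}")
        if self.total_length_cm <= 0:
            raise ValueError(f"fish {self.fish_id}: non-positive length")
        if self.total_mass_kg <= 0:
            raise ValueError(f"fish {self.fish_id}: non-positive mass")
        if self.liver_mass_kg < 0:
            raise ValueError(f"fish {self.fish_id}: negative liver mass")

    def is_definitive(self) -> bool:
        return self.sex is not None and self.color is not None


def hosts_to_frame(hosts: Sequence[HostRecord]) -> pd.DataFrame:
    """Tabulate host records (stable column order, one row per fish)."""
    rows = [asdict(h) for h in hosts]
    frame = pd.DataFrame(rows)
    cols = HOST_COLUMNS + [c for c in frame.columns if c not in HOST_COLUMNS]
    return frame[cols]


def hosts_from_frame(frame: pd.DataFrame) -> list[HostRecord]:
    hosts = []
    for row in frame.to_dict("records"):
        gonad = row.get("gonad_mass_kg")
        if gonad is not None and pd.isna(gonad):
            gonad = None
        sex = row["sex"] if pd.notna(row["sex"]) else None
        color = row["color"] if pd.notna(row["color"]) else None
        hosts.append(
            HostRecord(
                fish_id=str(row["fish_id"]),
                region=str(row["region"]),
                location=str(row["location"]),
                depth_m=float(row["depth_m"]),
                sex=sex,
                color=color,
                total_length_cm=float(row["total_length_cm"]),
                total_mass_kg=float(row["total_mass_kg"]),
                liver_mass_kg=float(row["liver_mass_kg"]),
                gonad_mass_kg=None if gonad is None else float(gonad),
            )
        )
    return hosts


@dataclass
class ParasiteCountTable:
    """Long-format fish x taxon counts; the burden model's response.

    Invariant: exactly one row per (fish, taxon) pair over the full grid,
    every count a non-negative integer.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"fish_id", "taxon_id", "count"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"count table missing columns: {sorted(missing)}")
        counts = self.frame["count"].to_numpy()
        if not np.issubdtype(np.asarray(counts).dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(counts != np.floor(counts)):
            raise ValueError("counts must be integers")
        if self.frame.duplicated(["fish_id", "taxon_id"]).any():
            dup = self.frame[self.frame.duplicated(["fish_id", "taxon_id"])]
            raise ValueError(
                f"duplicate (fish, taxon) rows, first: {dup.iloc[0].tolist()}"
            )

    @property
    def fish_ids(self) -> list[str]:
        return list(pd.unique(self.frame["fish_id"]))

    @property
    def taxon_ids(self) -> list[str]:
        return list(pd.unique(self.frame["taxon_id"]))

    def __len__(self) -> int:
        return len(self.frame)

    def to_wide(self) -> pd.DataFrame:
        """Fish x taxon abundance matrix (rows fish, columns taxa)."""
        wide = self.frame.pivot(index="fish_id", columns="taxon_id", values="count")
        return wide.fillna(0).astype(int)

    def total_per_fish(self) -> pd.Series:
        return self.frame.groupby("fish_id", sort=False)["count"].sum()
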