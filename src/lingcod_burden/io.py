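"""CSV ingestion and export with validation.

Host tables: one row per fish, header contract
``fish_id, region, location, depth_m, sex, color, total_length_cm,
total_mass_kg, liver_mass_kg`` (units in the column names).  Count tables:
long-format ``fish_id, taxon_id, count``.  Lines starting with ``#`` are
treated as comments (emitted tables carry a config-hash comment line).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import HOST_COLUMNS, HostRecord, ParasiteCountTable, hosts_to_frame

logger = logging.getLogger("lingcod_burden")


class SchemaError(ValueError):
    pass


def read_host_table(path) -> list[HostRecord]:
    """Read and validate hosts.csv; errors are row-addressed (1-based data rows)."""
    frame = pd.read_csv(path, comment="#", dtype={"fish_id": str})
    missing = [c for c in HOST_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"host table missing required column(s): {missing}")
    hosts = []
    for pos, row in enumerate(frame.to_dict("records"), start=1):
        try:
            sex = row["sex"] if pd.notna(row["sex"]) else None
            color = row["color"] if pd.notna(row["color"]) else None
            gonad = row.get("gonad_mass_kg")
            if gonad is not None and pd.isna(gonad):
                gonad = None
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
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"host table row {pos}: {exc}") from exc
    if not hosts:
        raise SchemaError("host table is empty")
    dup = pd.Series([h.fish_id for h in hosts]).duplicated()
    if dup.any():
        raise SchemaError(f"duplicate fish_id in host table (row {dup.idxmax() + 1})")
    return hosts


def read_count_table(path, hosts: Sequence[HostRecord]) -> ParasiteCountTable:
    """Read counts.csv and complete it to the full fish x taxon grid.

    Absent (fish, taxon) pairs are filled as structural zeros (a dissection
    that did not record a taxon observed zero individuals of it) and logged.
    Orphan fish ids and duplicate pairs are errors.
    """
    frame = pd.read_csv(path, comment="#", dtype={"fish_id": str, "taxon_id": str})
    missing = [c for c in ("fish_id", "taxon_id", "count") if c not in frame.columns]
    if missing:
        raise SchemaError(f"count table missing required column(s): {missing}")
    counts = frame["count"]
    bad = counts.isna() | (counts < 0) | (counts != np.floor(counts))
    if bad.any():
        raise SchemaError(
            f"count table row {int(bad.idxmax()) + 1}: counts must be "
            f"non-negative integers (got {counts[bad.idxmax()]!r})"
        )
    known = {h.fish_id for h in hosts}
    orphans = set(frame["fish_id"]) - known
    if orphans:
        raise SchemaError(f"count table references unknown fish_id(s): {sorted(orphans)[:5]}")
    if frame.duplicated(["fish_id", "taxon_id"]).any():
        first = frame[frame.duplicated(["fish_id", "taxon_id"])].iloc[0]
        raise SchemaError(
            f"duplicate (fish, taxon) pair: ({first['fish_id']}, {first['taxon_id']})"
        )

    fish_ids = [h.fish_id for h in hosts]
    taxa = list(pd.unique(frame["taxon_id"]))
    full = pd.MultiIndex.from_product([fish_ids, taxa], names=["fish_id", "taxon_id"])
    indexed = frame.set_index(["fish_id", "taxon_id"])["count"].reindex(full)
    n_filled = int(indexed.isna().sum())
    if n_filled:
        logger.info("count table: filled %d absent (fish, taxon) pairs with structural zeros", n_filled)
    completed = indexed.fillna(0).astype(int).reset_index()
    return ParasiteCountTable(completed)


def _write_frame(frame: pd.DataFrame, path, header_comment: Optional[str]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False)


def write_host_table(hosts, path, header_comment: Optional[str] = None) -> None:
    frame = hosts if isinstance(hosts, pd.DataFrame) else hosts_to_frame(hosts)
    _write_frame(frame, path, header_comment)


def write_count_table(counts, path, header_comment: Optional[str] = None) -> None:
    frame = counts.frame if isinstance(counts, ParasiteCountTable) else counts
    _write_frame(frame, path, header_comment)


def write_table(frame: pd.DataFrame, path, header_comment: Optional[str] = None) -> None:
    """Generic CSV export used by the pipeline stages."""
    _write_frame(frame, path, header_comment)
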