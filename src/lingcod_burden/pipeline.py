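"""Pipeline orchestration: generate or ingest data, then run the analysis
stages in dependency order with a reproducible manifest.

Stages: ``simulate`` (or CSV ingestion), ``frequency``, ``condition``,
``burden``, ``permute`` (depends on ``burden``), ``permanova``.  Identical
config + seed yields identical output checksums; every emitted file is
inventoried in the manifest with a sha256, and each table carries a header
comment with the config hash so published tables are self-identifying.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .burden import FitOptions, extract_taxon_effects, fit_burden_model
from .condition import fit_condition_model, flag_outliers
from .design import ModelDesign
from .frequency import chi_squared_test, morph_frequency_summary
from .io import read_count_table, read_host_table, write_count_table, write_host_table, write_table
from .permanova import community_dissimilarity, permanova
from .permutation import PermutationScheme, replicates_frame, run_permutation_test
from .synthetic import GeneratorConfig, generate_dataset

logger = logging.getLogger("lingcod_burden")

ALL_STAGES = ("simulate", "frequency", "condition", "burden", "permute", "permanova")
STAGE_DEPS = {"permute": ("burden",)}


@dataclass
class RunConfig:
    """One pipeline run: exactly one of (input CSV paths, generator config)."""

    outdir: str = "results"
    stages: Sequence[str] = ALL_STAGES
    seed: int = 0
    hosts_path: Optional[str] = None
    counts_path: Optional[str] = None
    generator: Optional[GeneratorConfig] = None
    taxon_structure: str = "full"
    permutation_modes: Sequence[str] = ("males_only", "both_sexes")
    n_permutation_replicates: int = 500
    n_permanova_permutations: int = 999
    distance_metric: str = "braycurtis"
    permanova_term_order: Sequence[str] = ("sex_color", "location", "depth")
    outer_tol: float = 1e-6
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        has_paths = self.hosts_path is not None and self.counts_path is not None
        has_gen = self.generator is not None
        if has_paths == has_gen:
            raise ValueError("supply exactly one of (hosts/counts paths, generator config)")
        if not self.stages:
            raise ValueError("stage list must be non-empty")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        if gen is not None:
            if "taxon_cov" in gen:
                gen["taxon_cov"] = np.asarray(gen["taxon_cov"], dtype=float)
            gen = GeneratorConfig(**gen)
        raw.update(overrides)
        return cls(generator=gen, **raw)

    def canonical(self) -> str:
        d = dataclasses.asdict(self)
        # hash covers only what determines the numbers, not where they land
        d.pop("outdir", None)
        d.pop("log_level", None)
        if self.generator is not None:
            g = dataclasses.asdict(self.generator)
            g["taxon_cov"] = np.asarray(g["taxon_cov"]).tolist()
            d["generator"] = g
        return json.dumps(d, sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)  # name -> "ok"|"failed: ..."|"skipped ..."
    files: dict = field(default_factory=dict)  # relative path -> sha256

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=2)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages; failures are recorded, dependents skipped."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"config_hash={config.config_hash()}"
    manifest = RunManifest(
        version=__version__, config_hash=config.config_hash(), seed=config.seed
    )
    emitted: list[Path] = []
    burden_fit = None
    hosts = counts = None
    requested = [s for s in ALL_STAGES if s in set(config.stages)]

    # data acquisition (simulate stage, or ingestion if paths were given)
    if config.generator is not None:
        gen = dataclasses.replace(config.generator, seed=config.seed)
    design = ModelDesign(taxon_structure=config.taxon_structure)

    for stage in requested:
        dep_failed = next(
            (d for d in STAGE_DEPS.get(stage, ()) if manifest.stages.get(d) != "ok"),
            None,
        )
        if dep_failed:
            manifest.stages[stage] = f"skipped (dependency: {dep_failed})"
            logger.info("stage %s skipped (dependency %s)", stage, dep_failed)
            continue
        t0 = time.perf_counter()
        try:
            if stage == "simulate":
                dataset = generate_dataset(gen)
                hosts, counts = dataset.hosts, dataset.counts
                paths = dataset.write(outdir, tag)
                emitted += list(paths.values())
            elif stage == "frequency":
                hosts, counts = _ensure_data(config, hosts, counts)
                res = morph_frequency_summary(hosts)
                out = res["summary"].copy()
                if res["table"] is not None:
                    stat, dof, p = chi_squared_test(res["table"])
                    out["chi_squared"], out["df"], out["p"] = stat, dof, p
                path = outdir / "morph_frequency.csv"
                write_table(out, path, tag)
                emitted.append(path)
            elif stage == "condition":
                hosts, counts = _ensure_data(config, hosts, counts)
                kept, flagged, log_lines = flag_outliers(hosts)
                for line in log_lines:
                    logger.info("condition: %s", line)
                rows = []
                for resp in ("fultons_k", "hsi"):
                    fit = fit_condition_model(kept, response=resp)
                    sub = fit.fixed_effects.copy()
                    sub.insert(0, "model", resp)
                    sub["converged"] = fit.converged
                    rows.append(sub)
                path = outdir / "condition_fits.csv"
                write_table(pd.concat(rows, ignore_index=True), path, tag)
                emitted.append(path)
            elif stage == "burden":
                hosts, counts = _ensure_data(config, hosts, counts)
                burden_fit = fit_burden_model(
                    hosts, counts, design, FitOptions(outer_tol=config.outer_tol)
                )
                path = outdir / "burden_fit.csv"
                tab = burden_fit.fixed_effects.copy()
                tab["converged"] = burden_fit.converged
                tab["theta"] = burden_fit.theta
                write_table(tab, path, tag)
                emitted.append(path)
                if design.taxon_structure != "none":
                    slopes = extract_taxon_effects(burden_fit)
                    spath = outdir / "taxon_slopes.csv"
                    write_table(slopes, spath, tag)
                    emitted.append(spath)
                report = {
                    "loglik": burden_fit.loglik,
                    "theta": burden_fit.theta,
                    "converged": burden_fit.converged,
                    "messages": burden_fit.messages,
                    "variance_components": {
                        k: (v.to_dict() if isinstance(v, pd.DataFrame) else v)
                        for k, v in burden_fit.variance_components.items()
                    },
                }
                rpath = outdir / "burden_report.json"
                rpath.write_text(json.dumps(report, sort_keys=True, indent=2, default=str))
                emitted.append(rpath)
            elif stage == "permute":
                hosts, counts = _ensure_data(config, hosts, counts)
                for mode in config.permutation_modes:
                    scheme = PermutationScheme(
                        mode=mode,
                        n_replicates=config.n_permutation_replicates,
                        seed=config.seed,
                    )
                    res = run_permutation_test(
                        hosts, counts, design, scheme,
                        FitOptions(outer_tol=config.outer_tol),
                        observed_fit=burden_fit,
                    )
                    logger.info("permutation %s: %s", mode, res.summary())
                    frame = replicates_frame(res)
                    path = outdir / f"permutation_{mode}.csv"
                    write_table(
                        frame, path,
                        f"{tag} observed_z={res.observed_z:.6f} "
                        f"extreme_proportion={res.extreme_proportion:.6f} "
                        f"n_failed={res.n_failed}",
                    )
                    emitted.append(path)
            elif stage == "permanova":
                hosts, counts = _ensure_data(config, hosts, counts)
                wide = counts.to_wide()
                dist, excluded = community_dissimilarity(wide, config.distance_metric)
                if excluded:
                    logger.info("permanova: excluded %d all-zero fish", len(excluded))
                hosts_df = pd.DataFrame(
                    {
                        "fish_id": [h.fish_id for h in hosts],
                        "sex_color": [f"{h.sex}-{h.color}" for h in hosts],
                        "location": [h.location for h in hosts],
                        "depth": [h.depth_m for h in hosts],
                    }
                ).set_index("fish_id").loc[dist.labels]
                table = permanova(
                    dist,
                    hosts_df[["sex_color", "location", "depth"]],
                    term_order=config.permanova_term_order,
                    n_permutations=config.n_permanova_permutations,
                    seed=config.seed,
                )
                path = outdir / "permanova.csv"
                write_table(table, path, tag)
                emitted.append(path)
            manifest.stages[stage] = "ok"
            logger.info("stage %s ok (%.2fs)", stage, time.perf_counter() - t0)
        except Exception as exc:
            manifest.stages[stage] = f"failed: {exc}"
            logger.exception("stage %s failed", stage)

    for path in emitted:
        manifest.files[str(Path(path).relative_to(outdir))] = _sha256(Path(path))
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest


def _ensure_data(config: RunConfig, hosts, counts):
    """Lazy CSV ingestion when the simulate stage is not part of the run."""
    if hosts is not None and counts is not None:
        return hosts, counts
    if config.hosts_path is None:
        raise RuntimeError(
            "no data available: include the simulate stage or provide input paths"
        )
    hosts = read_host_table(config.hosts_path)
    counts = read_count_table(config.counts_path, hosts)
    return hosts, counts
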