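"""Synthetic study generator: hosts and parasite counts drawn from the exact
generative model the burden GLMM assumes.

The default configuration mirrors the study design the models were built
for: 89 fish spread over 26 sampling locations in 4 regions, 25 parasite
taxa, strongly unbalanced sex-color cells (59 brown males, 4 blue males,
15 brown females, 11 blue females), overdispersed NB2 counts with a
log-length offset, nested region/site/fish intercepts, and a correlated
per-taxon (intercept, sex, color, interaction) response vector.  Counts are
drawn as

    count ~ NB2(mean = exp(eta), dispersion = theta),
    eta   = b0 + b_depth * depth_scaled + b_sex * male + b_color * brown
            + b_int * male * brown + u_region + u_site + u_fish
            + t_taxon' (1, male, brown, male*brown) + log(length_cm),

with depth standardized by the same scale-then-add-2 convention the fitted
model applies.  Randomness uses counter-based substreams keyed per fish and
per taxon, so changing ``n_taxa`` never perturbs host covariates under a
fixed seed, and every realized random-effect draw is stored in ``truth`` so
recovery tests can compare conditional modes against realized values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .design import scale_plus_two
from .nb import sample_nb
from .records import HostRecord, ParasiteCountTable, hosts_to_frame

# order of the sex-color cells everywhere in this module
CELLS = (
    ("male", "brown"),
    ("male", "blue"),
    ("female", "brown"),
    ("female", "blue"),
)
STUDY_CELL_COUNTS = (59, 4, 15, 11)


def _default_taxon_cov() -> np.ndarray:
    sds = np.array([1.2, 0.25, 0.25, 0.4])
    cov = np.diag(sds**2)
    # mild negative coupling: taxa with high baseline burden respond a bit
    # less strongly to the interaction (as seen for dominant taxa)
    cov[0, 3] = cov[3, 0] = -0.2 * sds[0] * sds[3]
    return cov


@dataclass
class GeneratorConfig:
    """All generative parameters for one synthetic study.

    ``sites_per_region`` may be an int (symmetric) or a per-region sequence;
    ``n_fish`` defaults to filling every site with ``fish_per_site`` fish and
    may be overridden (fish are then spread round-robin across sites, giving
    near-balanced but unequal site sizes, as in the real design).
    Coefficients are on the log (linear-predictor) scale.
    """

    n_regions: int = 4
    sites_per_region: Union[int, Sequence[int]] = (7, 7, 6, 6)
    fish_per_site: int = 4
    n_taxa: int = 25
    n_fish: Optional[int] = 89
    cell_probabilities: Sequence[float] = tuple(c / 89 for c in STUDY_CELL_COUNTS)
    exact_cells: bool = False
    beta_intercept: float = -2.6
    beta_depth: float = -0.12
    beta_sex_male: float = 0.94
    beta_color_brown: float = 0.08
    beta_interaction: float = -0.717
    sd_region: float = 0.15
    sd_site: float = 0.15
    sd_fish: float = 0.15
    taxon_cov: np.ndarray = field(default_factory=_default_taxon_cov)
    theta: float = 3.0
    length_range_cm: tuple[float, float] = (45.0, 95.0)
    depth_range_m: tuple[float, float] = (7.6, 72.2)
    mass_length_allometry: tuple[float, float, float] = (1.0e-5, 3.0, 0.08)
    mean_hsi: float = 0.030
    sd_log_hsi: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        sites = self.sites_list()
        if len(sites) != self.n_regions or any(s < 1 for s in sites):
            raise ValueError("sites_per_region must give >= 1 site for each region")
        if self.fish_per_site < 1:
            raise ValueError("fish_per_site must be >= 1")
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")
        if self.n_fish is not None and self.n_fish < 1:
            raise ValueError("n_fish must be >= 1")
        probs = np.asarray(self.cell_probabilities, dtype=float)
        if probs.shape != (4,) or np.any(probs < 0) or abs(probs.sum() - 1) > 1e-8:
            raise ValueError("cell_probabilities must be 4 non-negative values summing to 1")
        if not (self.theta > 0):
            raise ValueError("theta must be > 0")
        cov = np.asarray(self.taxon_cov, dtype=float)
        if cov.shape != (4, 4) or not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("taxon_cov must be a symmetric 4x4 matrix")
        if np.min(np.linalg.eigvalsh(cov)) < -1e-10:
            raise ValueError("taxon_cov must be positive semidefinite")
        lo, hi = self.length_range_cm
        if not (0 < lo <= hi):
            raise ValueError("length_range_cm must be positive with lo <= hi")
        dlo, dhi = self.depth_range_m
        if not (0 <= dlo <= dhi):
            raise ValueError("depth_range_m must be non-negative with lo <= hi")
        a, b, s = self.mass_length_allometry
        if a <= 0 or b <= 0 or s < 0:
            raise ValueError("mass_length_allometry must be (a>0, b>0, sd>=0)")
        if not (0 < self.mean_hsi < 1):
            raise ValueError("mean_hsi must lie in (0, 1)")

    def sites_list(self) -> list[int]:
        if isinstance(self.sites_per_region, int):
            return [self.sites_per_region] * self.n_regions
        return [int(s) for s in self.sites_per_region]

    @property
    def total_fish(self) -> int:
        if self.n_fish is not None:
            return self.n_fish
        return sum(self.sites_list()) * self.fish_per_site

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


@dataclass
class SyntheticDataset:
    """One realized study: hosts, long-format counts, and the generative truth
    (config plus every realized random-effect draw)."""

    hosts: list
    counts: ParasiteCountTable
    truth: dict

    def hosts_frame(self) -> pd.DataFrame:
        return hosts_to_frame(self.hosts)

    def write(self, outdir, header_comment: Optional[str] = None) -> dict:
        from .io import write_count_table, write_host_table

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "hosts": outdir / "hosts.csv",
            "counts": outdir / "counts.csv",
        }
        write_host_table(self.hosts, paths["hosts"], header_comment)
        write_count_table(self.counts, paths["counts"], header_comment)
        return paths


def _mvn_psd_draw(rng: np.random.Generator, cov: np.ndarray) -> np.ndarray:
    """MVN(0, cov) draw valid for merely positive *semi*definite cov."""
    w, V = np.linalg.eigh(cov)
    root = V * np.sqrt(np.maximum(w, 0.0))
    return root @ rng.standard_normal(cov.shape[0])


def _cell_assignments(config: GeneratorConfig, n_fish: int) -> Optional[np.ndarray]:
    """With exact_cells, a deterministic-count, randomly ordered cell vector."""
    if not config.exact_cells:
        return None
    probs = np.asarray(config.cell_probabilities, dtype=float)
    base = np.floor(probs * n_fish).astype(int)
    remainder = n_fish - base.sum()
    if remainder:
        frac = probs * n_fish - base
        for idx in np.argsort(-frac)[:remainder]:
            base[idx] += 1
    cells = np.repeat(np.arange(4), base)
    rng = np.random.default_rng([config.seed, 5])
    rng.shuffle(cells)
    return cells


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Draw one synthetic study from the generative model.

    Reproducible: the same config (including seed) yields byte-identical
    tables.  Hierarchy labels are nested by construction (each site belongs
    to one region, each fish to one site).
    """
    config.validate()
    seed = config.seed
    sites = config.sites_list()
    site_region: list[tuple[str, str]] = []
    for r, n_sites in enumerate(sites):
        for s in range(n_sites):
            site_region.append((f"R{r + 1}", f"R{r + 1}-S{s + 1}"))
    n_sites_total = len(site_region)
    n_fish = config.total_fish

    # fish -> site assignment: block-fill when n_fish matches the grid,
    # round-robin spread otherwise
    if config.n_fish is None:
        site_of_fish = np.repeat(np.arange(n_sites_total), config.fish_per_site)
    else:
        site_of_fish = np.arange(n_fish) % n_sites_total

    rng_region = np.random.default_rng([seed, 2])
    rng_site = np.random.default_rng([seed, 3])
    u_region = rng_region.normal(0.0, config.sd_region, config.n_regions)
    u_site = rng_site.normal(0.0, config.sd_site, n_sites_total)

    taxon_ids = [f"T{t + 1:02d}" for t in range(config.n_taxa)]
    taxon_effects = np.vstack(
        [
            _mvn_psd_draw(np.random.default_rng([seed, 4, t]), np.asarray(config.taxon_cov, float))
            for t in range(config.n_taxa)
        ]
    )

    forced_cells = _cell_assignments(config, n_fish)
    a, b_exp, sd_log_mass = config.mass_length_allometry

    hosts: list[HostRecord] = []
    u_fish = np.empty(n_fish)
    male = np.empty(n_fish)
    brown = np.empty(n_fish)
    depth = np.empty(n_fish)
    length = np.empty(n_fish)
    for i in range(n_fish):
        rng_f = np.random.default_rng([seed, 1, i])
        cell = (
            int(forced_cells[i])
            if forced_cells is not None
            else int(rng_f.choice(4, p=np.asarray(config.cell_probabilities, float)))
        )
        sex, color = CELLS[cell]
        male[i] = 1.0 if sex == "male" else 0.0
        brown[i] = 1.0 if color == "brown" else 0.0
        length[i] = rng_f.uniform(*config.length_range_cm)
        depth[i] = rng_f.uniform(*config.depth_range_m)
        mass = a * length[i] ** b_exp * np.exp(rng_f.normal(0.0, sd_log_mass))
        hsi = min(
            config.mean_hsi * np.exp(rng_f.normal(0.0, config.sd_log_hsi)), 0.25
        )
        gonad = 0.01 * mass * np.exp(rng_f.normal(0.0, 0.3))
        u_fish[i] = rng_f.normal(0.0, config.sd_fish)
        region_id, site_id = site_region[site_of_fish[i]]
        hosts.append(
            HostRecord(
                fish_id=f"F{i + 1:04d}",
                region=region_id,
                location=site_id,
                depth_m=round(float(depth[i]), 2),
                sex=sex,
                color=color,
                total_length_cm=round(float(length[i]), 1),
                total_mass_kg=max(round(float(mass), 6), 1e-6),
                liver_mass_kg=round(float(hsi * mass), 7),
                gonad_mass_kg=round(float(gonad), 4),
            )
        )

    # linear predictor uses the covariates as recorded (post-rounding), so a
    # refit of the written tables sees exactly the generative design
    depth_rec = np.array([h.depth_m for h in hosts])
    length_rec = np.array([h.total_length_cm for h in hosts])
    if n_fish >= 2 and np.std(depth_rec) > 0:
        depth_scaled, depth_meta = scale_plus_two(depth_rec)
    else:
        depth_scaled, depth_meta = np.full(n_fish, 2.0), None

    eta_fish = (
        config.beta_intercept
        + config.beta_depth * depth_scaled
        + config.beta_sex_male * male
        + config.beta_color_brown * brown
        + config.beta_interaction * male * brown
        + u_region[[int(site_region[s][0][1:]) - 1 for s in site_of_fish]]
        + u_site[site_of_fish]
        + u_fish
        + np.log(length_rec)
    )
    design_taxon = np.column_stack([np.ones(n_fish), male, brown, male * brown])

    frames = []
    for i in range(n_fish):
        rng_c = np.random.default_rng([seed, 6, i])
        eta = eta_fish[i] + taxon_effects @ design_taxon[i]
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        counts = sample_nb(rng_c, mu, config.theta)
        frames.append(
            pd.DataFrame(
                {"fish_id": hosts[i].fish_id, "taxon_id": taxon_ids, "count": counts}
            )
        )
    counts_table = ParasiteCountTable(pd.concat(frames, ignore_index=True))

    truth = {
        "config": config,
        "u_region": pd.Series(u_region, index=[f"R{r + 1}" for r in range(config.n_regions)]),
        "u_site": pd.Series(u_site, index=[s for _, s in site_region]),
        "u_fish": pd.Series(u_fish, index=[h.fish_id for h in hosts]),
        "taxon_effects": pd.DataFrame(
            taxon_effects,
            index=taxon_ids,
            columns=["intercept", "sex[male]", "color[brown]", "sex[male]*color[brown]"],
        ),
        "depth_scaling": depth_meta,
    }
    return SyntheticDataset(hosts=hosts, counts=counts_table, truth=truth)


def study_config(**overrides) -> GeneratorConfig:
    """The default study-scale configuration, optionally overridden."""
    return GeneratorConfig(**overrides)
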