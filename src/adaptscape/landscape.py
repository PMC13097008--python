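"""Synthetic landscape generator: clinal adaptive loci on a climate grid.

Generates the fixture every downstream stage is tested on: a rectangular grid
of climate cells (one recent scenario plus displaced future scenarios), a set
of sampling sites, and a genotype matrix in which most loci are neutral with
spatially autocorrelated allele frequencies (isolation by distance) and a
small fraction are adaptive, with allele frequency clines driven by one of the
climate variables.  Defaults mirror the study design this pipeline targets:
171 individuals across 10 sites, ~20 candidate adaptive loci among 1000
neutral ones, six climate variables, and model x RCP x period future
scenarios.

No coalescent or forward-time machinery is involved: neutral spatial structure
comes from a Gaussian-kernel random field on site coordinates, which is enough
to reproduce the weak isolation-by-distance signal the analysis assumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .climate import DEFAULT_VARIABLES, ClimateGrid, ScenarioKey
from .genotype import GenotypeMatrix, write_vcf

logger = logging.getLogger(__name__)

KM_PER_DEGREE = np.pi * 6371.0 / 180.0  # ~111.195 km per degree of latitude


def default_future_shifts(
    variables: Sequence[str] = DEFAULT_VARIABLES,
) -> dict[str, dict[str, float]]:
    """Eight future scenarios: {warmwet, hotdry} x RCP {4.5, 8.5} x 2 periods.

    Shifts are in SD units of the recent grid.  The hot-dry model warms more
    and dries (cwd up, recharge/runoff/storage down); the warm-wet model warms
    moderately and wets slightly.  RCP 8.5 and the later period scale the
    displacement up, mirroring the hierarchical scenario structure
    (model / RCP / period) of downscaled climate projections.
    """
    base = {
        "warmwet": {"tmx": 1.0, "tmn": 1.2, "cwd": 0.2, "rch": 0.5, "run": 0.5, "str": 0.3},
        "hotdry": {"tmx": 2.0, "tmn": 1.6, "cwd": 1.5, "rch": -0.8, "run": -0.8, "str": -0.5},
    }
    rcp_factor = {"4.5": 0.7, "8.5": 1.0}
    period_factor = {"2040-2069": 0.7, "2070-2099": 1.0}
    shifts: dict[str, dict[str, float]] = {}
    for model, mshift in base.items():
        for rcp, rf in rcp_factor.items():
            for period, pf in period_factor.items():
                key = ScenarioKey(model=model, rcp=rcp, period=period).label
                shifts[key] = {
                    v: round(mshift.get(v, 0.0) * rf * pf, 6) for v in variables
                }
    return shifts


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic landscape.

    ``adaptive_effect`` is the slope of logit allele frequency per SD of the
    driving climate variable; 2.0 gives strong, detectable clines.
    ``future_shift`` maps scenario label -> variable -> displacement in recent
    SD units.  ``ibd_scale_km`` is the autocorrelation range of neutral allele
    frequency fields.
    """

    n_cells_x: int = 30
    n_cells_y: int = 30
    cell_size_km: float = 10.0
    n_individuals: int = 171
    n_sites: int = 10
    n_neutral_loci: int = 1000
    n_adaptive_loci: int = 20
    adaptive_effect: float = 2.0
    driver_vars: tuple[str, ...] = ("tmx",)
    variables: tuple[str, ...] = DEFAULT_VARIABLES
    ibd_scale_km: float = 100.0
    ibd_sd: float = 0.2             # range-wide clinal component of neutral drift (logit SD)
    site_drift_sd: float = 2.0      # site-idiosyncratic local drift (logit SD)
    future_shift: dict[str, dict[str, float]] = field(default_factory=default_future_shifts)
    noise_sd: float = 2.0           # fine-scale (topographic) cell-level climate component
    perturbation_sd: float = 0.5    # spatial modulation of the future displacement
    displacement_baseline_coupling: float = -0.6  # corr(displacement, baseline field)
    missing_rate: float = 0.02
    site_spread_cells: float = 3.0  # sampling radius around each site center, in cells
    adaptive_p0_range: tuple[float, float] = (0.25, 0.75)
    balanced_sites: bool = False
    origin_lon: float = -122.0
    origin_lat: float = 34.0
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_cells_x": self.n_cells_x, "n_cells_y": self.n_cells_y,
            "n_individuals": self.n_individuals, "n_sites": self.n_sites,
            "n_neutral_loci": self.n_neutral_loci,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.n_adaptive_loci < 0:
            raise ValueError("n_adaptive_loci must be >= 0")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_adaptive_loci > 0 and not self.driver_vars:
            raise ValueError("driver_vars must be non-empty when adaptive loci requested")
        unknown = set(self.driver_vars) - set(self.variables)
        if unknown:
            raise ValueError(f"driver_vars not among variables: {sorted(unknown)}")
        if self.n_cells_x == 1 and self.n_cells_y == 1:
            raise ValueError("degenerate 1x1 grid: need spatial variation")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Ground truth of the simulation: which loci are adaptive and why."""

    adaptive_locus_ids: list[str]
    driver_of_locus: dict[str, str]
    effect_of_locus: dict[str, float]
    neutral_locus_ids: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.adaptive_locus_ids) & set(self.neutral_locus_ids)
        if overlap:
            raise ValueError(f"loci cannot be both adaptive and neutral: {sorted(overlap)[:5]}")

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        rows = [
            {"locus_id": l, "is_adaptive": True,
             "driver": self.driver_of_locus[l], "effect": self.effect_of_locus[l]}
            for l in self.adaptive_locus_ids
        ] + [
            {"locus_id": l, "is_adaptive": False, "driver": "", "effect": 0.0}
            for l in self.neutral_locus_ids
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "SyntheticTruth":
        df = pd.read_csv(Path(path), keep_default_na=False)
        ad = df[df["is_adaptive"].astype(bool)]
        ne = df[~df["is_adaptive"].astype(bool)]
        return cls(
            adaptive_locus_ids=ad["locus_id"].tolist(),
            driver_of_locus=dict(zip(ad["locus_id"], ad["driver"])),
            effect_of_locus=dict(zip(ad["locus_id"], ad["effect"].astype(float))),
            neutral_locus_ids=ne["locus_id"].tolist(),
        )


def _cell_centers(config: LandscapeConfig) -> pd.DataFrame:
    """Cell ids and lon/lat centers on a regular graticule.

    Longitude spacing is widened by 1/cos(latitude) so that east-west
    neighbours are ``cell_size_km`` apart on the ground, not just in degrees.
    """
    step_lon = config.cell_size_km / (
        KM_PER_DEGREE * np.cos(np.radians(config.origin_lat))
    )
    step_lat = config.cell_size_km / KM_PER_DEGREE
    ids, xs, ys = [], [], []
    for iy in range(config.n_cells_y):
        for ix in range(config.n_cells_x):
            ids.append(iy * config.n_cells_x + ix)
            xs.append(config.origin_lon + (ix + 0.5) * step_lon)
            ys.append(config.origin_lat + (iy + 0.5) * step_lat)
    return pd.DataFrame({"x": xs, "y": ys}, index=pd.Index(ids, name="cell_id"))


def _smooth_field(rng: np.random.Generator, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-SD planar gradient (random orientation + interaction).

    Kept deliberately low-order: the broad-scale component of each climate
    variable is then spanned by latitude, longitude and their product, the
    classic trend-surface predictors, while all finer structure comes from
    the cell-level (topographic) noise term.
    """
    xn = (xs - xs.mean()) / (xs.std() + 1e-12)
    yn = (ys - ys.mean()) / (ys.std() + 1e-12) if ys.std() > 0 else np.zeros_like(ys)
    a = rng.normal(size=3)
    f = a[0] * xn + a[1] * yn + a[2] * xn * yn
    sd = f.std()
    if sd < 1e-8:  # degenerate draw (e.g. 1-D grid with tiny slope)
        f = xn + yn
        sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def make_climate_grids(config: LandscapeConfig) -> dict[str, ClimateGrid]:
    """Recent plus future climate grids sharing one cell geometry.

    Each variable on the recent grid is a smooth spatial gradient plus iid
    noise, standardized to mean 0 / SD 1 over cells.  A future grid displaces
    each variable by ``future_shift[scenario][var]`` SD units, modulated by a
    small zero-mean smooth spatial perturbation, so the displacement varies
    gently in space but averages to the nominal shift.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    centers = _cell_centers(config)
    xs, ys = centers["x"].to_numpy(), centers["y"].to_numpy()

    recent = centers.copy()
    for v in config.variables:
        raw = _smooth_field(rng, xs, ys) + rng.normal(0, config.noise_sd, len(xs))
        recent[v] = (raw - raw.mean()) / raw.std()

    grids: dict[str, ClimateGrid] = {
        "recent": ClimateGrid(
            scenario=ScenarioKey.recent(), data=recent,
            variables=config.variables, cell_size_km=config.cell_size_km,
        )
    }
    for label, shifts in config.future_shift.items():
        fut = centers.copy()
        for v in config.variables:
            shift = float(shifts.get(v, 0.0))
            if shift == 0.0:
                fut[v] = recent[v]
                continue
            # displacement varies in space: partly coupled to the baseline
            # field (negative coupling = cooler/higher cells shift more),
            # partly an independent smooth pattern; zero-mean so the average
            # shift stays at the nominal value
            lam = config.displacement_baseline_coupling
            mix = np.sqrt(max(1.0 - lam ** 2, 0.0))
            h = lam * recent[v].to_numpy() + mix * _smooth_field(rng, xs, ys)
            h = (h - h.mean()) / h.std()
            pert = h * config.perturbation_sd
            fut[v] = recent[v] + shift * (1.0 + pert)
        grids[label] = ClimateGrid(
            scenario=ScenarioKey.from_label(label), data=fut,
            variables=config.variables, cell_size_km=config.cell_size_km,
        )
    return grids


def _site_layout(
    config: LandscapeConfig, centers: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    """Choose site cells (spread over the grid) and assign individuals.

    Site sizes default to an unbalanced design (a few intensively sampled
    focal sites among sparser range-wide sites), matching individual-based
    range-wide sampling; ``balanced_sites`` splits individuals evenly.
    """
    n = len(centers)
    # farthest-point style selection for spatial spread, seeded randomly
    first = int(rng.integers(n))
    chosen = [first]
    xy = centers[["x", "y"]].to_numpy()
    d_min = np.linalg.norm(xy - xy[first], axis=1)
    for _ in range(config.n_sites - 1):
        cand = int(np.argmax(d_min + rng.uniform(0, 1e-9, n)))
        chosen.append(cand)
        d_min = np.minimum(d_min, np.linalg.norm(xy - xy[cand], axis=1))
    site_cells = centers.iloc[chosen]

    if config.balanced_sites:
        sizes = np.full(config.n_sites, config.n_individuals // config.n_sites)
        sizes[: config.n_individuals % config.n_sites] += 1
    else:
        base = min(4, config.n_individuals // config.n_sites)
        remaining = config.n_individuals - base * config.n_sites
        weights = rng.dirichlet(np.full(config.n_sites, 1.5))
        extra = rng.multinomial(remaining, weights)
        sizes = base + extra
    return site_cells, sizes


def simulate_genotypes(
    config: LandscapeConfig,
    grids: Mapping[str, ClimateGrid],
) -> tuple[GenotypeMatrix, SyntheticTruth, pd.DataFrame]:
    """Simulate genotypes with neutral drift structure and climate-driven clines.

    Individuals are scattered around each site center within
    ``site_spread_cells`` grid cells, so a site spans a local climate gradient
    (mirroring intensive within-site sampling across climate cells).

    Neutral locus j: site-level allele frequencies follow a logit-normal field
    with two components — a weak range-wide cline with Gaussian-kernel spatial
    covariance (range ``ibd_scale_km``, SD ``ibd_sd``) producing isolation by
    distance, plus stronger site-idiosyncratic local drift (SD
    ``site_drift_sd``) that dominates the leading axes of genetic structure.

    Adaptive locus k driven by variable v responds to each individual's local
    climate: logit p_k(ind) = logit(p0_k) + effect * v(cell of ind) on the
    standardized recent grid, with p0_k drawn at intermediate frequency
    (``adaptive_p0_range``) so the cline stays unsaturated and polymorphic.

    Dosages are Binomial(2, p); missingness is applied uniformly at
    ``missing_rate``.  Returns the genotype matrix, the ground truth, and a
    sample coordinate table (sample_id, lon, lat, site_id).
    """
    from .climate import extract_at_points

    config.validate()
    if "recent" not in grids:
        raise ValueError("grids must contain the 'recent' scenario")
    rng = np.random.default_rng(config.seed + 1)
    recent = grids["recent"]
    site_cells, sizes = _site_layout(config, recent.data, rng)
    site_xy_km = site_cells[["x", "y"]].to_numpy() * KM_PER_DEGREE

    # individuals scattered around their site center, clipped to the grid
    jit = config.cell_size_km / KM_PER_DEGREE * config.site_spread_cells
    recs = []
    for s, (row, size) in enumerate(zip(site_cells.itertuples(), sizes)):
        for _ in range(int(size)):
            recs.append({
                "sample_id": f"ind_{len(recs):04d}",
                "lon": row.x + rng.uniform(-jit, jit),
                "lat": row.y + rng.uniform(-jit, jit),
                "site_id": f"site_{s:02d}",
            })
    coords = pd.DataFrame(recs)
    coords["lon"] = coords["lon"].clip(recent.data["x"].min(), recent.data["x"].max())
    coords["lat"] = coords["lat"].clip(recent.data["y"].min(), recent.data["y"].max())
    site_index = coords["site_id"].str.slice(5).astype(int).to_numpy()

    # per-individual standardized climate at the nearest grid cell
    ind_climate = extract_at_points(recent, coords)

    n_loci = config.n_neutral_loci + config.n_adaptive_loci
    # spatial covariance of neutral logit-frequency fields across sites:
    # range-wide kernel (IBD) + site-idiosyncratic drift
    d = np.linalg.norm(site_xy_km[:, None, :] - site_xy_km[None, :, :], axis=2)
    cov = config.ibd_sd ** 2 * np.exp(-(d ** 2) / (2 * config.ibd_scale_km ** 2))
    cov += np.eye(len(d)) * (config.site_drift_sd ** 2 + 1e-9)
    chol = np.linalg.cholesky(cov)

    # interleave adaptive loci among neutral ones along the chromosome
    locus_order = rng.permutation(n_loci)
    adaptive_slots = set(locus_order[: config.n_adaptive_loci].tolist())

    p0 = np.clip(rng.beta(0.8, 0.8, n_loci), 0.05, 0.95)
    lo_ad, hi_ad = config.adaptive_p0_range
    p0_adaptive = lo_ad + (hi_ad - lo_ad) * rng.beta(2, 2, n_loci)
    ind_p = np.empty((len(coords), n_loci))
    drivers: list[str | None] = []
    n_clamped = 0
    adaptive_counter = 0
    for j in range(n_loci):
        if j in adaptive_slots:
            v = config.driver_vars[adaptive_counter % len(config.driver_vars)]
            adaptive_counter += 1
            drivers.append(v)
            logit0 = np.log(p0_adaptive[j] / (1 - p0_adaptive[j]))
            logit = logit0 + config.adaptive_effect * ind_climate[v].to_numpy()
        else:
            drivers.append(None)
            logit0 = np.log(p0[j] / (1 - p0[j]))
            site_field = chol @ rng.normal(size=len(site_cells))
            logit = logit0 + site_field[site_index]
        p = 1 / (1 + np.exp(-logit))
        clamped = np.clip(p, 0.01, 0.99)
        n_clamped += int((clamped != p).sum())
        ind_p[:, j] = clamped
    if n_clamped:
        logger.info("clamped %d allele frequencies into [0.01, 0.99]", n_clamped)

    dosages = rng.binomial(2, ind_p).astype(float)
    if config.missing_rate > 0:
        mask = rng.uniform(size=dosages.shape) < config.missing_rate
        dosages[mask] = np.nan

    ids = [f"snp_{j:05d}" for j in range(n_loci)]
    variants = pd.DataFrame({
        "id": ids,
        "chrom": "chr1",
        "pos": np.arange(1, n_loci + 1) * 1000,
        "ref": "A",
        "alt": "T",
        "mean_depth": 30.0,
    })
    samples = pd.DataFrame({
        "id": coords["sample_id"], "lon": coords["lon"],
        "lat": coords["lat"], "site": coords["site_id"],
    })
    gm = GenotypeMatrix(dosages=dosages, variants=variants, samples=samples)
    truth = SyntheticTruth(
        adaptive_locus_ids=[ids[j] for j in range(n_loci) if drivers[j] is not None],
        driver_of_locus={ids[j]: drivers[j] for j in range(n_loci) if drivers[j] is not None},
        effect_of_locus={
            ids[j]: config.adaptive_effect for j in range(n_loci) if drivers[j] is not None
        },
        neutral_locus_ids=[ids[j] for j in range(n_loci) if drivers[j] is None],
    )
    return gm, truth, coords


def write_fixture(
    gm: GenotypeMatrix,
    grids: Mapping[str, ClimateGrid],
    coords: pd.DataFrame,
    out_dir: str | Path,
    truth: SyntheticTruth | None = None,
) -> dict[str, Path]:
    """Write a complete fixture: VCF, per-scenario grid CSVs, coords, truth.

    The VCF declares GT and DP; observed genotypes get DP 30 (above any
    default depth mask) and missing ones ``./.`` with DP 0, so the dosage
    matrix round-trips losslessly through the QC loader.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    try:
        paths["vcf"] = write_vcf(gm, out_dir / "genotypes.vcf")
        for label, grid in grids.items():
            paths[f"grid_{label}"] = grid.to_csv(out_dir / f"climate_{label}.csv")
        coords.to_csv(out_dir / "coords.csv", index=False)
        paths["coords"] = out_dir / "coords.csv"
        if truth is not None:
            paths["truth"] = truth.to_csv(out_dir / "truth.csv")
    except OSError as exc:
        raise IOError(f"failed writing fixture under {out_dir}: {exc}") from exc
    return paths


def simulate_fixture(
    config: LandscapeConfig | None = None,
) -> tuple[GenotypeMatrix, SyntheticTruth, pd.DataFrame, dict[str, ClimateGrid]]:
    """One-call convenience: grids + genotypes for a config (default study scale)."""
    config = config or LandscapeConfig()
    grids = make_climate_grids(config)
    gm, truth, coords = simulate_genotypes(config, grids)
    return gm, truth, coords, grids
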