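"""Synthetic radial city with a known pollution surface, campaigns, and cohort.

Everything downstream (predictor extraction, calibration, LUR fitting,
validation, exposure assignment, survival analysis) is exercised against this
generator, so each piece of ground truth — the generating log-linear surface,
the sampler distortions, the between-campaign drift, the exposure-mortality
log-hazard — is stored alongside the data it produced.

The city emulates a monocentric European city: traffic and population density
decay from the centre, major radial and ring roads carry the high traffic
counts, and the terrain is a smooth deterministic field. The latent NO2
surface is log-linear in the land-use predictors plus a spatially correlated
Gaussian field (exponential covariance), shared between the two campaigns;
campaign 2 differs by a small drift (additive log shift plus a
traffic-density interaction) and fresh measurement noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from scipy.interpolate import RegularGridInterpolator
from shapely.geometry import Polygon

from .lur import MeasurementSet
from .predictors import PREDICTOR_SCHEMA, assemble_predictor_table
from .scene import CensusBlock, CityScene, ConfigurationError, RoadSegment

CONCENTRATION_FLOOR = 1.0  # ug/m3; keeps measured values loggable


# ---------------------------------------------------------------------------
# city geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CityConfig:
    extent: float = 24_000.0          # square side, metres
    n_radial: int = 8                 # spoke roads from the centre
    n_ring: int = 3                   # ring roads
    blocks_per_side: int = 22         # census-block grid
    pop_scale: float = 1_500.0        # expected residents of a central block
    pop_decay: float = 6_000.0        # e-folding distance of population density
    ring_segments: int = 16           # chords approximating each ring

    def __post_init__(self) -> None:
        if self.extent <= 0:
            raise ConfigurationError("extent must be positive")
        if self.blocks_per_side <= 0:
            raise ConfigurationError("blocks_per_side must be positive")
        if self.n_radial < 1 or self.n_ring < 0:
            raise ConfigurationError("need at least one radial road")


def _altitude_field(config: CityConfig):
    e = config.extent

    def field_fn(x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ne_hills = 75.0 * np.exp(-(((x - 0.80 * e) ** 2) + ((y - 0.74 * e) ** 2)) / (2 * (0.26 * e) ** 2))
        sw_hills = 50.0 * np.exp(-(((x - 0.12 * e) ** 2) + ((y - 0.22 * e) ** 2)) / (2 * (0.17 * e) ** 2))
        return 20.0 + ne_hills + sw_hills + 10.0 * (y / e)

    return field_fn


def generate_city(config: CityConfig | None = None, seed: int = 0) -> CityScene:
    """Deterministic radial city: spokes, rings, and a census-block grid.

    Traffic counts decay outward so that both high-traffic (>10,000
    vehicles/day) and minor counted roads exist; block populations decay
    exponentially with distance from the centre.
    """
    config = config or CityConfig()
    rng = np.random.default_rng(seed)
    e = config.extent
    cx = cy = e / 2.0
    roads: list[RoadSegment] = []

    # radial spokes, three segments each with decaying counts
    max_r = 0.48 * e
    breaks = np.array([0.04, 0.35, 0.68, 1.0]) * max_r
    band_counts = [(26_000, 40_000), (11_000, 20_000), (4_500, 9_000)]
    for i in range(config.n_radial):
        theta = 2 * np.pi * i / config.n_radial + rng.uniform(-0.08, 0.08)
        ux, uy = math.cos(theta), math.sin(theta)
        for (r0, r1), (lo, hi) in zip(zip(breaks[:-1], breaks[1:]), band_counts):
            roads.append(
                RoadSegment(
                    start=(cx + r0 * ux, cy + r0 * uy),
                    end=(cx + r1 * ux, cy + r1 * uy),
                    vehicles_per_day=float(rng.integers(lo, hi)),
                )
            )

    # ring roads as chord polylines; the outermost ring is an orbital motorway
    # (big cities keep a high-count beltway at the periphery), inner rings
    # carry decaying urban traffic
    ring_counts = [(24_000, 34_000), (11_000, 16_000), (4_500, 8_000)]
    for j in range(config.n_ring):
        radius = max_r * (j + 1) / (config.n_ring + 0.5)
        if j == config.n_ring - 1 and config.n_ring > 1:
            lo, hi = 60_000, 90_000
        else:
            lo, hi = ring_counts[min(j, len(ring_counts) - 1)]
        angles = np.linspace(0, 2 * np.pi, config.ring_segments + 1) + rng.uniform(0, 0.2)
        pts = np.column_stack([cx + radius * np.cos(angles), cy + radius * np.sin(angles)])
        np.clip(pts, 1.0, e - 1.0, out=pts)
        for a, b in zip(pts[:-1], pts[1:]):
            roads.append(RoadSegment(tuple(a), tuple(b), float(rng.integers(lo, hi))))

    # census blocks: a warped grid covering the extent; cells are smaller near
    # the centre (older, denser urban fabric) and larger toward the suburbs
    alt = _altitude_field(config)
    m = config.blocks_per_side
    u = np.linspace(0.0, 1.0, m + 1)
    warp = u - 0.55 * np.sin(2 * np.pi * (u - 0.5)) / (2 * np.pi)
    edges = warp * e
    blocks: list[CensusBlock] = []
    bid = 0
    for iy in range(m):
        for ix in range(m):
            x0, x1 = edges[ix], edges[ix + 1]
            y0, y1 = edges[iy], edges[iy + 1]
            poly = Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])
            bx, by = (x0 + x1) / 2, (y0 + y1) / 2
            dist = math.hypot(bx - cx, by - cy)
            mean_pop = config.pop_scale * math.exp(-dist / config.pop_decay)
            residents = int(rng.poisson(mean_pop)) + 1
            green_p = min(0.08 + 0.55 * dist / (0.7 * e), 0.9)
            blocks.append(
                CensusBlock(
                    id=bid,
                    polygon=poly,
                    residents=residents,
                    area=poly.area,
                    altitude=float(alt(bx, by)),
                    green_adjacent=bool(rng.random() < green_p),
                )
            )
            bid += 1

    return CityScene(extent=e, centre=(cx, cy), roads=roads, blocks=blocks, altitude_field=alt)


# ---------------------------------------------------------------------------
# latent pollution surface
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurfaceParams:
    """Generating log-linear surface: ln NO2 = beta0 + X beta + noise."""

    beta0: float = 4.36
    betas: dict[str, float] = field(
        default_factory=lambda: {
            "dist_centre": -6.5e-5,
            "altitude": -2.5e-3,
            "x_coord": 8.0e-6,
            "traffic_density_150": 8.0e-4,
            "dist_hi_road": -1.0e-4,
        }
    )
    noise_sd: float = 0.12            # log scale
    noise_range: float = 3_000.0      # exponential correlation range, metres
    drift_shift: float = -0.075       # campaign 2 additive log shift
    drift_traffic_coef: float = 5.0e-4  # campaign 2 coefficient on traffic density

    def __post_init__(self) -> None:
        unknown = set(self.betas) - set(PREDICTOR_SCHEMA)
        if unknown:
            raise ConfigurationError(f"unknown surface predictors: {sorted(unknown)}")


def _gaussian_field(extent: float, sd: float, corr_range: float, rng: np.random.Generator):
    """Stationary Gaussian field with covariance sd^2 exp(-d/range).

    Simulated exactly (Cholesky) on a coarse grid and bilinearly interpolated;
    the grid spacing tracks the correlation range so the field is resolved.
    """
    spacing = max(corr_range / 2.5, extent / 39)
    n = int(np.ceil(extent / spacing)) + 1
    axis = np.linspace(0.0, extent, n)
    gx, gy = np.meshgrid(axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    d = np.hypot(pts[:, 0][:, None] - pts[:, 0], pts[:, 1][:, None] - pts[:, 1])
    cov = sd * sd * np.exp(-d / corr_range)
    cov[np.diag_indices_from(cov)] += 1e-10
    z = np.linalg.cholesky(cov) @ rng.standard_normal(len(pts))
    interp = RegularGridInterpolator(
        (axis, axis), z.reshape(n, n), method="linear", bounds_error=False, fill_value=None
    )
    return lambda x, y: interp(np.column_stack([np.asarray(x, float), np.asarray(y, float)]))


@dataclass
class SurfaceModel:
    """A realised latent surface over one city (noise field drawn once)."""

    city: CityScene = field(repr=False)
    params: SurfaceParams
    _noise: object = field(repr=False, default=None)

    def noise_at(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self._noise is None:
            return np.zeros(x.shape)
        return np.asarray(self._noise(x, np.asarray(y, float)), dtype=float)

    def log_concentration(
        self, xy: np.ndarray, campaign_index: int = 1, predictor_table: pd.DataFrame | None = None
    ) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        tab = predictor_table if predictor_table is not None else assemble_predictor_table(xy, self.city)
        out = np.full(len(tab), self.params.beta0)
        for name, b in self.params.betas.items():
            if b != 0.0:
                out += b * tab[name].to_numpy(dtype=float)
        out += self.noise_at(xy[:, 0], xy[:, 1])
        if campaign_index == 2:
            out += self.params.drift_shift
            out += self.params.drift_traffic_coef * tab["traffic_density_150"].to_numpy(dtype=float)
        return out

    def concentration(self, xy, campaign_index: int = 1, predictor_table=None) -> np.ndarray:
        return np.exp(self.log_concentration(xy, campaign_index, predictor_table))


def simulate_true_surface(
    city: CityScene, surface_params: SurfaceParams | None = None, seed: int = 0
) -> SurfaceModel:
    params = surface_params or SurfaceParams()
    rng = np.random.default_rng(seed)
    noise = None
    if params.noise_sd > 0:
        noise = _gaussian_field(city.extent, params.noise_sd, params.noise_range, rng)
    return SurfaceModel(city=city, params=params, _noise=noise)


# ---------------------------------------------------------------------------
# measurement campaigns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplerSpec:
    """Affine device response: reading = gain * truth + offset + noise."""

    name: str
    gain: float = 1.0
    offset: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ConfigurationError("sampler gain must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("sampler noise sd must be >= 0")


#: direct-reading device (the campaign-2 badge analogue)
REFERENCE_SAMPLER = SamplerSpec(name="reference", gain=1.0, offset=0.0, noise_sd=4.0)
#: distorted device whose calibration line back to the reference is
#: reference = 0.68 * distorted + 13.53
DISTORTED_SAMPLER = SamplerSpec(
    name="distorted", gain=1.0 / 0.68, offset=-13.53 / 0.68, noise_sd=4.0
)

DEFAULT_PERIOD_EFFECTS = (3.0, -1.0, -2.0)  # seasonal offsets, ug/m3


def place_sites(
    city: CityScene,
    n_background: int,
    n_traffic: int,
    n_regional: int = 0,
    seed: int = 0,
    start_id: int = 1,
) -> pd.DataFrame:
    """Monitoring locations: traffic sites hug high-traffic roads, background
    sites keep >150 m away from them, regional sites sit at the city edge."""
    rng = np.random.default_rng(seed)
    hi = city.high_traffic_roads
    if n_traffic and not hi:
        raise ConfigurationError("city has no high-traffic road to host traffic sites")
    rows = []

    def _random_bg(min_road_dist, min_centre_frac=0.0):
        from .predictors import distance_to_nearest_major_road

        for _ in range(20_000):
            x = rng.uniform(0.02 * city.extent, 0.98 * city.extent)
            y = rng.uniform(0.02 * city.extent, 0.98 * city.extent)
            d_centre = math.hypot(x - city.centre[0], y - city.centre[1])
            if d_centre < min_centre_frac * city.extent or d_centre > 0.55 * city.extent:
                continue
            if distance_to_nearest_major_road((x, y), city.roads) > min_road_dist:
                return x, y
        raise ConfigurationError("could not place a background site; geometry too dense")

    for _ in range(n_background):
        x, y = _random_bg(150.0)
        rows.append((x, y, "background"))
    for _ in range(n_traffic):
        seg = hi[int(rng.integers(len(hi)))]
        t = rng.uniform(0.1, 0.9)
        px = seg.start[0] + t * (seg.end[0] - seg.start[0])
        py = seg.start[1] + t * (seg.end[1] - seg.start[1])
        ang = rng.uniform(0, 2 * np.pi)
        off = rng.uniform(8.0, 40.0)
        x = min(max(px + off * math.cos(ang), 1.0), city.extent - 1.0)
        y = min(max(py + off * math.sin(ang), 1.0), city.extent - 1.0)
        rows.append((x, y, "traffic"))
    for _ in range(n_regional):
        x, y = _random_bg(600.0, min_centre_frac=0.42)
        rows.append((x, y, "regional_background"))

    return pd.DataFrame(
        {
            "site_id": [f"s{start_id + i:03d}" for i in range(len(rows))],
            "x": [r[0] for r in rows],
            "y": [r[1] for r in rows],
            "site_type": [r[2] for r in rows],
        }
    )


def simulate_campaign(
    city: CityScene,
    surface: SurfaceModel,
    site_list: pd.DataFrame,
    periods: int,
    sampler: SamplerSpec,
    campaign_index: int,
    seed: int = 0,
    period_effects: tuple[float, ...] | None = None,
    missing_rate: float = 0.0,
) -> MeasurementSet:
    """One-week deployments at each site: sampler.gain * (truth + seasonal
    offset + noise) + sampler.offset, floored at 1 ug/m3. With probability
    ``missing_rate`` a site loses one whole site-period (uniformly chosen), so
    the expected number of incomplete sites is n_sites * missing_rate."""
    if periods < 1:
        raise ConfigurationError("periods must be >= 1")
    if campaign_index not in (1, 2):
        raise ConfigurationError("campaign_index must be 1 or 2")
    xy = site_list[["x", "y"]].to_numpy(dtype=float)
    if not city.contains_points(xy[:, 0], xy[:, 1]).all():
        raise ConfigurationError("a monitoring site lies outside the city extent")
    effects = np.zeros(periods) if period_effects is None else np.asarray(period_effects, float)
    if len(effects) != periods:
        raise ConfigurationError("period_effects length must equal periods")

    rng = np.random.default_rng(seed)
    true = surface.concentration(xy, campaign_index)
    n = len(site_list)
    eps = rng.normal(0.0, sampler.noise_sd, size=(n, periods)) if sampler.noise_sd > 0 else np.zeros((n, periods))
    vals = sampler.gain * (true[:, None] + effects[None, :] + eps) + sampler.offset
    np.clip(vals, CONCENTRATION_FLOOR, None, out=vals)

    keep = np.ones((n, periods), dtype=bool)
    if missing_rate > 0:
        hit = rng.random(n) < missing_rate
        lost_period = rng.integers(0, periods, size=n)
        keep[np.arange(n)[hit], lost_period[hit]] = False
    site_ids = site_list["site_id"].to_numpy()
    records = pd.DataFrame(
        {
            "site_id": np.repeat(site_ids, periods),
            "period": np.tile(np.arange(1, periods + 1), n),
            "value": vals.ravel(),
        }
    )[keep.ravel()]
    return MeasurementSet(
        campaign=campaign_index,
        sampler=sampler.name,
        records=records.reset_index(drop=True),
        sites=site_list.copy(),
    )


def simulate_colocated_pairs(
    sites: pd.DataFrame,
    surface: SurfaceModel,
    sampler_a: SamplerSpec,
    sampler_b: SamplerSpec,
    seed: int = 0,
    campaign_index: int = 2,
) -> pd.DataFrame:
    """Both devices read the same true concentration with independent noise."""
    if len(sites) < 3:
        raise ValueError("co-location needs >= 3 sites for an identifiable calibration")
    rng = np.random.default_rng(seed)
    xy = sites[["x", "y"]].to_numpy(dtype=float)
    true = surface.concentration(xy, campaign_index)
    out = {}
    for tag, s in (("a", sampler_a), ("b", sampler_b)):
        eps = rng.normal(0.0, s.noise_sd, size=len(true)) if s.noise_sd > 0 else 0.0
        out[f"value_{tag}"] = np.clip(s.gain * (true + eps) + s.offset, CONCENTRATION_FLOOR, None)
    return pd.DataFrame({"site_id": sites["site_id"].to_numpy(), **out})


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

#: baseline covariate distributions (levels, probabilities) — independent of
#: address by construction; only the area socioeconomic index tracks pollution
COVARIATE_LEVELS: dict[str, tuple[tuple[str, ...], tuple[float, ...]]] = {
    "age_band": (("45-64", "65-74", "75-80"), (0.611, 0.273, 0.116)),
    "gender": (("male", "female"), (0.447, 0.553)),
    "marital_status": (("married", "single", "widowed_divorced"), (0.60, 0.20, 0.20)),
    "place_of_birth": (("city", "rest_of_country", "abroad"), (0.60, 0.30, 0.10)),
    "education": (("primary", "secondary", "high_school", "university"), (0.30, 0.30, 0.25, 0.15)),
    "occupation": (("employed", "retired", "housework", "other"), (0.50, 0.35, 0.10, 0.05)),
}

#: per-level log hazard ratios (same level order as COVARIATE_LEVELS);
#: the socioeconomic gradient runs low -> high (category 1 = most deprived)
DEFAULT_COVARIATE_EFFECTS: dict[str, tuple[float, ...]] = {
    "age_band": (0.0, 1.1, 1.9),
    "gender": (0.4, 0.0),
    "marital_status": (0.0, 0.15, 0.25),
    "place_of_birth": (0.0, 0.05, 0.1),
    "education": (0.25, 0.15, 0.08, 0.0),
    "occupation": (0.0, 0.1, 0.12, 0.2),
    "sep": (0.30, 0.22, 0.15, 0.07, 0.0),
}

DEFAULT_HORIZON_YEARS = 5.2
DEFAULT_EVENT_FRACTION = 0.0658  # emulates 45,006 deaths in 684,204 subjects


def simulate_cohort(
    city: CityScene,
    surface: SurfaceModel,
    n: int,
    beta_no2_per10: float,
    covariate_effects: dict[str, tuple[float, ...]] | None = None,
    confounding_strength: float = 0.6,
    horizon_years: float = DEFAULT_HORIZON_YEARS,
    seed: int = 0,
    target_event_fraction: float = DEFAULT_EVENT_FRACTION,
) -> tuple[pd.DataFrame, dict]:
    """Closed cohort with exposure-dependent survival and a spatial confounder.

    Addresses are drawn proportionally to block population; the census-block
    socioeconomic category (1 = low ... 5 = high) is built from a latent score
    mixing the block's true NO2 (weight ``confounding_strength``) with
    independent noise, so affluent areas are systematically more polluted, as
    in the monocentric city it emulates. Survival times are exponential with
    log hazard linear in true NO2 (``beta_no2_per10`` per 10 ug/m3) and the
    categorical covariates, administratively censored at ``horizon_years``.

    Returns (cohort table, ground-truth dictionary).
    """
    if n < 100:
        raise ValueError("cohort needs n >= 100")
    if horizon_years <= 0:
        raise ValueError("horizon must be positive")
    effects = dict(DEFAULT_COVARIATE_EFFECTS)
    if covariate_effects:
        effects.update(covariate_effects)
    rng = np.random.default_rng(seed)

    # addresses: block chosen by population, uniform within the block polygon
    blocks = city.blocks
    pops = np.array([b.residents for b in blocks], dtype=float)
    probs = pops / pops.sum()
    chosen = rng.choice(len(blocks), size=n, p=probs)
    bounds = np.array([blocks[b].polygon.bounds for b in range(len(blocks))])
    lo, hi = bounds[chosen][:, :2], bounds[chosen][:, 2:]
    # rejection sampling within each block's bounding box, vectorised;
    # rectangular blocks accept immediately, odd shapes retry
    polys = np.array([b.polygon for b in blocks], dtype=object)[chosen]
    xy = lo + rng.random((n, 2)) * (hi - lo)
    pending = np.nonzero(~shapely.covers(polys, shapely.points(xy)))[0]
    while pending.size:
        xy[pending] = lo[pending] + rng.random((pending.size, 2)) * (hi - lo)[pending]
        ok = shapely.covers(polys[pending], shapely.points(xy[pending]))
        pending = pending[~ok]

    no2_true = surface.concentration(xy, campaign_index=1)

    # block socioeconomic categories from a confounded latent score
    centroids = np.array([[b.polygon.centroid.x, b.polygon.centroid.y] for b in blocks])
    block_no2 = surface.concentration(centroids, campaign_index=1)
    zno2 = (block_no2 - block_no2.mean()) / block_no2.std()
    latent = confounding_strength * zno2 + rng.standard_normal(len(blocks))
    cuts = np.quantile(latent, [0.2, 0.4, 0.6, 0.8])
    block_sep = np.searchsorted(cuts, latent, side="right") + 1  # 1..5, 5 = high
    sep = block_sep[chosen]

    cov_cols: dict[str, np.ndarray] = {}
    lp = beta_no2_per10 * no2_true / 10.0
    for name, (levels, p) in COVARIATE_LEVELS.items():
        idx = rng.choice(len(levels), size=n, p=np.asarray(p) / np.sum(p))
        cov_cols[name] = np.asarray(levels)[idx]
        lp += np.asarray(effects[name])[idx]
    lp += np.asarray(effects["sep"])[sep - 1]

    # baseline rate targeting the configured event fraction at the mean hazard
    base_rate = -math.log(1.0 - target_event_fraction) / horizon_years
    rates = base_rate * np.exp(lp - lp.mean())
    t = rng.exponential(1.0 / rates)
    event = t <= horizon_years
    followup = np.minimum(t, horizon_years)

    cohort = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "x": xy[:, 0],
            "y": xy[:, 1],
            **cov_cols,
            "sep": sep,
            "no2_true": no2_true,
            "followup_time": followup,
            "event": event,
        }
    )
    truth = {
        "beta_no2_per10": beta_no2_per10,
        "hr_per10": math.exp(beta_no2_per10),
        "covariate_effects": {k: list(v) for k, v in effects.items()},
        "confounding_strength": confounding_strength,
        "horizon_years": horizon_years,
        "baseline_rate": base_rate,
        "seed": seed,
        "n": n,
    }
    return cohort, truth


def with_params(params: SurfaceParams, **overrides) -> SurfaceParams:
    """Convenience: a copy of ``params`` with fields replaced."""
    return replace(params, **overrides)
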