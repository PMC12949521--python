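"""Two-level Monte Carlo upscaling of soil Hg0 emissions from HgS nanoparticles.

Each field site contributes an areal emission flux built multiplicatively from
the bioavailable nanoparticulate mercury pool, the laboratory transformation
efficiency, and an activity scaling for the local abundance of
chemolithoautotrophs capable of HgS reduction:

    F = c_np * rho_b * depth * 1e-3 * eps * a_yr * g(ra)      [g Hg m^-2 yr^-1]

with c_np in ng Hg per g dry soil (lognormal uncertainty), rho_b in g/cm^3,
depth in m (the factor 1e-3 converts ng/g * g/cm^3 * m to g/m^2), eps the
per-incubation transformed fraction drawn from a truncated-normal mixture over
the laboratory strains, a_yr an annualization factor (1/yr), and
g(ra) = min(ra / ra_ref, 1) a linear-saturating scaling in the relative
abundance of capable taxa.

Uncertainty is propagated at two nested levels: inner draws over per-site
parameter uncertainty, and an outer bootstrap of sites within biome that
captures spatial heterogeneity.  Biome means are multiplied by biome areas and
summed to a global draw in tonnes per year; equal-tailed percentile intervals
summarize the draw vector.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

__all__ = [
    "BIOMES",
    "SiteRecord",
    "EfficiencyPrior",
    "FluxEstimate",
    "FluxSummary",
    "GridSpec",
    "load_sites",
    "write_sites",
    "load_areas",
    "sample_site_flux",
    "site_flux_mean",
    "upscale_global",
    "summarize",
    "coverage_check",
    "flux_map",
    "write_ascii_grid",
    "DEFAULT_RHO_B",
    "DEFAULT_DEPTH",
]

BIOMES = ("agricultural", "desert", "forest", "grassland", "wetland", "tundra")

#: Fallback soil bulk density (g/cm^3) and active depth (m) when a site
#: record does not provide its own values.
DEFAULT_RHO_B = 1.3
DEFAULT_DEPTH = 0.2

_G_PER_TONNE = 1e6
#: ng/g * g/cm^3 * m  ->  g/m^2  (1e-9 g/ng * 1e6 cm^3/m^3 = 1e-3)
_POOL_UNIT = 1e-3

_SITE_COLS = ["site_id", "biome", "lat", "lon", "c_np_median_ng_g", "c_np_gsd",
              "ra_mean", "ra_sd", "rho_b_g_cm3", "depth_m"]


@dataclass(frozen=True)
class SiteRecord:
    """One field location: HgS_NP pool, capable-taxon abundance, soil geometry.

    ``c_np_median``/``c_np_gsd`` parameterize a lognormal for the soil HgS_NP
    concentration (ng Hg / g dry soil); gsd 1 means no uncertainty.
    ``ra_mean``/``ra_sd`` parameterize a beta for the relative abundance of
    chemolithoautotrophs capable of HgS reduction; sd 0 means fixed.
    """

    site_id: str
    biome: str
    c_np_median: float
    c_np_gsd: float = 1.0
    ra_mean: float = 1.0
    ra_sd: float = 0.0
    rho_b: float = DEFAULT_RHO_B
    depth: float = DEFAULT_DEPTH
    lat: float | None = None
    lon: float | None = None

    def __post_init__(self) -> None:
        if self.biome not in BIOMES:
            raise ValueError(f"unknown biome {self.biome!r}; expected one of {BIOMES}")
        if self.c_np_median < 0:
            raise ValueError("c_np_median must be >= 0")
        if self.c_np_gsd < 1.0:
            raise ValueError("c_np_gsd must be >= 1")
        if not (0.0 <= self.ra_mean <= 1.0):
            raise ValueError("ra_mean must be in [0, 1]")
        if self.ra_sd < 0:
            raise ValueError("ra_sd must be >= 0")
        if self.rho_b <= 0:
            raise ValueError("rho_b must be > 0")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")


@dataclass(frozen=True)
class EfficiencyPrior:
    """Mixture of laboratory transformation efficiencies across strains.

    ``strains`` holds (mean, SD) pairs in percent of total mercury transformed
    per incubation; defaults are the measured efficiencies of the three
    chemolithoautotroph strains.  Draws are truncated normals on the fraction
    scale, confined to [0, 1], mixed with ``weights``.  ``a_yr`` converts the
    per-incubation fraction into an annual transformed fraction.
    """

    strains: tuple[tuple[float, float], ...] = ((9.7, 1.1), (7.4, 0.8), (7.9, 0.4))
    weights: tuple[float, ...] | None = None
    a_yr: float = 1.0

    def __post_init__(self) -> None:
        if not self.strains:
            raise ValueError("at least one strain required")
        for m, s in self.strains:
            if m < 0 or s < 0:
                raise ValueError("strain means and SDs must be >= 0")
        w = self.weights
        if w is None:
            w = tuple(1.0 / len(self.strains) for _ in self.strains)
            object.__setattr__(self, "weights", w)
        if len(w) != len(self.strains):
            raise ValueError("one weight per strain required")
        if abs(sum(w) - 1.0) > 1e-9 or any(x < 0 for x in w):
            raise ValueError("weights must be non-negative and sum to 1")
        if self.a_yr < 0:
            raise ValueError("a_yr must be >= 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """n draws of the transformed fraction in [0, 1] (not annualized)."""
        idx = rng.choice(len(self.strains), size=n, p=np.asarray(self.weights))
        out = np.empty(n)
        for k, (m_pct, s_pct) in enumerate(self.strains):
            sel = idx == k
            if not np.any(sel):
                continue
            m, s = m_pct / 100.0, s_pct / 100.0
            if s == 0.0:
                out[sel] = np.clip(m, 0.0, 1.0)
            else:
                a, b = (0.0 - m) / s, (1.0 - m) / s
                out[sel] = stats.truncnorm.rvs(
                    a, b, loc=m, scale=s, size=int(sel.sum()), random_state=rng)
        return out

    def mean(self) -> float:
        """Exact mixture mean of the truncated draw (fraction scale)."""
        total = 0.0
        for w, (m_pct, s_pct) in zip(self.weights, self.strains):
            m, s = m_pct / 100.0, s_pct / 100.0
            if s == 0.0:
                total += w * min(max(m, 0.0), 1.0)
            else:
                a, b = (0.0 - m) / s, (1.0 - m) / s
                total += w * stats.truncnorm.mean(a, b, loc=m, scale=s)
        return float(total)


@dataclass
class FluxEstimate:
    """Monte Carlo draws of the global annual Hg0 flux (tonnes/yr)."""

    draws: np.ndarray
    biome_draws: dict[str, np.ndarray]
    seed: int
    n_inner: int
    n_outer: int
    ra_ref: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.draws))

    @property
    def sd(self) -> float:
        if self.draws.size < 2:
            return 0.0
        return float(np.std(self.draws, ddof=1))


@dataclass(frozen=True)
class FluxSummary:
    mean: float
    sd: float
    intervals: dict[float, tuple[float, float]]

    def to_dict(self) -> dict:
        return {
            "mean_t_yr": self.mean,
            "sd_t_yr": self.sd,
            "intervals_t_yr": {
                f"{int(round(100 * lvl))}%": [lo, hi]
                for lvl, (lo, hi) in self.intervals.items()
            },
        }


# ---------------------------------------------------------------------------
# I/O

def load_sites(path: str | Path) -> list[SiteRecord]:
    """Read and validate a sites CSV; row-indexed errors on bad records."""
    df = pd.read_csv(path)
    required = ["site_id", "biome", "c_np_median_ng_g"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records: list[SiteRecord] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        def _get(col, default):
            if col in df.columns and pd.notna(row[col]):
                return float(row[col])
            return default
        try:
            records.append(SiteRecord(
                site_id=str(row["site_id"]),
                biome=str(row["biome"]),
                c_np_median=float(row["c_np_median_ng_g"]),
                c_np_gsd=_get("c_np_gsd", 1.0),
                ra_mean=_get("ra_mean", 1.0),
                ra_sd=_get("ra_sd", 0.0),
                rho_b=_get("rho_b_g_cm3", DEFAULT_RHO_B),
                depth=_get("depth_m", DEFAULT_DEPTH),
                lat=_get("lat", None),
                lon=_get("lon", None),
            ))
        except (ValueError, TypeError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValueError(f"{path}: invalid site rows:\n" + "\n".join(errors))
    return records


def write_sites(sites: Sequence[SiteRecord], path: str | Path) -> None:
    rows = []
    for s in sites:
        rows.append({
            "site_id": s.site_id, "biome": s.biome,
            "lat": s.lat, "lon": s.lon,
            "c_np_median_ng_g": s.c_np_median, "c_np_gsd": s.c_np_gsd,
            "ra_mean": s.ra_mean, "ra_sd": s.ra_sd,
            "rho_b_g_cm3": s.rho_b, "depth_m": s.depth,
        })
    pd.DataFrame(rows, columns=_SITE_COLS).to_csv(path, index=False)


def load_areas(path: str | Path) -> dict[str, float]:
    """Read a biome-areas CSV (columns biome, area_m2); all six biomes required."""
    df = pd.read_csv(path)
    if not {"biome", "area_m2"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns biome, area_m2")
    areas = {str(r.biome): float(r.area_m2) for r in df.itertuples()}
    return validate_areas(areas)


def validate_areas(areas: Mapping[str, float]) -> dict[str, float]:
    missing = [b for b in BIOMES if b not in areas]
    if missing:
        raise ValueError(f"missing biome areas: {missing}")
    unknown = [b for b in areas if b not in BIOMES]
    if unknown:
        raise ValueError(f"unknown biomes in areas: {unknown}")
    if any(a < 0 for a in areas.values()):
        raise ValueError("areas must be >= 0")
    return {b: float(areas[b]) for b in BIOMES}


# ---------------------------------------------------------------------------
# Sampling

def _beta_shapes(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments beta shapes; requires sd^2 < mean*(1-mean)."""
    var = sd * sd
    cap = mean * (1.0 - mean)
    if var >= cap:
        raise ValueError(
            f"ra_sd={sd:g} too large for a beta with mean {mean:g}")
    nu = cap / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def _draw_c_np(site: SiteRecord, rng: np.random.Generator, n: int) -> np.ndarray:
    if site.c_np_gsd == 1.0 or site.c_np_median == 0.0:
        return np.full(n, site.c_np_median)
    return np.exp(rng.normal(np.log(site.c_np_median),
                             np.log(site.c_np_gsd), size=n))


def _draw_ra(site: SiteRecord, rng: np.random.Generator, n: int) -> np.ndarray:
    if site.ra_sd == 0.0 or site.ra_mean in (0.0, 1.0):
        return np.full(n, site.ra_mean)
    a, b = _beta_shapes(site.ra_mean, site.ra_sd)
    return rng.beta(a, b, size=n)


def sample_site_flux(
    site: SiteRecord,
    prior: EfficiencyPrior,
    rng: np.random.Generator,
    n: int = 1,
    ra_ref: float = 1.0,
) -> np.ndarray:
    """``n`` Monte Carlo draws of the site's areal flux (g Hg m^-2 yr^-1).

    With all uncertainties degenerate (gsd 1, ra_sd 0, strain SDs 0) every
    draw equals the deterministic kernel product exactly.
    """
    if ra_ref <= 0:
        raise ValueError("ra_ref must be > 0")
    c = _draw_c_np(site, rng, n)
    ra = _draw_ra(site, rng, n)
    eps = prior.sample(rng, n)
    g = np.minimum(ra / ra_ref, 1.0)
    return c * site.rho_b * site.depth * _POOL_UNIT * eps * prior.a_yr * g


def site_flux_mean(site: SiteRecord, prior: EfficiencyPrior,
                   ra_ref: float = 1.0) -> float:
    """Exact expected areal flux under the kernel (g Hg m^-2 yr^-1).

    Uses the lognormal mean ``median * exp(ln(gsd)^2 / 2)``, the exact
    truncated-normal mixture mean for the efficiency, and the closed-form
    beta expectation of min(ra/ra_ref, 1) via regularized incomplete beta
    functions.
    """
    c_mean = site.c_np_median * np.exp(0.5 * np.log(site.c_np_gsd) ** 2)
    if site.ra_sd == 0.0 or site.ra_mean in (0.0, 1.0):
        g_mean = min(site.ra_mean / ra_ref, 1.0)
    else:
        a, b = _beta_shapes(site.ra_mean, site.ra_sd)
        if ra_ref >= 1.0:
            g_mean = site.ra_mean / ra_ref
        else:
            # E[min(X/r,1)] = (mean/r) I_r(a+1,b) + (1 - I_r(a,b))
            g_mean = (site.ra_mean / ra_ref) * special.betainc(a + 1.0, b, ra_ref) \
                + (1.0 - special.betainc(a, b, ra_ref))
    return float(c_mean * site.rho_b * site.depth * _POOL_UNIT
                 * prior.mean() * prior.a_yr * g_mean)


def _stable_hash(text: str) -> int:
    """Order-independent 64-bit stream key for a site or biome identifier."""
    return int.from_bytes(hashlib.blake2b(text.encode(), digest_size=8).digest(),
                          "big")


def upscale_global(
    sites: Sequence[SiteRecord],
    areas: Mapping[str, float],
    prior: EfficiencyPrior,
    n_inner: int = 1000,
    n_outer: int = 1000,
    seed: int = 0,
    ra_ref: float | None = None,
) -> FluxEstimate:
    """Nested Monte Carlo: inner parameter draws within an outer site bootstrap.

    For each of ``n_outer`` replicates, sites are resampled with replacement
    within their biome; each site contributes the mean of ``n_inner``
    parameter draws; the biome mean areal flux times the biome area gives the
    biome flux, and biomes sum to the global draw (tonnes/yr).  Each site's
    draws come from a substream keyed by a stable hash of its id, so the
    result is invariant to site ordering and reproducible given ``seed``.

    ``ra_ref`` defaults to the median ra_mean across sites.
    """
    if n_inner < 1 or n_outer < 1:
        raise ValueError("n_inner and n_outer must be >= 1")
    areas = validate_areas(areas)
    if not sites:
        raise ValueError("no sites supplied")
    by_biome: dict[str, list[int]] = {b: [] for b in BIOMES}
    for i, s in enumerate(sites):
        by_biome[s.biome].append(i)
    # bootstrap indices address sites in id order, so input order is immaterial
    for b in BIOMES:
        by_biome[b].sort(key=lambda i: sites[i].site_id)
    for b in BIOMES:
        if areas[b] > 0 and not by_biome[b]:
            raise ValueError(f"biome {b!r} has positive area but no sites")
    if ra_ref is None:
        ra_ref = float(np.median([s.ra_mean for s in sites]))
    if ra_ref <= 0:
        raise ValueError("ra_ref must be > 0 (all-zero abundances?)")

    # per-site mean areal flux for every outer replicate: shape (n_sites, n_outer)
    site_means = np.empty((len(sites), n_outer))
    for i, s in enumerate(sites):
        ss = np.random.SeedSequence([seed, _stable_hash(s.site_id)])
        rng = np.random.default_rng(ss)
        draws = sample_site_flux(s, prior, rng, n=n_outer * n_inner,
                                 ra_ref=ra_ref)
        site_means[i] = draws.reshape(n_outer, n_inner).mean(axis=1)

    biome_draws: dict[str, np.ndarray] = {}
    total = np.zeros(n_outer)
    for b in BIOMES:
        idx = np.asarray(by_biome[b], dtype=int)
        if idx.size == 0 or areas[b] == 0.0:
            biome_draws[b] = np.zeros(n_outer)
            continue
        rng_b = np.random.default_rng(
            np.random.SeedSequence([seed, _stable_hash(b), 1]))
        pick = idx[rng_b.integers(0, idx.size, size=(idx.size, n_outer))]
        # column j of pick is the bootstrap sample for outer replicate j
        mean_areal = site_means[pick, np.arange(n_outer)[None, :]].mean(axis=0)
        biome_draws[b] = mean_areal * areas[b] / _G_PER_TONNE
        total += biome_draws[b]

    return FluxEstimate(draws=total, biome_draws=biome_draws, seed=seed,
                        n_inner=n_inner, n_outer=n_outer, ra_ref=ra_ref)


def summarize(
    est: FluxEstimate | np.ndarray,
    levels: Sequence[float] = (0.5, 0.9),
) -> FluxSummary:
    """Mean, SD and equal-tailed percentile intervals of the flux draws.

    Intervals use empirical quantiles at ((1-L)/2, (1+L)/2) with the linear
    order-statistic interpolation convention (numpy method='linear').
    """
    draws = est.draws if isinstance(est, FluxEstimate) else np.asarray(est, float)
    if draws.size == 0:
        raise ValueError("empty draw vector")
    for lvl in levels:
        if not (0.0 < lvl < 1.0):
            raise ValueError("interval levels must be in (0, 1)")
    mean = float(np.mean(draws))
    sd = float(np.std(draws, ddof=1)) if draws.size > 1 else 0.0
    intervals = {}
    for lvl in levels:
        lo = float(np.quantile(draws, (1.0 - lvl) / 2.0, method="linear"))
        hi = float(np.quantile(draws, (1.0 + lvl) / 2.0, method="linear"))
        intervals[float(lvl)] = (lo, hi)
    return FluxSummary(mean=mean, sd=sd, intervals=intervals)


def coverage_check(
    generate,
    n_replicates: int,
    seed: int,
    level: float = 0.9,
    n_inner: int = 20,
    n_outer: int = 200,
) -> float:
    """Empirical coverage of the nominal interval over synthetic replicates.

    ``generate(seed) -> (sites, areas, prior, ra_ref, true_flux)`` must draw a
    fresh synthetic inventory with a known true expected global flux.  Returns
    the fraction of replicates whose nominal-``level`` interval contains the
    truth.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=2 * n_replicates)
    hits = 0
    for k in range(n_replicates):
        sites, areas, prior, ra_ref, truth = generate(int(sub[2 * k]))
        est = upscale_global(sites, areas, prior, n_inner=n_inner,
                             n_outer=n_outer, seed=int(sub[2 * k + 1]),
                             ra_ref=ra_ref)
        lo, hi = summarize(est, levels=(level,)).intervals[level]
        hits += int(lo <= truth <= hi)
    return hits / n_replicates


# ---------------------------------------------------------------------------
# Spatial output

@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid (EPSG:4326-style) for nearest-site rasterization."""

    lon_min: float
    lat_min: float
    lon_max: float
    lat_max: float
    res_deg: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("grid extent must be non-empty")
        if self.res_deg <= 0:
            raise ValueError("res_deg must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        nrow = int(np.ceil((self.lat_max - self.lat_min) / self.res_deg))
        ncol = int(np.ceil((self.lon_max - self.lon_min) / self.res_deg))
        return nrow, ncol


def _haversine_km(lat1, lon1, lat2, lon2):
    r = 6371.0
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return 2 * r * np.arcsin(np.sqrt(a))


def flux_map(
    sites: Sequence[SiteRecord],
    mean_fluxes: Sequence[float],
    grid: GridSpec | None = None,
    cutoff_km: float = 500.0,
) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Per-site mean areal flux as a point table, optionally rasterized.

    The point table (site_id, biome, lat, lon, flux_g_m2_yr) is always
    returned.  With a :class:`GridSpec`, each cell centre takes the flux of
    the nearest site within ``cutoff_km`` (haversine); cells with no site in
    range hold the grid's no-data value.  Requesting a raster with sites
    lacking coordinates is an error.
    """
    if len(sites) != len(mean_fluxes):
        raise ValueError("one mean flux per site required")
    table = pd.DataFrame({
        "site_id": [s.site_id for s in sites],
        "biome": [s.biome for s in sites],
        "lat": [s.lat for s in sites],
        "lon": [s.lon for s in sites],
        "flux_g_m2_yr": np.asarray(mean_fluxes, dtype=float),
    })
    if grid is None:
        return table, None
    if table["lat"].isna().any() or table["lon"].isna().any():
        raise ValueError("all sites need lat/lon for rasterization")

    nrow, ncol = grid.shape
    lats = grid.lat_max - (np.arange(nrow) + 0.5) * grid.res_deg  # north-up
    lons = grid.lon_min + (np.arange(ncol) + 0.5) * grid.res_deg
    raster = np.full((nrow, ncol), grid.nodata)
    if cutoff_km <= 0:
        return table, raster
    slat = table["lat"].to_numpy()
    slon = table["lon"].to_numpy()
    vals = table["flux_g_m2_yr"].to_numpy()
    for i in range(nrow):
        d = _haversine_km(lats[i], lons[:, None], slat[None, :], slon[None, :])
        j = np.argmin(d, axis=1)
        dmin = d[np.arange(ncol), j]
        ok = dmin <= cutoff_km
        raster[i, ok] = vals[j[ok]]
    return table, raster


def write_ascii_grid(raster: np.ndarray, grid: GridSpec, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid (plain-text, georeferenced)."""
    nrow, ncol = raster.shape
    header = (
        f"ncols {ncol}\n"
        f"nrows {nrow}\n"
        f"xllcorner {grid.lon_min:g}\n"
        f"yllcorner {grid.lat_min:g}\n"
        f"cellsize {grid.res_deg:g}\n"
        f"NODATA_value {grid.nodata:g}\n"
    )
    body = "\n".join(" ".join(f"{v:.6g}" for v in row) for row in raster)
    Path(path).write_text(header + body + "\n")
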