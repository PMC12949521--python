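"""Seeded synthetic inputs with the statistical structure each stage assumes.

Three generators cover the pipeline's inputs end to end:

- :func:`gen_pmf` — smooth Gaussian-bump free-energy profiles on z in
  [0, 4] nm, peaked inside the membrane and flat (~0) in the aqueous region,
  with optional additive sampling noise;
- :func:`gen_timecourse` — compartmental-model trajectories with
  multiplicative observation noise and the generating truth attached;
- :func:`gen_sites` — a per-biome field inventory (lognormal HgS_NP
  concentrations, beta-distributed capable-taxon abundances) together with
  biome areas and the exact expected global flux under the upscaling kernel,
  for calibration/coverage tests.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy import integrate, special

from .flux import (
    BIOMES,
    EfficiencyPrior,
    SiteRecord,
    _beta_shapes,
    _POOL_UNIT,
    _G_PER_TONNE,
)
from .kinetics import DEFAULT_PARAMS, KineticParams, TimeCourse, simulate_timecourse
from .membrane import DEFAULT_TEMPERATURE_K, FreeEnergyProfile

__all__ = [
    "PmfConfig",
    "KineticsConfig",
    "BiomeFieldConfig",
    "FieldConfig",
    "SynthConfig",
    "SyntheticTimeCourse",
    "SyntheticField",
    "gen_pmf",
    "gen_timecourse",
    "gen_sites",
    "DEFAULT_FIELD_BIOMES",
]


@dataclass(frozen=True)
class PmfConfig:
    """Gaussian-bump profile: peak ``barrier_height`` at ``barrier_center``."""

    barrier_height: float = 105.0  # kJ/mol, HgS_NP-like default
    barrier_center: float = 0.95   # nm, region I near the region-II interface
    width: float = 0.25            # nm
    noise_sd: float = 0.0          # kJ/mol
    n_points: int = 161
    z_max: float = 4.0
    label: str = "synthetic"
    temperature_K: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.width <= 0 or self.z_max <= 0 or self.n_points < 2:
            raise ValueError("width, z_max must be > 0 and n_points >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class KineticsConfig:
    """Laboratory incubation conditions: 50 uM HgS_NP dose, ~3 day course."""

    truth: KineticParams = DEFAULT_PARAMS
    total_hg: float = 50.0  # uM
    b0: float = 0.05        # initial cell density (OD-like units)
    noise_cv: float = 0.05
    n_times: int = 20
    t_max: float = 72.0     # h

    def __post_init__(self) -> None:
        if not (0.0 <= self.noise_cv < 1.0):
            raise ValueError("noise_cv must be in [0, 1)")
        if self.total_hg <= 0 or self.b0 <= 0 or self.t_max <= 0:
            raise ValueError("total_hg, b0, t_max must be > 0")
        if self.n_times < 2:
            raise ValueError("n_times must be >= 2")


@dataclass(frozen=True)
class BiomeFieldConfig:
    """Per-biome site-population parameters.

    Site HgS_NP medians are lognormal(``c_np_median``, ``c_np_gsd_spatial``)
    across sites; each site then carries measurement gsd ``c_np_gsd_meas``.
    Site mean abundances are beta with mean ``ra_mean`` and spatial SD
    ``ra_sd_spatial``; each site's own uncertainty is ``ra_cv_meas`` times its
    mean.
    """

    n_sites: int
    c_np_median: float          # ng Hg / g dry soil, biome-level median
    area_m2: float
    ra_mean: float
    c_np_gsd_spatial: float = 1.8
    c_np_gsd_meas: float = 1.3
    ra_sd_spatial: float | None = None  # default 0.3 * ra_mean
    ra_cv_meas: float = 0.2
    rho_b: float = 1.3
    depth: float = 0.2

    def __post_init__(self) -> None:
        if self.ra_sd_spatial is None:
            object.__setattr__(self, "ra_sd_spatial", 0.3 * self.ra_mean)
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if min(self.c_np_gsd_spatial, self.c_np_gsd_meas) < 1.0:
            raise ValueError("geometric SDs must be >= 1")
        if not (0.0 <= self.ra_mean <= 1.0):
            raise ValueError("ra_mean must be in [0, 1]")


#: Approximate biome extents and realistic soil HgS_NP / abundance levels.
DEFAULT_FIELD_BIOMES: dict[str, BiomeFieldConfig] = {
    "agricultural": BiomeFieldConfig(n_sites=20, c_np_median=12.0,
                                     area_m2=1.6e13, ra_mean=0.010),
    "desert": BiomeFieldConfig(n_sites=20, c_np_median=2.0,
                               area_m2=2.8e13, ra_mean=0.003),
    "forest": BiomeFieldConfig(n_sites=20, c_np_median=15.0,
                               area_m2=4.0e13, ra_mean=0.008),
    "grassland": BiomeFieldConfig(n_sites=20, c_np_median=8.0,
                                  area_m2=4.0e13, ra_mean=0.007),
    "wetland": BiomeFieldConfig(n_sites=20, c_np_median=25.0,
                                area_m2=9.0e12, ra_mean=0.015),
    "tundra": BiomeFieldConfig(n_sites=20, c_np_median=6.0,
                               area_m2=1.0e13, ra_mean=0.004),
}


@dataclass(frozen=True)
class FieldConfig:
    biomes: dict[str, BiomeFieldConfig] = field(
        default_factory=lambda: dict(DEFAULT_FIELD_BIOMES))
    prior: EfficiencyPrior = field(default_factory=EfficiencyPrior)
    #: Reference abundance at which community activity matches the lab
    #: monoculture; activity scales linearly below it.
    ra_ref: float = 1.0

    def __post_init__(self) -> None:
        missing = [b for b in BIOMES if b not in self.biomes]
        if missing:
            raise ValueError(f"missing biome configs: {missing}")
        if self.ra_ref <= 0:
            raise ValueError("ra_ref must be > 0")


@dataclass(frozen=True)
class SynthConfig:
    """Bundle of all three generator configurations plus the root seed."""

    seed: int = 0
    pmf: PmfConfig = field(default_factory=PmfConfig)
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    field_: FieldConfig = field(default_factory=FieldConfig)


class SyntheticTimeCourse(NamedTuple):
    noisy: TimeCourse
    clean: TimeCourse
    truth: KineticParams


class SyntheticField(NamedTuple):
    sites: list[SiteRecord]
    areas: dict[str, float]
    prior: EfficiencyPrior
    ra_ref: float
    true_flux: float  # tonnes/yr, exact expectation under the kernel


def gen_pmf(config: PmfConfig, seed: int = 0) -> FreeEnergyProfile:
    """Synthetic free-energy profile with a known barrier."""
    rng = np.random.default_rng(seed)
    z = np.linspace(0.0, config.z_max, config.n_points)
    dg = config.barrier_height * np.exp(
        -((z - config.barrier_center) ** 2) / (2.0 * config.width**2))
    if config.noise_sd > 0:
        dg = dg + rng.normal(0.0, config.noise_sd, size=z.size)
    return FreeEnergyProfile(z=z, dg=dg, label=config.label,
                             temperature_K=config.temperature_K)


def gen_timecourse(config: KineticsConfig, seed: int = 0) -> SyntheticTimeCourse:
    """Noisy laboratory-style time course with the generating truth attached.

    Multiplicative Gaussian noise (CV ``noise_cv``) is applied independently
    to every observed series and truncated at zero.
    """
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, config.t_max, config.n_times)
    clean = simulate_timecourse(config.truth, config.total_hg, config.b0, times)
    if config.noise_cv == 0.0:
        return SyntheticTimeCourse(noisy=clean, clean=clean, truth=config.truth)
    noisy_kwargs = {}
    sd = {}
    for name in ("cell_density", "n_ex", "n_in", "d_in", "e",
                 "s_sulfate", "s_intermediate", "s_zero"):
        truth_series = getattr(clean, name)
        noise = rng.normal(0.0, config.noise_cv, size=times.size)
        noisy_kwargs[name] = np.clip(truth_series * (1.0 + noise), 0.0, None)
        sd[name] = np.maximum(config.noise_cv * truth_series,
                              config.noise_cv * config.total_hg * 1e-3)
    noisy = TimeCourse(times=times, total_hg=config.total_hg, sd=sd,
                       **noisy_kwargs)
    return SyntheticTimeCourse(noisy=noisy, clean=clean, truth=config.truth)


def _expected_g(cfg: BiomeFieldConfig, ra_ref: float) -> float:
    """E over sites and inner draws of min(ra / ra_ref, 1).

    Inner draws are beta with mean x (the site's spatial draw), so for
    ra_ref >= 1 the min never binds and the expectation is E[x]/ra_ref.
    Otherwise the inner expectation has a closed form in regularized
    incomplete beta functions and is integrated over the spatial beta law.
    """
    if cfg.ra_mean == 0.0:
        return 0.0
    if ra_ref >= 1.0:
        return cfg.ra_mean / ra_ref
    a0, b0 = _beta_shapes(cfg.ra_mean, cfg.ra_sd_spatial)

    def inner_mean(x: float) -> float:
        sd = cfg.ra_cv_meas * x
        if sd == 0.0 or x <= 0.0 or x >= 1.0:
            return min(x / ra_ref, 1.0)
        a, b = _beta_shapes(x, sd)
        return (x / ra_ref) * special.betainc(a + 1.0, b, ra_ref) \
            + (1.0 - special.betainc(a, b, ra_ref))

    from scipy.stats import beta as beta_dist
    val, _ = integrate.quad(
        lambda x: inner_mean(x) * beta_dist.pdf(x, a0, b0), 0.0, 1.0,
        limit=200)
    return float(val)


def expected_global_flux(config: FieldConfig) -> float:
    """Exact expected global flux (t/yr) under the generating model + kernel."""
    prior = config.prior
    total = 0.0
    for biome, cfg in config.biomes.items():
        c_mean = cfg.c_np_median * np.exp(
            0.5 * (np.log(cfg.c_np_gsd_spatial) ** 2
                   + np.log(cfg.c_np_gsd_meas) ** 2))
        areal = (c_mean * cfg.rho_b * cfg.depth * _POOL_UNIT
                 * prior.mean() * prior.a_yr * _expected_g(cfg, config.ra_ref))
        total += areal * cfg.area_m2 / _G_PER_TONNE
    return float(total)


def gen_sites(config: FieldConfig, seed: int = 0) -> SyntheticField:
    """Synthetic field inventory plus the exact expected flux it implies."""
    rng = np.random.default_rng(seed)
    sites: list[SiteRecord] = []
    areas: dict[str, float] = {}
    for biome in BIOMES:
        cfg = config.biomes[biome]
        areas[biome] = cfg.area_m2
        ln_med = np.log(cfg.c_np_median) if cfg.c_np_median > 0 else -np.inf
        for k in range(cfg.n_sites):
            if cfg.c_np_median == 0.0:
                c_med = 0.0
            elif cfg.c_np_gsd_spatial == 1.0:
                c_med = cfg.c_np_median
            else:
                c_med = float(np.exp(rng.normal(
                    ln_med, np.log(cfg.c_np_gsd_spatial))))
            if cfg.ra_sd_spatial == 0.0 or cfg.ra_mean in (0.0, 1.0):
                ra = cfg.ra_mean
            else:
                a0, b0 = _beta_shapes(cfg.ra_mean, cfg.ra_sd_spatial)
                ra = float(np.clip(rng.beta(a0, b0), 1e-9, 1.0 - 1e-9))
            sites.append(SiteRecord(
                site_id=f"{biome}-{k:03d}",
                biome=biome,
                c_np_median=c_med,
                c_np_gsd=cfg.c_np_gsd_meas,
                ra_mean=ra,
                ra_sd=cfg.ra_cv_meas * ra,
                rho_b=cfg.rho_b,
                depth=cfg.depth,
                lat=float(rng.uniform(-55.0, 70.0)),
                lon=float(rng.uniform(-180.0, 180.0)),
            ))
    return SyntheticField(
        sites=sites,
        areas=areas,
        prior=config.prior,
        ra_ref=config.ra_ref,
        true_flux=expected_global_flux(config),
    )
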