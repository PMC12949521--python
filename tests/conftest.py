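import numpy as np
import pytest

from hgflux.flux import BIOMES, EfficiencyPrior, SiteRecord
from hgflux.kinetics import TimeCourse
from hgflux.membrane import FreeEnergyProfile, RegionPartition


@pytest.fixture
def partition():
    return RegionPartition()


def make_profile(z, dg, **kw):
    return FreeEnergyProfile(z=np.asarray(z, float), dg=np.asarray(dg, float), **kw)


@pytest.fixture
def profile_factory():
    return make_profile


def make_timecourse(times, e, total_hg=50.0, **series):
    """Minimal hand-built time course; unspecified series are zero."""
    times = np.asarray(times, float)
    zeros = np.zeros_like(times)
    kwargs = dict(
        cell_density=zeros + 0.05, n_ex=zeros, n_in=zeros, d_in=zeros,
        s_sulfate=zeros, s_intermediate=zeros, s_zero=zeros,
    )
    kwargs.update({k: np.asarray(v, float) for k, v in series.items()})
    return TimeCourse(times=times, e=np.asarray(e, float), total_hg=total_hg,
                      **kwargs)


@pytest.fixture
def timecourse_factory():
    return make_timecourse


def degenerate_site(biome="forest", c=100.0, ra=1.0, rho_b=1.3, depth=0.2,
                    site_id="s1", **kw):
    """Site with all uncertainty switched off (gsd 1, sd 0)."""
    return SiteRecord(site_id=site_id, biome=biome, c_np_median=c,
                      c_np_gsd=1.0, ra_mean=ra, ra_sd=0.0,
                      rho_b=rho_b, depth=depth, **kw)


@pytest.fixture
def degenerate_site_factory():
    return degenerate_site


def single_strain_prior(mean_pct=8.0, sd_pct=0.0, a_yr=1.0):
    return EfficiencyPrior(strains=((mean_pct, sd_pct),), a_yr=a_yr)


@pytest.fixture
def degenerate_prior_factory():
    return single_strain_prior


@pytest.fixture
def one_biome_areas():
    def _make(biome="forest", area=1.0e12):
        return {b: (area if b == biome else 0.0) for b in BIOMES}
    return _make
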