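# Methods

## 1. Membrane-crossing energetics

A free-energy profile ΔG(z) along the membrane normal (z in nm, ΔG in
kJ/mol) is partitioned into the four conventional regions: lipid alkyl
chains (I, z ≤ 1 nm), phospholipid headgroups (II, 1–2 nm), the
headgroup–water interface (III, 2–2.5 nm) and bulk water (IV, z > 2.5 nm).
Intervals are closed on the right, so the aqueous region is strictly
z > 2.5 nm. Boundaries are configurable.

**Baseline.** Profiles are anchored by subtracting the *mean* ΔG over
region IV rather than the endpoint value: umbrella-sampling tails are noisy
and a regional mean is the more robust zero. The operation is idempotent and
shift-equivariant.

**Barrier.** The barrier is the raw sample maximum of the normalized profile
over regions I–III. No spline or interpolation is applied — umbrella-sampling
profiles are densely sampled, and interpolation would manufacture resolution
the data do not carry. Argmax ties break toward smaller z (the membrane
interior). Readers reject files whose |z| exceeds 100, with a hint that the
file is probably in Ångström; silent rescaling would be worse than an error.

**Rate ratio.** Two barriers are compared as a Boltzmann factor at a shared
kinetic prefactor, k_low/k_high = exp(ΔΔG·1000/(R·T)) with
R = 8.314 J mol⁻¹ K⁻¹. The default temperature is 298.15 K; with the 105 and
212 kJ/mol defaults this reproduces a ~5.6 × 10¹⁸-fold difference (300 K
does not, which is why 298.15 K is the default rather than 300 K). The
exponent is always formed in log space and `log10_crossing_rate_ratio` is
exact for arbitrarily large gaps; the linear-scale function returns `inf`
past the float64 overflow threshold. A Kramers-type treatment with
species-specific diffusivities along z would modify the prefactor; only the
barrier term is modelled here, and absolute rates via `arrhenius_rate`
require the caller to supply a prefactor.

## 2. Transformation kinetics

Mercury pools (µM as Hg): extracellular particles n_ex, internalized
particles n_in, intracellular dissolved Hg(II) d_in, and cumulative volatile
Hg⁰ e. The model is the minimal irreversible chain consistent with an
uptake → dissolution → reduction sequence:

- uptake is second order in cell density and extracellular particles
  (k_up·B·n_ex), since internalization is a cell-surface encounter process;
- dissolution (k_diss) and reduction (k_red) are first order; k_red lumps
  the mercuric-reductase (merA), superoxide and cytochrome-c routes, which
  are not separately rate-resolved;
- each mole of Hg dissolved releases one mole of sulfide-derived S,
  partitioned into sulfate, an intermediate pool (thiosulfate/sulfite) and
  elemental sulfur by fixed fractions f_j summing to 1;
- growth is logistic (r, K) plus a yield term y per µM S oxidized; y = 0
  recovers pure logistic growth.

Direct surface reduction of intact intracellular particles (reduction before
dissolution) is deliberately not modelled. Hg⁰ escape is treated as
instantaneous and irreversible: e is cumulative production = emission.

**Integration.** LSODA at rtol 1e-8 / atol 1e-12. Negative excursions within
−1e-12 are clipped to zero; anything larger is raised as a solver failure
rather than silently repaired. Mercury is conserved to better than 1e-8
relative on every simulated course, and the sulfur ledger equals cumulative
dissolved mercury 1:1.

**Oracle.** With biomass frozen (r = y = 0) the chain is linear with
effective uptake k₁ = k_up·b0, and the Bateman closed form is exact. The
general formula is singular at repeated rates; callers must perturb one rate
by ~1e-9 relative (documented error message) — a limit form was judged not
worth the extra surface for an oracle function.

**Fitting.** Bounded least squares (scipy `least_squares`, trf) over all
eight observed series simultaneously, weighted 1/SD when the time course
carries SDs and by 1/max|series| otherwise so no series dominates on scale
alone. Multi-start: the supplied init plus log-uniform draws within bounds
(default 8 starts, seeded, best residual wins). Parameter SDs come from the
Gauss–Newton curvature at the optimum; parameters within 1e-8 of a bound
are flagged. Fits with fewer observations than free parameters are rejected.

**Default parameters** (`DEFAULT_PARAMS`) emulate the *T. thioparus*
condition: a 50 µM HgS_NP dose, growth on the 100-hour scale, and ~9.7 % of
total mercury volatilized by 18 h. k_up = 0.135 (per cell-density unit per
h) was calibrated once against that 18-h conversion figure with
k_diss = 0.35 h⁻¹ ("readily dissolved": minutes-to-hours scale),
k_red = 0.25 h⁻¹, r = 0.03 h⁻¹, K = 0.6, y = 0.004, and sulfur branching
0.6/0.25/0.15 (sulfate-dominated).

## 3. Global flux upscaling

**Kernel.** Each site's areal flux is multiplicative:
F = c_np · ρ_b · depth · 10⁻³ · ε · a_yr · g(ra) in g Hg m⁻² yr⁻¹, where
c_np (ng Hg/g dry soil) × ρ_b (g/cm³) × depth (m) × 10⁻³ is the areal
HgS_NP pool in g/m² (10⁻⁹ g/ng × 10⁶ cm³/m³), ε is the laboratory
transformed fraction, a_yr (default 1 yr⁻¹) annualizes it, and
g(ra) = min(ra/ra_ref, 1) scales activity linearly in the relative abundance
of capable chemolithoautotrophs, saturating at lab-like communities. Every
factor is a configuration hook, so a differently specified kernel (e.g. from
a deposited supplementary model) can be slotted in.

**ra_ref.** `upscale_global` defaults ra_ref to the median abundance across
sites, which makes the *relative* spatial pattern abundance-driven but pins
typical sites at g ≈ 1. The synthetic study conditions instead set
ra_ref = 1: combining a pure-culture efficiency with a field community in
which capable taxa are ~0.3–1.5 % of the population argues for activity
proportional to that fraction, saturating only at a fully capable community.
With realistic soil concentrations (2–25 ng/g medians by biome) this yields
a global flux of a few hundred tonnes per year — the scale of geogenic
emissions — whereas g ≈ 1 would imply implausible tens of thousands.

**Uncertainty architecture.** Inner level: per-site parameter draws —
lognormal c_np (median, geometric SD), beta ra (method-of-moments from
mean/SD), and a truncated-normal mixture over the three lab strains
(9.7 ± 1.1, 7.4 ± 0.8, 7.9 ± 0.4 %, equal weights, truncated to [0, 1]).
Outer level: sites resampled with replacement within biome, capturing
spatial heterogeneity. For each of n_outer replicates every site contributes
the mean of n_inner draws; the biome mean areal flux × biome area, summed
over biomes, is one global draw (tonnes/yr, 10⁻⁶ t/g). The reported SD is
the SD of this draw vector; intervals are equal-tailed empirical percentiles
at ((1−L)/2, (1+L)/2) with numpy's linear order-statistic interpolation,
fixed as the package convention.

**Reproducibility.** Each site's draw stream is seeded by
SeedSequence([seed, blake2(site_id)]) and bootstrap streams by
SeedSequence([seed, blake2(biome), 1]); within each biome the bootstrap
indexes sites in id order. Input file order therefore cannot perturb any
draw, and identical seeds give bit-identical draw vectors. A site duplicated
within a bootstrap replicate reuses its replicate's draw row — duplicates
represent the same physical site, not new measurements.

**Spatial output.** Per-site mean fluxes are written as a point CSV; when a
lon/lat grid is supplied, cells take the value of the nearest site within a
haversine cutoff (default 500 km), no-data elsewhere. The raster is written
as an ESRI ASCII grid — a plain-text, georeferenced single-band format any
GIS reads.

## 4. Synthetic data: what it emulates, what it does not

`gen_pmf` produces a Gaussian bump (default peak 105 kJ/mol at 0.95 nm,
width 0.25 nm, 161 points on [0, 4] nm) plus optional white noise — the
gross shape of a membrane-permeation profile (≈0 in water, single dominant
barrier in region I). Real profiles have interfacial minima, asymmetric
wells and correlated window errors; passing the extraction tests shows the
estimator is exact for an isolated-peak profile, not that it resolves
competing local maxima. At noise SD 2 kJ/mol the extracted barrier is biased
high by ~1.6 kJ/mol (the maximum over near-peak samples inherits the
expected maximum of their noise); the tests pin this bias against an
independent recomputation rather than pretending it away.

`gen_timecourse` applies independent multiplicative Gaussian noise
(default CV 5 %, truncated at 0) to every series of a simulated course and
attaches the generating truth. Real assay errors are serially and
cross-series correlated and mercury fractions are compositionally coupled;
recovery results are therefore an idealized-noise statement.

`gen_sites` draws, per biome, site-level lognormal concentration medians
(spatial gsd 1.8 around biome medians 2–25 ng/g), measurement gsd 1.3, beta
abundances (means 0.3–1.5 %, spatial CV 30 %, measurement CV 20 %),
ρ_b = 1.3 g/cm³, depth = 0.2 m, and 20 sites per biome over six biomes
(agricultural 1.6e13, desert 2.8e13, forest 4.0e13, grassland 4.0e13,
wetland 9e12, tundra 1e13 m²) — survey-scale realism without spatial
autocorrelation or soil-chemistry covariates. The generator also returns the
*exact* expected global flux under the kernel: lognormal means in closed
form, truncated-normal mixture mean in closed form, and the beta expectation
of min(ra/ra_ref, 1) via regularized incomplete beta functions (reduced to
E[ra]/ra_ref when ra_ref ≥ 1; numerically integrated over the spatial law
otherwise). This truth is what the coverage audit scores against.

**Coverage.** Over 500 regenerated inventories, the nominal 90 % interval
covers the analytic truth ~87–88 % of the time. Percentile bootstrap
intervals are known to undercover slightly for skewed (lognormal) data at 20
sites per biome; aggregation over six biomes moderates but does not remove
this. The audit is reported as measured.

## 5. Problem sizes

Defaults were chosen so each stage is statistically meaningful at desk
scale: 20–37 point time courses, 100 recovery replicates, 10⁵-draw
moment checks, 500-replicate coverage audits with n_inner = 20 /
n_outer = 200, and n_inner = 100 / n_outer = 400 for single headline
upscaling runs. All sizes are arguments, not constants.

## 6. Known limitations

- The rate-ratio prefactor is assumed species-independent; diffusivity
  differences along z are not modelled.
- Reduction pathways are lumped; pathway-resolved kinetics would need
  strain-specific k_red values (a config hook exists).
- The upscaling kernel is a first-order multiplicative skeleton; mercury
  speciation dynamics, re-deposition, vegetation and oceanic pathways are
  out of scope.
- The annualization factor a_yr = 1 treats the lab incubation efficiency as
  an annual transformed fraction; there is no temporal-extrapolation model
  behind it, and it should be revisited when field rate data exist.
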