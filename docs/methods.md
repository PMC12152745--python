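# Methods

This note documents the models implemented in `aeromig`, their assumptions,
the numerical choices made where the design was open, and what the synthetic
scenarios do and do not establish about real radar data.

## Vertical profiles and integration

A vertical profile is a stack of 100 m altitude bins (lower bounds
0–4900 m a.s.l.) holding linear reflectivity η (cm² km⁻³) and the
reflectivity-weighted mean ground velocity (u eastward, v northward,
m s⁻¹). Velocity may be missing while reflectivity is present — a common
state in operational radar products with aggressive velocity quality
control.

All height-indexed computation (vertical interpolation, mean flight height,
ground-level extraction) uses **bin centers** (lower bound + 50 m), a
symmetric within-bin assumption. Integration is a rectangle rule over the
fixed 100 m bins; no trapezoid is taken across bins because the bin value
already represents a bin average. Density is dens = η/σ with σ = 11 cm² per
bird; VID = Σ dens·Δh and MTR = Σ dens·|V_ground|·Δh with Δh = 0.1 km and
ground speed converted to km h⁻¹.

**MTR missingness.** MTR is declared missing whenever *any* bin with
positive density lacks a velocity estimate. A partial-bin MTR silently
computed from the remaining bins would be biased low on exactly the nights
with the worst data, so the quantity is withheld instead and the night's gap
flag records it.

Heights are anchored at sea level (the altitude ceiling is 5000 m a.s.l.,
not above ground), matching how operational vertical profiles are binned;
stations sit at 80–218 m a.s.l. so the lowest bins may be partly below the
antenna.

## Bird–insect partition

Assumptions: insects move approximately with the wind plus a small fixed
self-propelled speed a_i = 1 m s⁻¹ oriented **downwind**; birds are
self-propelled at a fixed airspeed a_b = 8 m s⁻¹ with an unknown heading;
a bin's observed mean velocity is the reflectivity-weighted mixture of the
two ground velocities. Eliminating the unit heading vector from

    V_obs = f·(V_wind + a_b·ĥ) + (1 − f)·(V_wind + a_i·ŵ)

gives, with A = V_obs − V_wind,

    g(f) = f²(a_i² − a_b²) + 2 f a_i((A·ŵ) − a_i) + |A − a_i·ŵ|² = 0.

g is concave with g(0) ≥ 0 and g(1) = |A|² − a_b², so whenever |A| ≤ a_b
there is exactly one root in [0, 1] (the upper root of the parabola), and it
is the bird fraction. Numerical policy:

- |A| ≥ a_b → f = 1 with recorded residual |A| − a_b (observed airspeed
  exceeding the bird airspeed cannot be represented by the mixture);
- calm wind (|V_wind| < 0.5 m s⁻¹) → the downwind direction is undefined and
  the insect self-propulsion term is dropped, reducing the solution to
  f = |A|/a_b;
- the root is clipped to [0, 1] against floating-point excursions at the
  endpoints; the residual column is exactly zero unless clamping occurred.

The heading vector is ĥ = (A − (1−f)·a_i·ŵ)/(f·a_b) for f > 0; bird
reflectivity is η_bird = f·η, so η_bird + η_insect = η holds exactly.
Compass convention everywhere: bearing = atan2(u, v) in degrees, 0° = N,
90° = E, for both heading and track (track adds the wind back in). A scalar
fallback f = clip((|A| − a_i)/(a_b − a_i), 0, 1) is available as a
diagnostic; it is exact only in the collinear geometry and is not used by
the pipeline.

Between A = 0 and |A| = a_i the model resolves the observation with a bird
component flying against the wind (f up to a_i/(a_i + a_b)); this is the
mixture model's honest answer, not an artifact, and it vanishes at the
pure-insect point A = a_i·ŵ. Varying (a_i, a_b) over [0.5, 3] × [8, 12]
keeps all outputs within their physical ranges (tested), but the fractions
themselves shift; the defaults are the field's standard passerine/insect
airspeeds.

## Atmospheric pairing and flow assistance

Pressure-level tables (3-hourly, 15 levels from 1000 to 600 hPa, one file
per grid point chosen as the nearest cell to the radar) are interpolated
**linearly in time first, then in altitude**, using the (time-interpolated)
geopotential height of each level as the vertical coordinate. Outside the
level span values clamp to the nearest level rather than extrapolating —
inventing a lapse rate below the lowest level would be less defensible than
a small constant bias in the lowest bins. Profile timestamps outside the
grid's time span yield missing values with a logged warning. Pairing is
exact (to 1e-9) for fields jointly linear in time and height.

Flow assistance uses the equal-airspeed model: with tailwind component t and
crosswind component c relative to the preferred direction,
assistance = t + √(a² − c²) − a. When |c| > a full crosswind compensation is
infeasible and the value is **missing** (not floored); downstream covariate
rows with missing tailwind are dropped. The preferred direction is the
bird-reflectivity-weighted circular mean of tracks per station and season.

Ground-level values are taken from the bin whose center is closest to the
station antenna height; an equidistant tie resolves to the lower bin. The
collinearity screen drops the lower-priority member of any covariate pair
with |Pearson r| > 0.7; the default priority keeps tailwind first, specific
humidity over air temperature and vertical air motion (omega) over turbulent
kinetic energy. Constant columns are excluded with a warning.

## Screening

- **Season windows:** boreal spring Feb 20 – Jun 1, fall Aug 1 – Nov 25,
  both boundaries inclusive (a one-day convention choice with negligible
  effect on season statistics); windows are overridable per configuration.
- **Night:** solar elevation below −0.833° (standard refraction-corrected
  horizon). Solar position uses the NOAA fractional-year series for
  declination and the equation of time; sunset/sunrise instants are located
  by root-finding the elevation crossing. Accuracy is a few hundredths of a
  degree — minutes-level agreement with independent almanac calculations,
  verified in the tests against a separately coded low-precision algorithm.
- **Night keys:** each nocturnal instant belongs to the night of its most
  recent sunset, dated by the station's civil time zone (a fixed UTC offset
  in the station configuration).
- **Direction filter:** spring removes tracks strictly inside (90°, 270°)
  (southbound); fall removes tracks strictly below 90° or strictly above
  270° (northbound); 90° and 270° are retained in both seasons, following
  the strict printed inequalities. The filter is applied to the track
  (ground direction) in both seasons. Bins with missing track pass through
  flagged rather than being silently dropped.
- **Thinning:** one scan per night, the one closest to sunset + 3 h (peak
  migration, and safely past dusk bat emergence); ties go to the earlier
  scan. Used for the covariate table and radar–acoustic pairing only — the
  phenology statistics use all nocturnal scans.
- **Completeness:** a season supports MT totals when ≥ 75% of window nights
  have usable data, supports MTR mean/CV when more than 14 consecutive
  nights have data, and is near-complete with more than 3000 volumes.

## Phenology

Nightly MT integrates MTR with midpoint-to-midpoint weights clipped to
[sunset, sunrise]; the time-weighted nightly mean MTR uses the same weights.
An intra-night gap in usable MTR longer than 1 h sets the night's gap flag;
flagged nights still contribute to totals (transparent gaps rather than
imputation). Multi-night outages are likewise not interpolated.

The CV uses the sample (n−1) standard deviation. Bootstrap CIs resample
nights with replacement, 10 000 replicates, percentile method at 2.5/97.5%,
fully determined by the seed. Percent-of-nights sorts nights by traffic
**descending** and reports 100·k/N for the minimal k reaching the target
fraction, with N the number of window nights with usable data; the
chronological orderings are reserved for the core spans (first dates
crossing the lo/hi cumulative fractions) and the peak date (first date
crossing 50%). Cumulative-fraction crossings use a 1e-9 relative tolerance
so exact-fraction boundaries are not missed to floating-point rounding.

## Acoustics

Call rate is calls per recording hour, computed per night after summing
counts and hours across the night's recordings. The fourth-root transform
stabilizes the variance of the strongly right-skewed nightly counts. Radar
and acoustic nights are inner-joined on the night key; the correlation with
radar bird density is reported both for the transformed (default) and raw
rate, since either convention is defensible.

## Synthetic scenarios

The generator produces the structure the analysis assumes, with all
randomness flowing from one seed:

- **Seasonal truth:** nightly passage ∝ Gaussian(date; peak, sd 20 days) ×
  LogNormal(−σ²/2, σ) with σ = `night_sigma`, normalized so the season total
  equals `total_passage` exactly. The −σ²/2 mean correction keeps the
  expected total invariant in σ, so σ is a pure episodicity knob.
- **Atmosphere:** a slowly varying base wind plus a Gaussian-in-altitude
  nocturnal jet (center 1750 m, width 600 m) whose amplitude follows an
  AR(1) process across nights; standard-atmosphere geopotential heights; a
  constant lapse for temperature; exponentially decaying humidity and TKE.
- **Profiles:** per scan, a within-night traffic shape peaking ~3 h after
  sunset apportions the night's MT over scan intervals exactly (the shape is
  normalized against the same midpoint weights the pipeline integrates
  with); bird density is allocated over altitude ∝ exp(−h/1000 m), optionally
  weighted by exp(κ_w·tailwind); per-bin observed velocity is the exact
  reflectivity-weighted mixture of bird and insect ground velocities plus
  isotropic Gaussian noise (default sd 0.5 m s⁻¹ — there is no published
  radar velocity error model, so a plain isotropic error is used).
- **Calls:** nightly counts are Poisson around a rate proportional to bird
  density discounted by exp(−height/1000 m) — lower flight is more audible.

Presets: `tropical` (weak base wind, stable jet, night σ = 0.35),
`temperate` (strong variable wind, night σ = 1.2), and `noisefree`
(tropical with zero velocity noise and exact headings) for forward–inverse
recovery checks. Default problem sizes — a full 117-night fall window at
30-minute scans and 50 bins — were chosen so a full scenario simulates and
analyzes in seconds on one core.

**What passing recovery tests shows, and what it does not.** The generator
composes observations with the *same* mixture model the partition inverts,
so noise-free recovery is an internal-consistency check of the algebra and
plumbing, not evidence that real insect targets follow the wind at exactly
1 m s⁻¹. Likewise the generator has no ground clutter, anomalous
propagation, dealiasing failures, range-dependent beam geometry, or
non-bird/non-insect scatterers; real-data performance depends on upstream
profile quality in ways these tests cannot certify. What the synthetic
route does establish: the quadratic matches an independent grid-search
oracle; the integration, screening and phenology statistics agree with
brute-force computation; the episodicity statistics recover the generating
σ ordering; and the whole pipeline is deterministic given a seed.

## Known limitations

- The partition assumes exactly two taxa at fixed airspeeds; mixed bins of
  birds at heterogeneous airspeeds (or bats) bias f.
- Velocity noise propagates into f with error ≈ noise/a_b per component;
  at 0.5 m s⁻¹ noise the median |Δf| is ≈ 0.045, and insect-dominated bins
  acquire a small positive bird-reflectivity bias (noise can only increase
  the apparent departure from pure drift), which inflates season totals by
  ~10% in the noisy presets.
- Statistical modeling of density against covariates (GAMs etc.) is out of
  scope; the pipeline emits the analysis-ready covariate table instead.
- Fixed-offset civil time zones; no polar day/night handling (irrelevant at
  study latitudes).
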