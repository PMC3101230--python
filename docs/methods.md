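# Methods

`winterchill` estimates how much winter chill — the cold exposure temperate
fruit and nut trees need to break dormancy — a site can count on under a
given climate, and how that quantity shifts under warming scenarios. This
note records the models, the numerical choices, and what the synthetic data
do and do not establish.

## Station screening

Daily Tmin/Tmax/precipitation records are screened over a calibration window
(1973–2002 by default): a station survives with at least 5000 daily records
in the window, no more than 25% of its daily minimum or maximum temperatures
missing, and no more than 50% of its rainfall missing. "Daily records"
counts rows present with at least one variable non-missing, not calendar
coverage, and thresholds are inclusive on the passing side (exactly 25%
missing passes) — the filter phrase excludes stations with *more than* the
threshold missing. Rows with Tmax < Tmin are retained with both temperatures
set missing, on the view that a transposition is more likely than two valid
values. Missing cells may be empty or `NA`; dates are proleptic Gregorian
and leap days are kept.

## Climate scenarios

For each station and calendar month, ordinary least squares relates the
monthly mean Tmin, mean Tmax and precipitation total to the calendar year
(the abscissa is the year itself, not an index). A "typical year Y" scenario
is the trend prediction at Y minus the calibration-period monthly mean —
a representation of long-term conditions around Y rather than the weather
observed in Y. Future scenarios arrive as 12-month anomaly tables (one row
group per epoch × emissions pathway × climate model label). Temperature
anomalies are additive; precipitation anomalies are multiplicative factors
floored at 0, which keeps generated precipitation non-negative. No
significance screening is applied to fitted slopes. Monthly aggregates with
more than half of a month's days missing are treated as missing; months with
fewer than 3 non-missing years yield no trend.

## Weather generator

The generator reproduces the site statistics that matter for a
temperature-driven chill model: monthly means, day-to-day variability,
persistence, and the wet/dry rhythm that real archives need for calibration.

* **Temperatures.** Daily Tmin is a smooth seasonal climatology plus
  `sd[m] * z_t`, with `z_t = rho*z_{t-1} + sqrt(1-rho^2)*eps_t` a standard
  AR(1); Tmax uses a residual correlated with the Tmin residual
  (`w = c*z + sqrt(1-c^2)*u`, `u` an independent AR(1)) on top of the Tmax
  climatology, then is clamped to `tmax >= tmin` (clamp counts are reported;
  they are rare, ~0.05% of days at the default parameters).
* **Mean-preserving climatology.** Monthly means are interpolated linearly
  between mid-month anchors so chill accumulation sees no step at month
  boundaries. Plain anchoring at the monthly means would bias each month's
  average toward its neighbours (up to ~0.5 °C for strong seasonal cycles),
  so the anchors are solved from a 12×12 linear operator such that the
  interpolated daily series averages back exactly to the requested monthly
  means.
* **Scenario injection.** Temperature deltas are added per month as steps
  (not interpolated): a single-month anomaly then passes through to that
  month's generated mean exactly, which is the bookkeeping the
  anomaly/delta-change method assumes. Only means are perturbed, not
  variability.
* **Precipitation.** Occurrence is a two-state first-order Markov chain with
  monthly transition probabilities (wet day ⇔ > 0.1 mm, the common generator
  convention); wet-day amounts are gamma draws (method-of-moments fit),
  scaled by the scenario's monthly factor. Months with zero observed wet
  days generate zero precipitation; near-constant wet-day amounts fall back
  to an exponential with the observed mean.
* **Calibration.** Monthly moments are sample statistics (zero standard
  deviations floored at 0.1 °C); the lag-1 autocorrelation comes from
  deseasonalized Tmin residuals on consecutive days; correlations are
  clipped to ±0.99. Calibration requires at least 5 years of record.
* **Determinism.** One integer seed is expanded (SeedSequence) into
  independent substreams for Tmin, Tmax and precipitation; identical inputs
  give byte-identical series. Very long series shift their nominal start
  year down so timestamps stay inside pandas' nanosecond range — calendar
  labels of synthetic series are nominal.

The fabricated-site helper (`synthetic_site_params`) builds parameters from
latitude and mean annual temperature: a sinusoidal seasonal cycle whose
amplitude grows ~0.35 °C per degree of latitude, an 8 °C diurnal range,
2.5 °C daily variability, lag-1 autocorrelation 0.65 — typical mid-latitude
station values.

## Hourly reconstruction

Daytime temperatures follow a sine arc from Tmin at sunrise, with period
stretched by 4 h so the maximum falls in mid-afternoon; night temperatures
decline logarithmically from the sunset value to the next day's Tmin,
reaching it exactly at the next sunrise. The night curve is anchored one
whole hour after sunset (ln 0 is undefined), so the first post-sunset sample
equals the sunset temperature. Solar declination uses the 7-term Fourier
series in the day angle Γ = 2π(J−1)/365; daylength is (2/15)·arccos(−tan φ
tan δ) in degrees of hour angle, clamped into [0, 24] h for polar latitudes.
All times are local solar time with no longitude correction — chill totals
are insensitive to a uniform phase shift of the diurnal cycle. Leap years
keep the calendar day-of-year (Feb 29 = 60) while Γ continues to use 365;
the declination error is below 0.1%.

Degenerate days (daylength ≤ 4 h or ≥ 23 h) fall back to a 24-point cosine
interpolation between Tmin and Tmax; fallbacks are counted on the series.
The first night of a series backfills the first day's Tmin, and the final
night reuses the last day's own Tmin (there is no later day to take it
from) — one boundary night is negligible over a season.

## Chill models

The Dynamic Model's hourly recursion and constants are given in the module
docstring (`winterchill.chill`); the constants are the canonical published
values (slp 1.6, tetmlt 277 K, E0 4153.5 K, E1 12888.8 K, A0 1.395·10⁵,
A1 2.567·10¹⁸) and are configurable for sensitivity analysis. Two
closed-form facts anchor the tests independently of the recursion: at
constant temperature the precursor follows `E_n = xs(1 − e^(−n·ak1))`, so
the first portion completes at hour `⌈−ln(1 − 1/xs)/ak1⌉`; and wherever the
equilibrium `xs ≤ 1` (above ~28 °C) no portion can ever complete.

Chilling Hours count hours in (0, 7.2] °C. The Utah Model uses the standard
weight table with half-open bands ((−∞,1.4]→0, (1.4,2.4]→0.5, (2.4,9.1]→1,
(9.1,12.4]→0.5, (12.4,15.9]→0, (15.9,18]→−0.5, (18,∞)→−1); boundary openness
is a convention choice, documented here because published tables differ.
Utah seasonal totals may be negative and are reported as-is.

Dormancy windows are Oct 1 – Apr 30 23:00 in the Northern Hemisphere and
Apr 1 – Oct 31 23:00 in the Southern (half-open at the end date; one
boundary day is negligible for seasonal totals). Latitude 0 is treated as
Northern. 101 generated years contain 100 complete northern winters.

**Safe Winter Chill (SWC)** is the empirical 10% quantile of the seasonal
totals — the chill exceeded in 90% of winters, the planning quantity for an
orchard. The estimator interpolates linearly between order statistics
(position 0.1·(n−1)+1 on the sorted sample; SWC of 1…100 is 10.9). At least
10 seasons are required. The estimator carries the usual small positive
bias of sample quantiles at n = 100 (~0.3 units for a Normal(60, 10²)
distribution), well inside scenario differences of interest.

## Spatial stage

Station SWC and station mean annual temperature are each interpolated by
ordinary kriging restricted to the 12 nearest stations, with a spherical
semivariogram fitted by bounded least squares to the empirical semivariogram
(15 equal-width distance bins up to 40% of the maximum pairwise distance).
Cells coinciding with a station return the station value exactly; singular
neighbourhood systems fall back to inverse-distance weighting and are
counted. Weights always sum to 1 (ordinary-kriging unbiasedness), asserted
on the solver output.

The temperature correction fits a degree-5 polynomial CP(T) between station
mean annual temperature and station SWC (internally centred/scaled; at
least 20 stations spanning ≥ 10 °C required), with validity range the widest
contiguous interval around the data on which the fit is non-negative;
CP(T) = 0 outside. The corrected surface is

    SWC_corr = SWC_int + CP(T_interp + T_diff) − CP(T_interp),  floored at 0,

the delta form of "correct by how much the fine-scale temperature deviation
would change chill". The polynomial is refitted per scenario (configurable).
Cells further than 5° from the nearest station (plane Euclidean distance in
degrees — matching the degree-based phrasing of the rule; configurable) are
masked as unreliable, and cells with high-resolution mean annual temperature
below 0 °C or above 20 °C as unsuitable for chill-requiring crops. Rasters
are exchanged as NetCDF (scipy backend) or CSV; station tables as CSV.

## Pipeline and problem sizes

The orchestrator is deterministic given config + seed: per-(station,
scenario) generator seeds derive from a SeedSequence over (seed, station
index, scenario index), and the manifest records SHA-256 checksums of every
output. The spatial stage runs when at least 13 stations survive (the
kriging neighbourhood plus one); smaller toy runs record the skip.

Test and demonstration runs use deliberately small worlds: 3–12 fabricated
stations, 11–30 generated years for mechanism tests, and one full
station-workload run (2 past + 18 future scenarios × 101 years, ~1 minute).
The acceptance script re-derives every headline quantity at these sizes.

## What the synthetic world does and does not show

The generator emulates seasonal climatology, autocorrelated daily
variability, Markov-gamma precipitation, monthly warming trends and anomaly
perturbation. It does not emulate weather fronts or spell-length
distributions beyond first-order persistence, elevation effects, coastal
asymmetries, or observation error; the fine-temperature raster is a smooth
gradient plus terrain-like noise, not a real climatology. Passing tests
therefore establish the correctness of the algorithms and their couplings —
filter arithmetic, trend recovery, anomaly pass-through, chill kinetics,
quantile statistics, kriging exactness, correction gain, mask geometry —
not the climatological fidelity of any particular map. The
frost-compensation result (warming raises Chill Portions where winters sit
below 0 °C and lowers them where winters are mild) is a property of the
Dynamic Model's temperature window and reproduces at toy scale for that
reason.

## Known limitations

* The weather generator perturbs means only; scenarios that change
  variability or spell lengths are out of reach.
* Kriging distances and the 5° mask are computed on the lon/lat plane;
  near-polar or dateline-spanning grids would need great-circle distances.
* The night curve ties each night to the *next* day's Tmin; advective
  warm nights violate the monotone-decline assumption.
* Utah and Chilling Hours are included as comparators; they are known to
  behave poorly in warm climates and are not recommended there.
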