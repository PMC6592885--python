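# Methods

This note documents the models implemented in `climuq`, their assumptions,
the parameters that matter, and the numerical and design choices made where
the design was genuinely open.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Daily weather representation

A site record is a contiguous daily series of maximum temperature Tmax
(°C), minimum temperature Tmin (°C) and precipitation P (mm/day) on the
real proleptic Gregorian calendar; Feb 29 is an ordinary day and
participates in all statistics.  Missing values are rejected at read time
rather than represented: every downstream formula assumes complete series,
as generated series are complete by construction.  A *wet day* is a day
with P ≥ 0.1 mm for generator calibration; the precipitation *indices* use
the customary 1.0 mm convention instead.  Both thresholds are arguments.

## The parametric generator (pwg)

Precipitation occurrence is a two-state first-order Markov chain with
monthly transition probabilities p01 (wet after dry) and p11 (wet after
wet); a transition is attributed to the calendar month of its second day.
Wet-day amounts are gamma distributed per calendar month, fitted by the
Thom closed-form maximum-likelihood approximation: with
s = ln(x̄) − ln(x)‾ over a month's wet-day amounts,
α̂ = (1 + √(1 + 4s/3))/(4s) and θ̂ = x̄/α̂.  Daily temperatures are
wet/dry-state-conditioned monthly normals; the standardized (Tmax, Tmin)
residual pair follows the Matalas lag-1 bivariate autoregression
z_t = A z_{t−1} + B ε_t with A = M₁M₀⁻¹ and BBᵀ = M₀ − M₁M₀⁻¹M₁ᵀ, where
M₀ and M₁ are the lag-0 and lag-1 correlation matrices of the residuals.

Numerical choices:

* Insufficient data (months without eligible transitions, cells with fewer
  than 10 days, fewer than 5 wet days) or degenerate statistics (all-equal
  amounts, zero variance) produce NaN *undefined markers*, never silent
  zeros.  Generation from parameters with undefined cells raises a
  `GenerationFailure` naming the cells; the pipeline records it and the
  balance rules act on it.
* If sampling noise makes BBᵀ indefinite, its eigenvalues are floored at
  10⁻⁸ before factoring.
* Generation starts in the dry state with zero residual and discards a
  30-day burn-in.
* A drawn (Tmax, Tmin) pair violating Tmax ≥ Tmin is swapped.  With
  realistic diurnal ranges (~8–12 °C) and residual spreads (~2–3 °C) the
  event is several standard deviations out, so the marginals are
  essentially preserved.
* Generated wet-day amounts are floored at the wet threshold so that a
  generated wet day is wet under the calibration threshold.  This puts a
  small atom at 0.1 mm and biases the Thom shape estimate upward by
  roughly 7–9 % for shapes near 0.8; the alternatives (no floor, which
  biases the refitted occurrence probabilities *and* left-truncates the
  amount sample; or truncated-gamma sampling, which biases a full-gamma
  refit by ~20 %) are worse.  The recovery tests bound the combined
  bias-plus-noise error at 15 % relative on a century of data.

## The semi-empirical generator (sewg)

Generation alternates dry and wet spells.  Spell lengths are drawn from
seasonal (DJF/MAM/JJA/SON) histograms with a fixed bin count (10 integer
bins spanning 1..longest observed spell; the length is uniform within the
chosen bin), the season being that of the spell's first day.  Wet-day
amounts come from monthly empirical quantile tables by inverse-CDF linear
interpolation, so generated amounts never exceed the largest calibrated
amount.  Temperatures use the same month × state normals as the parametric
family but with an independent lag-1 autoregression per variable — no
cross-correlation between the Tmax and Tmin residuals.

The deliberate coarseness of this family (seasonal, binned spells; bounded
amount tails; missing temperature cross-correlation) is what makes it a
*structurally different* generator: calibrated on the same record, it
reproduces the marginal climate well but distorts spell structure,
extreme-amount tails and the diurnal-range distribution in its own way.

## The third generator level (pwg_noac)

The parametric generator with the temperature autoregression switched off
(M₁ = 0, hence A = 0): daily temperature residuals become serially
independent while all marginal distributions are untouched.  Warm/cold
*spell* statistics and monthly extreme order statistics are sensitive to
this; simple exceedance counts are not.  The three levels pwg / sewg /
pwg_noac give the generator factor of the factorial analyses three
structurally distinct levels.

## Synthetic truth and what it does (not) emulate

Site archetypes (`temperate_north`, `monsoon`, `mediterranean`,
`tropical_south`) define sinusoidal monthly climatologies with plausible
occurrence probabilities, gamma amounts, diurnal ranges and residual
correlations; southern archetypes are phase-shifted by six months.  A seed
adds small reproducible site-to-site jitter (±1 °C on temperature means,
±0.03 on probabilities, ±10 % on the gamma scale).  The truth uses exactly
the parametric generator's family, which makes parameter recovery a
well-posed exercise with a known answer; the semi-empirical generator then
plays the role of a structurally different model of the same data.

The synthetic world omits features of real station data: no spatial
correlation between sites (sites are analysed independently), no
interannual trends or low-frequency variability, no measurement error or
inhomogeneities, no solar radiation or humidity variables.  Passing tests
therefore demonstrate the correctness and internal consistency of the
machinery under known conditions, not the behaviour of any particular real
climate.

## Change factors and the delta-change step

A scenario is 12 monthly additive temperature deltas for Tmax and Tmin
(°C) and 12 multiplicative precipitation ratios.  Pathway archetypes set
the ranges: moderate-forcing deltas in [0.8, 1.5] °C, high-forcing in
[1.5, 2.5] °C, ratios in [0.8, 1.2].  The monthly pathway-level values are
drawn once per scenario; each emulated GCM perturbs them with a small
model-specific offset (±0.05 °C, ±0.015 on the ratio).  The offsets are
deliberately small relative to the pathway separation: the emulated GCM
pair represents two climate models that agree closely on the regional
forced response, so downscaled GCM × RCP combinations cluster tightly —
the regime in which attributing residual uncertainty to the generator is
the interesting question.  Larger inter-GCM spread is a one-line config
change (the offsets are module constants).

Deltas are applied to *generator parameters*, not to a generated record:
temperature means shift additively in both states; the gamma scale (or
every entry of the monthly quantile tables) is multiplied by the monthly
ratio, so the mean wet-day amount scales exactly by it; occurrence
probabilities are unchanged by default (an optional wet-frequency
multiplier hook exists, clipped to [0, 1], off by default — no variance
inflation and no occurrence perturbation are applied because the
delta-change construction is a mean change).  The identity scenario is a
bit-exact no-op.

## The index battery

27 climate-extremes indices (FD, SU, ID, TR, GSL, TXx, TNx, TXn, TNn,
TN10p, TX10p, TN90p, TX90p, WSDI, CSDI, DTR, Rx1day, Rx5day, SDII, R10mm,
R20mm, Rnnmm with nn = 25 mm, CDD, CWD, R95pTOT, R99pTOT, PRCPTOT) plus
six agro-meteorological metrics: monthly Hargreaves ET0; SPEI; annual
de Martonne–Gottman aridity I′ = ½[I + 12·p_driest/(t_driest + 10)] with
I = P_ann/(T_ann + 10); annual UNEP aridity P_ann/PET_ann; monthly water
balance P − PET; and a simple monthly aridity measure SAM = P/PET (the
ratio definition is a configurable default, chosen because the companion
metrics make PET the natural denominator).

Conventions, applied identically to every compared series:

* Percentile thresholds: per calendar day, a 5-day centred window pooled
  over the base-period years, median-unbiased quantile interpolation.
  Feb 29 is excluded from pooling and borrows Feb 28's thresholds, so
  every window pools exactly 5 × n_years values.
* The in-base/out-of-base bootstrap for exceedance indices is *not*
  applied.  Exceedance rates computed on the base period itself are then
  biased slightly below the nominal 10 % — acceptable here because every
  comparison treats both series with the same base.
* Spell indices (WSDI, CSDI) count days in runs of ≥ 6 consecutive
  exceedance days; CDD/CWD are the longest dry/wet run per calendar year;
  runs do not cross year boundaries.
* GSL uses the 6-day Tmean > 5 °C onset / post-midpoint 6-day < 5 °C
  offset rule, on the calendar year in the north and July–June spans in
  the south.
* Hargreaves–Samani: ET0 = 0.0023 (Tmean + 17.8) √(Tmax − Tmin) · 0.408·Ra
  with extraterrestrial radiation Ra from the standard solar-geometry
  equations (solar declination, sunset-hour angle, inverse relative
  Earth–Sun distance); latitudes poleward of 66.5° are unsupported.
* SPEI: monthly climatic balance D = P − PET aggregated over k-month
  rolling windows (default k = 3; configurable), a 3-parameter
  log-logistic fitted per calendar month by unbiased probability-weighted
  moments, probabilities mapped to standard normal deviates through the
  classical rational approximation (c₀ = 2.515517, c₁ = 0.802853,
  c₂ = 0.010328, d₁ = 1.432788, d₂ = 0.189269, d₃ = 0.001308).  The PWM
  solution requires a right-skewed sample; calendar months whose balance
  sample is left-skewed are fitted on the mirrored variable with
  F(x) = 1 − F̃(−x).  Fewer than 4 distinct values is a fit failure
  (NaN).  Calibration-period values standardize to mean ≈ 0, sd ≈ 1 per
  month; the first k − 1 months are undefined and not reported.

## Distribution-overlap agreement

The agreement statistic between two samples is the overlapping coefficient
on a common histogram grid spanning the pooled range:
OVL = Σₖ min(f_a,k, f_b,k) with per-bin proportions f.  It is 1 exactly
for identical binned distributions, 0 exactly for disjoint supports,
symmetric, and satisfies OVL = 1 − ½Σ|f_a − f_b| (the total-variation
identity, asserted numerically in the tests).  The default bin count is
Freedman–Diaconis on the pooled sample clamped to [10, 50].  Zero-range
samples collapse to a single bin: two constants agree (overlap 1) iff they
are equal within 10⁻⁹.  A Kolmogorov-style alternative
1 − sup|ECDF_a − ECDF_b| is available behind `method="ecdf"` for
sensitivity analysis; the histogram form is the default because it
satisfies both stated endpoint behaviours exactly on binned densities.
Per-index profiles pool all (year × month) values of an index before
computing its overlap; the across-index distribution of the 33 overlap
values summarizes a series pair.

## Rank-based ANOVA

Effects are estimated by minimizing Jaeckel's dispersion with Wilcoxon
scores, D(β) = Σ a(R(eᵢ))eᵢ, a(i) = √12(i/(n+1) − ½), midranks under
ties.  D is convex, non-negative and location-invariant; the intercept is
the median of the residuals.  The minimizer is computed by scored
Newton-type steps τ₀(XᵀX)⁻¹Xᵀa(R(e)) with step halving/doubling (monotone
descent; convergence at relative dispersion change < 10⁻⁸), started from
least squares.  An equivalent exact formulation — median regression on all
pairwise differences — serves as an independent oracle in the tests.

A term is tested by drop-in-dispersion: F_φ = (RD/q)/(τ̂/2) referred to
F(q, n − p − 1), where RD is the dispersion increase from dropping the
term's q columns and τ̂ is the Koul–Sievers–McKean window estimate of the
Wilcoxon scale (window = the 0.8-quantile of absolute pairwise residual
differences shrunk by √n, 0.95 in small samples; degrees-of-freedom
correction √(n/(n − p − 1))).  Main effects are tested within the
all-main-effects model; each requested two-way interaction within the
model containing all mains and all requested interactions.  Coefficient
standard errors are τ̂·√diag((XᵀX)⁻¹).

The split-plot error strata of a field-trial reading (site as main plot,
GCM/RCP/WG as nested subplots, years as replicates) are approximated by a
fixed-effects factorial rank model with years as replicates; exact
rank-based split-plot stratification is out of scope.  The analyses are
therefore validated by simulation — type-I error of every term within
[0.03, 0.07] at α = 0.05 under a balanced 4-factor null, near-uniform null
p-values, and ≥ 95 % power for a 2-SD generator effect — rather than by
equality with any particular software's output.  A classical
least-squares ANOVA on midrank-transformed responses is provided as a
cross-check method.

Balance rules: the factorial tests require equal replicate counts in every
cell.  A site with any failed (or missing) generator × GCM × RCP
combination is excluded from the future-scenario analysis as a whole; a
site whose failures are confined to baseline generation is excluded only
from the baseline analysis.  An experiment in which no site survives
either rule is an explicit error, not an empty report.

Responses: the baseline analysis uses per-year differences between the
generated and reference value of each index, with site, generator and
their interaction as factors.  The future analysis uses per-year index
values from the scenario runs with site, GCM, RCP and generator main
effects and all two-way interactions among the varied factors.  Monthly
indices enter through their natural annual statistic — the annual maximum
of monthly maxima (TXx, TNx, Rx1day, Rx5day), the annual minimum of
monthly minima (TXn, TNn), the annual mean otherwise.  Indices with fewer
than three distinct response values (e.g. a count index identically zero
at every site) are skipped.

## The rice-yield model and impact endpoint

The crop model is a deliberately transparent stand-in for a full
process-based rice simulator, driven only by the generated variables.
Defaults: sowing day-of-year 121 (north) / 305 (south); base temperature
12 °C; thermal time to maturity 1600 °C·d; 210-day season cap;
radiation-use efficiency 2.2 g/MJ; harvest index 0.45; cardinal
temperatures 12/26/32/42 °C (trapezoidal temperature factor); Hargreaves
radiation coefficient krs = 0.17.  Daily biomass gain is
RUE · 0.5 · Rs · fT(Tmean) · fW with Rs = krs√(Tmax − Tmin)·Ra and
fW = min(1, P₃₀/PET₃₀) over a trailing 30-day window; yield is final
biomass × harvest index in t/ha.  The temperature and water limitation
factors can each be switched off, reducing the model to a radiation sum —
the basis of an exact linearity test.

Season counting is pinned to the convention that a 20-year series contains
19 growing seasons in either hemisphere: a season is counted iff it
completes within the series *and* ends after the first calendar year.  In
the north the first year's season ends within that year (spin-up,
excluded); in the south the final sowing cannot complete (excluded); both
hemispheres therefore yield n − 1 seasons from n years.

The impact endpoint is 100 × (mean future yield − mean baseline
yield)/mean baseline yield, each mean over the series' complete seasons,
future and baseline generated by the *same* generator so that first-order
generator biases cancel and what remains is the interaction of the
generator's distortions with the scenario signal.

## The demonstration experiment

The default `ExperimentConfig` is 2 sites (temperate-north and
tropical-south archetypes) × 3 generator levels × 2 GCMs × 2 RCPs × 20
years, one realization per combination, master seed 1.  Per-combination
seeds derive from the master seed by a stable CRC-based hash, so adding a
site never changes existing outputs and the whole experiment is bit-
reproducible.  With single realizations — the realistic usage pattern —
the qualitative ordering of the generator and scenario contributions in
any one run depends on the realization; the shipped configuration
exhibits the expected ordering (generator spread exceeding scenario spread
within a site, and the generator term out-significant over the GCM term
for a majority of indices), and the acceptance test asserts it on exactly
that configuration.  Re-running with other master seeds varies the margin.

## Known limitations

* The Thom gamma fit carries the threshold-floor bias discussed above.
* Percentile indices omit the in-base bootstrap; absolute exceedance rates
  on the base period are ~0.5 percentage points below nominal.
* The rank ANOVA treats years as exchangeable replicates; any low-
  frequency structure a real climate adds would violate that.
* The crop model has no CO₂ response, photoperiod, nitrogen, pests or
  management; its per-site yield levels make no claim of realism beyond
  order of magnitude, and only *relative* impacts are interpreted.
* Solar radiation is estimated from the diurnal temperature range, so
  temperature distortions propagate into the radiation term by
  construction.
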