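# Methods

## The experiment this package models

A greenhouse factorial experiment on maize: three commercial hybrids
(DKB177, SX7341, P3707VYH) × seed inoculation with a 17-isolate synthetic
bacterial community (SynCom) × two irrigation regimes — well-watered (WW)
and drought-stressed (DS, reduced irrigation from DAS 50 to 80 with full
rehydration at DAS 80; DAS = days after sowing, harvest at 117 DAS).
Each treatment cell carries four sensor-instrumented plants (leaf
temperature, heat-dissipation sap flow, capacitive soil-water content,
every 5 min) plus ten plants harvested for yield; four environment
stations log air temperature, relative humidity and illuminance every
15 min. Root microbiomes are profiled as an OTU × sample count table in
which 23 OTUs map to the 17 SynCom isolates.

## Environment processing

- PAR = 0.0185 × lux (fixed greenhouse conversion factor).
- VPD from the Arden–Buck saturation vapor pressure,
  `VPD = (1 − RH/100)·0.61121·exp(17.502·T/(240.97+T))` kPa. VPD is zero
  exactly at saturation and monotone (increasing in T, decreasing in RH).
- Binning: timestamps map to half-open `[start, start+width)` windows
  aligned to midnight; width (default 30 min) must divide 24 h. Within a
  bin, raw points of all stations are pooled, Tukey-IQR filtered, and the
  retained mean is reported with retained/removed counts.
- Tukey fences: k = 1.5 with linear-interpolation quartiles. These are the
  conventional choices; both are parameters so a sensitivity analysis is a
  one-line change. Outliers are removed *within* each bin across pooled
  station points, before averaging — removing after averaging would let a
  single failed sensor shift a bin mean.
- Bins whose points are all missing or all removed propagate as missing
  values (never zeros); no imputation is done.

## Leaf-temperature contrast and the signed significant area

Per 30-min bin, each plant contributes the mean of its raw 5-min points;
the Tukey-IQR filter then runs *across the replicates* of each treatment
cell so a failed probe cannot contaminate a cell mean. ΔT_leaf =
mean(inoculated) − mean(uninoculated), tested per bin at α = 0.05. Bins
with fewer than two retained replicates in either arm are untestable:
missing p, never significant, but still counted in the temporal bin total
so the denominator of "significant bins out of N" stays purely temporal.

The per-bin test defaults to the **pooled two-sample Student t**. With
four replicates per arm an exact rank test is too coarse (its smallest
two-sided p is 0.0286), and the Welch test's Satterthwaite degrees of
freedom make it measurably conservative at n = 4 + 4 (its true size under
an equal-variance Gaussian null is ≈ 0.041); the pooled t has exact size
under that null, which is also what the replicate-noise model of the
generator produces. Welch (`test="welch"`) and Mann–Whitney
(`test="mannwhitney"`) remain available, and no claim is made that the
pooled t is robust to strong variance heterogeneity between arms.

The **signed significant area** integrates |ΔT_leaf| over significant bins
only, split by sign, by rectangles: 1 aau = 1 °C × one 30-min bin, other
widths scale proportionally; no contiguity of bins is required. The
statistic is additive under any split of the series at a bin boundary and
scales linearly with the temperature scale (p-values of the t test are
scale-invariant). No multiple-testing correction is applied across bins by
default — each bin is reported marginally — with a Benjamini–Hochberg
option (`bh=True`) for sensitivity analysis.

## Sap flow and SWC

The daily-window comparison takes, per plant and day, the mean of all raw
points in [10:00, 16:00) — the maximal-transpiration hours, 72 points per
plant per day at 5-min cadence — and compares arms per day with the same
test engine, reporting the smallest passed threshold of {0.05, 0.01,
0.001} as stars. Analysis runs on the logged flow signal by default; the
Granier heat-dissipation conversion (`flux = α·K^β`, K = (ΔT_max − ΔT)/ΔT,
α = 119·10⁻⁶ m³ m⁻² s⁻¹, β = 1.231 — the classic calibration constants)
is provided but off by default, since probe calibrations are
installation-specific. The SWC contrast (DS − WW per hybrid) reuses the
per-bin contrast machinery unchanged.

## Agronomy

HI = 100·grain/biomass (%), invariant under joint rescaling. Yield
components are analysed per plant with a full-factorial three-way OLS
ANOVA (hybrid × regime × inoculation; 7 effect terms + residual).
**Type-II sums of squares** are used: identical to the classical balanced
table, robust to the mild imbalance left by removed plants, and additive
with the residual to the total SS when balanced. Shapiro–Wilk (on
residuals) and Levene (across cells) p-values are attached as diagnostics,
not gates. Tukey HSD compact-letter groups are computed only for terms
significant at α (skippable with `posthoc=False` in simulation studies).

Phenology: unpaired t-tests per hybrid between inoculation arms on
emergence, anthesis and silking DAS; ASI = silking − anthesis per plant
where both exist. Plants lacking either date are *flowerless*: excluded
from ASI, counted in the flowering proportion. The flowering rule is
implemented as "flag an inoculation effect when the flowering proportion
differs between arms by more than 10 percentage points"; the threshold is
a configurable, explicitly documented stand-in because the underlying
field rule is stated ambiguously in the literature this design follows.

## Microbiome

Tests run on relative abundances. The two-group Kruskal–Wallis statistic
uses average ranks and the standard tie correction; p-values come from the
χ² (df = 1) approximation or, by default whenever the pooled n ≤ 10, from
**exact enumeration of all C(n, n₁) labelings** of the pooled ranks. At
4 + 4 replicates the exact test's attainable levels are discrete (smallest
two-sided p = 2/70 ≈ 0.0286), so any procedure thresholded at 0.05
actually operates below its nominal level; rates observed in calibration
runs should be compared against the discrete null, not against α itself.

*Robust colonizer*: a SynCom OTU with p < α **and** higher median relative
abundance in inoculated samples, judged per (hybrid × regime) with a
per-regime rollup ("robust in ≥ 1 hybrid"). The direction requirement is
essential — significance alone would also flag taxa displaced by the
inoculum. *Enriched/depleted/unchanged* partitions the resident
(non-SynCom) OTUs the same way (hybrids pooled per regime by default; both
pooling modes are exposed because either is defensible); per-regime sets
are reported together with their union and intersection. No
multiple-testing correction by default, matching the per-OTU P < 0.05
convention of this analysis family; BH optional. Note that a strong
spike-in *mechanically* depletes every resident OTU's relative abundance
(compositional closure); the enrichment/depletion calls describe relative,
not absolute, abundance shifts.

Bray–Curtis `d = 1 − 2·Σmin/(Σu+Σv)` (undefined for two all-zero
samples); PCoA by eigendecomposition of the double-centered squared
distance matrix, axes scaled by √eigenvalue, **negative eigenvalues
reported** rather than dropped, proportions explained relative to the
positive spectrum. ANOSIM uses Clarke's statistic
R = (r̄_between − r̄_within)/(M/2), M = n(n−1)/2, average ranks for ties —
the form under which R = 1 when every between-group distance exceeds every
within-group distance — with p = (1 + #{R_perm ≥ R_obs})/(1 + n_perm)
under seeded label permutations, or exact enumeration of all distinct
labelings for small n.

## The synthetic-data generator

What it emulates, and the defaults (all overridable per run):

- **Environment**: air T = 25 ± 8 °C sinusoid peaking at 14:00, RH
  65 ± 20% in anti-phase, illuminance a half-sine daylight curve (dawn
  06:00, 12 h photoperiod — site photoperiod is irrelevant to the
  statistics) peaking at 21,650 lux (≈ 400 μmol m⁻² s⁻¹ PAR), plus AR(1)
  noise (ρ = 0.6; stationary sd 0.8 °C / 3% / 500 lux) independent per
  station. RH is clamped to [0, 100] and night illuminance is exactly 0.
- **Plants**: T_leaf = air T + cell offset + 0.8 °C kPa⁻¹ × VPD + N(0,
  0.3²); the inoculation offset defaults to −1.5 °C (inoculated cooler).
  Sap flow = gain × VPD × soil-water availability with arm gains 2.5 vs
  1.1 g H₂O h⁻¹ kPa⁻¹, chosen to reproduce a ≈ 2.3× midday arm ratio
  (≈ 5 vs 2.2 g H₂O h⁻¹). SWC holds a 500-unit set point under WW; under
  DS a fractional deficit grows through the drought window at 0.08/day
  scaled by normalized VPD (evapotranspirative loss ∝ VPD — a
  qualitative stand-in, not a soil-hydrology model) and relaxes at 0.5/day
  after rehydration.
- **OTU counts**: per-sample compositions Dirichlet(c·m) with c = 2000
  around a ranked-lognormal resident baseline plus a flat SynCom
  background of 5·10⁻⁴ per OTU (seed/soil carry-over); counts are
  multinomial at library size 50,000. Inoculated samples multiply SynCom
  proportions by 10 (inoculated-arm aggregate ≈ 9–12% of reads) and shift
  20 mid-rank resident OTUs, half ×5 and half ÷5 — the balanced shift
  keeps the renormalisation near unity (so the injected fold change
  survives closure) and exercises both enrichment and depletion calls.
- **Yield**: cell mean + N(0, 8²) g. DS means encode the
  genotype-specific rescue (DKB177 38.7 vs 9.8 g, P3707VYH 42.7 vs
  12.4 g inoculated/uninoculated, SX7341 flat at 25 g); WW cells are a
  flat 70 g in both arms. Biomass (WW 200 g, DS 150 g, sd 20) is floored
  just above grain so HI is always computable. Drought delays anthesis
  and silking by 9 days (sd 1.5).

All generators are bit-reproducible given (design, params, seed);
`simulate_experiment` derives independent sub-seeds for the four streams
from one master seed.

**What passing tests do and do not show.** The generator produces Gaussian
sensor noise, stationary diurnal cycles, no missing intervals, no sensor
drift, no spatial greenhouse gradients, and treatment effects that are
constant in time. Tests passing on it validate the *machinery* — binning,
filtering, test calibration, area bookkeeping, count-model inference —
under known truth; they do not certify performance on real data with
heteroscedastic, autocorrelated or gappy sensors, nor do they reproduce
any particular field experiment's absolute numbers (e.g. aau totals or
community R statistics, which depend on the real effect sizes and the
17,000-OTU richness of real root profiles).

## Numerical choices and degenerate inputs

- Quartiles by linear interpolation; fences closed intervals
  (boundary points retained). Filtering a constant vector retains
  everything (IQR = 0).
- Constant pooled data in a rank test: (H, p) = (0, 1) by convention.
- Exact-test tail comparisons use a 1e-12 slack so ties at the observed
  statistic count into the tail (conservative).
- Per-bin tests with both arms constant and equal return missing p (0/0
  t-statistic) and are reported not significant.
- An empty significant set yields areas (0, 0); `pct_significant` of an
  empty series is 0.
- PCoA truncates to the positive spectrum with a warning when more axes
  are requested than exist.
- Problem sizes in the test suite: calibration suites use 100–200
  replicates of 960-bin series, 200-replicate ANOVA power runs at
  10 plants/cell, and 500-OTU null tables — large enough for the stated
  ±2 s.e. bands while keeping the default suite a few minutes on one CPU.

## Known limitations

- The per-bin contrast treats bins independently; temporal autocorrelation
  of sensor noise would inflate the effective number of significant bins
  (the no-correction default mirrors the marginal-bin convention of this
  analysis family).
- Type-II ANOVA is not recommended under severe imbalance or empty cells
  (the model refuses empty cells outright).
- The Granier conversion assumes the classic calibration constants unless
  probe-specific ones are supplied.
- Compositional effects couple OTU tests (see above); no log-ratio
  transformation is offered in this version.
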