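# Methods

## Data model

The unit of analysis is the sector–year cell of a surveillance panel.  A
cell carries a count of official inspections $n_{jt}$ and of irregularities
$x_{jt} \le n_{jt}$; its dispute rate is $y_{jt} = x_{jt}/n_{jt} \in [0,1]$,
stored at full precision (three-decimal printing in official reports is a
display concern; comparisons against published values use an absolute
tolerance of 0.001).  Missing cells are explicit (NaN) and excluded from
every statistic with a logged warning — official documentation of this kind
of record is not always complete, and silent imputation would be worse than
an honest gap.

The embedded ICQRF record consists of nine whole-period sector totals and
a complete 9 × 24 matrix of yearly dispute rates for 1997–2020.  Per-year
inspection counts are not published, so the yearly rates are stored as
authoritative input rather than derived.  One arithmetic blemish in the
source is preserved as printed: the published grand total of inspections
(444,007) is one fewer than the sum of its own nine sector rows (444,008);
the sector rows are what every computation uses.

## Two-period design and descriptives

`PeriodDesign(cutoff_year)` assigns years ≤ cutoff to period 1 and the
rest to period 2; both periods must be non-empty.  For the ICQRF record
the cutoff is 2004 — the year the EU food-hygiene package (EC 852–854/2004,
882/2004) entered into force — giving an 8 + 16 split.

Descriptive summaries report the sample mean, the $n-1$ standard
deviation (the usual small-sample reporting convention), the median
(midpoint-averaged for even lengths) and linear-interpolation quartiles.
Boxplot whiskers use the Tukey 1.5 × IQR fences; this is a display default,
chosen because no alternative convention is dictated by the data, and the
fence values are exported alongside so no information is locked into the
figure.

## The NPC permutation test

**Hypotheses.**  The global null is the intersection over sectors of
per-sector distributional equality between the periods; the alternative is
the union of per-sector inequalities.  This composite structure is exactly
what nonparametric combination (NPC) is built for: partial tests that are
marginally exact and a combination that preserves their dependence.

**Partial statistic.**  $T_j = |\bar y_j^{(1)} - \bar y_j^{(2)}|$, the
absolute difference of period means — the standard NPC partial test for a
location shift, two-sided by construction.  The signed difference is kept
alongside so reports can state the direction of a significant change.

**Permutation scheme.**  The exchangeable unit is the *year*: a permutation
reassigns year labels to the two periods once and applies that same
reassignment to every sector's series.  Permuting each sector independently
would destroy the cross-sector dependence of a given year's inspection
campaign and invalidate the combined test.  Years with a missing cell in
any sector are dropped from the joint test (complete-case over permutation
units); the per-sector `permutation_pvalue` drops only that sector's
missing years.

**Enumeration.**  When $\binom{n_1+n_2}{n_1} \le$ `max_exhaustive`
(default $10^6$) all splits are enumerated; p-values are then exact
rationals with known denominator and independent of any seed.  The
24-year design's 735,471 splits enumerate in a few seconds.  Larger spaces
use conditional Monte Carlo with $B$ = `n_monte_carlo` random splits and
the estimator $p = (1 + \#\{T^* \ge T\})/(1+B)$, which cannot return zero —
a requirement of the Fisher combination, where $\log 0$ would be fatal.
The default CMC seed (20040101) is recorded in all outputs.

**Combination.**  For each permutation $b$ and sector $j$ the partial
significance level is $L_{bj} = \#\{b' : T_{b'j} \ge T_{bj}\}/B$, computed
against the pooled permutation distribution.  Rows of $L$ are combined
with Fisher's $-2\sum_j \log L_{bj}$ (default; Liptak and Tippett
selectable) and the global p-value is the fraction of permutations whose
combined value is at least the observed one.  For Liptak the level 1.0
attained by each sector's minimum statistic is pulled just inside $(0,1)$
before $\Phi^{-1}$; this affects no ordering.  Partial p-values are
reported raw, matching the usual surveillance-report convention; a
Bonferroni flag exists but is off by default.

**Numerical ties.**  Complementary splits (and any splits tied in exact
arithmetic) must count as ties — "≥ observed" is the conservative
convention — but floating-point summation order can separate them by an
ulp.  Permutation statistics are therefore rounded at $10^{-12}$ (and
combined statistics at $10^{-10}$) before comparison.  On the rate scale
(values of order $10^{-1}$, differences of order $10^{-2}$) this is about
ten orders of magnitude below any genuine separation, and it makes the
vectorised enumeration agree exactly with a plain-loop enumeration.

## NPC ranking

Within each year, sectors are ranked by dispute rate (rank 1 = highest;
ties get average ranks; a sector missing in a year is ranked among those
present).  A per-period global ranking orders sectors by the combined
score $S_j = -2 \sum_t \log(1 - \lambda_{jt})$ — additive over years, so
combining year sets commutes with summation.

Two choices of the score $\lambda_{jt} \in (0,1)$ are offered:

- **`rate` (default):** the dispute rate itself.  Rates are already
  proportions, $-\log(1-\lambda)$ is strictly increasing in the rate, and
  the combined values can be max-normalised back onto the rate scale for
  bar-chart display.  On the ICQRF record this ordering coincides with the
  ordering by period mean rate in both periods — the concordance one
  expects when the combination is a monotone accumulation of the rates
  themselves.  A rate of exactly 1.0 is nudged one ulp inside the unit
  interval to keep the logarithm finite.
- **`midrank`:** $\lambda = (k - r + 0.5)/k$ from the within-year rank $r$
  among the $k$ sectors present.  Purely ordinal, hence invariant under
  any strictly increasing within-year transformation of the rates — the
  property to reach for when the rate scales of different years are not
  comparable.  The two transforms can disagree on adjacent positions when
  sectors are close in level but not in rank.

Exact ties in combined scores receive average global ranks and a tie flag;
no arbitrary ordering is ever invented.

## Trend index

`trend_index` summarises one sector's full series in a scalar:

- **`ols_slope_scaled` (default):** 100 × the OLS slope of rate on
  calendar year — percentage points of dispute rate per year.  Chosen as
  default because it uses every observed year, is zero exactly for
  constant series, negates exactly under time reversal, and scales
  linearly under rate rescaling.
- **`total_relative_change`:** $(y_{\text{last}} - y_{\text{first}})/y_{\text{first}}$;
  endpoint-only, undefined for a zero first value.
- **`mean_link_relative`:** mean of year-over-year ratios minus one;
  undefined when an interior value is zero.

At least three observed years are required.  Published trend values for
this kind of record are not reproducible — no formula accompanies them and
none of the candidate definitions matches their magnitudes under any
scaling tried — so the package commits to transparent definitions and
asserts only the qualitative structure they share with the published
values: on the ICQRF record, meat has the largest (positive) index and
sowing seeds the most negative.  The method name is recorded in every
result.

## Synthetic panels

The generator emulates the structure the analysis assumes: sector $j$ has
a period-1 dispute probability $\pi_j$ and an additive period-2 shift
$\delta_j$ (with $\pi_j, \pi_j + \delta_j \in [0,1]$); irregularity counts
are binomial draws given the cell's inspection count.  Binomial noise on
counts — not Gaussian noise on rates — reproduces the variance–mean
coupling of real panels, where low-rate sectors show visibly tighter
series.  Inspection counts per cell are fixed, or drawn mean-preservingly
lognormal around per-sector means (default multiplicative sigma 0.25, a
modelling convenience for unpublished per-year effort; real counts are not
lognormal-verified).  The `fixture_like_config` preset sets baselines to
each sector's pre-2004 mean rate, effects to the post-minus-pre
differences, and inspection means to the sector totals spread over the 24
years, so the synthetic world matches the real record's scale.

What the generator does *not* model — temporal autocorrelation, drift
within periods, inspection-targeting feedback — bounds what passing tests
show: calibration results demonstrate correctness of the test under
exchangeable years, not robustness to serial dependence in real data.

One root seed drives a replicate study; per-replicate generator and
test seeds derive from it through a counter-based spawn scheme, so any
single replicate can be reproduced in isolation.

`estimate_operating_characteristics` measures, over ≥ 100 replicates, the
global and per-sector rejection rates at α and the mean absolute error of
the naive effect estimate (difference of period mean rates) against the
configured effects.  The calibration checks in the test suite use 1000
null replicates at a reduced permutation budget ($B = 500$) — the point
where Monte-Carlo error on a 5% rejection rate (±3 s.e. ≈ ±2.1 points) is
small enough to be informative while the whole check runs in seconds — and
200 replicates for the power check against a meat-like shift (+0.13 on a
0.05 baseline at 1000 inspections per cell).

## Known limitations

- Rates are treated as exchangeable across years within a period; serial
  dependence would make the permutation test only approximately valid.
- The per-sector partial p-values are reported unadjusted for multiplicity,
  as is conventional for this kind of surveillance table; the global NPC
  test is the multiplicity-safe statement.
- The embedded record inherits two visibly truncated cells from its source
  (honey 2019 and eggs 2016 carry fewer printed decimals than the rest of
  the table); they are stored exactly as printed.
- The `rate` ranking transform is not invariant under within-year monotone
  transformations; use `midrank` when only the ordinal structure is
  trusted.
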