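# Methods

This note documents the statistical procedures implemented in
`shrubring`, the design choices that were genuinely open, the synthetic
data model, and what the test suite does and does not demonstrate.

## Data model

The atomic object is one dated ring-width series (µm, one value per
consecutive calendar year) carrying hierarchy labels
site / stock / shoot / radius. Radii are labelled `a`–`d` (`a` the
longest, typically the lower side of the arched stem); `ab`, `cd` and
`abcd` denote width-level means of the member radii. A missing ring —
a year in which the cambium produced no detectable ring — is encoded as
width 0; a physically absent year is a data error, not a gap. Averaging
radial combinations happens on widths (the combinations are growth-rate
summaries); dimensionless index averaging only ever happens after
detrending.

Tucson `.rwl` I/O uses the decadal layout with the `-9999` sentinel
(0.001 mm units; this matches the 1 µm measurement resolution) and
accepts `999`-terminated 0.01 mm data. Because 999 is a legal µm width,
only `-9999` terminates a series eagerly; a trailing 999 at end of input
is resolved as the 0.01 mm sentinel. Hierarchy is parsed from the
8-character ID (site chars 1–2, stock index char 3, shoot chars 4–5,
radius letter/tag from char 6) unless a metadata sidecar overrides it.

## Detrending

The conservative cascade removes the age/size trend:

1. modified negative exponential `w(τ) = a·e^(−bτ) + k`,
   `a, b > 0, k ≥ 0`, fitted by bounded nonlinear least squares
   (initialised at `a = w₀ − w_last` floored at 10⁻³, `b = 2/n`,
   `k = w_last`; tolerances 10⁻⁸, at most 200 function evaluations).
   The fit is rejected when its total decline is below 10⁻⁶ of the mean
   width — an effectively flat exponential carries no trend information;
2. otherwise an ordinary least-squares line, accepted only when its
   slope is ≤ 0 and it stays positive over the series;
3. otherwise a horizontal line at the series mean.

Indices are observed/fitted; the fitted curve is positive by
construction, so a zero width (missing ring) simply yields index 0 and
stays in the series. Series with fewer than five non-zero widths are
refused. A mean index outside [0.8, 1.2] is logged as a possible
structural break, not raised. Detrending is scale-equivariant: indices
do not change under multiplication of the widths by a constant, so
constant shoot-vigour or radius-asymmetry factors drop out.

Baillie–Pilcher standardization maps widths to
`ln(100·w_t / MA5_t)` with a centred 5-year moving average; the first
and last two years are dropped so every retained value is built from a
complete window (no window shrinking at the edges). Zero widths are
floored at 1 µm before the ratio, since the alternative — dropping the
year — would misalign the two series being compared.

The low-pass trend filter zeroes all discrete Fourier coefficients with
period strictly below the cutoff (default 3 yr) and returns the real
part of the inverse transform, without tapering or padding; the DC
component is untouched, so the output mean equals the input mean
exactly. The filter is linear and idempotent.

## Synchrony statistics

*Gleichläufigkeit.* Over the `m = n − 1` intervals of the shared years,
an agreement of the two signs scores 1, a tie (either difference exactly
0) scores ½, a disagreement 0; Glk is 100 × the mean score. Ties are
rare in µm data but do occur; the ½ convention keeps Glk symmetric in
the two series. Significance uses a normal null centred at 50 % with the
exact variance for 1-dependent indicators,
`Var(Glk)/100² = m/4 + (m−1)/18` divided by `m²`: consecutive
year-to-year differences share a term, which makes adjacent agreement
indicators positively correlated (lag-1 indicator covariance 1/36,
zero beyond lag 1). The naive `50/√m` standard deviation ignores this
and roughly doubles the type-I error (≈ 9 % instead of 5 % at n = 30 in
a 20 000-pair simulation); with the corrected variance the empirical
size is ≈ 4.5 %. The same variance generates the per-overlap
significance guide lines (`glk_threshold`).

*t-statistic.* `t = r·√(N−2)/√(1−r²)`, increasing in `r` and (for
`r > 0`) in `N`. `|r| = 1` is reported as a signed infinity flag rather
than an exception, and infinite values are excluded (with a count) from
all group means. `t_BP` applies this to the Pearson correlation of the
BP-standardized series on their shared retained years; 3.5 is used as
the conventional secure-dating floor. The sign of `r` is kept — a
negative `t_BP` is informative about misdating.

*Dating screen.* Each series is correlated, after BP standardization,
against the mean of all other series at lags −2…+2 (leave-one-out). A
series is flagged when its best lag is non-zero or the lag-0 correlation
falls below 0.32 (a COFECHA-style floor, exposed as a parameter). The
lag convention: `r(L)` compares the series in year `t` with the
reference in year `t + L`, so a series dated one year too late peaks at
`L = −1`. This is a whole-series screen, deliberately simpler than
segment-wise dating control; it is meant to catch gross shifts and
missing rings, not to replace visual cross-dating.

## Chronology statistics

MS and AC are computed per series and averaged over the group; for the
homogeneity table they are computed on detrended indices (both are also
callable on raw widths). Adjacent pairs summing to zero (two missing
rings in a row) are skipped with a logged count; `[a, 0]` attains the
theoretical MS maximum of 200 %.

Rbar is the arithmetic mean of all pairwise Pearson correlations, each
on the pair's maximal shared years by default; a fixed common interval
can be imposed. EV uses the correlation matrix (not covariance — index
series are dimensionless with unequal variances) over a fixed interval
that every series must cover, because the eigendecomposition needs a
complete matrix; EV = 100 × (largest eigenvalue)/N. S/N and EPS derive
from (N, Rbar); the identity `EPS = SNR/(1+SNR)` holds exactly by
construction. `recommend_n` inverts it:
`N_min = ⌈ eps·(1−r) / (r·(1−eps)) ⌉`, with a search-step guard against
floating-point edge cases; it is non-increasing in `r` and
non-decreasing in the target.

Chronologies are plain unweighted means per calendar year (no biweight
robust mean, no variance stabilization by sample depth), with median,
quartiles and 5/95 percentiles as spread bands and the sample depth per
year.

## The three-level pipeline

*Radii within shoot*: for every shoot with all four radii, synchrony of
`a:b`, `c:d`, `a:cd`, `b:cd`, `ab:cd` (the combinations built on the
fly), summarized per comparison label as box-plot statistics over
shoots. *Shoots within stock*: for each label in
`a, b, c, d, ab, cd, abcd`, the full pairwise matrix over shoots, with a
"secure" mark where the mean t_BP reaches 3.5. *Stocks*: per label, each
stock's mean chronology over its shoots, then all stock pairs, with Glk
significance stars. All reports are invariant to input order (series are
iterated in sorted ID order throughout).

Group differences (e.g. mean ring width per stock) use Student's
pooled-variance two-sample t-test; zero pooled variance degenerates to
`p = 1` (equal means) or an infinity-flagged t (unequal). Compact
significance letters are the maximal cliques of the "not significantly
different" graph (brute-force clique enumeration; group counts are
tiny), so groups share a letter iff no pairwise difference at the chosen
α (default 0.01). No family-wise correction is applied by default,
matching common reporting practice in this literature; the per-test α is
configurable.

The extreme-year test is paired across shoots (each shoot measured in
both the candidate year and its predecessor) — the natural pairing since
shoot identity is a strong blocking factor — with an unpaired option; a
second, two-sample test compares the candidate year against all other
years pooled. Candidate years are either supplied or auto-detected as
the largest relative rise and drop of the pooled mean chronology over
well-replicated years. One caveat documented deliberately: on raw widths
the paired year-over-year test also responds to the deterministic aging
decline of the growth curve (≈ 2.5 %/yr under the default synthetic
regime), so its size calibration is performed on trend-free stands; in
practice extreme-year pulses are an order of magnitude larger than one
year of age trend.

Long-term trends are the low-pass filtered per-stock mean `abcd`
chronologies; the final 5-year segment is classified
increasing/constant/decreasing by the sign of its least-squares slope
with a dead band of 1 % of the series mean per year (a pure sign test
would flip on numerically tiny slopes).

## Synthetic stand generator

Widths are generated as

```
W = (a·e^(−bτ) + k) · e^(c_t) · site_s · shoot_sh · radius_r · dist_{s,t} · e^(ε)
```

with `c_t ~ N(0, σ_climate)` shared stand-wide (one growing season is
one climate draw), lognormal shoot vigour and residual radius-year
noise, per-stock multiplicative disturbance pulses (probability per
stock-year, depth, duration — emulating avalanche/snow-load damage
shared by all shoots of a stock), rounding to 1 µm, and zeros below the
missing-ring threshold. The error structure is multiplicative because
ring widths are positive and the downstream statistics are relative.
Shoot ages are drawn uniformly in the configured range and all series
end at the final year (one sampling campaign). The draw order (climate,
then per stock: disturbances, then per shoot: age and vigour, then per
radius: noise) is a documented contract so that a seed pins the output
across refactors; identical parameters give bit-identical collections.

Defaults (the frozen `default_scenario` regime): 3 stocks of
15/16/16 shoots, four radii, years 1986–2021, ages 19–35, growth curve
(500 µm, 0.07 /yr, 310 µm), σ_climate = 0.30, site multipliers
0.82/1.00/1.09 (giving per-stock mean widths ≈ 460/580/620 µm, the
wind-exposed stock poorest), σ_shoot = 0.15, radius multipliers
a 1.3 / b 0.8 / c 0.95 / d 0.95 (radius-a dominance), disturbance
(0.02, 0.5, 2 yr), σ_noise = 0.20 (scalar, or per-radius to emulate a
less noisy fast radius), missing-ring threshold 30 µm. These values
were chosen once to land in the intended regimes — mean widths within
450–650 µm, detrended mean sensitivity ≈ 35–50 %, low lag-1
autocorrelation, EPS of 15 four-radius shoot means well above 0.85 —
and are not tuned per test.

Because constant factors drop out of detrended indices, the analytic
inter-series correlation of two same-stock single-radius series on the
log scale is shared variance over total:
`(σ_c² + duration·p(1−p)·ln(depth)²) / (σ_c² + duration·p(1−p)·ln(depth)² + σ_e²)`
(a year is covered by ≈ Binomial(duration, p) active pulses). This
closed form is the oracle against which the measured Rbar is checked
(±0.1 over 50 replicate stands).

What the generator does **not** emulate: wedging and false rings,
within-series measurement error and its autocorrelation, climate signal
autocorrelation (year effects are white), pith-offset geometry and
eccentricity as a spatial process, shoot mortality, and any real climate
response function. Passing tests therefore demonstrate that the
statistical machinery recovers a known multiplicative
signal/noise/disturbance structure at realistic sizes — not that it
handles every pathology of real shrub material.

## Problem sizes and numerical choices in the test suite

Monte-Carlo checks use: 1000 random pairs for the exact Glk/brute-force
comparison and 2000 pairs for its null calibration; 400 pairs for the
t_BP null; 50 replicate stands for parameter recovery (Rbar/EPS/MS);
200 replicates each for extreme-year power (×1.6 pulse, p ≤ 0.001,
power > 0.95) and size (trend-free null stands, rejection ≤ 0.07 at
α = 0.05). All simulations are seeded; the full suite runs in about a
minute on one core. Scalar identities (EPS↔SNR, the t equation) are
asserted to 10⁻⁹ or against an independent oracle (exact-correlation
construction + the t implied by scipy's correlation p-value).

## Known limitations

- The dating screen is whole-series; short misdated segments inside an
  otherwise well-dated series can escape it.
- EV requires a complete common interval; groups with disjoint coverage
  get EV = NaN (flagged) while Rbar/EPS still use pairwise overlaps.
- The negative-exponential fit is a local optimiser; with the documented
  initialisation it is reliable on decreasing series, and any failure
  falls through the conservative cascade rather than erroring.
- Glk significance assumes continuous data; heavy tie loads (coarse
  rounding) make the test conservative.
- Raw-width year-over-year tests absorb the age trend (see above);
  detrend first when that matters.
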