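# shrubring

Hierarchical ring-width variability analysis for multi-stemmed shrubs.

Tall clonal shrubs such as green alder (*Alnus alnobetula*) at the alpine
treeline grow many arched stems (**shoots**) from one rootstock
(**stock**), and each stem disc is measured along several **radii**
(`a` = longest, usually the lower stem side; `b` opposite; `c`, `d`
orthogonal) because bending and snow load make radial growth strongly
asymmetric. Before such data can answer ecological questions — how much
does climate synchronize growth, how many radii/shoots/individuals must
be sampled — the agreement of ring-width series has to be quantified at
three nested levels: radii within a shoot, shoots within a stock, and
stocks against each other. `shrubring` implements that entire analysis
as a library plus a small CLI, together with a seeded synthetic stand
generator so every stage can be exercised without field data.

## What it computes

**Cross-dating synchrony** of two series over their `N` shared years:

- *Gleichläufigkeit* `Glk` — percentage of year-to-year changes agreeing
  in sign (ties score ½), with a one-sided significance test against a
  serial-dependence-aware normal null centred at 50 %;
- the overlap-adjusted t-statistic of a correlation `r`:
  `t = r·√(N−2) / √(1−r²)`;
- the Baillie–Pilcher score `t_BP`: the same t applied to the Pearson
  correlation of the two log-standardized series
  (`ln(100·w_t / MA5_t)`, a centred 5-year moving-average ratio);
  `t_BP ≥ 3.5` is the conventional floor for a secure cross-date.

**Chronology homogeneity** of a detrended group of `N` series:

- mean sensitivity `MS = 100 · mean( 2|x_t − x_{t−1}| / (x_t + x_{t−1}) )`,
- first-order autocorrelation `AC`,
- mean inter-series correlation `Rbar` (per-pair maximal overlap),
- signal-to-noise ratio `S/N = N·r̄ / (1−r̄)`,
- expressed population signal `EPS = S/N / (1 + S/N)` (0.85 = usual
  quality threshold),
- `EV` — percent variance of the first principal component of the
  inter-series correlation matrix.

Detrending uses the conservative cascade (modified negative exponential
`a·e^(−bτ) + k`, else a non-positive-slope line, else the horizontal
mean), indices = observed/fitted. Long-term trends come from an FFT
low-pass filter (periods below 3 yr removed, mean preserved exactly).
`recommend_n(rbar, eps_target)` inverts the EPS formula into a minimal
sample size.

## Worked example

```python
import shrubring as sr

params = sr.default_scenario(seed=1)   # 3 stocks x 15-16 shoots x 4 radii
stand  = sr.generate_stand(params)

group = list(stand.select(stock="WE1", radius="a"))   # 15 series
st = sr.group_stats(group)                             # detrends, then scores
print(f"ms {st.ms_percent:.1f}  ac {st.ac1:.2f}  rbar {st.rbar:.3f} "
      f"eps {st.eps:.3f}  ev {st.ev_percent:.1f}")
print(sr.recommend_n(0.657), sr.recommend_n(0.324))
```

prints

```
ms 41.2  ac 0.03  rbar 0.757 eps 0.979  ev 80.3
3 12
```

Read: the radius-a series of the wind-exposed stock are highly sensitive
(mean sensitivity ≈ 41 %, i.e. adjacent rings differ by 41 % on
average), carry almost no growth memory (lag-1 autocorrelation 0.03),
and share a strong common signal (mean inter-series correlation 0.757,
EPS 0.979 ≫ 0.85, 80 % of variance on the first component) — 15 shoots
are far more than needed for a representative chronology. The last line
is the sampling-design answer: with a coherence of 0.657 three series
already reach EPS 0.85, while at 0.324 twelve are required.

The same analysis from a shell:

```sh
shrubring simulate --seed 1 --out stand
shrubring validate stand/stand.rwl --meta stand/metadata.tsv
shrubring stats    stand/stand.rwl --meta stand/metadata.tsv
shrubring pipeline stand/stand.rwl --meta stand/metadata.tsv --out report
```

`report/` then holds the stock summary (shoot counts, ages, mean widths
with significance letters), the homogeneity table, stock-pair synchrony
with Glk significance stars, per-stock radius- and shoot-level synchrony
distributions, extreme-year tests (paired against the preceding year)
and the low-pass trend classification. Real measurements in Tucson
`.rwl` or wide delimited tables are read the same way; an optional
metadata sidecar (`series_id, site, stock, shoot, radius`) overrides the
ID-embedded hierarchy.

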