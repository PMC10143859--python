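"""Chronology homogeneity statistics and sample-size recommendation.

For a group of (detrended) ring-width series this module computes the
classic dendrochronological summary statistics:

* **MS** — mean sensitivity, the mean relative change between adjacent
  rings, ``100 · mean(2|x_t − x_{t−1}| / (x_t + x_{t−1}))``, bounded in
  [0, 200] %;
* **AC** — first-order autocorrelation;
* **Rbar** — mean pairwise inter-series Pearson correlation, each pair
  evaluated on its maximal shared years (or a fixed common interval);
* **S/N** — signal-to-noise ratio ``N·r/(1−r)``;
* **EPS** — expressed population signal ``SNR/(1+SNR)``, the degree to
  which the sample chronology reflects the hypothetically perfect
  (infinitely replicated) chronology; 0.85 is the conventional floor;
* **EV** — percentage of variance carried by the first principal
  component of the inter-series correlation matrix.

It also builds mean chronologies with spread bands and inverts the EPS
formula into a minimal-replication recommendation.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd

from .detrend import fit_conservative
from .errors import IntervalError, LengthError, OverlapError
from .series import CommonInterval, RingWidthSeries, overlap

logger = logging.getLogger(__name__)

#: conventional EPS quality threshold
EPS_THRESHOLD = 0.85


def _values(series) -> np.ndarray:
    if isinstance(series, RingWidthSeries):
        return np.asarray(series.widths, dtype=float)
    return np.asarray(series, dtype=float)


def mean_sensitivity(series) -> float:
    """Mean sensitivity in percent; adjacent pairs summing to 0 are skipped."""
    x = _values(series)
    if x.size < 2:
        raise LengthError("mean sensitivity needs at least 2 values")
    s = x[1:] + x[:-1]
    d = np.abs(x[1:] - x[:-1])
    keep = s > 0
    n_skipped = int(np.count_nonzero(~keep))
    if n_skipped:
        logger.info("mean_sensitivity: skipped %d zero-sum pairs", n_skipped)
    if not keep.any():
        raise LengthError("all adjacent pairs are zero")
    return 100.0 * float(np.mean(2.0 * d[keep] / s[keep]))


def ac1(series) -> float:
    """Lag-1 autocorrelation (Pearson of the series against itself shifted).

    Returns NaN when either lagged slice has zero variance (undefined).
    """
    x = _values(series)
    if x.size < 3:
        raise LengthError("lag-1 autocorrelation needs at least 3 values")
    a, b = x[:-1], x[1:]
    if np.std(a) == 0 or np.std(b) == 0:
        return math.nan
    return float(np.corrcoef(a, b)[0, 1])


def rbar(
    group: list[RingWidthSeries], interval: CommonInterval | None = None
) -> float:
    """Mean pairwise Pearson correlation over a group.

    Each pair is evaluated on its maximal shared years, or on ``interval``
    when given (every series must then cover it).  Pairs with overlap < 3
    or zero variance are skipped with a log message.
    """
    if len(group) < 2:
        raise ValueError("rbar needs at least 2 series")
    rs: list[float] = []
    for i in range(len(group)):
        for j in range(i + 1, len(group)):
            x, y = group[i], group[j]
            if interval is not None:
                x = x.crop(interval.start_year, interval.end_year)
                y = y.crop(interval.start_year, interval.end_year)
            _, xv, yv = overlap(x, y)
            if xv.size < 3:
                logger.info(
                    "rbar: pair (%s, %s) overlap %d < 3, skipped",
                    x.series_id, y.series_id, xv.size,
                )
                continue
            if np.std(xv) == 0 or np.std(yv) == 0:
                logger.info(
                    "rbar: pair (%s, %s) has zero variance, skipped",
                    x.series_id, y.series_id,
                )
                continue
            rs.append(float(np.corrcoef(xv, yv)[0, 1]))
    if not rs:
        raise OverlapError("no valid pairs for rbar")
    return float(np.mean(rs))


def snr(n: int, r: float) -> float:
    """Signal-to-noise ratio ``N·r/(1−r)`` of N series with mean correlation r.

    ``r = 1`` returns infinity; a negative r passes through (with a
    warning) as a negative ratio.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if r >= 1.0:
        return math.inf
    if r < 0:
        logger.warning("snr: negative mean correlation %.3f", r)
    return n * r / (1.0 - r)


def eps_from_snr(s: float) -> float:
    """Expressed population signal from a signal-to-noise ratio: SNR/(1+SNR)."""
    if math.isinf(s):
        return 1.0
    return s / (1.0 + s)


def eps(n: int, r: float) -> float:
    """EPS of N series with mean inter-series correlation r."""
    return eps_from_snr(snr(n, r))


def ev_first(group: list[RingWidthSeries], interval: CommonInterval) -> float:
    """Percent variance of the first PC of the inter-series correlation matrix.

    Computed over a fixed interval that every series must cover (PCA
    needs a complete matrix); the correlation (not covariance) matrix is
    used because index series are dimensionless with differing variances.
    """
    if interval.n_years < 3:
        raise IntervalError("EV interval must span at least 3 years")
    if len(group) < 2:
        raise ValueError("EV needs at least 2 series")
    data = np.vstack(
        [s.crop(interval.start_year, interval.end_year).widths for s in group]
    )
    corr = np.corrcoef(data)
    corr = np.nan_to_num(corr, nan=0.0)  # zero-variance series contribute nothing
    np.fill_diagonal(corr, 1.0)
    eig = np.linalg.eigvalsh(corr)
    return 100.0 * float(eig[-1]) / len(group)


@dataclasses.dataclass(frozen=True)
class Chronology:
    """Per-year summary of a group of series.

    ``table`` columns: mean, median, q25, q75, p5, p95, depth — the
    box-plot convention used throughout (mean + median + quartile box +
    5/95 percentile whiskers).
    """

    table: pd.DataFrame

    @property
    def years(self) -> np.ndarray:
        return self.table.index.to_numpy()

    @property
    def mean(self) -> pd.Series:
        return self.table["mean"]

    def mean_series(
        self, template: RingWidthSeries, radius_label: str = "mean"
    ) -> RingWidthSeries:
        """Mean chronology repackaged as a series (for pairwise synchrony)."""
        return template.with_values(
            self.table["mean"].to_numpy(),
            series_id=f"{template.stock}.{radius_label}",
            radius_label=radius_label,
            first_year=int(self.table.index[0]),
        )


def build_chronology(group: list[RingWidthSeries]) -> Chronology:
    """Per-calendar-year mean/median/quartiles/percentiles and sample depth."""
    if not group:
        raise ValueError("cannot build a chronology from an empty group")
    wide = pd.DataFrame(
        {s.series_id: pd.Series(s.widths, index=s.years) for s in group}
    ).sort_index()
    q = wide.quantile([0.05, 0.25, 0.5, 0.75, 0.95], axis=1).T
    table = pd.DataFrame(
        {
            "mean": wide.mean(axis=1),
            "median": q[0.5],
            "q25": q[0.25],
            "q75": q[0.75],
            "p5": q[0.05],
            "p95": q[0.95],
            "depth": wide.notna().sum(axis=1).astype(int),
        }
    )
    table.index.name = "year"
    return Chronology(table)


@dataclasses.dataclass(frozen=True)
class ChronologyStats:
    """Homogeneity summary of one group of series (one table row)."""

    n_series: int
    ms_percent: float
    ac1: float
    rbar: float
    snr: float
    eps: float
    ev_percent: float
    interval: CommonInterval | None


def group_stats(
    group: list[RingWidthSeries],
    interval: CommonInterval | None = None,
    detrend: bool = True,
) -> ChronologyStats:
    """Detrend a group and compute its full homogeneity record.

    MS and AC are computed per series on the detrended indices and then
    averaged; Rbar uses per-pair maximal overlap on the indices; EV uses
    the fixed ``interval`` (default: the group's common interval).  Set
    ``detrend=False`` to run on the values as passed (e.g. raw widths).
    """
    if len(group) < 2:
        raise ValueError("group_stats needs at least 2 series")
    if detrend:
        indexed = [s.with_values(fit_conservative(s).indices) for s in group]
    else:
        indexed = list(group)
    if interval is None:
        start = max(s.first_year for s in indexed)
        end = min(s.last_year for s in indexed)
        interval = CommonInterval(start, end) if start <= end else None

    ms = float(np.mean([mean_sensitivity(s) for s in indexed]))
    ac = float(np.nanmean([ac1(s) for s in indexed]))
    r = rbar(indexed)
    n = len(indexed)
    s_n = snr(n, r)
    e = eps_from_snr(s_n)
    if interval is not None and interval.n_years >= 3:
        ev = ev_first(indexed, interval)
    else:
        ev = math.nan
        logger.warning("group_stats: no usable common interval, EV undefined")
    return ChronologyStats(
        n_series=n,
        ms_percent=ms,
        ac1=ac,
        rbar=r,
        snr=s_n,
        eps=e,
        ev_percent=ev,
        interval=interval,
    )


def recommend_n(rbar_value: float, eps_target: float = EPS_THRESHOLD) -> int:
    """Smallest N with ``N·r/(N·r + 1 − r) ≥ eps_target``.

    Inverts the EPS formula to answer the sampling-design question "how
    many series of this coherence do I need".  Raises ``ValueError`` when
    the target is unattainable (``rbar ≤ 0``).
    """
    if not 0.0 < eps_target < 1.0:
        raise ValueError("eps_target must be in (0, 1)")
    if rbar_value <= 0.0:
        raise ValueError("eps target unattainable: rbar <= 0")
    if rbar_value >= 1.0:
        return 1
    n = math.ceil(eps_target * (1.0 - rbar_value) / (rbar_value * (1.0 - eps_target)))
    n = max(n, 1)
    while eps(n, rbar_value) < eps_target:  # guard against float edge cases
        n += 1
    return n
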