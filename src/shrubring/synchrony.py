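"""Pairwise cross-dating agreement statistics.

Two complementary measures of year-to-year agreement between ring-width
series are provided:

* **Gleichläufigkeit (Glk)** — the percentage of year-to-year changes
  agreeing in sign.  Agreement scores 1, a tie (either difference
  exactly zero) scores ½, disagreement 0; the percentage is the mean
  score over the ``m = n − 1`` shared intervals.  Under independence the
  mean score is 1/2 and the agreement indicators are 1-dependent
  (consecutive year-to-year differences share a term), giving the exact
  null variance ``(m/4 + (m−1)/18)/m²``; a normal approximation with
  that variance yields a one-sided p-value and significance thresholds
  that hold their nominal size (the naive ``50/√m`` standard deviation
  under-disperses and roughly doubles the type-I error).
* **Baillie–Pilcher t (t_BP)** — the Pearson correlation ``r`` of the two
  log-standardized series (5-year moving-average ratio, see
  :mod:`shrubring.detrend`), converted to ``t = r·√(N−2)/√(1−r²)`` with
  ``N`` the retained overlap.  A t_BP of 3.5 is the conventional floor
  for a secure cross-date.

A leave-one-out correlation screen against the group mean flags likely
misdated series and missing/false rings at small lags.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

from .detrend import bp_standardize, bp_years
from .errors import OverlapError
from .series import Finding, RingWidthSeries, overlap

#: conventional secure-dating threshold for t_BP
T_BP_SECURE = 3.5
#: leave-one-out lag-0 correlation floor below which a series is flagged
SCREEN_R_MIN = 0.32


@dataclasses.dataclass(frozen=True)
class SyncResult:
    """Pairwise synchrony between two series.

    ``t_bp`` keeps the sign of ``r``; a perfectly correlated pair is
    reported with ``t_infinite=True`` (and ``t_bp = inf``) rather than an
    exception, and such values are excluded from group means.
    """

    glk_percent: float
    glk_p: float
    overlap_n: int
    r: float
    t_bp: float
    t_infinite: bool = False
    retained_n: int = 0


def glk(x, y) -> tuple[float, float, int]:
    """Gleichläufigkeit of two series: ``(percent, one-sided p, overlap n)``.

    Accepts two :class:`RingWidthSeries` (aligned on calendar years) or
    two equal-length plain sequences (assumed already aligned).
    """
    if isinstance(x, RingWidthSeries) and isinstance(y, RingWidthSeries):
        _, xv, yv = overlap(x, y)
    else:
        xv = np.asarray(x, dtype=float)
        yv = np.asarray(y, dtype=float)
        if xv.size != yv.size:
            raise ValueError("plain sequences must have equal length")
    n = int(xv.size)
    if n < 3:
        raise OverlapError(f"Glk needs an overlap of at least 3 years, got {n}")
    dx = np.diff(xv)
    dy = np.diff(yv)
    score = np.where(
        (dx == 0) | (dy == 0), 0.5, (np.sign(dx) == np.sign(dy)).astype(float)
    )
    percent = 100.0 * float(np.mean(score))
    p = glk_pvalue(percent, n)
    return percent, p, n


def _glk_null_sd(overlap_n: int) -> float:
    """Null standard deviation of Glk (%) over ``m = n − 1`` intervals.

    Exact for continuous series: indicator variance 1/4, lag-1
    covariance 1/36 (indicators are 1-dependent), zero beyond lag 1.
    """
    m = overlap_n - 1
    return 100.0 * math.sqrt(m / 4.0 + (m - 1) / 18.0) / m


def glk_pvalue(glk_percent: float, overlap_n: int) -> float:
    """One-sided upper p-value from the serial-dependence-aware normal null."""
    z = (glk_percent - 50.0) / _glk_null_sd(overlap_n)
    return float(stats.norm.sf(z))


def glk_threshold(overlap_n: int, alpha: float = 0.05) -> float:
    """Glk value a pair of length ``overlap_n`` must reach for significance.

    These are the dashed guide lines drawn through Glk box plots (e.g. at
    p ≤ 0.05 and p ≤ 0.001).
    """
    return 50.0 + float(stats.norm.isf(alpha)) * _glk_null_sd(overlap_n)


def t_from_r(r: float, n: int) -> float:
    """Overlap-adjusted t of a correlation: ``t = r·√(n−2)/√(1−r²)``.

    ``|r| = 1`` returns a signed infinity rather than raising.
    """
    if n < 3:
        raise OverlapError(f"t statistic needs n >= 3, got {n}")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    if abs(r) >= 1.0 - 1e-12:
        return math.copysign(math.inf, r)
    return r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)


def tbp(x: RingWidthSeries, y: RingWidthSeries, min_overlap: int = 7) -> SyncResult:
    """Full pairwise synchrony record (Glk on raw overlap, t on BP indices).

    Each series is BP-standardized over its whole length; the Pearson
    correlation and t are computed on the shared retained years.
    """
    years, xv, yv = overlap(x, y)
    if years.size < min_overlap:
        raise OverlapError(
            f"{x.series_id} vs {y.series_id}: overlap {years.size} < {min_overlap}"
        )
    glk_percent, glk_p, n_raw = glk(x, y)

    bx = pd.Series(bp_standardize(x), index=bp_years(x))
    by = pd.Series(bp_standardize(y), index=bp_years(y))
    common = bx.index.intersection(by.index)
    if common.size < 3:
        raise OverlapError(
            f"{x.series_id} vs {y.series_id}: BP-retained overlap {common.size} < 3"
        )
    xs = bx.loc[common].to_numpy()
    ys = by.loc[common].to_numpy()
    if np.std(xs) == 0 or np.std(ys) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(xs, ys)[0, 1])
    r = min(1.0, max(-1.0, r))
    t = t_from_r(r, int(common.size))
    return SyncResult(
        glk_percent=glk_percent,
        glk_p=glk_p,
        overlap_n=n_raw,
        r=r,
        t_bp=t,
        t_infinite=not math.isfinite(t),
        retained_n=int(common.size),
    )


@dataclasses.dataclass(frozen=True)
class PairwiseResult:
    """Symmetric pairwise matrix over a group plus its off-diagonal mean."""

    metric: str
    matrix: pd.DataFrame
    mean: float
    n_infinite: int
    findings: list[Finding]


def pairwise_matrix(
    group: list[RingWidthSeries], metric: str = "glk", min_overlap: int = 7
) -> PairwiseResult:
    """Evaluate a synchrony metric over all unordered pairs of a group.

    ``metric`` is ``"glk"``, ``"tbp"`` or ``"r"``.  The diagonal is NaN;
    pairs below the overlap minimum become NaN cells with a finding;
    infinite t values are excluded from the mean (their count is
    reported).
    """
    if metric not in ("glk", "tbp", "r"):
        raise ValueError(f"unknown metric {metric!r}")
    if len(group) < 2:
        raise ValueError("pairwise matrix needs at least 2 series")
    ids = [s.series_id for s in group]
    mat = pd.DataFrame(np.nan, index=ids, columns=ids)
    findings: list[Finding] = []
    values: list[float] = []
    n_inf = 0
    for i in range(len(group)):
        for j in range(i + 1, len(group)):
            try:
                if metric == "glk":
                    # Glk needs only a 3-year overlap, not the BP window
                    v, _, _ = glk(group[i], group[j])
                else:
                    res = tbp(group[i], group[j], min_overlap=min_overlap)
                    v = res.r if metric == "r" else res.t_bp
            except OverlapError as exc:
                findings.append(Finding("insufficient_overlap", ids[i], str(exc)))
                continue
            mat.iloc[i, j] = mat.iloc[j, i] = v
            if math.isfinite(v):
                values.append(v)
            else:
                n_inf += 1
    mean = float(np.mean(values)) if values else math.nan
    return PairwiseResult(metric, mat, mean, n_inf, findings)


@dataclasses.dataclass(frozen=True)
class ScreenRecord:
    """Leave-one-out dating screen result for one series.

    Lag convention: ``r(L)`` correlates the series' value in year ``t``
    with the group mean in year ``t + L``; a series whose years are
    labelled one year too late therefore peaks at ``L = −1``.
    """

    series_id: str
    best_lag: int
    r_best: float
    r_lag0: float
    flagged: bool


def crossdate_screen(
    group: list[RingWidthSeries],
    lags: range = range(-2, 3),
    r_threshold: float = SCREEN_R_MIN,
) -> list[ScreenRecord]:
    """Screen each series against the BP-standardized mean of all others.

    A series is flagged when its best-correlating lag is not zero or the
    lag-0 correlation falls below ``r_threshold`` (COFECHA-style floor,
    here applied whole-series rather than per segment).
    """
    if len(group) < 3:
        raise ValueError("dating screen needs at least 3 series")
    bp = {
        s.series_id: pd.Series(bp_standardize(s), index=bp_years(s)) for s in group
    }
    records: list[ScreenRecord] = []
    for s in group:
        others = [bp[o.series_id] for o in group if o.series_id != s.series_id]
        ref = pd.concat(others, axis=1).mean(axis=1)
        own = bp[s.series_id]
        best_lag, best_r, r0 = 0, -np.inf, np.nan
        for lag in lags:
            shifted = ref.copy()
            shifted.index = shifted.index - lag  # ref year t+L aligned to own t
            common = own.index.intersection(shifted.index)
            if common.size < 5:
                continue
            a = own.loc[common].to_numpy()
            b = shifted.loc[common].to_numpy()
            if np.std(a) == 0 or np.std(b) == 0:
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            if lag == 0:
                r0 = r
            if r > best_r:
                best_r, best_lag = r, lag
        flagged = best_lag != 0 or (not np.isnan(r0) and r0 < r_threshold) or np.isnan(r0)
        records.append(ScreenRecord(s.series_id, best_lag, best_r, r0, flagged))
    return records
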