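"""Conservative detrending, Baillie–Pilcher standardization, FFT low-pass.

Detrending removes the age/size-related growth trend from a ring-width
series so that year-to-year (high-frequency) variation can be compared
across series.  The conservative cascade tried here is the classic one:

1. modified negative exponential ``w(τ) = a·exp(−b·τ) + k`` with
   ``a > 0, b > 0, k ≥ 0`` (τ = ring index from the pith);
2. if that fails or is effectively flat, an ordinary least-squares line,
   accepted only when its slope is ≤ 0 and it stays positive;
3. otherwise a horizontal line at the series mean.

Dimensionless indices are the ratio observed / fitted.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.optimize import curve_fit

from .errors import DegenerateSeriesError, LengthError
from .series import RingWidthSeries

logger = logging.getLogger(__name__)

#: BP standardization uses a centered 5-year moving average.
BP_WINDOW = 5


@dataclasses.dataclass(frozen=True)
class DetrendResult:
    """Fitted growth curve and index series for one input series.

    ``method`` is one of ``negative_exponential``, ``linear_negative`` or
    ``horizontal_mean``; ``params`` carries the fitted coefficients
    (``a, b, k`` or ``slope, intercept`` or ``mean``).
    """

    method: str
    fitted: np.ndarray
    indices: np.ndarray
    params: dict[str, float]


def _values(series) -> np.ndarray:
    if isinstance(series, RingWidthSeries):
        return np.asarray(series.widths, dtype=float)
    return np.asarray(series, dtype=float)


def _negexp(tau, a, b, k):
    return a * np.exp(-b * tau) + k


def fit_conservative(series) -> DetrendResult:
    """Fit the conservative cascade and return indices observed/fitted.

    Accepts a :class:`RingWidthSeries` or a plain width array.  Zero
    widths (inserted missing rings) stay in the fit — they carry level
    information — and simply yield index 0.  Requires at least five
    non-zero widths; an all-zero series is degenerate.
    """
    w = _values(series)
    n = w.size
    if np.count_nonzero(w) == 0:
        raise DegenerateSeriesError("all widths are zero")
    if np.count_nonzero(w) < 5:
        raise LengthError("need at least 5 non-zero widths to detrend")
    tau = np.arange(n, dtype=float)
    mean_w = float(np.mean(w))

    # 1. modified negative exponential
    fitted = None
    a0 = max(float(w[0] - w[-1]), 1e-3)
    p0 = (a0, 2.0 / n, max(float(w[-1]), 0.0))
    try:
        popt, _ = curve_fit(
            _negexp,
            tau,
            w,
            p0=p0,
            bounds=([1e-12, 1e-12, 0.0], [np.inf, np.inf, np.inf]),
            method="trf",
            xtol=1e-8,
            ftol=1e-8,
            max_nfev=200,
        )
        cand = _negexp(tau, *popt)
        # reject an effectively flat exponential: no meaningful decline
        if cand[0] - cand[-1] > 1e-6 * mean_w and np.all(cand > 0):
            fitted = cand
            result = DetrendResult(
                "negative_exponential",
                fitted,
                w / fitted,
                {"a": float(popt[0]), "b": float(popt[1]), "k": float(popt[2])},
            )
    except (RuntimeError, ValueError):
        fitted = None

    # 2. least-squares line, accepted only for non-positive slope
    if fitted is None:
        slope, intercept = np.polyfit(tau, w, 1)
        cand = slope * tau + intercept
        if slope <= 0 and np.all(cand > 0):
            fitted = cand
            result = DetrendResult(
                "linear_negative",
                fitted,
                w / fitted,
                {"slope": float(slope), "intercept": float(intercept)},
            )

    # 3. horizontal line at the mean
    if fitted is None:
        fitted = np.full(n, mean_w)
        result = DetrendResult(
            "horizontal_mean", fitted, w / fitted, {"mean": mean_w}
        )

    m = float(np.mean(result.indices))
    if not 0.8 <= m <= 1.2:
        logger.warning(
            "mean index %.3f outside [0.8, 1.2]; possible structural break", m
        )
    return result


def detrend_series(series: RingWidthSeries) -> RingWidthSeries:
    """Return the dimensionless index series as a RingWidthSeries container."""
    res = fit_conservative(series)
    return series.with_values(res.indices)


def bp_standardize(series, zero_floor: float = 1.0) -> np.ndarray:
    """Baillie–Pilcher log standardization of a width series.

    Each retained year's value is ``ln(100 · w_t / MA5_t)`` where ``MA5``
    is the centered 5-year moving average of the widths.  The first two
    and last two years are dropped so every retained value is built from
    a complete window.  Zero widths (missing rings) are floored at
    ``zero_floor`` µm before the ratio/log.
    """
    w = _values(series).copy()
    if w.size < BP_WINDOW + 2:
        raise LengthError(
            f"BP standardization needs at least {BP_WINDOW + 2} rings, got {w.size}"
        )
    w[w <= 0] = zero_floor
    ma = np.convolve(w, np.full(BP_WINDOW, 1.0 / BP_WINDOW), mode="valid")
    core = w[2:-2]
    return np.log(100.0 * core / ma)


def bp_years(series: RingWidthSeries) -> np.ndarray:
    """Calendar years retained by :func:`bp_standardize` for this series."""
    return series.years[2:-2]


def lowpass_trend(values, cutoff_years: float = 3.0) -> np.ndarray:
    """FFT low-pass filter: remove all periods strictly shorter than cutoff.

    The discrete Fourier transform of the input is taken, coefficients
    whose period is below ``cutoff_years`` are zeroed, and the inverse
    transform's real part returned.  The DC component is untouched, so
    the output mean equals the input mean exactly.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise LengthError("low-pass filtering needs at least 4 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    spectrum = np.fft.rfft(x)
    freq = np.fft.rfftfreq(x.size, d=1.0)  # cycles per year
    spectrum[freq > 1.0 / cutoff_years] = 0.0
    return np.fft.irfft(spectrum, n=x.size)
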