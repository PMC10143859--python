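"""Optional plotting helpers (thin layer over matplotlib).

matplotlib is imported lazily so the analysis core has no hard plotting
dependency; install the ``plot`` extra to use these.
"""

from __future__ import annotations

from .chronology import Chronology


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_chronology(chron: Chronology, ax=None, title: str | None = None):
    """Mean line with quartile box band and 5/95 percentile whisker band."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    t = chron.table
    ax.fill_between(t.index, t["p5"], t["p95"], alpha=0.15, label="5–95%")
    ax.fill_between(t.index, t["q25"], t["q75"], alpha=0.3, label="25–75%")
    ax.plot(t.index, t["mean"], color="black", lw=1.5, label="mean")
    ax.plot(t.index, t["median"], color="black", lw=1.0, ls=":", label="median")
    ax.set_xlabel("year")
    ax.set_ylabel("ring width (µm)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize="small")
    return ax


def plot_trends(smoothed: dict, ax=None):
    """Smoothed per-stock mean chronologies on one axis."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    for stock in sorted(smoothed):
        ax.plot(smoothed[stock].index, smoothed[stock].values, label=stock, ls="--")
    ax.set_xlabel("year")
    ax.set_ylabel("ring width (µm), low-pass")
    ax.legend(fontsize="small")
    return ax
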