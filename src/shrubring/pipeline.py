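"""Three-level growth-variability analysis pipeline.

The scientific question has three nested levels: how well do ring-width
series agree (i) among radii of one shoot, (ii) among shoots of one
stock (clonal individual) and (iii) among stocks at different microsites?
This module wires the synchrony and chronology statistics into those
comparisons, adds extreme-year tests and long-term trend extraction, and
bundles everything into a deterministic report.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .chronology import build_chronology, group_stats
from .detrend import lowpass_trend
from .errors import OverlapError, SampleSizeError, ShrubRingError
from .series import (
    COMBINATION_LABELS,
    CommonInterval,
    Finding,
    RingWidthSeries,
    SeriesCollection,
    combine_radii,
    validate_collection,
)
from .synchrony import T_BP_SECURE, SyncResult, pairwise_matrix, tbp

#: labels analysed at the shoot and stock levels
ALL_LABELS = ("a", "b", "c", "d", "ab", "cd", "abcd")
#: radius comparisons within one shoot
RADIUS_COMPARISONS = (("a", "b"), ("c", "d"), ("a", "cd"), ("b", "cd"), ("ab", "cd"))


# ---------------------------------------------------------------------------
# basic two-sample machinery
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    mean1: float
    mean2: float
    infinite: bool = False


def group_ttest(sample1, sample2) -> TTestResult:
    """Student's pooled-variance two-sample t-test (two-sided).

    Degenerate zero-variance inputs do not raise: equal means give
    ``t = 0, p = 1``; unequal means give an infinity-flagged t with
    ``p = 0``.
    """
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise SampleSizeError("each sample needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite sample values")
    df = a.size + b.size - 2
    m1, m2 = float(np.mean(a)), float(np.mean(b))
    pooled = (np.sum((a - m1) ** 2) + np.sum((b - m2) ** 2)) / df
    if pooled == 0.0:
        if m1 == m2:
            return TTestResult(0.0, df, 1.0, m1, m2)
        return TTestResult(math.copysign(math.inf, m1 - m2), df, 0.0, m1, m2, True)
    t = (m1 - m2) / math.sqrt(pooled * (1.0 / a.size + 1.0 / b.size))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(float(t), float(df), p, m1, m2)


def significance_letters(
    names: list[str], pvalues: dict[tuple[str, str], float], alpha: float = 0.01
) -> dict[str, str]:
    """Compact letter display for pairwise comparisons.

    Groups sharing a letter are pairwise not significantly different
    (p > alpha); groups with no letter in common differ somewhere at
    ``p <= alpha``.  Letters are the maximal cliques of the
    "not-different" graph, found by brute force (group counts here are
    tiny).
    """
    k = len(names)
    ns = {}
    for i, j in itertools.combinations(range(k), 2):
        p = pvalues.get((names[i], names[j]), pvalues.get((names[j], names[i]), 1.0))
        ns[(i, j)] = p > alpha

    def is_clique(sub):
        return all(ns[(i, j)] for i, j in itertools.combinations(sub, 2))

    cliques = []
    for size in range(k, 0, -1):
        for sub in itertools.combinations(range(k), size):
            if is_clique(sub) and not any(set(sub) <= set(c) for c in cliques):
                cliques.append(sub)
    cliques.sort(key=lambda c: c[0])
    letters = {name: "" for name in names}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for i in clique:
            letters[names[i]] += letter
    return letters


# ---------------------------------------------------------------------------
# shoot-level series construction
# ---------------------------------------------------------------------------

def shoot_label_series(
    collection: SeriesCollection, stock: str, label: str
) -> tuple[list[RingWidthSeries], list[Finding]]:
    """One series per shoot of ``stock`` for a radius label or combination.

    Combinations are averaged from the member radii; shoots missing a
    required radius are excluded with a finding.
    """
    out: list[RingWidthSeries] = []
    findings: list[Finding] = []
    for shoot, radii in sorted(collection.by_shoot(stock).items()):
        if label in radii:
            out.append(radii[label])
        elif label in COMBINATION_LABELS:
            if all(r in radii for r in label):
                out.append(combine_radii(radii, label))
            else:
                missing = [r for r in label if r not in radii]
                findings.append(
                    Finding(
                        "missing_radius",
                        None,
                        f"shoot {stock}/{shoot} lacks radius {missing} for {label}",
                    )
                )
    return out, findings


def _box_stats(values: np.ndarray) -> dict[str, float]:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return {k: math.nan for k in ("mean", "median", "q25", "q75", "p5", "p95")} | {
            "n": 0
        }
    return {
        "mean": float(np.mean(v)),
        "median": float(np.median(v)),
        "q25": float(np.percentile(v, 25)),
        "q75": float(np.percentile(v, 75)),
        "p5": float(np.percentile(v, 5)),
        "p95": float(np.percentile(v, 95)),
        "n": int(v.size),
    }


@dataclasses.dataclass(frozen=True)
class ComparisonReport:
    """One level of the variability analysis.

    ``cells`` holds per-comparison synchrony records; ``summary`` the
    box-plot distribution per comparison label; ``group_tests`` any
    attached two-sample tests.
    """

    level: str
    cells: pd.DataFrame
    summary: pd.DataFrame
    group_tests: pd.DataFrame | None = None
    findings: list[Finding] = dataclasses.field(default_factory=list)


# ---------------------------------------------------------------------------
# level 1: radii within one shoot
# ---------------------------------------------------------------------------

def compare_radii_within_shoot(
    collection: SeriesCollection, stock: str, min_overlap: int = 7
) -> ComparisonReport:
    """Synchrony of opposite radii and radius/combination pairs per shoot.

    For each shoot with all four radii: a:b, c:d, a:cd, b:cd and ab:cd.
    Returns per-shoot records and the per-label distribution over shoots.
    """
    rows = []
    findings: list[Finding] = []
    for shoot, radii in sorted(collection.by_shoot(stock).items()):
        if not all(r in radii for r in "abcd"):
            findings.append(
                Finding(
                    "missing_radius", None, f"shoot {stock}/{shoot} lacks a radius"
                )
            )
            continue
        derived = dict(radii)
        derived["ab"] = combine_radii(radii, "ab")
        derived["cd"] = combine_radii(radii, "cd")
        for left, right in RADIUS_COMPARISONS:
            label = f"{left}:{right}"
            try:
                res = tbp(derived[left], derived[right], min_overlap=min_overlap)
            except OverlapError as exc:
                findings.append(Finding("insufficient_overlap", None, str(exc)))
                continue
            rows.append(_sync_row(res, shoot=shoot, comparison=label))
    cells = pd.DataFrame(
        rows,
        columns=["shoot", "comparison", "overlap_n", "glk", "glk_p", "r", "t_bp",
                 "t_infinite"],
    )
    summary = _summarize_cells(cells, key="comparison")
    return ComparisonReport("radius_within_shoot", cells, summary, findings=findings)


def _sync_row(res: SyncResult, **keys) -> dict:
    return {
        **keys,
        "overlap_n": res.overlap_n,
        "glk": res.glk_percent,
        "glk_p": res.glk_p,
        "r": res.r,
        "t_bp": res.t_bp,
        "t_infinite": res.t_infinite,
    }


def _summarize_cells(cells: pd.DataFrame, key: str) -> pd.DataFrame:
    rows = []
    if cells.empty:
        return pd.DataFrame(
            columns=[key, "n", "glk_mean", "glk_median", "glk_q25", "glk_q75",
                     "tbp_mean", "tbp_median", "tbp_q25", "tbp_q75", "n_infinite"]
        )
    for label, sub in cells.groupby(key, sort=False):
        g = _box_stats(sub["glk"].to_numpy())
        finite_t = sub.loc[~sub["t_infinite"], "t_bp"].to_numpy()
        t = _box_stats(finite_t)
        rows.append(
            {
                key: label,
                "n": len(sub),
                "glk_mean": g["mean"],
                "glk_median": g["median"],
                "glk_q25": g["q25"],
                "glk_q75": g["q75"],
                "tbp_mean": t["mean"],
                "tbp_median": t["median"],
                "tbp_q25": t["q25"],
                "tbp_q75": t["q75"],
                "n_infinite": int(sub["t_infinite"].sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# level 2: shoots within one stock
# ---------------------------------------------------------------------------

def compare_shoots_within_stock(
    collection: SeriesCollection,
    stock: str,
    labels: tuple[str, ...] = ALL_LABELS,
    min_overlap: int = 7,
) -> ComparisonReport:
    """Pairwise synchrony among shoots of one stock, per radius label.

    For each label the full pairwise matrix over the shoots' series is
    evaluated; the summary marks which labels reach a secure mean t_BP
    (≥ 3.5).
    """
    rows = []
    srows = []
    findings: list[Finding] = []
    for label in labels:
        group, f = shoot_label_series(collection, stock, label)
        findings.extend(f)
        if len(group) < 2:
            findings.append(
                Finding("too_few_shoots", None, f"{stock}/{label}: < 2 shoots")
            )
            continue
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                try:
                    res = tbp(group[i], group[j], min_overlap=min_overlap)
                except OverlapError as exc:
                    findings.append(Finding("insufficient_overlap", None, str(exc)))
                    continue
                rows.append(
                    _sync_row(
                        res,
                        label=label,
                        shoot_x=group[i].shoot,
                        shoot_y=group[j].shoot,
                    )
                )
    cells = pd.DataFrame(
        rows,
        columns=["label", "shoot_x", "shoot_y", "overlap_n", "glk", "glk_p", "r",
                 "t_bp", "t_infinite"],
    )
    summary = _summarize_cells(cells, key="label")
    if not summary.empty:
        summary["secure"] = summary["tbp_mean"] >= T_BP_SECURE
    return ComparisonReport("shoot_within_stock", cells, summary, findings=findings)


# ---------------------------------------------------------------------------
# level 3: stocks against each other
# ---------------------------------------------------------------------------

def _stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def stock_mean_series(
    collection: SeriesCollection, stock: str, label: str
) -> RingWidthSeries | None:
    """Mean chronology over the shoots of a stock, for one label."""
    group, _ = shoot_label_series(collection, stock, label)
    if not group:
        return None
    chron = build_chronology(group)
    return chron.mean_series(group[0], radius_label=label)


def compare_stocks(
    collection: SeriesCollection,
    labels: tuple[str, ...] = ALL_LABELS,
    min_overlap: int = 7,
) -> ComparisonReport:
    """Synchrony of stock mean series for every label and stock pair.

    Significance stars for Glk come from its one-sided normal p-value
    (``***`` p ≤ 0.001, ``**`` p ≤ 0.01, ``*`` p ≤ 0.05).  The report is
    symmetric in stock order (pairs are listed once, sorted).
    """
    stocks = collection.stocks()
    if len(stocks) < 2:
        raise SampleSizeError("stock comparison needs at least 2 stocks")
    rows = []
    findings: list[Finding] = []
    for label in labels:
        means = {st: stock_mean_series(collection, st, label) for st in stocks}
        for sx, sy in itertools.combinations(stocks, 2):
            if means[sx] is None or means[sy] is None:
                continue
            try:
                res = tbp(means[sx], means[sy], min_overlap=min_overlap)
            except OverlapError as exc:
                findings.append(Finding("insufficient_overlap", None, str(exc)))
                continue
            row = _sync_row(res, label=label, stock_x=sx, stock_y=sy)
            row["glk_stars"] = _stars(res.glk_p)
            rows.append(row)
    cells = pd.DataFrame(
        rows,
        columns=["label", "stock_x", "stock_y", "overlap_n", "glk", "glk_p",
                 "glk_stars", "r", "t_bp", "t_infinite"],
    )
    summary = _summarize_cells(cells, key="label")
    return ComparisonReport("stock_vs_stock", cells, summary, findings=findings)


# ---------------------------------------------------------------------------
# extreme years
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ExtremeYearResult:
    """Tests of one candidate extreme growth year.

    ``paired`` compares each shoot's width in ``year`` against ``year−1``
    (same shoots measured in both years); ``vs_all`` compares widths in
    ``year`` against all other years pooled (unpaired).
    """

    year: int
    n_shoots: int
    paired: TTestResult
    vs_all: TTestResult


def extreme_year_test(
    group: list[RingWidthSeries], year: int, paired: bool = True
) -> ExtremeYearResult:
    """Test whether ``year`` differs from the preceding year (and the rest).

    ``group`` is a set of shoot-level series (typically abcd means, one
    per shoot); at least 3 shoots must cover both ``year`` and
    ``year − 1``.
    """
    cur, prev, others = [], [], []
    for s in group:
        if s.first_year <= year - 1 and s.last_year >= year:
            cur.append(s.widths[year - s.first_year])
            prev.append(s.widths[year - 1 - s.first_year])
            mask = s.years != year
            others.extend(s.widths[mask])
    if len(cur) < 3:
        raise SampleSizeError(
            f"only {len(cur)} shoots cover {year - 1}-{year}; need >= 3"
        )
    cur_a, prev_a = np.asarray(cur), np.asarray(prev)
    if paired:
        d = cur_a - prev_a
        df = d.size - 1
        sd = float(np.std(d, ddof=1))
        if sd == 0.0:
            pt = TTestResult(0.0, df, 1.0, float(cur_a.mean()), float(prev_a.mean())) \
                if np.allclose(d, 0) else TTestResult(
                    math.copysign(math.inf, d.mean()), df, 0.0,
                    float(cur_a.mean()), float(prev_a.mean()), True)
        else:
            t = float(d.mean() / (sd / math.sqrt(d.size)))
            p = 2.0 * float(stats.t.sf(abs(t), df))
            pt = TTestResult(t, df, p, float(cur_a.mean()), float(prev_a.mean()))
    else:
        pt = group_ttest(cur_a, prev_a)
    vs_all = group_ttest(cur_a, np.asarray(others))
    return ExtremeYearResult(year, len(cur), pt, vs_all)


# ---------------------------------------------------------------------------
# long-term trends
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TrendReport:
    """Per-stock smoothed mean chronologies and final-segment classification."""

    table: pd.DataFrame
    smoothed: dict[str, pd.Series]
    findings: list[Finding] = dataclasses.field(default_factory=list)


def trend_report(
    collection: SeriesCollection,
    cutoff_years: float = 3.0,
    window: int = 5,
    deadband_frac: float = 0.01,
) -> TrendReport:
    """Low-pass growth trends of the per-stock mean abcd chronologies.

    The final ``window`` years of the smoothed mean are classified as
    increasing / constant / decreasing by the sign of their least-squares
    slope, with a dead band of ``deadband_frac`` of the series mean per
    year counting as constant.
    """
    rows = []
    smoothed: dict[str, pd.Series] = {}
    findings: list[Finding] = []
    for stock in collection.stocks():
        series = stock_mean_series(collection, stock, "abcd")
        if series is None or len(series) < 8:
            findings.append(
                Finding("short_series", None, f"stock {stock}: mean series < 8 years")
            )
            continue
        smooth = lowpass_trend(series.widths, cutoff_years=cutoff_years)
        smoothed[stock] = pd.Series(smooth, index=series.years, name=stock)
        tail = smooth[-window:]
        slope = float(np.polyfit(np.arange(window), tail, 1)[0])
        dead = deadband_frac * float(np.mean(series.widths))
        if abs(slope) < dead:
            cls = "constant"
        elif slope > 0:
            cls = "increasing"
        else:
            cls = "decreasing"
        rows.append(
            {
                "stock": stock,
                "n_years": len(series),
                "mean_width": float(np.mean(series.widths)),
                "final_slope": slope,
                "classification": cls,
            }
        )
    table = pd.DataFrame(
        rows, columns=["stock", "n_years", "mean_width", "final_slope",
                       "classification"]
    )
    return TrendReport(table, smoothed, findings)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineConfig:
    """Knobs of the full analysis run (all mirrored by the CLI)."""

    interval: tuple[int, int] | None = None
    labels: tuple[str, ...] = ALL_LABELS
    alpha_groups: float = 0.01
    extreme_years: tuple[int, ...] | None = None  # None = auto-detect
    extreme_paired: bool = True
    min_overlap: int = 7
    trend_cutoff: float = 3.0
    trend_window: int = 5
    trend_deadband: float = 0.01

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**mapping)
        if cfg.interval is not None:
            cfg.interval = tuple(int(y) for y in cfg.interval)
        if cfg.extreme_years is not None:
            cfg.extreme_years = tuple(int(y) for y in cfg.extreme_years)
        cfg.labels = tuple(cfg.labels)
        return cfg


@dataclasses.dataclass
class PipelineReport:
    """Bundle of all analysis tables; deterministic for a given input."""

    findings: list[Finding]
    stock_summary: pd.DataFrame
    homogeneity: pd.DataFrame
    stock_synchrony: ComparisonReport | None
    radii_within_shoot: dict[str, ComparisonReport]
    shoots_within_stock: dict[str, ComparisonReport]
    extreme_years: pd.DataFrame
    trends: TrendReport

    def to_text(self) -> str:
        """Plain-text rendering of every table (tab-separated blocks)."""
        out = []

        def block(title: str, df: pd.DataFrame):
            out.append(f"## {title}")
            if df is None or df.empty:
                out.append("(empty)")
            else:
                out.append(df.to_csv(sep="\t", index=False, float_format="%.4f").rstrip())
            out.append("")

        out.append("# shrubring pipeline report")
        out.append("")
        if self.findings:
            out.append("## validation findings")
            for f in self.findings:
                out.append(f"- {f.kind}\t{f.series_id or '-'}\t{f.message}")
            out.append("")
        block("stock summary", self.stock_summary)
        block("chronology homogeneity", self.homogeneity)
        if self.stock_synchrony is not None:
            block("stock-pair synchrony", self.stock_synchrony.cells)
        for stock in sorted(self.radii_within_shoot):
            block(
                f"radius synchrony within shoots of {stock}",
                self.radii_within_shoot[stock].summary,
            )
        for stock in sorted(self.shoots_within_stock):
            block(
                f"shoot synchrony within {stock}",
                self.shoots_within_stock[stock].summary,
            )
        block("extreme years", self.extreme_years)
        block("long-term trends", self.trends.table)
        return "\n".join(out)

    def write(self, outdir) -> None:
        """Write all tables as TSV plus the plain-text summary."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tables = {
            "stock_summary.tsv": self.stock_summary,
            "homogeneity.tsv": self.homogeneity,
            "extreme_years.tsv": self.extreme_years,
            "trends.tsv": self.trends.table,
        }
        if self.stock_synchrony is not None:
            tables["stock_synchrony.tsv"] = self.stock_synchrony.cells
        for name, df in tables.items():
            df.to_csv(outdir / name, sep="\t", index=False, float_format="%.6g")
        for stock, rep in self.radii_within_shoot.items():
            rep.summary.to_csv(
                outdir / f"radii_within_shoot_{stock}.tsv",
                sep="\t", index=False, float_format="%.6g",
            )
        for stock, rep in self.shoots_within_stock.items():
            rep.summary.to_csv(
                outdir / f"shoots_within_stock_{stock}.tsv",
                sep="\t", index=False, float_format="%.6g",
            )
        (outdir / "summary.txt").write_text(self.to_text())


def _detect_extreme_years(collection: SeriesCollection) -> tuple[int, ...]:
    """Candidate extreme years: largest relative rise and drop of the
    pooled shoot-level mean chronology (well-replicated years only)."""
    shoot_series: list[RingWidthSeries] = []
    for stock in collection.stocks():
        group, _ = shoot_label_series(collection, stock, "abcd")
        shoot_series.extend(group)
    if not shoot_series:
        return ()
    chron = build_chronology(shoot_series)
    tab = chron.table
    tab = tab[tab["depth"] >= tab["depth"].max() / 2]
    if len(tab) < 3:
        return ()
    mean = tab["mean"]
    rel = mean.diff() / mean.shift()
    rel = rel.dropna()
    if rel.empty:
        return ()
    up = int(rel.idxmax())
    down = int(rel.idxmin())
    return tuple(sorted({up, down}))


def run_pipeline(
    collection: SeriesCollection, config: PipelineConfig | None = None
) -> PipelineReport:
    """Run the full three-level analysis on a collection.

    A failed stage is recorded as a finding; independent later stages
    still run.  Output is deterministic given the input collection and
    configuration.
    """
    cfg = config or PipelineConfig()
    findings = list(validate_collection(collection))
    stocks = collection.stocks()
    interval = (
        CommonInterval(*cfg.interval).validate() if cfg.interval is not None else None
    )

    # -- stock summary (shoot counts, ages, widths, significance letters)
    rows = []
    shoot_mean_widths: dict[str, np.ndarray] = {}
    for stock in stocks:
        group, f = shoot_label_series(collection, stock, "abcd")
        findings.extend(f)
        if not group:
            continue
        ages = np.array([len(s) for s in group], dtype=float)
        widths = np.array([float(np.mean(s.widths)) for s in group])
        shoot_mean_widths[stock] = widths
        rows.append(
            {
                "stock": stock,
                "n_shoots": len(group),
                "age_mean": float(ages.mean()),
                "age_sd": float(ages.std(ddof=1)) if len(group) > 1 else math.nan,
                "age_min": int(ages.min()),
                "age_max": int(ages.max()),
                "rw_mean": float(widths.mean()),
                "rw_sd": float(widths.std(ddof=1)) if len(group) > 1 else math.nan,
            }
        )
    stock_summary = pd.DataFrame(
        rows, columns=["stock", "n_shoots", "age_mean", "age_sd", "age_min",
                       "age_max", "rw_mean", "rw_sd"]
    )
    if len(shoot_mean_widths) >= 2:
        names = sorted(shoot_mean_widths)
        pvals = {}
        for sx, sy in itertools.combinations(names, 2):
            if len(shoot_mean_widths[sx]) >= 2 and len(shoot_mean_widths[sy]) >= 2:
                pvals[(sx, sy)] = group_ttest(
                    shoot_mean_widths[sx], shoot_mean_widths[sy]
                ).p
        letters = significance_letters(names, pvals, alpha=cfg.alpha_groups)
        stock_summary["letters"] = [
            letters.get(s, "") for s in stock_summary["stock"]
        ]

    # -- chronology homogeneity per stock and label
    hrows = []
    for stock in stocks:
        for label in cfg.labels:
            group, f = shoot_label_series(collection, stock, label)
            findings.extend(f)
            if len(group) < 2:
                continue
            try:
                st = group_stats(group, interval=interval)
            except ShrubRingError as exc:
                findings.append(
                    Finding("stats_failed", None, f"{stock}/{label}: {exc}")
                )
                continue
            hrows.append(
                {
                    "stock": stock,
                    "label": label,
                    "n_series": st.n_series,
                    "ms_percent": st.ms_percent,
                    "ac1": st.ac1,
                    "eps": st.eps,
                    "snr": st.snr,
                    "rbar": st.rbar,
                    "ev_percent": st.ev_percent,
                }
            )
    homogeneity = pd.DataFrame(
        hrows, columns=["stock", "label", "n_series", "ms_percent", "ac1", "eps",
                        "snr", "rbar", "ev_percent"]
    )

    # -- synchrony levels
    radii_within_shoot: dict[str, ComparisonReport] = {}
    shoots_within_stock: dict[str, ComparisonReport] = {}
    for stock in stocks:
        rep = compare_radii_within_shoot(collection, stock, min_overlap=cfg.min_overlap)
        radii_within_shoot[stock] = rep
        findings.extend(rep.findings)
        rep = compare_shoots_within_stock(
            collection, stock, labels=cfg.labels, min_overlap=cfg.min_overlap
        )
        shoots_within_stock[stock] = rep
        findings.extend(rep.findings)
    stock_synchrony = None
    if len(stocks) >= 2:
        stock_synchrony = compare_stocks(
            collection, labels=cfg.labels, min_overlap=cfg.min_overlap
        )
        findings.extend(stock_synchrony.findings)

    # -- extreme years
    years = (
        cfg.extreme_years
        if cfg.extreme_years is not None
        else _detect_extreme_years(collection)
    )
    erows = []
    for stock in stocks:
        group, _ = shoot_label_series(collection, stock, "abcd")
        for year in years:
            try:
                res = extreme_year_test(group, year, paired=cfg.extreme_paired)
            except (SampleSizeError, ValueError) as exc:
                findings.append(Finding("extreme_year_skipped", None, str(exc)))
                continue
            erows.append(
                {
                    "stock": stock,
                    "year": res.year,
                    "n_shoots": res.n_shoots,
                    "mean_width": res.paired.mean1,
                    "prev_mean_width": res.paired.mean2,
                    "paired_t": res.paired.t,
                    "paired_p": res.paired.p,
                    "vs_all_t": res.vs_all.t,
                    "vs_all_p": res.vs_all.p,
                }
            )
    extreme = pd.DataFrame(
        erows, columns=["stock", "year", "n_shoots", "mean_width",
                        "prev_mean_width", "paired_t", "paired_p", "vs_all_t",
                        "vs_all_p"]
    )

    trends = trend_report(
        collection,
        cutoff_years=cfg.trend_cutoff,
        window=cfg.trend_window,
        deadband_frac=cfg.trend_deadband,
    )
    findings.extend(trends.findings)

    return PipelineReport(
        findings=findings,
        stock_summary=stock_summary,
        homogeneity=homogeneity,
        stock_synchrony=stock_synchrony,
        radii_within_shoot=radii_within_shoot,
        shoots_within_stock=shoots_within_stock,
        extreme_years=extreme,
        trends=trends,
    )
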