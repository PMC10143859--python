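"""Core data model for hierarchical ring-width collections.

A sampling campaign on a multi-stemmed clonal shrub yields one ring-width
series per measurement *radius* (``a`` = the longest radius, usually on the
lower side of the arched stem; ``b`` opposite; ``c``/``d`` orthogonal), up
to four radii per *shoot* (one stem disc), many shoots per *stock* (one
clonal individual) and one or more stocks per *site*.  This module holds
the atomic series type, the hierarchy-aware collection, radial averaging
and structural validation.

Conventions
-----------
* Ring widths are stored in micrometres (µm) as floats; an inserted
  missing ring is encoded as width ``0``.
* Series are dense in calendar years: one value per consecutive year.  A
  physically absent year is a data error, not a gap to be skipped.
* A detrended index series reuses :class:`RingWidthSeries` as its
  container (the values are then dimensionless, not µm).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping
from typing import Iterator, NamedTuple

import numpy as np

from .errors import AlignmentError, IntervalError

#: Single-radius labels in measurement order.
RADIUS_LABELS = ("a", "b", "c", "d")
#: Radial combinations: means of opposite radii and of all four radii.
COMBINATION_LABELS = ("ab", "cd", "abcd")


class CommonInterval(NamedTuple):
    """Closed calendar-year interval ``[start_year, end_year]``."""

    start_year: int
    end_year: int

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    def validate(self) -> "CommonInterval":
        if self.start_year > self.end_year:
            raise IntervalError(
                f"start_year {self.start_year} > end_year {self.end_year}"
            )
        return self


@dataclasses.dataclass(frozen=True, eq=False)
class RingWidthSeries:
    """One dated radius measurement sequence with hierarchy labels.

    Parameters
    ----------
    series_id
        Unique identifier (by the package's Tucson convention: two-char
        site, one-char stock index, two-char shoot index, radius letter).
    site, stock, shoot
        Hierarchy labels.  ``stock`` is site-qualified (e.g. ``"WE1"``).
    radius_label
        One of ``a``–``d``, a combination tag (``ab``, ``cd``, ``abcd``)
        or ``"mean"`` for derived averages.
    first_year
        Calendar year of the first ring.
    widths
        Ring widths in µm, one per consecutive year; ``0`` encodes an
        inserted missing ring.  Kept read-only after construction.
    """

    series_id: str
    site: str
    stock: str
    shoot: str
    radius_label: str
    first_year: int
    widths: np.ndarray

    def __post_init__(self) -> None:
        w = np.array(self.widths, dtype=float)
        if w.ndim != 1:
            raise ValueError("widths must be one-dimensional")
        if w.size < 2:
            raise ValueError("a ring-width series needs at least 2 rings")
        w.flags.writeable = False
        object.__setattr__(self, "widths", w)
        object.__setattr__(self, "first_year", int(self.first_year))

    # -- basic geometry -------------------------------------------------
    def __len__(self) -> int:
        return int(self.widths.size)

    @property
    def last_year(self) -> int:
        return self.first_year + len(self) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    @property
    def interval(self) -> CommonInterval:
        return CommonInterval(self.first_year, self.last_year)

    def covers(self, interval: CommonInterval) -> bool:
        return (
            self.first_year <= interval.start_year
            and self.last_year >= interval.end_year
        )

    # -- derivation -----------------------------------------------------
    def crop(self, start_year: int, end_year: int) -> "RingWidthSeries":
        """Restrict to ``[start_year, end_year]`` (must be covered)."""
        if start_year > end_year:
            raise IntervalError(f"start {start_year} > end {end_year}")
        if not self.covers(CommonInterval(start_year, end_year)):
            raise IntervalError(
                f"{self.series_id}: [{start_year}, {end_year}] not covered by "
                f"[{self.first_year}, {self.last_year}]"
            )
        i = start_year - self.first_year
        return self.with_values(
            self.widths[i : i + end_year - start_year + 1], first_year=start_year
        )

    def with_values(
        self,
        values: np.ndarray,
        *,
        series_id: str | None = None,
        radius_label: str | None = None,
        first_year: int | None = None,
    ) -> "RingWidthSeries":
        """Copy of this series with new values, keeping hierarchy labels."""
        return RingWidthSeries(
            series_id=series_id if series_id is not None else self.series_id,
            site=self.site,
            stock=self.stock,
            shoot=self.shoot,
            radius_label=(
                radius_label if radius_label is not None else self.radius_label
            ),
            first_year=first_year if first_year is not None else self.first_year,
            widths=values,
        )

    # -- equality -------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RingWidthSeries):
            return NotImplemented
        return (
            self.series_id == other.series_id
            and self.site == other.site
            and self.stock == other.stock
            and self.shoot == other.shoot
            and self.radius_label == other.radius_label
            and self.first_year == other.first_year
            and np.array_equal(self.widths, other.widths)
        )

    def __hash__(self) -> int:
        return hash((self.series_id, self.first_year, len(self)))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"RingWidthSeries({self.series_id!r}, {self.site}/{self.stock}/"
            f"{self.shoot}/{self.radius_label}, {self.first_year}-"
            f"{self.last_year}, n={len(self)})"
        )


class SeriesCollection:
    """A set of :class:`RingWidthSeries` with hierarchy-aware selection.

    Invariants enforced on insertion: unique ``series_id`` and at most one
    series per ``(site, stock, shoot, radius_label)`` cell.  Iteration is
    in sorted ``series_id`` order so downstream reports are deterministic.
    """

    def __init__(self, series: Iterable[RingWidthSeries] = ()) -> None:
        self._by_id: dict[str, RingWidthSeries] = {}
        self._cells: set[tuple[str, str, str, str]] = set()
        for s in series:
            self.add(s)

    def add(self, s: RingWidthSeries) -> None:
        if s.series_id in self._by_id:
            raise ValueError(f"duplicate series_id {s.series_id!r}")
        cell = (s.site, s.stock, s.shoot, s.radius_label)
        if cell in self._cells:
            raise ValueError(f"duplicate hierarchy cell {cell}")
        self._by_id[s.series_id] = s
        self._cells.add(cell)

    # -- container protocol --------------------------------------------
    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[RingWidthSeries]:
        for sid in sorted(self._by_id):
            yield self._by_id[sid]

    def __contains__(self, series_id: str) -> bool:
        return series_id in self._by_id

    def __getitem__(self, series_id: str) -> RingWidthSeries:
        return self._by_id[series_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SeriesCollection):
            return NotImplemented
        return list(self) == list(other)

    # -- hierarchy queries ----------------------------------------------
    @property
    def ids(self) -> list[str]:
        return sorted(self._by_id)

    def sites(self) -> list[str]:
        return sorted({s.site for s in self})

    def stocks(self) -> list[str]:
        return sorted({s.stock for s in self})

    def shoots(self, stock: str | None = None) -> list[str]:
        return sorted(
            {s.shoot for s in self if stock is None or s.stock == stock}
        )

    def radius_labels(self) -> list[str]:
        return sorted({s.radius_label for s in self})

    def select(
        self,
        *,
        site: str | None = None,
        stock: str | None = None,
        shoot: str | None = None,
        radius: str | None = None,
    ) -> "SeriesCollection":
        """Sub-collection matching all given hierarchy labels."""
        return SeriesCollection(
            s
            for s in self
            if (site is None or s.site == site)
            and (stock is None or s.stock == stock)
            and (shoot is None or s.shoot == shoot)
            and (radius is None or s.radius_label == radius)
        )

    def by_shoot(self, stock: str) -> dict[str, dict[str, RingWidthSeries]]:
        """Map shoot -> {radius_label -> series} for one stock."""
        out: dict[str, dict[str, RingWidthSeries]] = {}
        for s in self:
            if s.stock == stock:
                out.setdefault(s.shoot, {})[s.radius_label] = s
        return out

    def common_interval(self) -> CommonInterval | None:
        """Widest interval covered by every series, or None if empty."""
        if not self._by_id:
            return None
        start = max(s.first_year for s in self)
        end = min(s.last_year for s in self)
        if start > end:
            return None
        return CommonInterval(start, end)


def overlap(
    x: RingWidthSeries, y: RingWidthSeries
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shared calendar years of two series and the aligned value arrays.

    Returns ``(years, x_values, y_values)``; all three are empty when the
    series do not overlap.
    """
    start = max(x.first_year, y.first_year)
    end = min(x.last_year, y.last_year)
    if start > end:
        z = np.array([])
        return z.astype(int), z, z
    years = np.arange(start, end + 1)
    xi = start - x.first_year
    yi = start - y.first_year
    n = end - start + 1
    return years, x.widths[xi : xi + n], y.widths[yi : yi + n]


def combine_radii(
    shoot_series: Mapping[str, RingWidthSeries], subset: str
) -> RingWidthSeries:
    """Average the widths of two or four radii of one shoot.

    ``subset`` is ``"ab"``, ``"cd"`` or ``"abcd"``.  The member series
    must share an identical year support (same disc, same rings); zeros
    from inserted missing rings enter the mean as true zeros.  Averaging
    is done on widths (µm) — index-level averaging, when wanted, happens
    after detrending.
    """
    if subset not in COMBINATION_LABELS:
        raise ValueError(f"subset must be one of {COMBINATION_LABELS}, got {subset!r}")
    members = []
    for lab in subset:
        if lab not in shoot_series:
            raise ValueError(f"radius {lab!r} missing for combination {subset!r}")
        members.append(shoot_series[lab])
    first = members[0]
    for m in members[1:]:
        if m.first_year != first.first_year or len(m) != len(first):
            raise AlignmentError(
                f"radii {first.series_id} and {m.series_id} differ in year "
                "support; crop to common years before combining"
            )
    mean = np.mean([m.widths for m in members], axis=0)
    sid = first.series_id
    if sid.endswith(first.radius_label):
        sid = sid[: len(sid) - len(first.radius_label)] + subset
    else:
        sid = f"{sid}_{subset}"
    return first.with_values(mean, series_id=sid, radius_label=subset)


@dataclasses.dataclass(frozen=True)
class Finding:
    """One structured validation finding (the validator never raises)."""

    kind: str
    series_id: str | None
    message: str


def validate_collection(
    collection: SeriesCollection | Iterable[RingWidthSeries],
) -> list[Finding]:
    """Structural screen of a collection; an empty list means valid.

    Reported kinds: ``duplicate_id``, ``duplicate_cell``,
    ``negative_width``, ``non_finite`` and ``singleton_shoot`` (a shoot
    represented by a single radius, which excludes it from radial
    comparisons).
    """
    series = list(collection)
    findings: list[Finding] = []

    seen_ids: set[str] = set()
    seen_cells: set[tuple[str, str, str, str]] = set()
    shoot_counts: dict[tuple[str, str, str], int] = {}
    for s in series:
        if s.series_id in seen_ids:
            findings.append(
                Finding("duplicate_id", s.series_id, "series_id occurs more than once")
            )
        seen_ids.add(s.series_id)
        cell = (s.site, s.stock, s.shoot, s.radius_label)
        if cell in seen_cells:
            findings.append(
                Finding("duplicate_cell", s.series_id, f"duplicate hierarchy cell {cell}")
            )
        seen_cells.add(cell)
        key = (s.site, s.stock, s.shoot)
        shoot_counts[key] = shoot_counts.get(key, 0) + 1
        if np.any(s.widths < 0):
            findings.append(
                Finding("negative_width", s.series_id, "negative ring width")
            )
        if not np.all(np.isfinite(s.widths)):
            findings.append(
                Finding("non_finite", s.series_id, "non-finite ring width (year gap?)")
            )
    for (site, stock, shoot), n in sorted(shoot_counts.items()):
        if n == 1:
            findings.append(
                Finding(
                    "singleton_shoot",
                    None,
                    f"shoot {site}/{stock}/{shoot} has a single series",
                )
            )
    return findings
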