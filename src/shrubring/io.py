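"""Readers and writers: Tucson decadal (.rwl) and delimited wide tables.

Tucson format
-------------
Each line carries an 8-character series ID, the calendar year of the
line's first value, and up to ten integer widths.  A series is terminated
by a sentinel: ``-9999`` for data in 0.001 mm (= 1 µm) units, ``999`` for
0.01 mm units.  Internally all widths are µm, so 0.001 mm values pass
through unchanged and 0.01 mm values are multiplied by ten.

Hierarchy labels are parsed from the ID by this package's convention —
characters 1–2 site, 3 stock index, 4–5 shoot index, 6+ radius letter or
combination tag (e.g. ``WE101a`` = site WE, stock WE1, shoot 01, radius
a).  An explicit metadata sidecar (delimited, columns ``series_id, site,
stock, shoot, radius``) overrides ID parsing, since 8-character IDs
cannot carry rich metadata portably.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import TextIO

import numpy as np
import pandas as pd

from .errors import FormatError, NamingError
from .series import RADIUS_LABELS, COMBINATION_LABELS, RingWidthSeries, SeriesCollection

def parse_series_id(series_id: str) -> dict[str, str]:
    """Split an ID into hierarchy labels by the package convention.

    Falls back to empty labels for IDs shorter than six characters; an
    unrecognized tail becomes the radius label verbatim.
    """
    sid = series_id.strip()
    site = sid[0:2]
    stock_ix = sid[2:3]
    shoot = sid[3:5]
    tail = sid[5:].strip().lower()
    if tail in COMBINATION_LABELS or tail == "mean":
        radius = tail  # combination tags win over a bare position-6 letter
    elif tail and tail[0] in RADIUS_LABELS:
        radius = tail[0]
    else:
        radius = tail
    return {
        "site": site,
        "stock": site + stock_ix,
        "shoot": shoot,
        "radius": radius,
    }


def _as_text_stream(source) -> TextIO:
    if hasattr(source, "read"):
        return source
    if isinstance(source, Path):
        return open(source, "r")
    if isinstance(source, str):
        # a single line with no newline may be a path; otherwise content
        if source and "\n" not in source and Path(source).exists():
            return open(source, "r")
        return _io.StringIO(source)
    raise TypeError(f"cannot read from {type(source).__name__}")


def read_metadata(source) -> pd.DataFrame:
    """Read a metadata sidecar (any common delimiter) into a DataFrame."""
    stream = _as_text_stream(source)
    df = pd.read_csv(stream, sep=None, engine="python", dtype=str)
    required = {"series_id", "site", "stock", "shoot", "radius"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"metadata sidecar missing columns {sorted(missing)}")
    return df.set_index("series_id")


def _labels_for(series_id: str, metadata: pd.DataFrame | None) -> dict[str, str]:
    if metadata is not None and series_id in metadata.index:
        row = metadata.loc[series_id]
        return {
            "site": str(row["site"]),
            "stock": str(row["stock"]),
            "shoot": str(row["shoot"]),
            "radius": str(row["radius"]),
        }
    return parse_series_id(series_id)


def read_rwl(source, metadata=None) -> SeriesCollection:
    """Parse Tucson decadal text into a :class:`SeriesCollection`.

    ``source`` may be a path, a string of file content or an open text
    stream; ``metadata`` an optional sidecar (path, stream or DataFrame).
    """
    if metadata is not None and not isinstance(metadata, pd.DataFrame):
        metadata = read_metadata(metadata)
    stream = _as_text_stream(source)

    open_records: dict[str, dict] = {}  # id -> {first_year, values}
    finished: list[RingWidthSeries] = []

    for line_no, raw in enumerate(stream.read().splitlines(), start=1):
        line = raw.rstrip()
        if not line.strip():
            continue
        sid = line[:8].strip()
        fields = line[8:].split()
        if not sid or not fields:
            raise FormatError("expected 8-char ID and a decade year", line_no)
        try:
            year = int(fields[0])
            values = [int(f) for f in fields[1:]]
        except ValueError:
            raise FormatError(f"non-numeric field in {fields!r}", line_no) from None

        rec = open_records.get(sid)
        if rec is None:
            rec = open_records[sid] = {"first_year": year, "values": []}
        else:
            expected = rec["first_year"] + len(rec["values"])
            if year < expected:
                raise FormatError(
                    f"series {sid!r}: decade {year} overlaps data up to "
                    f"{expected - 1}",
                    line_no,
                )
            if year > expected:
                raise FormatError(
                    f"series {sid!r}: decade {year} leaves a gap after "
                    f"{expected - 1}",
                    line_no,
                )
        for v in values:
            # only -9999 terminates eagerly: 999 is a legal µm width, so it
            # is resolved as the 0.01 mm sentinel only at end of input
            if v == -9999:
                finished.append(
                    _finish_record(sid, rec, factor=1.0, metadata=metadata)
                )
                del open_records[sid]
                break
            rec["values"].append(v)

    for sid in sorted(open_records):
        rec = open_records[sid]
        if rec["values"] and rec["values"][-1] == 999:
            rec["values"].pop()
            finished.append(_finish_record(sid, rec, factor=10.0, metadata=metadata))
        else:
            raise FormatError(f"unterminated series (no sentinel): {sid}")
    return SeriesCollection(finished)


def _finish_record(sid: str, rec: dict, factor: float, metadata) -> RingWidthSeries:
    widths = np.asarray(rec["values"], dtype=float) * factor
    labels = _labels_for(sid, metadata)
    return RingWidthSeries(
        series_id=sid,
        site=labels["site"],
        stock=labels["stock"],
        shoot=labels["shoot"],
        radius_label=labels["radius"],
        first_year=rec["first_year"],
        widths=widths,
    )


def write_rwl(
    collection: SeriesCollection, stream: TextIO | None = None, precision: str = "0.001mm"
) -> str | None:
    """Emit a collection as Tucson decadal text.

    Default precision is 0.001 mm (sentinel ``-9999``), matching 1 µm
    measurement resolution; ``precision="0.01mm"`` divides by ten and
    terminates with ``999``.  Returns the text when ``stream`` is None.
    """
    if precision == "0.001mm":
        divisor, sentinel = 1.0, -9999
    elif precision == "0.01mm":
        divisor, sentinel = 10.0, 999
    else:
        raise ValueError(f"unknown precision {precision!r}")

    lines: list[str] = []
    for s in collection:
        sid = s.series_id
        if len(sid) > 8:
            raise NamingError(f"series_id {sid!r} longer than 8 characters")
        scaled = s.widths / divisor
        ints = np.rint(scaled).astype(int)
        year = s.first_year
        values = list(ints) + [sentinel]
        pos = 0
        while pos < len(values):
            # fill to the end of the current decade (10 * (year // 10) + 9)
            room = 10 - (year % 10)
            chunk = values[pos : pos + room]
            body = "".join(f"{v:>6d}" for v in chunk)
            lines.append(f"{sid:<8}{year:>4d}{body}")
            n_data = min(room, len(values) - pos)
            pos += n_data
            year += n_data
    text = "\n".join(lines) + ("\n" if lines else "")
    if stream is None:
        return text
    stream.write(text)
    return None


def to_frame(collection: SeriesCollection) -> pd.DataFrame:
    """Wide table: index = calendar year, one column per series (µm)."""
    cols = {}
    for s in collection:
        cols[s.series_id] = pd.Series(s.widths, index=s.years)
    df = pd.DataFrame(cols)
    df.index.name = "year"
    return df.sort_index()


def metadata_frame(collection: SeriesCollection) -> pd.DataFrame:
    """Sidecar table with one row of hierarchy labels per series."""
    rows = [
        {
            "series_id": s.series_id,
            "site": s.site,
            "stock": s.stock,
            "shoot": s.shoot,
            "radius": s.radius_label,
        }
        for s in collection
    ]
    return pd.DataFrame(rows, columns=["series_id", "site", "stock", "shoot", "radius"])


def write_table(
    collection: SeriesCollection, stream: TextIO | None = None, sep: str = "\t"
) -> str | None:
    """Write the wide year × series table as delimited text."""
    df = to_frame(collection)
    text = df.to_csv(sep=sep, float_format="%.6g")
    if stream is None:
        return text
    stream.write(text)
    return None


def read_table(source, metadata=None, sep: str | None = None) -> SeriesCollection:
    """Read a wide delimited table (year column + one column per series).

    Each series column must be a single contiguous block of numbers; an
    interior hole is a format error (a missing ring is ``0``, not blank).
    """
    if metadata is not None and not isinstance(metadata, pd.DataFrame):
        metadata = read_metadata(metadata)
    stream = _as_text_stream(source)
    df = pd.read_csv(stream, sep=sep, engine="python" if sep is None else "c")
    if df.columns[0].lower() != "year":
        raise FormatError("first column of a wide table must be 'year'")
    df = df.set_index(df.columns[0])
    years = df.index.to_numpy()
    if not np.array_equal(years, np.arange(years[0], years[0] + len(years))):
        raise FormatError("year column must be consecutive integers")

    out = []
    for sid in df.columns:
        col = df[sid].to_numpy(dtype=float)
        valid = np.isfinite(col)
        if not valid.any():
            continue
        first, last = np.nonzero(valid)[0][[0, -1]]
        if not valid[first : last + 1].all():
            raise FormatError(f"series {sid!r} has an interior year gap")
        labels = _labels_for(str(sid), metadata)
        out.append(
            RingWidthSeries(
                series_id=str(sid),
                site=labels["site"],
                stock=labels["stock"],
                shoot=labels["shoot"],
                radius_label=labels["radius"],
                first_year=int(years[first]),
                widths=col[first : last + 1],
            )
        )
    return SeriesCollection(out)
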