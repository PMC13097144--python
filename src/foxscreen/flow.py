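"""Event-level flow data structures, FCS 3.0/3.1 I/O, compensation, and
continuous-acquisition stream segmentation.

The :class:`EventTable` is the package's core container: an ordered channel
list plus an ``(n_events, n_channels)`` value matrix, with an optional
per-event timestamp vector (seconds) and an optional ground-truth label frame
attached by the simulator.  FCS support is deliberately minimal — list-mode
floating-point data only — but round-trips everything this pipeline needs.
"""

from __future__ import annotations

import re
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EventTable",
    "PlateLayout",
    "SpilloverMatrix",
    "SegmentationResult",
    "SegmentationError",
    "FcsFormatError",
    "read_fcs",
    "write_fcs",
    "apply_compensation",
    "segment_stream",
    "split_stream",
    "validate_segmentation",
    "SegmentationValidation",
    "ROLES",
    "well_sort_key",
]

ROLES = frozenset({"compound", "dmso_positive", "cd4_only_negative", "unstained"})

_WELL_RE = re.compile(r"^([A-P])(\d{1,2})$")

#: scatter / housekeeping channels never touched by compensation
_NON_FLUOR_PREFIXES = ("FSC", "SSC", "Time")


def well_sort_key(well: str) -> tuple[int, int]:
    """Row-major sort key for a 16x24 well coordinate like ``'B07'``."""
    m = _WELL_RE.match(well)
    if m is None:
        raise ValueError(f"invalid 384-well coordinate: {well!r}")
    row = ord(m.group(1)) - ord("A")
    col = int(m.group(2))
    if not 1 <= col <= 24:
        raise ValueError(f"column out of range for a 16x24 plate: {well!r}")
    return row, col


@dataclass
class EventTable:
    """Per-event channel measurements for one well or one acquisition stream."""

    channels: list[str]
    events: np.ndarray
    time: np.ndarray | None = None
    source: str = ""
    labels: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float)
        if self.events.ndim != 2:
            raise ValueError("events must be a 2-D (n_events, n_channels) array")
        if self.events.shape[1] != len(self.channels):
            raise ValueError(
                f"events has {self.events.shape[1]} columns for "
                f"{len(self.channels)} channels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel names")
        if self.time is not None:
            self.time = np.asarray(self.time, dtype=float)
            if self.time.shape != (self.events.shape[0],):
                raise ValueError("time vector length does not match event count")
            if self.time.size and np.any(np.diff(self.time) < 0):
                raise ValueError("time must be non-decreasing")
        if self.labels is not None and len(self.labels) != self.events.shape[0]:
            raise ValueError("labels length does not match event count")

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in table ({self.channels})") from None

    def __getitem__(self, name: str) -> np.ndarray:
        return self.events[:, self.channel_index(name)]

    def subset(self, index) -> "EventTable":
        """Row-subset (mask or integer index) preserving time and labels."""
        labels = None
        if self.labels is not None:
            if isinstance(index, slice):
                labels = self.labels.iloc[index]
            else:
                arr = np.asarray(index)
                labels = (
                    self.labels.iloc[np.flatnonzero(arr)]
                    if arr.dtype == bool
                    else self.labels.iloc[arr]
                )
            labels = labels.reset_index(drop=True)
        return EventTable(
            channels=list(self.channels),
            events=self.events[index],
            time=None if self.time is None else self.time[index],
            source=self.source,
            labels=labels,
        )

    def to_dataframe(self, include_labels: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(self.events, columns=self.channels)
        if self.time is not None:
            df["time_s"] = self.time
        if include_labels and self.labels is not None:
            df = pd.concat([df, self.labels.reset_index(drop=True)], axis=1)
        return df


# ---------------------------------------------------------------------------
# Plate layout
# ---------------------------------------------------------------------------


@dataclass
class WellEntry:
    role: str
    compound_id: str = ""
    concentration_um: float = float("nan")

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown well role {self.role!r}; expected one of {sorted(ROLES)}")


@dataclass
class PlateLayout:
    """Well -> role/compound/concentration map for a 384-well plate."""

    plate_id: str
    wells: dict[str, WellEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for well in self.wells:
            well_sort_key(well)  # validates coordinates

    def acquisition_order(self, serpentine: bool = False) -> list[str]:
        """Wells in acquisition order; default row-major A1..A24, B1.."""
        ordered = sorted(self.wells, key=well_sort_key)
        if not serpentine:
            return ordered
        out: list[str] = []
        by_row: dict[int, list[str]] = {}
        for w in ordered:
            by_row.setdefault(well_sort_key(w)[0], []).append(w)
        for row in sorted(by_row):
            ws = by_row[row]
            out.extend(ws if row % 2 == 0 else ws[::-1])
        return out

    def wells_with_role(self, role: str) -> list[str]:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        return [w for w in self.acquisition_order() if self.wells[w].role == role]

    @classmethod
    def from_csv(cls, path, plate_id: str | None = None) -> "PlateLayout":
        df = pd.read_csv(path, dtype={"well": str, "role": str, "compound_id": str})
        required = {"well", "role"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"layout CSV missing columns: {sorted(missing)}")
        wells = {}
        for _, row in df.iterrows():
            conc = row.get("concentration_um", float("nan"))
            cid = row.get("compound_id", "")
            cid = "" if pd.isna(cid) else str(cid)
            wells[str(row["well"])] = WellEntry(
                role=str(row["role"]),
                compound_id=cid,
                concentration_um=float(conc) if pd.notna(conc) else float("nan"),
            )
        if plate_id is None:
            plate_id = str(df["plate_id"].iloc[0]) if "plate_id" in df.columns else Path(path).stem
        return cls(plate_id=plate_id, wells=wells)

    def to_csv(self, path) -> None:
        rows = [
            {
                "plate_id": self.plate_id,
                "well": w,
                "role": e.role,
                "compound_id": e.compound_id,
                "concentration_um": e.concentration_um,
            }
            for w, e in sorted(self.wells.items(), key=lambda kv: well_sort_key(kv[0]))
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# FCS 3.0 / 3.1 list-mode I/O
# ---------------------------------------------------------------------------


class FcsFormatError(ValueError):
    """Malformed FCS header or keyword block."""

    def __init__(self, message: str, keyword: str | None = None):
        super().__init__(message)
        self.keyword = keyword


_HEADER_LEN = 58
_TIME_CHANNEL = "Time"
_REQUIRED_KEYWORDS = ("$PAR", "$TOT", "$DATATYPE", "$BYTEORD", "$MODE")


def write_fcs(table: EventTable, path, timestep: float = 0.01) -> None:
    """Write an :class:`EventTable` as a single-dataset FCS 3.1 file.

    Data are stored as little-endian float32 in list mode.  When the table
    carries a time vector it is appended as a ``Time`` channel in units of
    ``timestep`` seconds (recorded in ``$TIMESTEP``).
    """
    channels = list(table.channels)
    data = table.events.astype("<f4")
    if table.time is not None:
        channels.append(_TIME_CHANNEL)
        ticks = (table.time / timestep).astype("<f4")
        data = np.column_stack([data, ticks]).astype("<f4")
    n_events, n_par = data.shape

    delim = "/"
    for name in channels:
        if delim in name:
            raise ValueError(f"channel name may not contain {delim!r}: {name!r}")

    keywords: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        ("$BEGINDATA", "{begindata:>10d}"),
        ("$ENDDATA", "{enddata:>10d}"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_events)),
    ]
    if table.time is not None:
        keywords.append(("$TIMESTEP", repr(float(timestep))))
    for i, name in enumerate(channels, start=1):
        rng = float(np.max(data[:, i - 1], initial=0.0))
        keywords.extend(
            [
                (f"$P{i}N", name),
                (f"$P{i}B", "32"),
                (f"$P{i}E", "0,0"),
                (f"$P{i}R", str(int(np.ceil(rng)) + 1)),
            ]
        )

    def render(begindata: int, enddata: int) -> bytes:
        parts = [delim]
        for key, val in keywords:
            val = val.format(begindata=begindata, enddata=enddata)
            parts.append(f"{key}{delim}{val}{delim}")
        return "".join(parts).encode("ascii")

    # fixed-width placeholders make the TEXT length independent of the offsets
    text_probe = render(0, 0)
    text_begin = _HEADER_LEN
    text_end = text_begin + len(text_probe) - 1
    data_begin = text_end + 1
    data_end = data_begin + data.nbytes - 1
    text = render(data_begin, data_end)
    assert len(text) == len(text_probe)

    header = (
        b"FCS3.1    "
        + f"{text_begin:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + f"{data_begin:>8d}".encode()
        + f"{data_end:>8d}".encode()
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    assert len(header) == _HEADER_LEN
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FcsFormatError("empty TEXT segment")
    delim = raw[0:1].decode("latin-1")
    body = raw.decode("latin-1")
    # double-delimiter escaping per the FCS standard
    parts = body.strip(delim).replace(delim * 2, "\x00").split(delim)
    parts = [p.replace("\x00", delim) for p in parts]
    if len(parts) % 2 != 0:
        parts = parts[:-1]
    return {parts[i].strip().upper(): parts[i + 1] for i in range(0, len(parts), 2)}


def read_fcs(path) -> EventTable:
    """Read a single-dataset FCS 3.0/3.1 list-mode file.

    Supports float (``$DATATYPE`` F/D) data in either byte order.  A ``Time``
    channel, when present, is moved to ``EventTable.time`` scaled by
    ``$TIMESTEP`` (seconds).
    """
    blob = Path(path).read_bytes()
    if len(blob) < _HEADER_LEN:
        raise FcsFormatError("file too short for an FCS header")
    version = blob[:6].decode("latin-1", errors="replace")
    if not version.startswith("FCS3"):
        raise FcsFormatError(f"unsupported FCS version {version!r}")
    try:
        text_begin = int(blob[10:18])
        text_end = int(blob[18:26])
        data_begin = int(blob[26:34])
        data_end = int(blob[34:42])
    except ValueError as exc:
        raise FcsFormatError(f"non-numeric header offsets: {exc}") from exc

    kw = _parse_text_segment(blob[text_begin : text_end + 1])
    for key in _REQUIRED_KEYWORDS:
        if key not in kw:
            raise FcsFormatError(f"missing required keyword {key}", keyword=key)

    if kw["$MODE"].upper() != "L":
        raise FcsFormatError(f"unsupported $MODE {kw['$MODE']!r}", keyword="$MODE")
    datatype = kw["$DATATYPE"].upper()
    if datatype not in ("F", "D"):
        raise FcsFormatError(f"unsupported $DATATYPE {datatype!r}", keyword="$DATATYPE")
    byteord = kw["$BYTEORD"].replace(" ", "")
    if byteord in ("1,2,3,4", "1,2"):
        endian = "<"
    elif byteord in ("4,3,2,1", "2,1"):
        endian = ">"
    else:
        raise FcsFormatError(f"unsupported $BYTEORD {byteord!r}", keyword="$BYTEORD")

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    if data_begin == 0 and "$BEGINDATA" in kw:
        data_begin = int(kw["$BEGINDATA"])
        data_end = int(kw["$ENDDATA"])
    width = 4 if datatype == "F" else 8
    expected = n_par * n_tot * width
    raw = blob[data_begin : data_begin + expected]
    if len(raw) != expected:
        raise FcsFormatError(
            f"DATA segment holds {len(raw)} bytes, expected {expected} "
            f"($PAR={n_par}, $TOT={n_tot})"
        )
    dtype = np.dtype(f"{endian}f{width}")
    data = np.frombuffer(raw, dtype=dtype).reshape(n_tot, n_par).astype(float)

    channels = []
    for i in range(1, n_par + 1):
        key = f"$P{i}N"
        if key not in kw:
            raise FcsFormatError(f"missing required keyword {key}", keyword=key)
        channels.append(kw[key])

    time = None
    if _TIME_CHANNEL in channels:
        if "$TIMESTEP" not in kw:
            raise FcsFormatError(
                "file has a Time channel but no $TIMESTEP keyword", keyword="$TIMESTEP"
            )
        ti = channels.index(_TIME_CHANNEL)
        time = data[:, ti] * float(kw["$TIMESTEP"])
        data = np.delete(data, ti, axis=1)
        channels = [c for c in channels if c != _TIME_CHANNEL]

    return EventTable(channels=channels, events=data, time=time, source=str(path))


# ---------------------------------------------------------------------------
# Compensation
# ---------------------------------------------------------------------------


@dataclass
class SpilloverMatrix:
    """Square spillover matrix; ``matrix[i, j]`` is the fraction of channel
    ``channels[i]``'s true signal observed in ``channels[j]``."""

    channels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.channels)
        if self.matrix.shape != (n, n):
            raise ValueError("spillover matrix must be square over its channels")
        if not np.allclose(np.diag(self.matrix), 1.0):
            raise ValueError("spillover matrix diagonal must be 1")
        if np.linalg.cond(self.matrix) > 1e12:
            raise ValueError("spillover matrix is singular or near-singular")

    @classmethod
    def identity(cls, channels: list[str]) -> "SpilloverMatrix":
        return cls(list(channels), np.eye(len(channels)))

    @classmethod
    def from_csv(cls, path) -> "SpilloverMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("spillover CSV must have identical row/column channel names")
        return cls(list(df.columns), df.to_numpy(dtype=float))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.channels, columns=self.channels).to_csv(path)


def apply_compensation(table: EventTable, spill: SpilloverMatrix) -> EventTable:
    """Linear unmixing: replaces the spill channels by ``observed @ inv(spill)``.

    Scatter and time columns are untouched.  Negative compensated values are
    retained.
    """
    idx = [table.channel_index(c) for c in spill.channels]  # KeyError if absent
    for c in spill.channels:
        if c.startswith(_NON_FLUOR_PREFIXES):
            raise ValueError(f"refusing to compensate non-fluorescence channel {c!r}")
    observed = table.events[:, idx]
    compensated = np.linalg.solve(spill.matrix.T, observed.T).T
    events = table.events.copy()
    events[:, idx] = compensated
    return EventTable(
        channels=list(table.channels),
        events=events,
        time=None if table.time is None else table.time.copy(),
        source=table.source,
        labels=table.labels,
    )


# ---------------------------------------------------------------------------
# Stream segmentation
# ---------------------------------------------------------------------------


class SegmentationError(RuntimeError):
    """Raised when burst detection disagrees with the expected well count."""

    def __init__(self, message: str, found: int, expected: int, diagnostics: dict):
        super().__init__(message)
        self.found = found
        self.expected = expected
        self.diagnostics = diagnostics


@dataclass
class SegmentationResult:
    """Index ranges (into the time-sorted stream) for every identified well."""

    well_ranges: dict[str, tuple[int, int]]
    discarded: int
    diagnostics: dict

    @property
    def assigned(self) -> int:
        return sum(hi - lo for lo, hi in self.well_ranges.values())


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index ranges of True runs."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[0::2], edges[1::2]))


def segment_stream(
    stream: EventTable,
    layout: PlateLayout,
    profile=None,
    *,
    bin_seconds: float = 0.2,
    rate_fraction: float = 0.1,
    min_gap_seconds: float = 0.5,
    min_burst_seconds: float = 1.0,
    serpentine: bool = False,
    acquisition_order: list[str] | None = None,
) -> SegmentationResult:
    """Segment a continuous acquisition stream into per-well event ranges.

    Event rate is binned at ``bin_seconds``; bins below ``rate_fraction`` of
    the median non-empty bin rate are "low", and low runs lasting at least
    ``min_gap_seconds`` are gaps (shakes, rinses, inter-well up time).  The
    inter-gap bursts are mapped 1:1, in acquisition order, onto the layout
    wells; a count mismatch raises :class:`SegmentationError` with
    diagnostics.  ``profile`` is accepted for interface symmetry with the
    simulator and recorded in the diagnostics only.
    """
    if stream.time is None:
        raise ValueError("stream has no time channel; cannot segment")
    t = stream.time
    if np.any(np.diff(t) < 0):
        raise ValueError("stream time must be non-decreasing")
    order = acquisition_order if acquisition_order is not None else layout.acquisition_order(serpentine)
    expected = len(order)
    if expected == 0:
        raise ValueError("layout has no wells")

    edges = np.arange(t[0], t[-1] + 2 * bin_seconds, bin_seconds)
    counts, _ = np.histogram(t, bins=edges)
    rates = counts / bin_seconds
    busy = rates[rates > 0]
    if busy.size == 0:
        raise ValueError("stream contains no events")
    threshold = rate_fraction * float(np.median(busy))
    low = rates < threshold

    min_gap_bins = max(1, int(np.ceil(min_gap_seconds / bin_seconds - 1e-9)))
    gap_runs = [(a, b) for a, b in _runs(low) if b - a >= min_gap_bins]
    # refine gap edges: low-but-nonempty boundary bins belong to the adjacent
    # burst (a well's first/last straggler events), not to the gap
    refined = []
    for a, b in gap_runs:
        a0, b0 = a, b
        while a < b and counts[a] > 0:
            a += 1
        while b > a and counts[b - 1] > 0:
            b -= 1
        if a == b:  # every gap bin holds events; split at the middle
            a = b = (a0 + b0) // 2
        refined.append((a, b))
    gap_runs = refined

    # bursts span the full region between adjacent gaps (so no edge events are
    # shaved off); spans with no busy bin are not wells
    bursts: list[tuple[float, float]] = []
    cursor = 0
    bounds = gap_runs + [(len(rates), len(rates))]
    for a, b in bounds:
        if np.any(~low[cursor:a]):
            bursts.append((edges[cursor], edges[a]))
        cursor = b
    # a rate blip inside a long pause is not a well; real bursts last a sip
    n_noise_bursts = sum(1 for s, e in bursts if e - s < min_burst_seconds)
    bursts = [(s, e) for s, e in bursts if e - s >= min_burst_seconds]

    gap_durations = [(b - a) * bin_seconds for a, b in gap_runs]
    diagnostics = {
        "bin_seconds": bin_seconds,
        "rate_threshold": threshold,
        "n_gaps": len(gap_runs),
        "n_noise_bursts": n_noise_bursts,
        "gap_durations": gap_durations,
        "window_durations": [e - s for s, e in bursts],
        "profile": profile,
    }
    if len(bursts) != expected:
        raise SegmentationError(
            f"detected {len(bursts)} well bursts but layout expects {expected}",
            found=len(bursts),
            expected=expected,
            diagnostics=diagnostics,
        )

    well_ranges: dict[str, tuple[int, int]] = {}
    for well, (start, end) in zip(order, bursts):
        lo = int(np.searchsorted(t, start, side="left"))
        hi = int(np.searchsorted(t, end, side="left"))
        well_ranges[well] = (lo, hi)
    assigned = sum(hi - lo for lo, hi in well_ranges.values())
    return SegmentationResult(
        well_ranges=well_ranges,
        discarded=stream.n_events - assigned,
        diagnostics=diagnostics,
    )


def split_stream(stream: EventTable, result: SegmentationResult) -> dict[str, EventTable]:
    """Materialize per-well :class:`EventTable` slices from a segmentation."""
    out = {}
    for well, (lo, hi) in result.well_ranges.items():
        sub = stream.subset(slice(lo, hi))
        sub.source = f"{stream.source}#{well}"
        out[well] = sub
    return out


@dataclass
class SegmentationValidation:
    status: str  # ok | failed | unverifiable
    control_checks: pd.DataFrame
    best_shift: int | None
    shift_violations: dict[int, int]

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def validate_segmentation(
    per_well: pd.DataFrame,
    layout: PlateLayout,
    *,
    ceiling_pct: float = 5.0,
    max_shift: int = 5,
    serpentine: bool = False,
) -> SegmentationValidation:
    """Check stain-control wells against the layout to confirm well identity.

    ``per_well`` must carry ``well``, ``cd4_pct_singlets`` and
    ``foxp3_pct_cd4`` columns (as produced by the gating summaries).  CD4-only
    wells must show FoxP3+ below ``ceiling_pct``; unstained wells must show
    both CD4+ and FoxP3+ below it.  On failure the rotation ``k`` (summary at
    order position ``i`` belongs to the layout well at position ``i + k``)
    minimizing control violations is reported.
    """
    order = layout.acquisition_order(serpentine)
    summaries = per_well.set_index("well")
    n = len(order)

    def violations(shift: int) -> tuple[int, list[dict]]:
        count = 0
        rows = []
        for i, well in enumerate(order):
            target = order[(i + shift) % n]
            role = layout.wells[target].role
            if well not in summaries.index:
                continue
            rec = summaries.loc[well]
            checks = []
            if role == "cd4_only_negative":
                checks.append(("foxp3_pct_cd4", float(rec["foxp3_pct_cd4"])))
            elif role == "unstained":
                checks.append(("cd4_pct_singlets", float(rec["cd4_pct_singlets"])))
                checks.append(("foxp3_pct_cd4", float(rec["foxp3_pct_cd4"])))
            for metric, value in checks:
                passed = bool(np.isnan(value)) or value <= ceiling_pct
                if not passed:
                    count += 1
                rows.append(
                    {"well": well, "role": role, "metric": metric, "value": value, "passed": passed}
                )
        return count, rows

    base_violations, base_rows = violations(0)
    checks_df = pd.DataFrame(base_rows, columns=["well", "role", "metric", "value", "passed"])
    if checks_df.empty:
        return SegmentationValidation(
            status="unverifiable", control_checks=checks_df, best_shift=None, shift_violations={}
        )
    shift_violations = {
        k: violations(k)[0] for k in range(-max_shift, max_shift + 1)
    }
    best_shift = min(shift_violations, key=lambda k: (shift_violations[k], abs(k)))
    status = "ok" if base_violations == 0 else "failed"
    return SegmentationValidation(
        status=status,
        control_checks=checks_df,
        best_shift=best_shift,
        shift_violations=shift_violations,
    )
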