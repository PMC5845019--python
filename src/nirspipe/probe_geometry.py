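"""Probe grid construction, channel enumeration and ROI labelling.

The default montage is a 4x5 checkerboard of 10 sources and 10 detectors
at 3 cm pitch (spanning 9 cm x 12 cm).  Every nearest-neighbour
source-detector pair at exactly 3 cm forms a measurement channel, giving
16 horizontal + 15 vertical = 31 channels.

Channel numbering convention (canonical for this package): for each
optode row from the top, first the horizontal pairs of that row
left-to-right, then the vertical pairs connecting it to the row below,
left-to-right.  This is the unique numbering of the 4x5 grid that is
consistent with the region-of-interest channel lists used by the group
statistics (low ids frontal, high ids posterior).

Coordinates are probe-plane centimetres with the origin at the top-left
optode; x increases to the subject's right, y increases toward posterior.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import pandas as pd

from .errors import FormatError, LayoutMismatchError, ParameterError

#: Inter-optode pitch in centimetres.
PITCH_CM = 3.0

#: Canonical (roi, hemisphere) -> channel-id sets for the default layout.
ROI_CHANNELS: dict[tuple[str, str], frozenset[int]] = {
    ("PFC", "left"): frozenset({1, 2, 5, 6}),
    ("PFC", "right"): frozenset({3, 4, 7, 8}),
    ("preSMA", "left"): frozenset({10, 11, 15}),
    ("preSMA", "right"): frozenset({12, 13, 17}),
    ("M1", "left"): frozenset({14, 19, 20}),
    ("M1", "right"): frozenset({18, 21, 22}),
    ("SMC", "left"): frozenset({23, 24, 28, 29}),
    ("SMC", "right"): frozenset({26, 27, 30, 31}),
}

#: Channels of the default layout that belong to no ROI.
UNASSIGNED_CHANNELS = frozenset({9, 16, 25})

# Side assignment for mid-line channels, keyed by channel id. Derived from
# the ROI lists (channel 7 is listed on the right); remaining mid-line
# channels default to the left.
_MIDLINE_SIDE_OVERRIDE = {7: "right"}


@dataclass(frozen=True)
class Optode:
    """A single source or detector on the probe plane."""

    id: int
    role: str  # "source" or "detector"
    x_cm: float
    y_cm: float

    def __post_init__(self) -> None:
        if self.role not in ("source", "detector"):
            raise ParameterError(f"unknown optode role {self.role!r}")


@dataclass(frozen=True)
class Channel:
    """A source-detector pair at 3 cm separation."""

    id: int
    source_id: int
    detector_id: int
    midpoint: tuple[float, float]
    hemisphere: str = "left"
    roi: str = "none"


@dataclass
class ProbeLayout:
    """Optode grid plus its enumerated measurement channels."""

    optodes: list[Optode]
    channels: list[Channel]
    grid_shape: tuple[int, int]  # rows x cols

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def channel_ids(self) -> list[int]:
        return [ch.id for ch in self.channels]

    def channel(self, channel_id: int) -> Channel:
        for ch in self.channels:
            if ch.id == channel_id:
                return ch
        raise KeyError(f"no channel with id {channel_id}")

    def hemisphere_channels(self, side: str) -> set[int]:
        if side not in ("left", "right"):
            raise ParameterError(f"side must be 'left' or 'right', got {side!r}")
        return {ch.id for ch in self.channels if ch.hemisphere == side}

    def roi_channels(self, roi: str, side: str | None = None) -> set[int]:
        return {
            ch.id
            for ch in self.channels
            if ch.roi == roi and (side is None or ch.hemisphere == side)
        }

    def span_cm(self) -> tuple[float, float]:
        """(y extent, x extent) of the optode array in cm."""
        xs = [o.x_cm for o in self.optodes]
        ys = [o.y_cm for o in self.optodes]
        return (max(ys) - min(ys), max(xs) - min(xs))

    def to_frame(self) -> pd.DataFrame:
        """One row per channel: id, endpoints, position, labels."""
        return pd.DataFrame(
            {
                "id": [ch.id for ch in self.channels],
                "source_id": [ch.source_id for ch in self.channels],
                "detector_id": [ch.detector_id for ch in self.channels],
                "x_cm": [ch.midpoint[0] for ch in self.channels],
                "y_cm": [ch.midpoint[1] for ch in self.channels],
                "hemisphere": [ch.hemisphere for ch in self.channels],
                "roi": [ch.roi for ch in self.channels],
            }
        )


def _optode_grid(rows: int, cols: int, pitch: float = PITCH_CM) -> list[Optode]:
    """Checkerboard of optodes; top-left is a source."""
    optodes = []
    oid = 1
    for r in range(rows):
        for c in range(cols):
            role = "source" if (r + c) % 2 == 0 else "detector"
            optodes.append(Optode(oid, role, c * pitch, r * pitch))
            oid += 1
    return optodes


def enumerate_channels(optodes: Iterable[Optode], pitch: float = PITCH_CM) -> list[tuple[int, int]]:
    """All (source_id, detector_id) pairs separated by exactly ``pitch`` cm.

    Brute-force over all optode pairs; order is unspecified.  Used as the
    geometric ground truth that the canonical ordering must match as a set.
    """
    opts = list(optodes)
    pairs = []
    for i, a in enumerate(opts):
        for b in opts[i + 1 :]:
            if a.role == b.role:
                continue
            d = math.hypot(a.x_cm - b.x_cm, a.y_cm - b.y_cm)
            if math.isclose(d, pitch, rel_tol=0.0, abs_tol=1e-9):
                src, det = (a, b) if a.role == "source" else (b, a)
                pairs.append((src.id, det.id))
    return pairs


def build_layout(rows: int, cols: int, pitch: float = PITCH_CM) -> ProbeLayout:
    """Build a rows x cols checkerboard grid and enumerate its channels.

    Channels are numbered per optode row: horizontal pairs of the row
    left-to-right, then vertical pairs joining it to the next row.
    Hemisphere is decided by the channel midpoint relative to the grid
    midline; exact mid-line channels default to the left (the default
    31-channel layout overrides this for the channels whose side is fixed
    by the ROI lists).
    """
    if rows < 1 or cols < 1:
        raise ParameterError("grid must have at least one row and one column")
    optodes = _optode_grid(rows, cols, pitch)
    grid = {(o.y_cm, o.x_cm): o for o in optodes}
    midline = (cols - 1) * pitch / 2.0

    is_default = (rows, cols) == (4, 5)
    channels: list[Channel] = []
    cid = 1

    def _add(a: Optode, b: Optode) -> None:
        nonlocal cid
        src, det = (a, b) if a.role == "source" else (b, a)
        mx = (a.x_cm + b.x_cm) / 2.0
        my = (a.y_cm + b.y_cm) / 2.0
        if mx < midline:
            side = "left"
        elif mx > midline:
            side = "right"
        else:
            side = _MIDLINE_SIDE_OVERRIDE.get(cid, "left") if is_default else "left"
        channels.append(Channel(cid, src.id, det.id, (mx, my), hemisphere=side))
        cid += 1

    for r in range(rows):
        for c in range(cols - 1):
            _add(grid[(r * pitch, c * pitch)], grid[(r * pitch, (c + 1) * pitch)])
        if r < rows - 1:
            for c in range(cols):
                _add(grid[(r * pitch, c * pitch)], grid[((r + 1) * pitch, c * pitch)])

    return ProbeLayout(optodes=optodes, channels=channels, grid_shape=(rows, cols))


def build_default_layout() -> ProbeLayout:
    """The canonical 4x5 grid: 20 optodes, 31 channels, ROI labels attached."""
    return assign_rois(build_layout(4, 5))


def assign_rois(layout: ProbeLayout) -> ProbeLayout:
    """Attach the canonical ROI labels to a 31-channel layout.

    PFC / preSMA / M1 / SMC per hemisphere; channels 9, 16 and 25 stay
    unassigned.  Raises :class:`LayoutMismatchError` for any other
    channel count.
    """
    if layout.n_channels != 31:
        raise LayoutMismatchError(
            f"ROI labels are defined for 31 channels, layout has {layout.n_channels}"
        )
    side_of: dict[int, str] = {}
    roi_of: dict[int, str] = {}
    for (roi, side), ids in ROI_CHANNELS.items():
        for i in ids:
            roi_of[i] = roi
            side_of[i] = side
    new_channels = [
        replace(
            ch,
            roi=roi_of.get(ch.id, "none"),
            hemisphere=side_of.get(ch.id, ch.hemisphere),
        )
        for ch in layout.channels
    ]
    return ProbeLayout(
        optodes=list(layout.optodes),
        channels=new_channels,
        grid_shape=layout.grid_shape,
    )


def hemisphere_channels(layout: ProbeLayout, side: str) -> set[int]:
    """Channel ids on one side of the grid midline (module-level alias)."""
    return layout.hemisphere_channels(side)


# ---------------------------------------------------------------------------
# serialization

_HEADER_KEYS = ("rows", "cols", "pitch_cm")


def write_layout(layout: ProbeLayout, path) -> None:
    """Write the layout as a commented TSV (one row per channel)."""
    rows, cols = layout.grid_shape
    with open(path, "w") as fh:
        fh.write(f"# rows: {rows}\n# cols: {cols}\n# pitch_cm: {PITCH_CM}\n")
        layout.to_frame().to_csv(fh, sep="\t", index=False)


def read_layout(path) -> ProbeLayout:
    """Read a layout written by :func:`write_layout` (bit-exact round trip)."""
    header: dict[str, str] = {}
    body = io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                try:
                    key, value = line[1:].split(":", 1)
                except ValueError as exc:
                    raise FormatError(f"malformed header line: {line!r}") from exc
                header[key.strip()] = value.strip()
            else:
                body.write(line)
    for key in _HEADER_KEYS:
        if key not in header:
            raise FormatError(f"layout file missing header field {key!r}")
    body.seek(0)
    frame = pd.read_csv(body, sep="\t")
    layout = build_layout(int(header["rows"]), int(header["cols"]), float(header["pitch_cm"]))
    if len(frame) != layout.n_channels:
        raise FormatError(
            f"layout file has {len(frame)} channels, grid implies {layout.n_channels}"
        )
    by_id = {int(row.id): row for row in frame.itertuples()}
    layout.channels = [
        replace(ch, hemisphere=str(by_id[ch.id].hemisphere), roi=str(by_id[ch.id].roi))
        for ch in layout.channels
    ]
    return layout
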