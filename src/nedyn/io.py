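"""Readers and writers shared by all analysis stages.

Image stacks are held as 5-D arrays indexed ``(channel, time, z, y, x)`` with
physical calibration attached.  Traced contours and membrane polylines travel
as a flat CSV point-list schema (one vertex per row).  Run configuration is a
validated JSON document.

Coordinate convention: pixel coordinates are 0-based, x to the right, y down,
with pixel centers on integer coordinates.  All physical conversions multiply
by ``pixel_size_um``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, ConfigDict
from skimage.draw import polygon as _raster_polygon

from .errors import ConfigurationError, FormatError, InputError

VALID_UNITS = ("pixel", "um", "nm")

#: Axis letters used by tifffile that we map onto our own convention.
_AXIS_ALIASES = {"S": "C", "I": "T", "Q": "T"}

#: Default axis interpretation for files carrying no axis metadata.
#: 3-D arrays are read as a single-slice time series (T, Y, X).
_DEFAULT_AXES = {2: "YX", 3: "TYX", 4: "TZYX", 5: "CTZYX"}

ORIGIN_CONVENTION = "0-based; x right, y down; pixel centers at integers"


@dataclass
class ImageStack:
    """A calibrated multi-channel time-lapse z-stack.

    ``pixels`` has shape (n_channels, T, Z, Y, X); ``shape`` exposes the
    per-channel (T, Z, Y, X) view used throughout the analysis modules.
    """

    pixels: np.ndarray
    channels: list[str]
    pixel_size_um: float
    z_step_um: float = 1.0
    time_step_s: float = 1.0
    origin: str = ORIGIN_CONVENTION

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 5:
            raise InputError(
                f"pixels must be 5-D (C,T,Z,Y,X); got {self.pixels.ndim}-D"
            )
        if min(self.pixels.shape) < 1:
            raise InputError("every axis must have length >= 1")
        if len(self.channels) != self.pixels.shape[0]:
            raise InputError(
                f"{len(self.channels)} channel labels for "
                f"{self.pixels.shape[0]} channels"
            )
        if not (self.pixel_size_um > 0):
            raise InputError("pixel_size_um must be > 0")
        if not (self.time_step_s > 0):
            raise InputError("time_step_s must be > 0")
        if not (self.z_step_um > 0):
            raise InputError("z_step_um must be > 0")
        if not np.all(np.isfinite(self.pixels)):
            raise InputError("intensities must be finite")
        if (self.pixels < 0).any():
            raise InputError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        """Per-channel (T, Z, Y, X) shape."""
        return tuple(self.pixels.shape[1:])

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[1]

    def channel(self, key: int | str) -> np.ndarray:
        """Return one channel as a (T, Z, Y, X) array."""
        if isinstance(key, str):
            try:
                key = self.channels.index(key)
            except ValueError:
                raise InputError(
                    f"unknown channel {key!r}; have {self.channels}"
                ) from None
        return self.pixels[key]


def _normalize_axes(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder/expand an array with labelled axes to (C, T, Z, Y, X)."""
    axes = "".join(_AXIS_ALIASES.get(a, a) for a in axes.upper())
    if len(axes) != data.ndim:
        raise InputError(
            f"axes string {axes!r} does not match {data.ndim}-D data"
        )
    if len(set(axes)) != len(axes):
        raise InputError(f"repeated axis letters in {axes!r}")
    for a in axes:
        if a not in "CTZYX":
            raise InputError(f"unsupported axis letter {a!r} in {axes!r}")
    for a in "CTZYX":
        if a not in axes:
            data = data[np.newaxis]
            axes = a + axes
    order = [axes.index(a) for a in "CTZYX"]
    return np.transpose(data, order)


def read_stack(
    path: str | Path,
    *,
    pixel_size_um: Optional[float] = None,
    z_step_um: Optional[float] = None,
    time_step_s: Optional[float] = None,
    axes: Optional[str] = None,
    channels: Optional[Sequence[str]] = None,
) -> ImageStack:
    """Read a TIFF into an :class:`ImageStack`.

    Calibration precedence: explicit overrides > metadata written by
    :func:`write_stack` > error.  Axis order likewise; files with no axis
    metadata fall back to a dimensionality-based default (2-D -> YX,
    3-D -> TYX, 4-D -> TZYX).
    """
    p = Path(path)
    if not p.exists():
        raise InputError(f"no such file: {p}")
    try:
        with tifffile.TiffFile(p) as tf:
            series = tf.series[0]
            data = np.asarray(series.asarray())
            meta: dict = {}
            if tf.shaped_metadata:
                meta = dict(tf.shaped_metadata[0])
            file_axes = meta.get("axes") or getattr(series, "axes", None)
    except (tifffile.TiffFileError, ValueError, IndexError, OSError) as exc:
        raise InputError(f"could not read TIFF {p}: {exc}") from exc

    if "shape" in meta:
        data = data.reshape(meta["shape"])
    use_axes = axes or file_axes
    # trust auto-detected axis labels only when they are unambiguous;
    # tifffile guesses sample/unknown axes (S, Q, I) for plain files
    trusted = (axes is not None or "axes" in meta
               or (use_axes is not None
                   and set(use_axes.upper()) <= set("CTZYX")))
    if use_axes is None or len(use_axes) != data.ndim or not trusted:
        if data.ndim not in _DEFAULT_AXES:
            raise InputError(f"cannot interpret {data.ndim}-D TIFF {p}")
        use_axes = _DEFAULT_AXES[data.ndim]
    pixels = _normalize_axes(data, use_axes)

    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    if px is None:
        raise ConfigurationError(
            f"{p}: no pixel size in metadata and no override given"
        )
    zs = z_step_um if z_step_um is not None else meta.get("z_step_um", 1.0)
    ts = time_step_s if time_step_s is not None else meta.get("time_step_s", 1.0)
    labels = list(channels) if channels is not None else meta.get("channels")
    if labels is None:
        labels = [f"ch{i}" for i in range(pixels.shape[0])]
    return ImageStack(
        pixels=pixels,
        channels=labels,
        pixel_size_um=float(px),
        z_step_um=float(zs),
        time_step_s=float(ts),
    )


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as a multi-page TIFF with calibration metadata.

    ``read_stack(write_stack(s))`` reproduces pixels and calibration exactly.
    """
    p = Path(path)
    tifffile.imwrite(
        p,
        stack.pixels,
        photometric="minisblack",
        metadata={
            "axes": "CTZYX",
            "channels": list(stack.channels),
            "pixel_size_um": stack.pixel_size_um,
            "z_step_um": stack.z_step_um,
            "time_step_s": stack.time_step_s,
            "origin": stack.origin,
        },
    )
    return p


# ---------------------------------------------------------------------------
# Regions of interest
# ---------------------------------------------------------------------------


@dataclass
class RegionSpec:
    """A polygonal or rectangular region of interest in one frame/slice.

    For boxes ``corner`` is the (x, y) of the top-left pixel.  An optional
    exact pixel ``mask`` (as produced by segmentation) takes precedence over
    the rasterized polygon when pixel statistics are computed.
    """

    kind: str
    vertices: Optional[np.ndarray] = None
    corner: Optional[tuple[int, int]] = None
    width: Optional[int] = None
    height: Optional[int] = None
    frame: int = 0
    z: int = 0
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.kind not in ("polygon", "box"):
            raise InputError(f"unknown region kind {self.kind!r}")
        if self.kind == "polygon":
            if self.vertices is None:
                raise InputError("polygon region requires vertices")
            self.vertices = np.asarray(self.vertices, dtype=float)
            if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
                raise InputError("vertices must be an (N, 2) array of (x, y)")
            if len(self.vertices) < 3:
                raise InputError("polygon needs >= 3 vertices")
        else:
            if self.corner is None or self.width is None or self.height is None:
                raise InputError("box region requires corner, width, height")
            if self.width < 1 or self.height < 1:
                raise InputError("box width and height must be >= 1 pixel")

    @classmethod
    def box(cls, x: int, y: int, width: int, height: int, **kw) -> "RegionSpec":
        return cls(kind="box", corner=(int(x), int(y)),
                   width=int(width), height=int(height), **kw)

    @classmethod
    def polygon(cls, vertices, **kw) -> "RegionSpec":
        return cls(kind="polygon", vertices=np.asarray(vertices, float), **kw)

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean pixel mask of this region on a (Y, X) frame."""
        if self.mask is not None:
            if self.mask.shape != tuple(shape):
                raise InputError(
                    f"stored mask shape {self.mask.shape} != frame {shape}"
                )
            return self.mask.astype(bool)
        ny, nx = shape
        if self.kind == "box":
            x0, y0 = self.corner
            if x0 < 0 or y0 < 0 or x0 + self.width > nx or y0 + self.height > ny:
                raise InputError("box extends outside the frame")
            m = np.zeros(shape, dtype=bool)
            m[y0:y0 + self.height, x0:x0 + self.width] = True
            return m
        v = self.vertices
        # find_contours places borders at +/-0.5 around pixel centers
        if (v[:, 0] < -0.5).any() or (v[:, 0] > nx - 0.5).any() \
                or (v[:, 1] < -0.5).any() or (v[:, 1] > ny - 0.5).any():
            raise InputError("polygon extends outside the frame")
        rr, cc = _raster_polygon(v[:, 1], v[:, 0], shape)
        m = np.zeros(shape, dtype=bool)
        m[rr, cc] = True
        return m

    def area_px(self, shape: tuple[int, int]) -> int:
        return int(self.to_mask(shape).sum())


# ---------------------------------------------------------------------------
# Point lists (traced contours / membrane polylines)
# ---------------------------------------------------------------------------

_POINTLIST_COLUMNS = ["object_id", "slice_or_frame", "vertex_index",
                      "x", "y", "closed_flag"]


@dataclass
class PointList:
    """Ordered vertices of one traced object on one slice/frame.

    For closed objects the first vertex is *not* repeated at the end;
    closure is implicit.
    """

    object_id: str
    slice_index: int
    vertices: np.ndarray  # (N, 2) as (x, y)
    closed: bool
    units: str = "pixel"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise InputError("vertices must be an (N, 2) array")
        if self.units not in VALID_UNITS:
            raise InputError(f"units must be one of {VALID_UNITS}")


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("1", "true", "t", "yes")
    return bool(value)


def read_pointlists(path: str | Path, units: Optional[str] = None) -> list[PointList]:
    """Read a point-list CSV into a list of :class:`PointList`.

    The file must carry columns ``object_id, slice_or_frame, vertex_index,
    x, y, closed_flag`` and may carry a ``units`` column.  Units come from
    that column when present (and must be uniform), otherwise from the
    ``units`` argument.
    """
    p = Path(path)
    if not p.exists():
        raise InputError(f"no such file: {p}")
    try:
        df = pd.read_csv(p)
    except (pd.errors.ParserError, UnicodeDecodeError, ValueError) as exc:
        raise FormatError(f"could not parse point-list CSV {p}: {exc}") from exc
    missing = [c for c in _POINTLIST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{p}: missing columns {missing}")

    if "units" in df.columns:
        file_units = set(df["units"].astype(str))
        if len(file_units) > 1:
            raise FormatError(f"{p}: mixed units {sorted(file_units)}")
        resolved = file_units.pop()
        if units is not None and units != resolved:
            raise FormatError(
                f"{p}: file declares units {resolved!r}, caller asked {units!r}"
            )
    elif units is not None:
        resolved = units
    else:
        raise FormatError(f"{p}: no units column and no units argument")
    if resolved not in VALID_UNITS:
        raise FormatError(f"units must be one of {VALID_UNITS}, got {resolved!r}")

    out: list[PointList] = []
    for (obj, sl), grp in df.groupby(["object_id", "slice_or_frame"], sort=True):
        idx = grp["vertex_index"].to_numpy()
        if len(idx) != len(set(idx)):
            raise FormatError(f"{p}: duplicate vertex_index in object {obj!r}")
        if not np.all(np.diff(idx) > 0):
            raise FormatError(
                f"{p}: non-monotone vertex_index within object {obj!r}"
            )
        closed_vals = set(grp["closed_flag"].map(_as_bool))
        if len(closed_vals) > 1:
            raise FormatError(f"{p}: inconsistent closed_flag in object {obj!r}")
        closed = closed_vals.pop()
        verts = grp[["x", "y"]].to_numpy(dtype=float)
        if closed and len(verts) > 1 and np.array_equal(verts[0], verts[-1]):
            verts = verts[:-1]  # closure stored implicitly
        out.append(PointList(str(obj), int(sl), verts, closed, resolved))
    return out


def write_pointlists(objects: Sequence[PointList], path: str | Path) -> Path:
    """Write point lists in the CSV schema read by :func:`read_pointlists`."""
    p = Path(path)
    rows = []
    units = {o.units for o in objects}
    if len(units) > 1:
        raise InputError(f"cannot mix units in one file: {sorted(units)}")
    for o in objects:
        for i, (x, y) in enumerate(o.vertices):
            rows.append({
                "object_id": o.object_id,
                "slice_or_frame": o.slice_index,
                "vertex_index": i,
                "x": x,
                "y": y,
                "closed_flag": int(o.closed),
                "units": o.units,
            })
    pd.DataFrame(rows).to_csv(p, index=False)
    return p


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


class RunConfig(BaseModel):
    """Validated analysis configuration; unknown keys are rejected.

    Every parameter has a default so a config file only needs to state
    deviations.  Calibration fields default to None, meaning "take from
    image metadata or fail".
    """

    model_config = ConfigDict(extra="forbid")

    input_path: Optional[str] = None
    output_dir: str = "nedyn_out"
    seed: int = 0

    # calibration overrides
    pixel_size_um: Optional[float] = None
    z_step_um: Optional[float] = None
    time_step_s: Optional[float] = None

    # segmentation / import
    threshold_method: str = "otsu"
    min_area_px: int = 20
    baseline_n: int = 3
    k_sd: float = 3.0
    persistence: int = 2

    # FRAP
    n_prebleach: int = 3
    a_max: float = 1.5

    # morphometry
    slice_spacing_um: float = 0.1625

    # line scans
    line_width_px: int = 3
    n_end: int = 2
    n_flank: int = 5

    # hole classification
    pairing_max_nm: float = 300.0
    width_max_nm: float = 100.0
    flank_min_nm: float = 100.0
    taper_max_nm: float = 20.0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        p = Path(path)
        if not p.exists():
            raise InputError(f"no such config file: {p}")
        try:
            payload = json.loads(p.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"invalid JSON in {p}: {exc}") from exc
        try:
            return cls(**payload)
        except Exception as exc:  # pydantic ValidationError
            raise ConfigurationError(f"invalid config {p}: {exc}") from exc
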