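"""Nuclear-import quantification from time-lapse stacks.

The per-frame metric follows the background-box recipe: camera background is
the mean of a box drawn in a vacant area, cytoplasm the mean of a box inside
the embryo, and the nucleus the mean inside the (segmented or user-traced)
chromatin region.  The background-corrected nucleocytoplasmic ratio

    (N - bg) / (C - bg)

is multiplied by the nuclear area to account for differences in nuclear size;
both the bare ratio and the area-scaled value are reported (area in um^2 by
default, pixels behind a flag).  Traces are referenced to a named anchor event
(anaphase onset, furrow ingression, or pseudocleavage regression).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from skimage import filters, measure, morphology

from .errors import (ConfigurationError, ContrastError, InputError,
                     NormalizationError, SegmentationError, TraceError)
from .io import ImageStack, RegionSpec


@dataclass
class NCComponents:
    """One frame's import metric and its ingredients."""

    nc_value: float        # ratio * nuclear area
    ratio: float           # (N - bg) / (C - bg)
    nuclear_mean: float
    cyto_mean: float
    background: float
    area_um2: float
    area_px: int


@dataclass
class ImportTrace:
    """Per-frame import metric referenced to an anchor event."""

    times_s: np.ndarray
    nc_value: np.ndarray
    ratio: np.ndarray
    nuclear_mean: np.ndarray
    cyto_mean: np.ndarray
    background: np.ndarray
    area_um2: np.ndarray
    anchor_event: str
    anchor_frame: int

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if not np.all(np.diff(self.times_s) > 0):
            raise InputError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.times_s,
            "N": self.nuclear_mean,
            "C": self.cyto_mean,
            "bg": self.background,
            "area_um2": self.area_um2,
            "ratio": self.ratio,
            "nc_value": self.nc_value,
        })


@dataclass
class NormalizedTrace:
    """Min-max normalized traces, their average, and per-interval differences."""

    times_s: np.ndarray
    normalized: np.ndarray     # (n_traces, T)
    average: np.ndarray        # (T,)
    differences: np.ndarray    # (T-1,) first differences of the average


def segment_nucleus(frame: np.ndarray, method: str = "otsu",
                    min_area_px: int = 20) -> RegionSpec:
    """Threshold a chromatin image and return the largest component.

    Replaces the manual chromatin tracing step with a reproducible global
    threshold (Otsu by default); small components are removed; the largest
    surviving connected component is returned as a polygon RegionSpec with
    its exact pixel mask attached.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise InputError("frame must be 2-D")
    if np.ptp(frame) == 0:
        raise SegmentationError("constant frame cannot be thresholded")
    try:
        thresh_fn = getattr(filters, f"threshold_{method}")
    except AttributeError:
        raise InputError(f"unknown threshold method {method!r}") from None
    thr = float(thresh_fn(frame))
    mask = frame > thr
    if min_area_px > 1:
        mask = morphology.remove_small_objects(mask, max_size=min_area_px - 1)
    labels = measure.label(mask)
    if labels.max() == 0:
        raise SegmentationError(
            f"no component of >= {min_area_px} px at threshold {thr}"
        )
    counts = np.bincount(labels.ravel())[1:]
    keep = labels == (int(np.argmax(counts)) + 1)
    contours = measure.find_contours(keep.astype(float), 0.5)
    boundary = max(contours, key=len)
    vertices = np.column_stack([boundary[:, 1], boundary[:, 0]])  # (x, y)
    return RegionSpec(kind="polygon", vertices=vertices, mask=keep)


def nc_ratio(frame: np.ndarray, nucleus: RegionSpec, cyto_box: RegionSpec,
             bg_box: RegionSpec, pixel_size_um: float,
             area_in_pixels: bool = False) -> NCComponents:
    """Background-corrected N/C ratio scaled by nuclear area for one frame."""
    frame = np.asarray(frame, dtype=float)
    nmask = nucleus.to_mask(frame.shape)
    cmask = cyto_box.to_mask(frame.shape)
    bmask = bg_box.to_mask(frame.shape)
    if not nmask.any():
        raise SegmentationError("empty nucleus region")
    if (nmask & cmask).any():
        raise ConfigurationError("cytoplasm box overlaps the nucleus")
    if (nmask & bmask).any():
        raise ConfigurationError("background box overlaps the nucleus")
    n_mean = float(frame[nmask].mean())
    c_mean = float(frame[cmask].mean())
    bg = float(frame[bmask].mean())
    if c_mean <= bg:
        raise ContrastError(
            f"cytoplasm mean {c_mean} <= background {bg}: degenerate contrast"
        )
    area_px = int(nmask.sum())
    area_um2 = area_px * pixel_size_um ** 2
    ratio = (n_mean - bg) / (c_mean - bg)
    area = area_px if area_in_pixels else area_um2
    return NCComponents(
        nc_value=ratio * area,
        ratio=ratio,
        nuclear_mean=n_mean,
        cyto_mean=c_mean,
        background=bg,
        area_um2=area_um2,
        area_px=area_px,
    )


def _parse_anchor(anchor: Union[str, tuple[str, int]]) -> tuple[str, int]:
    if isinstance(anchor, str):
        name, _, frame = anchor.partition(":")
        if not frame:
            raise InputError(
                f"anchor {anchor!r} must be 'event_name:frame_index'"
            )
        return name, int(frame)
    name, frame = anchor
    return str(name), int(frame)


def import_trace(stack: ImageStack, reporter_channel: Union[int, str],
                 chromatin_channel: Union[int, str],
                 anchor: Union[str, tuple[str, int]],
                 cyto_box: RegionSpec, bg_box: RegionSpec,
                 method: str = "otsu", min_area_px: int = 20,
                 nucleus_override: Optional[RegionSpec] = None,
                 ) -> ImportTrace:
    """Build an import trace from a two-channel stack.

    Per frame, the nucleus is segmented on a max-intensity z-projection of
    the chromatin channel (or taken from ``nucleus_override``) and the
    metric is evaluated on the projected reporter channel.  Isolated
    per-frame failures yield NaN entries; more than 50% failures abort.
    """
    event, anchor_frame = _parse_anchor(anchor)
    n_frames = stack.n_frames
    if not (0 <= anchor_frame < n_frames):
        raise InputError(
            f"anchor frame {anchor_frame} outside stack of {n_frames} frames"
        )
    reporter = stack.channel(reporter_channel)
    chromatin = stack.channel(chromatin_channel)
    times = (np.arange(n_frames) - anchor_frame) * stack.time_step_s

    cols = {k: np.full(n_frames, np.nan) for k in
            ("nc_value", "ratio", "N", "C", "bg", "area")}
    n_failed = 0
    for t in range(n_frames):
        rep = reporter[t].max(axis=0)
        chrom = chromatin[t].max(axis=0)
        try:
            nucleus = nucleus_override or segment_nucleus(
                chrom, method=method, min_area_px=min_area_px)
            comp = nc_ratio(rep, nucleus, cyto_box, bg_box,
                            stack.pixel_size_um)
        except (SegmentationError, ContrastError):
            n_failed += 1
            continue
        cols["nc_value"][t] = comp.nc_value
        cols["ratio"][t] = comp.ratio
        cols["N"][t] = comp.nuclear_mean
        cols["C"][t] = comp.cyto_mean
        cols["bg"][t] = comp.background
        cols["area"][t] = comp.area_um2
    if n_failed > n_frames / 2:
        raise TraceError(
            f"segmentation failed on {n_failed}/{n_frames} frames"
        )
    return ImportTrace(
        times_s=times,
        nc_value=cols["nc_value"],
        ratio=cols["ratio"],
        nuclear_mean=cols["N"],
        cyto_mean=cols["C"],
        background=cols["bg"],
        area_um2=cols["area"],
        anchor_event=event,
        anchor_frame=anchor_frame,
    )


def detect_onset(trace: ImportTrace, baseline_n: int = 3, k_sd: float = 3.0,
                 persistence: int = 2, signal: str = "ratio",
                 ) -> Optional[float]:
    """First time the import signal rises persistently above baseline.

    Onset = first time t at which the signal exceeds
    mean + k_sd * sd of the first ``baseline_n`` points for ``persistence``
    consecutive frames; None if never exceeded.  The bare N/C ratio is used
    by default: the area-scaled nc_value drifts upward with nuclear growth
    even before import starts, which defeats a baseline threshold
    (``signal="nc_value"`` selects the area-scaled metric anyway).
    """
    if signal == "ratio":
        values = trace.ratio
    elif signal == "nc_value":
        values = trace.nc_value
    else:
        raise InputError(f"signal must be 'ratio' or 'nc_value', got {signal!r}")
    if baseline_n < 1 or persistence < 1:
        raise InputError("baseline_n and persistence must be >= 1")
    if len(values) < baseline_n + persistence:
        raise InputError(
            f"trace of {len(values)} points too short for baseline_n="
            f"{baseline_n} + persistence={persistence}"
        )
    finite = values[np.isfinite(values)]
    if len(finite) < baseline_n + persistence:
        raise InputError("too many missing values for onset detection")
    base = finite[:baseline_n]
    sd = float(np.std(base, ddof=1)) if baseline_n > 1 else 0.0
    threshold = float(np.mean(base)) + k_sd * sd
    for i in range(len(values) - persistence + 1):
        window = values[i:i + persistence]
        if np.all(np.isfinite(window)) and np.all(window > threshold):
            return float(trace.times_s[i])
    return None


def normalize_and_difference(traces: Sequence[ImportTrace],
                             signal: str = "nc_value") -> NormalizedTrace:
    """Min-max normalize traces on a common grid, average, and difference.

    Each trace is rescaled to [0, 1] over its own range, the rescaled traces
    are averaged pointwise, and the first differences of the average over
    consecutive time intervals are returned.  Gapped (NaN) frames propagate
    as NaN differences for the adjoining intervals.
    """
    if not traces:
        raise InputError("need at least one trace")
    times = traces[0].times_s
    for i, tr in enumerate(traces[1:], start=1):
        if len(tr.times_s) != len(times) or not np.allclose(tr.times_s, times):
            raise InputError(f"trace {i} is not on the common time grid")
    rows = []
    for i, tr in enumerate(traces):
        v = tr.nc_value if signal == "nc_value" else tr.ratio
        lo, hi = np.nanmin(v), np.nanmax(v)
        if not np.isfinite(lo) or hi == lo:
            raise NormalizationError(f"trace {i} is constant or empty")
        rows.append((v - lo) / (hi - lo))
    normalized = np.vstack(rows)
    with np.errstate(invalid="ignore"):
        average = np.nanmean(normalized, axis=0)
    return NormalizedTrace(
        times_s=times,
        normalized=normalized,
        average=average,
        differences=np.diff(average),
    )
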