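"""Synthetic inputs with known ground truth for every analysis stage.

Each generator is a pure function of its parameters (seed included) and its
output is recovered by the matching analysis operation at zero noise:

* ``gen_embryo_timelapse`` — a two-channel confocal-like time lapse (20 s
  frame interval, five z-slices at 2 um steps) of a nuclear disk growing
  linearly in radius while importing a reporter above a constant cytoplasm,
  with an additive camera offset and Gaussian read noise.  Nuclear excess
  intensity follows the saturating exponential C*F*(1 - exp(-k_in*t)); the
  analysis stages never assume this model, it only supplies a closed-form
  truth.
* ``gen_frap_curve`` — prebleach frames plus a single-exponential recovery
  A*(1 - exp(-tau*t)) at 10 s intervals, with an optional incomplete bleach
  depth and clipped Gaussian noise.
* ``gen_sphere_contours`` — regular polygon traces of a sphere's z-sections
  at 0.1625 um spacing, optionally radially jittered.
* ``gen_membrane_field`` — a traced membrane line interrupted by gaps of
  requested widths; tapered gap edges end straight, blunt (non-tapered)
  edges end with a perpendicular hook so the taper criterion rejects them.

Noise is additive Gaussian clipped at zero: adequate for testing estimators;
Poisson/photobleaching realism is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import nemap
from .errors import ParameterError
from .frap import FRAPSeries
from .io import ImageStack, RegionSpec
from .morphometry import ContourStack
from .nemap import MembraneTrace


@dataclass
class SynthImportParams:
    """Growing, importing nucleus in a two-channel embryo time lapse."""

    r0_um: float = 1.0                  # nuclear radius at frame 0
    growth_um_per_s: float = 0.002      # linear radial growth
    cyto_intensity: float = 100.0       # reporter counts above camera offset
    background: float = 50.0            # camera offset, everywhere
    k_in: float = 0.02                  # import rate constant (1/s)
    plateau: float = 3.0                # F: saturating excess = C*F
    import_start_s: float = 0.0         # import delayed until this time
    noise_sd: float = 2.0
    frame_interval_s: float = 20.0
    n_frames: int = 60
    frame_px: int = 256
    pixel_size_um: float = 0.1
    n_z: int = 5
    z_step_um: float = 2.0
    embryo_radius_um: float = 10.0
    chromatin_intensity: float = 200.0  # chromatin channel, nucleus only
    chromatin_cyto: float = 5.0         # dim soluble histone signal
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cyto_intensity", "background", "chromatin_intensity",
                     "chromatin_cyto"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.k_in < 0:
            raise ParameterError("k_in must be >= 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.n_frames < 1 or self.frame_interval_s <= 0:
            raise ParameterError("need n_frames >= 1 and positive interval")
        r_max = self.r0_um + self.growth_um_per_s * \
            (self.n_frames - 1) * self.frame_interval_s
        half_frame_um = self.frame_px * self.pixel_size_um / 2.0
        if r_max >= min(self.embryo_radius_um, half_frame_um):
            raise ParameterError(
                f"nucleus (final radius {r_max:.2f} um) would exceed the "
                f"embryo/frame"
            )


def default_boxes(params: SynthImportParams) -> tuple[RegionSpec, RegionSpec]:
    """Cytoplasm (20x20 px, inside the embryo, clear of the nucleus) and
    camera-background (50x50 px, vacant corner) boxes for generated stacks."""
    c = params.frame_px // 2
    cyto = RegionSpec.box(c - 10, c + 60, 20, 20)
    bg = RegionSpec.box(2, 2, 50, 50)
    return cyto, bg


def gen_embryo_timelapse(params: SynthImportParams,
                         ) -> tuple[ImageStack, pd.DataFrame]:
    """Generate a (reporter, chromatin) stack plus its ground-truth table.

    Truth columns: frame, time_s, radius_um, area_um2 (central cross
    section), ratio_true = 1 + F*(1 - exp(-k_in*(t - t0))) for t >= t0, and
    nc_value_true = ratio_true * area_um2.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = p.frame_px
    c = float(n // 2)
    yy, xx = np.ogrid[:n, :n]
    dist2 = (xx - c) ** 2 + (yy - c) ** 2
    embryo = dist2 <= (p.embryo_radius_um / p.pixel_size_um) ** 2
    z_offsets = (np.arange(p.n_z) - (p.n_z - 1) / 2.0) * p.z_step_um

    pixels = np.zeros((2, p.n_frames, p.n_z, n, n), dtype=np.float32)
    truth = []
    for t in range(p.n_frames):
        time_s = t * p.frame_interval_s
        r = p.r0_um + p.growth_um_per_s * time_s
        dt_import = time_s - p.import_start_s
        if p.k_in > 0 and dt_import >= 0:
            frac = 1.0 - math.exp(-p.k_in * dt_import)
        else:
            frac = 0.0
        excess = p.cyto_intensity * p.plateau * frac
        for zi, z in enumerate(z_offsets):
            if abs(z) < r:
                rz_px = math.sqrt(r ** 2 - z ** 2) / p.pixel_size_um
                nucleus = dist2 <= rz_px ** 2
            else:
                nucleus = np.zeros((n, n), dtype=bool)
            rep = p.background + p.cyto_intensity * embryo + excess * nucleus
            chrom = (p.background + p.chromatin_cyto * embryo
                     + p.chromatin_intensity * nucleus)
            pixels[0, t, zi] = rep
            pixels[1, t, zi] = chrom
        ratio_true = 1.0 + p.plateau * frac
        area = math.pi * r ** 2
        truth.append({
            "frame": t,
            "time_s": time_s,
            "radius_um": r,
            "area_um2": area,
            "ratio_true": ratio_true,
            "nc_value_true": ratio_true * area,
        })
    if p.noise_sd > 0:
        pixels += rng.normal(0.0, p.noise_sd, pixels.shape).astype(np.float32)
        np.clip(pixels, 0.0, None, out=pixels)
    stack = ImageStack(
        pixels=pixels,
        channels=["reporter", "chromatin"],
        pixel_size_um=p.pixel_size_um,
        z_step_um=p.z_step_um,
        time_step_s=p.frame_interval_s,
    )
    return stack, pd.DataFrame(truth)


@dataclass
class SynthFRAPParams:
    """Single-exponential FRAP recovery with prebleach frames."""

    mobile_fraction: float = 0.2        # A, the true mobile fraction
    tau_per_s: float = 0.03
    n_prebleach: int = 3
    bleach_depth: float = 0.0           # fraction of prebleach signal at t=0
    frame_interval_s: float = 10.0
    n_post: int = 60
    noise_sd: float = 0.05
    prebleach_intensity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mobile_fraction <= 1.0):
            raise ParameterError("mobile_fraction must be in [0, 1]")
        if not (self.tau_per_s > 0):
            raise ParameterError("tau_per_s must be > 0")
        if not (0.0 <= self.bleach_depth < 1.0):
            raise ParameterError("bleach_depth must be in [0, 1)")
        if self.n_post < 4:
            raise ParameterError(
                "need >= 4 post-bleach frames (fit impossible otherwise)"
            )
        if self.n_prebleach < 1:
            raise ParameterError("need >= 1 prebleach frame")
        if self.noise_sd < 0 or self.prebleach_intensity <= 0:
            raise ParameterError("invalid intensity parameters")


def gen_frap_curve(params: SynthFRAPParams) -> FRAPSeries:
    """Raw bleach series: prebleach plateau then exponential recovery.

    Post-bleach (normalized) signal is
    depth + (1 - depth) * A * (1 - exp(-tau*t)) plus clipped Gaussian noise;
    everything is scaled by the prebleach intensity.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    dt = p.frame_interval_s
    t_post = np.arange(p.n_post) * dt
    recovery = p.bleach_depth + (1.0 - p.bleach_depth) * \
        p.mobile_fraction * (1.0 - np.exp(-p.tau_per_s * t_post))
    values = np.concatenate([
        np.full(p.n_prebleach, 1.0), recovery
    ]) * p.prebleach_intensity
    if p.noise_sd > 0:
        values = values + rng.normal(
            0.0, p.noise_sd * p.prebleach_intensity, values.shape)
        values = np.clip(values, 0.0, None)
    times = np.concatenate([
        (np.arange(p.n_prebleach) - p.n_prebleach) * dt, t_post
    ])
    return FRAPSeries(times_s=times, intensities=values,
                      n_prebleach=p.n_prebleach, frame_interval_s=dt)


def gen_sphere_contours(radius_um: float, z_step_um: float = 0.1625,
                        n_vertices: int = 256, jitter_um: float = 0.0,
                        seed: int = 0) -> ContourStack:
    """Regular n-gon traces of a sphere's z-sections.

    Slices sit at z = k * z_step for integer k with |z| strictly inside
    (-r, r), so no slice is tangent; each vertex sits at the section radius
    sqrt(r^2 - z^2), radially perturbed by at most ``jitter_um``.
    """
    if radius_um <= 0:
        raise ParameterError("radius_um must be > 0")
    if n_vertices < 8:
        raise ParameterError("need n_vertices >= 8")
    if z_step_um >= 2 * radius_um:
        raise ParameterError("z_step >= 2*radius leaves no interior slice")
    if jitter_um < 0:
        raise ParameterError("jitter_um must be >= 0")
    rng = np.random.default_rng(seed)
    k_max = int(math.floor(radius_um / z_step_um))
    if k_max * z_step_um >= radius_um:
        k_max -= 1
    theta = 2.0 * math.pi * np.arange(n_vertices) / n_vertices
    slices = []
    for k in range(-k_max, k_max + 1):
        z = k * z_step_um
        rho = math.sqrt(radius_um ** 2 - z ** 2)
        if jitter_um > 0:
            rho = rho + rng.uniform(-jitter_um, jitter_um, n_vertices)
        verts = np.column_stack([rho * np.cos(theta), rho * np.sin(theta)])
        slices.append((k, verts))
    return ContourStack(slices=slices, z_step_um=z_step_um,
                        object_id=f"sphere_r{radius_um:g}")


@dataclass
class SynthHoleFieldParams:
    """A traced membrane line interrupted by gaps of known widths."""

    gap_widths_nm: tuple = (50.0, 120.0)
    tapers: Optional[tuple] = None       # per-gap; default all tapered
    flank_nm: float = 300.0              # length of every membrane chain
    vertex_spacing_nm: float = 10.0
    field_area_um2: float = 0.1
    hook_nm: float = 60.0                # blunt-edge perpendicular excursion
    label: str = "region"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tapers is None:
            self.tapers = tuple(True for _ in self.gap_widths_nm)
        if len(self.tapers) != len(self.gap_widths_nm):
            raise ParameterError("tapers must match gap_widths_nm in length")
        if any(w <= 0 for w in self.gap_widths_nm):
            raise ParameterError("gap widths must be > 0 (non-overlapping)")
        if self.flank_nm <= 0 or self.vertex_spacing_nm <= 0:
            raise ParameterError("flank and vertex spacing must be > 0")
        if self.flank_nm < 2 * self.vertex_spacing_nm:
            raise ParameterError(
                "flank too short for the requested vertex spacing"
            )
        if not (self.field_area_um2 > 0):
            raise ParameterError("field area must be > 0")
        if self.hook_nm <= 0:
            raise ParameterError("hook_nm must be > 0")


def _make_chain(x0: float, length: float, spacing: float,
                hook_left: bool, hook_right: bool, hook_nm: float,
                ) -> np.ndarray:
    n = max(3, int(round(length / spacing)) + 1)
    xs = np.linspace(x0, x0 + length, n)
    ys = np.zeros(n)
    # a blunt (non-tapering) edge: the vertex adjacent to the terminal one
    # is displaced perpendicular to the membrane line, leaving the endpoint
    # itself (and hence the measured gap width) in place
    if hook_left:
        ys[1] = hook_nm
    if hook_right:
        ys[-2] = hook_nm
    return np.column_stack([xs, ys])


def gen_membrane_field(params: SynthHoleFieldParams,
                       ) -> tuple[MembraneTrace, pd.DataFrame]:
    """Membrane chains separated by the requested gaps, plus ground truth.

    Truth columns: gap, width_nm, tapered, flank_left_nm, flank_right_nm,
    and accepted_truth (criteria evaluated at the classifier defaults).
    """
    p = params
    n_gaps = len(p.gap_widths_nm)
    chains = []
    truth = []
    # chain i sits left of gap i; one final chain closes the field
    x = 0.0
    hooks_right = [not t for t in p.tapers]           # gap i's left edge
    hooks_left = [False] + [not t for t in p.tapers]  # chain i+1's left edge
    for i in range(n_gaps + 1):
        chains.append(_make_chain(
            x, p.flank_nm, p.vertex_spacing_nm,
            hook_left=hooks_left[i],
            hook_right=hooks_right[i] if i < n_gaps else False,
            hook_nm=p.hook_nm,
        ))
        x += p.flank_nm
        if i < n_gaps:
            x += p.gap_widths_nm[i]
    for i, (w, tapered) in enumerate(zip(p.gap_widths_nm, p.tapers)):
        truth.append({
            "gap": i,
            "width_nm": float(w),
            "tapered": bool(tapered),
            "flank_left_nm": p.flank_nm,
            "flank_right_nm": p.flank_nm,
            "accepted_truth": (
                w < nemap.DEFAULT_WIDTH_MAX_NM
                and bool(tapered)
                and p.flank_nm >= nemap.DEFAULT_FLANK_MIN_NM
            ),
        })
    trace = MembraneTrace(chains=chains, area_um2=p.field_area_um2,
                          label=p.label)
    return trace, pd.DataFrame(truth)
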