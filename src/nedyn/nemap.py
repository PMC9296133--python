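"""Nascent-NPC hole detection in traced nuclear-membrane polylines.

Membranes traced in 2-D tomogram slices arrive as polyline chains (vertices
in nm).  Interruptions between facing chain ends are enumerated as gap
candidates and scored against three acceptance criteria that distinguish a
nascent nuclear pore from a simple NE hole:

1. the gap between the two membrane edges is less than 100 nm (strict);
2. both membrane edges taper to a point (operationalized as the
   perpendicular spread of the terminal vertex run staying below a bound,
   i.e. the edge narrows instead of ending bluntly);
3. there are stretches of continuous membrane on both sides of the gap
   (flank arc length at or above a minimum, 100 nm by default).

Accepted holes per traced region are converted to densities per um^2; both
the mean of per-region densities and the pooled count/area are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import GeometryError, InputError

DEFAULT_PAIRING_MAX_NM = 300.0
DEFAULT_WIDTH_MAX_NM = 100.0
DEFAULT_FLANK_MIN_NM = 100.0
DEFAULT_TAPER_MAX_NM = 20.0
TAPER_RUN_VERTICES = 5


@dataclass
class MembraneTrace:
    """Traced membrane chains for one tomogram region (vertices in nm)."""

    chains: list[np.ndarray]
    area_um2: float
    label: str = "region"

    def __post_init__(self) -> None:
        if not (self.area_um2 > 0):
            raise InputError("region area must be > 0")
        chains = []
        for i, c in enumerate(self.chains):
            c = np.asarray(c, dtype=float)
            if c.ndim != 2 or c.shape[1] != 2 or len(c) < 2:
                raise GeometryError(f"chain {i} must be an (N>=2, 2) array")
            chains.append(c)
        self.chains = chains


@dataclass
class GapCandidate:
    """A pair of facing chain ends: the raw geometry of a potential hole."""

    width_nm: float
    taper_a_nm: float
    taper_b_nm: float
    flank_a_nm: float
    flank_b_nm: float
    end_a: tuple[float, float]
    end_b: tuple[float, float]
    chain_a: int
    chain_b: int


@dataclass
class HoleCall:
    """A gap candidate scored against the three acceptance criteria."""

    candidate: GapCandidate
    c1_width: bool
    c2_taper: bool
    c3_flanks: bool

    @property
    def accepted(self) -> bool:
        return self.c1_width and self.c2_taper and self.c3_flanks


@dataclass
class RegionDensity:
    label: str
    area_um2: float
    n_candidates: int
    n_accepted: int
    density_per_um2: float


@dataclass
class DensityResult:
    regions: list[RegionDensity]
    mean_density_per_um2: float     # mean of per-region densities
    pooled_density_per_um2: float   # sum(counts) / sum(areas)

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "region": r.label,
            "area_um2": r.area_um2,
            "n_candidates": r.n_candidates,
            "n_accepted": r.n_accepted,
            "density_per_um2": r.density_per_um2,
        } for r in self.regions]
        rows.append({
            "region": "summary",
            "area_um2": sum(r.area_um2 for r in self.regions),
            "n_candidates": sum(r.n_candidates for r in self.regions),
            "n_accepted": sum(r.n_accepted for r in self.regions),
            "density_per_um2": self.pooled_density_per_um2,
        })
        df = pd.DataFrame(rows)
        df.attrs["mean_density_per_um2"] = self.mean_density_per_um2
        return df


def _arc_length(chain: np.ndarray) -> float:
    return float(np.sum(np.hypot(*np.diff(chain, axis=0).T)))


def _is_closed(chain: np.ndarray) -> bool:
    return len(chain) > 2 and np.allclose(chain[0], chain[-1])


def _terminal_run(chain: np.ndarray, end: int,
                  k: int = TAPER_RUN_VERTICES) -> np.ndarray:
    """Last k vertices ordered toward the endpoint (run[-1] is terminal)."""
    if end == 0:
        return chain[:k][::-1]
    return chain[-k:]


def _taper_measure(run: np.ndarray) -> float:
    """Max perpendicular spread of the terminal run about its own direction.

    Zero for a straight (tapering) edge; large when the edge ends with a
    blunt hook or fold.
    """
    if len(run) < 3:
        return 0.0
    d = run[-1] - run[0]
    norm = float(np.hypot(*d))
    if norm == 0:
        return float(np.max(np.hypot(*(run - run[0]).T)))
    u = d / norm
    rel = run - run[0]
    perp = np.abs(rel[:, 0] * u[1] - rel[:, 1] * u[0])
    return float(perp.max())


def detect_gaps(trace: MembraneTrace,
                pairing_max_nm: float = DEFAULT_PAIRING_MAX_NM,
                return_unpaired: bool = False):
    """Enumerate facing chain-end pairs as gap candidates.

    Two endpoints form a candidate when they belong to different chains, are
    mutually nearest among all endpoints, and lie within ``pairing_max_nm``
    of each other.  Endpoints of the same chain are never paired (a straight
    open chain shorter than the pairing radius would otherwise pair with
    itself).  Unpaired endpoints — edges of large ruptures — are returned
    separately on request.
    """
    ends = []  # (chain_idx, end_idx, coord, flank, taper)
    for ci, chain in enumerate(trace.chains):
        if _is_closed(chain):
            continue
        flank = _arc_length(chain)
        for end in (0, 1):
            coord = chain[0] if end == 0 else chain[-1]
            taper = _taper_measure(_terminal_run(chain, end))
            ends.append((ci, end, coord, flank, taper))

    candidates: list[GapCandidate] = []
    paired: set[int] = set()
    if len(ends) >= 2:
        coords = np.array([e[2] for e in ends])
        dist = np.hypot(coords[:, 0, None] - coords[None, :, 0],
                        coords[:, 1, None] - coords[None, :, 1])
        same_chain = np.equal.outer([e[0] for e in ends],
                                    [e[0] for e in ends])
        dist[same_chain] = np.inf
        nearest = dist.argmin(axis=1)
        for i in range(len(ends)):
            j = int(nearest[i])
            if j <= i or int(nearest[j]) != i:
                continue
            if dist[i, j] > pairing_max_nm:
                continue
            a, b = ends[i], ends[j]
            candidates.append(GapCandidate(
                width_nm=float(dist[i, j]),
                taper_a_nm=a[4], taper_b_nm=b[4],
                flank_a_nm=a[3], flank_b_nm=b[3],
                end_a=tuple(a[2]), end_b=tuple(b[2]),
                chain_a=a[0], chain_b=b[0],
            ))
            paired.update((i, j))
    if return_unpaired:
        unpaired = [tuple(ends[i][2]) for i in range(len(ends))
                    if i not in paired]
        return candidates, unpaired
    return candidates


def classify_hole(candidate: GapCandidate,
                  width_max_nm: float = DEFAULT_WIDTH_MAX_NM,
                  flank_min_nm: float = DEFAULT_FLANK_MIN_NM,
                  taper_max_nm: float = DEFAULT_TAPER_MAX_NM) -> HoleCall:
    """Score one gap candidate against the three acceptance criteria.

    Criterion 1 is a strict inequality: a gap of exactly ``width_max_nm`` is
    rejected.
    """
    return HoleCall(
        candidate=candidate,
        c1_width=candidate.width_nm < width_max_nm,
        c2_taper=(candidate.taper_a_nm <= taper_max_nm
                  and candidate.taper_b_nm <= taper_max_nm),
        c3_flanks=(candidate.flank_a_nm >= flank_min_nm
                   and candidate.flank_b_nm >= flank_min_nm),
    )


def hole_density(calls: Mapping[str, Sequence[HoleCall]],
                 areas: Mapping[str, float]) -> DensityResult:
    """Per-region, mean-of-regions, and pooled hole densities (um^-2)."""
    missing = [label for label in calls if label not in areas]
    if missing:
        raise InputError(f"regions with calls but no area: {missing}")
    regions = []
    for label, area in areas.items():
        if not (area > 0):
            raise InputError(f"region {label!r} has non-positive area {area}")
        region_calls = list(calls.get(label, ()))
        n_acc = sum(1 for c in region_calls if c.accepted)
        regions.append(RegionDensity(
            label=str(label),
            area_um2=float(area),
            n_candidates=len(region_calls),
            n_accepted=n_acc,
            density_per_um2=n_acc / float(area),
        ))
    if not regions:
        raise InputError("no regions given")
    total_area = sum(r.area_um2 for r in regions)
    total_count = sum(r.n_accepted for r in regions)
    return DensityResult(
        regions=regions,
        mean_density_per_um2=float(np.mean(
            [r.density_per_um2 for r in regions])),
        pooled_density_per_um2=total_count / total_area,
    )
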