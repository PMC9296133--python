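"""FRAP recovery analysis.

Fluorescence recovery after photobleaching of a nuclear-envelope region is
normalized to the prebleach mean and fit to the single-exponential model

    f(t) = A * (1 - exp(-tau * t))

where ``A`` is the mobile fraction, ``tau`` the recovery rate (1/s), and the
half-time T1/2 = ln(2)/tau.  The immobile fraction is 1 - A.  t = 0 is the
first post-bleach frame, so the printed model implies f(0) = 0 (full bleach);
an optional constant-offset variant covers incomplete bleaching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitError, InputError, NormalizationError, SummaryError

LN2 = math.log(2.0)


@dataclass
class FRAPSeries:
    """A raw bleach series: prebleach frames followed by recovery frames."""

    times_s: np.ndarray      # full series; negative times are prebleach
    intensities: np.ndarray
    n_prebleach: int
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times_s.shape != self.intensities.shape:
            raise InputError("times and intensities must have equal length")
        if self.n_prebleach < 0 or self.n_prebleach >= len(self.intensities):
            raise InputError("n_prebleach must be in [0, len(series))")


@dataclass
class FRAPCurve:
    """Prebleach-normalized recovery curve; times start at 0 post-bleach."""

    times_s: np.ndarray
    normalized: np.ndarray
    raw: np.ndarray
    n_prebleach: int
    prebleach_mean: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.normalized = np.asarray(self.normalized, dtype=float)
        if (self.times_s < 0).any() or not np.all(np.diff(self.times_s) > 0):
            raise InputError("post-bleach times must be >= 0, strictly increasing")


@dataclass
class FRAPFit:
    """Fitted recovery parameters."""

    mobile_fraction: float          # A
    tau_per_s: float
    t_half_s: float                 # ln(2)/tau
    immobile_fraction: float        # 1 - A
    rss: float
    converged: bool
    se_mobile: float = float("nan")
    se_tau: float = float("nan")
    offset: float = 0.0
    above_one: bool = False         # flagged when A > 1 (noise, not physics)


@dataclass
class FitSummary:
    n: int
    n_excluded: int
    mean_mobile: float
    sd_mobile: Optional[float]
    mean_tau: float
    sd_tau: Optional[float]
    mean_t_half: float
    sd_t_half: Optional[float]


def normalize_frap(
    series: Union[FRAPSeries, Sequence[float], np.ndarray],
    frame_interval_s: Optional[float] = None,
    n_prebleach: Optional[int] = None,
) -> FRAPCurve:
    """Normalize a raw series to the prebleach mean and re-zero time.

    Accepts either a :class:`FRAPSeries` or a plain intensity array plus
    ``frame_interval_s`` and ``n_prebleach``.
    """
    if isinstance(series, FRAPSeries):
        raw = series.intensities
        dt = series.frame_interval_s
        npre = series.n_prebleach
    else:
        if frame_interval_s is None or n_prebleach is None:
            raise InputError(
                "frame_interval_s and n_prebleach required for array input"
            )
        raw = np.asarray(series, dtype=float)
        dt, npre = float(frame_interval_s), int(n_prebleach)
    if npre < 1:
        raise InputError("need at least one prebleach frame")
    if len(raw) <= npre:
        raise InputError("series has no post-bleach frames")
    pre_mean = float(np.mean(raw[:npre]))
    if pre_mean <= 0:
        raise NormalizationError(f"prebleach mean {pre_mean} is not positive")
    post = raw[npre:] / pre_mean
    times = np.arange(len(post), dtype=float) * dt
    return FRAPCurve(times, post, raw, npre, pre_mean, dt)


def _model(t: np.ndarray, a: float, tau: float) -> np.ndarray:
    return a * (1.0 - np.exp(-tau * t))


def _model_offset(t: np.ndarray, a: float, tau: float, c: float) -> np.ndarray:
    return c + a * (1.0 - np.exp(-tau * t))


def fit_recovery(
    curve: FRAPCurve,
    a_max: float = 1.5,
    init: Optional[tuple[float, float]] = None,
    include_offset: bool = False,
) -> FRAPFit:
    """Least-squares fit of the recovery model to a normalized curve.

    The mobile fraction is bounded to [0, a_max] with a_max = 1.5 by default
    so noise near A ~ 1 is not clipped at a hard physical bound; fits with
    A > 1 are flagged.  If the default start fails, tau is multistarted over
    five decades; among converged starts the lowest-RSS solution wins.
    """
    t = curve.times_s
    y = curve.normalized
    if len(t) < 4:
        raise InputError(f"need >= 4 post-bleach points, got {len(t)}")
    if len(np.unique(t)) < 2:
        raise InputError("need at least 2 distinct times")

    if init is not None:
        a0, tau0 = init
        a0 = float(np.clip(a0, 0.0, a_max))
    else:
        a0 = float(np.clip(y[-1], 0.0, a_max))
        tpos = t[t > 0]
        tau0 = 1.0 / float(np.median(tpos)) if len(tpos) else 1.0
    tau_starts = [tau0 * 10.0 ** k for k in (0, -2, -1, 1, 2)]

    best = None
    attempts: list[str] = []
    for tau_s in tau_starts:
        try:
            if include_offset:
                p0 = [a0, tau_s, float(y[0])]
                bounds = ([0.0, 1e-12, -a_max], [a_max, np.inf, a_max])
                popt, pcov = curve_fit(_model_offset, t, y, p0=p0,
                                       bounds=bounds, maxfev=20000)
                resid = y - _model_offset(t, *popt)
            else:
                p0 = [a0, tau_s]
                bounds = ([0.0, 1e-12], [a_max, np.inf])
                popt, pcov = curve_fit(_model, t, y, p0=p0,
                                       bounds=bounds, maxfev=20000)
                resid = y - _model(t, *popt)
        except (RuntimeError, ValueError) as exc:
            attempts.append(f"tau0={tau_s:g}: {exc}")
            continue
        rss = float(np.sum(resid ** 2))
        attempts.append(f"tau0={tau_s:g}: rss={rss:g}")
        if best is None or rss < best[0]:
            best = (rss, popt, pcov)
    if best is None:
        raise FitError("fit did not converge after multistart; " +
                       "; ".join(attempts))

    rss, popt, pcov = best
    a_hat, tau_hat = float(popt[0]), float(popt[1])
    c_hat = float(popt[2]) if include_offset else 0.0
    with np.errstate(invalid="ignore"):
        ses = np.sqrt(np.diag(pcov))
    return FRAPFit(
        mobile_fraction=a_hat,
        tau_per_s=tau_hat,
        t_half_s=LN2 / tau_hat,
        immobile_fraction=1.0 - a_hat,
        rss=rss,
        converged=True,
        se_mobile=float(ses[0]),
        se_tau=float(ses[1]),
        offset=c_hat,
        above_one=a_hat > 1.0,
    )


def summarize_fits(fits: Sequence[FRAPFit]) -> FitSummary:
    """Mean +/- sample SD of A, tau and T1/2 over converged fits."""
    conv = [f for f in fits if f.converged]
    if not conv:
        raise SummaryError("no converged fits to summarize")
    a = np.array([f.mobile_fraction for f in conv])
    tau = np.array([f.tau_per_s for f in conv])
    th = np.array([f.t_half_s for f in conv])

    def _sd(x: np.ndarray) -> Optional[float]:
        return float(np.std(x, ddof=1)) if len(x) > 1 else None

    return FitSummary(
        n=len(conv),
        n_excluded=len(fits) - len(conv),
        mean_mobile=float(a.mean()), sd_mobile=_sd(a),
        mean_tau=float(tau.mean()), sd_tau=_sd(tau),
        mean_t_half=float(th.mean()), sd_t_half=_sd(th),
    )


# ---------------------------------------------------------------------------
# CSV interface (columns: time_s, intensity, phase in {pre, post})
# ---------------------------------------------------------------------------


def read_frap_csv(path: str | Path) -> FRAPSeries:
    p = Path(path)
    if not p.exists():
        raise InputError(f"no such file: {p}")
    df = pd.read_csv(p)
    for col in ("time_s", "intensity", "phase"):
        if col not in df.columns:
            raise InputError(f"{p}: missing column {col!r}")
    phases = df["phase"].astype(str).str.strip().str.lower()
    if not phases.isin(["pre", "post"]).all():
        raise InputError(f"{p}: phase must be 'pre' or 'post'")
    npre = int((phases == "pre").sum())
    if not (phases.iloc[:npre] == "pre").all():
        raise InputError(f"{p}: prebleach rows must precede post-bleach rows")
    times = df["time_s"].to_numpy(dtype=float)
    dts = np.diff(times)
    if len(dts) == 0 or not np.all(dts > 0):
        raise InputError(f"{p}: times must be strictly increasing")
    return FRAPSeries(
        times_s=times,
        intensities=df["intensity"].to_numpy(dtype=float),
        n_prebleach=npre,
        frame_interval_s=float(np.median(dts)),
    )


def write_frap_series(series: FRAPSeries, path: str | Path) -> Path:
    p = Path(path)
    phase = ["pre"] * series.n_prebleach + \
            ["post"] * (len(series.intensities) - series.n_prebleach)
    pd.DataFrame({
        "time_s": series.times_s,
        "intensity": series.intensities,
        "phase": phase,
    }).to_csv(p, index=False)
    return p


def fit_to_frame(fits: Sequence[FRAPFit]) -> pd.DataFrame:
    """Tabulate fits with the output CSV schema."""
    return pd.DataFrame([{
        "A": f.mobile_fraction,
        "tau_per_s": f.tau_per_s,
        "t_half_s": f.t_half_s,
        "immobile": f.immobile_fraction,
        "rss": f.rss,
        "converged": f.converged,
        "se_A": f.se_mobile,
        "se_tau": f.se_tau,
    } for f in fits])
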