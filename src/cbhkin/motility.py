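"""Translational rates, moving times, and processivity.

A molecule's translational rate k_tr is its net first-to-last displacement
divided by its moving time (track span). Processive sliders give a slow
k_tr peak; surface-diffusing molecules an apparently fast one, so the k_tr
histogram is decomposed into Gaussian peaks. Moving times are fitted with a
single exponential decay, either over the whole histogram excluding the
first bin, or restricted to times beyond a threshold (long movers are
almost purely processive). Processivity is then the number of cellobiose
units released per productive run: slow rate × moving-time constant /
product length (~1 nm per cellobiose).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ._gaussian import GaussianMixtureFit, fit_gaussian_mixture
from .errors import (
    FitFailureError,
    InsufficientDataError,
    InvalidParameterError,
    TrajectoryFormatError,
)
from .models import ImagingConditions

MOVING_TIME_MODES = ("full_excl_first_bin", "tail_gt_threshold")


@dataclass(frozen=True)
class Track:
    """One localized single-molecule trajectory (times in s, positions nm)."""

    track_id: str
    t: np.ndarray
    xy: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.t)

    @property
    def moving_time(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def net_displacement(self) -> float:
        return float(np.linalg.norm(self.xy[-1] - self.xy[0]))

    @property
    def k_tr(self) -> float:
        return self.net_displacement / self.moving_time


@dataclass(frozen=True)
class TrackSet:
    """Tracks retained for analysis plus the filtering tallies."""

    tracks: tuple[Track, ...]
    n_static: int
    n_too_short: int

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)


@dataclass(frozen=True)
class MotionSummary:
    """Per-track rates with an optional fitted peak decomposition."""

    per_track: pd.DataFrame  # track_id, n_frames, moving_time, net_displacement, k_tr
    fit: GaussianMixtureFit | None = None

    @property
    def k_tr_values(self) -> np.ndarray:
        return self.per_track["k_tr"].to_numpy()

    @property
    def moving_times(self) -> np.ndarray:
        return self.per_track["moving_time"].to_numpy()

    @property
    def slow_peak(self) -> float:
        if self.fit is None:
            raise InvalidParameterError("no peak fit attached")
        return self.fit.smallest_peak

    @property
    def fast_peak(self) -> float:
        if self.fit is None:
            raise InvalidParameterError("no peak fit attached")
        return self.fit.largest_peak


@dataclass(frozen=True)
class MovingTimeFit:
    """Single-exponential fit of the moving-time histogram."""

    mode: str
    tau: float
    threshold: float
    r_squared: float
    amplitude: float
    n_times: int

    def __post_init__(self):
        if not self.tau > 0:
            raise InvalidParameterError("tau must be > 0")
        if self.mode not in MOVING_TIME_MODES:
            raise InvalidParameterError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class ProcessivityEstimate:
    """Catalytic steps per productive run; rounded value used in reports."""

    value: float
    rounded: int
    v_slow: float
    tau: float
    product_length: float


def pooled_precision(cond: ImagingConditions) -> float:
    """RMS of the per-axis localization precisions."""
    return math.sqrt((cond.loc_precision_x**2 + cond.loc_precision_y**2) / 2.0)


def load_tracks(
    traj: pd.DataFrame,
    cond: ImagingConditions,
    min_frames: int = 2,
    static_threshold_mult: float = 3.0,
) -> TrackSet:
    """Build Track objects from a trajectory table and filter them.

    Tracks with fewer than ``min_frames`` localizations are dropped; tracks
    whose net displacement does not exceed ``static_threshold_mult`` × the
    pooled localization precision are classified static and excluded from
    rate analysis (their count is reported). Frames within a track must be
    strictly increasing.
    """
    if min_frames < 2:
        raise InvalidParameterError("min_frames must be >= 2")
    threshold = static_threshold_mult * pooled_precision(cond)
    tracks: list[Track] = []
    n_static = 0
    n_short = 0
    for tid, g in traj.groupby("track_id", sort=True):
        frames = g["frame"].to_numpy()
        if not (np.diff(frames) > 0).all():
            raise TrajectoryFormatError(f"track {tid}: frames not strictly increasing")
        if len(g) < min_frames:
            n_short += 1
            continue
        tr = Track(
            track_id=str(tid),
            t=g["t"].to_numpy(dtype=float),
            xy=g[["x", "y"]].to_numpy(dtype=float),
        )
        if tr.net_displacement <= threshold:
            n_static += 1
            continue
        tracks.append(tr)
    return TrackSet(tuple(tracks), n_static=n_static, n_too_short=n_short)


def translational_rates(tracks: TrackSet | list[Track]) -> MotionSummary:
    """k_tr per track: Euclidean first-to-last distance over track span."""
    rows = [
        (tr.track_id, tr.n_frames, tr.moving_time, tr.net_displacement, tr.k_tr)
        for tr in tracks
    ]
    df = pd.DataFrame(
        rows, columns=["track_id", "n_frames", "moving_time", "net_displacement", "k_tr"]
    )
    return MotionSummary(per_track=df)


def fit_ktr_distribution(
    summary: MotionSummary,
    n_components: int | None = None,
    bin_width: float | None = None,
    improvement_threshold: float = 0.01,
) -> MotionSummary:
    """Fit the k_tr histogram with 1 or 2 Gaussians (auto-selected when
    ``n_components`` is None); returns a summary carrying the fit."""
    values = summary.k_tr_values
    if len(values) < 30:
        raise InsufficientDataError("need >= 30 tracks to fit the k_tr distribution")
    if n_components is not None and n_components not in (1, 2):
        raise InvalidParameterError("n_components must be 1 or 2")
    fit = fit_gaussian_mixture(
        values,
        bin_width=bin_width,
        max_components=2,
        n_components=n_components,
        improvement_threshold=improvement_threshold,
        min_values=30,
    )
    return MotionSummary(per_track=summary.per_track, fit=fit)


def _single_exp(t, a, tau):
    return a * np.exp(-t / tau)


def fit_moving_time(
    times,
    mode: str = "full_excl_first_bin",
    threshold: float = 10.0,
    bin_width: float = 1.0,
) -> MovingTimeFit:
    """Single-exponential fit of the moving-time histogram.

    ``full_excl_first_bin`` drops the first histogram bin (dominated by
    tracks too short to classify); ``tail_gt_threshold`` keeps only bins
    whose lower edge is at or beyond ``threshold`` seconds, where the
    population is essentially purely processive.
    """
    times = np.asarray(list(times), dtype=float)
    if mode not in MOVING_TIME_MODES:
        raise InvalidParameterError(f"unknown mode {mode!r}")
    if not bin_width > 0:
        raise InvalidParameterError("bin_width must be > 0")
    if mode == "full_excl_first_bin" and len(times) < 10:
        raise InsufficientDataError("need >= 10 moving times for the full fit")
    if mode == "tail_gt_threshold" and int((times >= threshold).sum()) < 5:
        raise InsufficientDataError(
            f"need >= 5 moving times at or beyond {threshold} s for the tail fit"
        )
    edges = np.arange(0.0, times.max() + bin_width, bin_width)
    if len(edges) < 3:
        edges = np.array([0.0, bin_width, 2 * bin_width])
    counts, edges = np.histogram(times, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if mode == "full_excl_first_bin":
        keep = np.arange(len(centers)) >= 1
    else:
        keep = edges[:-1] >= threshold
    x, y = centers[keep], counts[keep].astype(float)
    if int((y > 0).sum()) < 2:
        raise InsufficientDataError("fewer than two populated bins in the fit range")
    tau0 = max(float(times.mean()), bin_width)
    try:
        popt, _ = curve_fit(
            _single_exp, x, y, p0=[max(y.max(), 1.0), tau0],
            bounds=(1e-12, np.inf), maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(
            "moving-time fit did not converge", diagnostics={"cause": str(exc)}
        ) from exc
    resid = y - _single_exp(x, *popt)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else float("nan")
    return MovingTimeFit(
        mode=mode, tau=float(popt[1]), threshold=threshold,
        r_squared=r2, amplitude=float(popt[0]), n_times=len(times),
    )


def processivity(
    v_slow: float, tau: float, product_length: float = 1.0
) -> ProcessivityEstimate:
    """Catalytic steps per run: v_slow × tau / product_length.

    With the slow translational rate in nm/s, the moving-time constant in
    s and the cellobiose length (~1 nm), this counts cellobiose units
    released during an average productive run.
    """
    if not (v_slow > 0 and tau > 0 and product_length > 0):
        raise InvalidParameterError("v_slow, tau and product_length must be > 0")
    value = v_slow * tau / product_length
    return ProcessivityEstimate(
        value=value, rounded=int(round(value)),
        v_slow=v_slow, tau=tau, product_length=product_length,
    )


def single_molecule_rate(v_slow: float, product_length: float = 1.0) -> float:
    """Hydrolytic turnover of a productively bound molecule (s⁻¹): the
    sliding velocity divided by the product length released per step."""
    if not (v_slow > 0 and product_length > 0):
        raise InvalidParameterError("v_slow and product_length must be > 0")
    return v_slow / product_length
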