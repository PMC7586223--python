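"""Dwell-time (binding-time) distributions and exponential-decay fits.

Binding times of individual molecules on a fibril are pooled into a
histogram binned at the frame interval and fitted with a single or double
exponential decay, y(t) = Σ A_i exp(−k_i t). For a double fit the two
components are labeled fast/slow by rate; each component's share of events
is the area of its decay integrated over [0, ∞), i.e. f_i ∝ A_i / k_i.
Photobleaching competes with true dissociation, so an optional correction
subtracts the bleach rate from each fitted rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    EmptyDatasetError,
    FitFailureError,
    InsufficientDataError,
    InvalidParameterError,
)
from .models import ImagingConditions

RATE_FLOOR = 1e-6  # s^-1; lower bound for a bleach-corrected rate

ILL_SEPARATED = "ill-separated: k_fast/k_slow < 2"
MINOR_COMPONENT = "minor component: smallest area fraction < 0.10"
MIN_COMPONENT_FRACTION = 0.10
UNRELIABLE_BLEACH = "bleach rate >= slowest observed rate; correction unreliable"


def rate_to_time_constant(rate: float) -> float:
    """Convert an exponential rate constant (s⁻¹) to its time constant (s)."""
    if not rate > 0:
        raise InvalidParameterError("rate must be > 0")
    return 1.0 / rate


def time_constant_to_rate(tau: float) -> float:
    """Convert an exponential time constant (s) to its rate constant (s⁻¹)."""
    if not tau > 0:
        raise InvalidParameterError("tau must be > 0")
    return 1.0 / tau


@dataclass(frozen=True)
class DwellDataset:
    """Uncensored dwell times with their frame-interval histogram."""

    dwells: np.ndarray
    frame_interval: float
    bin_edges: np.ndarray
    counts: np.ndarray
    n_censored: int
    min_frames: int

    @property
    def n(self) -> int:
        return len(self.dwells)


@dataclass(frozen=True)
class ExpDecayFit:
    """A fitted sum of exponential decays.

    For ``n_components == 2`` the first component is the fast one. The
    fractions are area ratios, f_i = (A_i/k_i) / Σ_j (A_j/k_j).
    """

    n_components: int
    amplitudes: tuple[float, ...]
    rates: tuple[float, ...]
    fractions: tuple[float, ...]
    r_squared: float
    n_events: int
    bleach_corrected: bool = False
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise InvalidParameterError("fractions must sum to 1")
        if self.n_components == 2 and not self.rates[0] > self.rates[1]:
            raise InvalidParameterError("fast rate must exceed slow rate")

    @property
    def k_fast(self) -> float:
        return self.rates[0]

    @property
    def k_slow(self) -> float:
        return self.rates[-1]

    @property
    def frac_fast(self) -> float:
        return self.fractions[0]

    @property
    def frac_slow(self) -> float:
        return self.fractions[-1]


def _area_fractions(amplitudes, rates) -> tuple[float, ...]:
    if any(k <= 0 for k in rates):
        raise InvalidParameterError("all rates must be > 0 to compute area fractions")
    areas = np.asarray(amplitudes, dtype=float) / np.asarray(rates, dtype=float)
    return tuple(areas / areas.sum())


def collect_dwells(
    events: pd.DataFrame, cond: ImagingConditions, min_frames: int = 1
) -> DwellDataset:
    """Extract dwell times from an event table and histogram them.

    Movie-end-censored events are excluded (their count is reported);
    events spanning fewer than ``min_frames`` frame intervals are dropped
    as unresolvable. Histogram bin edges sit at multiples of the frame
    interval.
    """
    if min_frames < 1:
        raise InvalidParameterError("min_frames must be >= 1")
    dt = cond.frame_interval
    censored = events["end_cause"] == "movie_end"
    dwells = (events.loc[~censored, "t_end"] - events.loc[~censored, "t_bind"]).to_numpy()
    dwells = dwells[dwells >= min_frames * dt]
    if len(dwells) == 0:
        raise EmptyDatasetError("no uncensored dwells of at least min_frames intervals")
    lo = min_frames * dt
    hi = (np.floor(dwells.max() / dt) + 1) * dt
    edges = np.arange(lo, hi + 0.5 * dt, dt)
    counts, edges = np.histogram(dwells, bins=edges)
    return DwellDataset(
        dwells=dwells,
        frame_interval=dt,
        bin_edges=edges,
        counts=counts,
        n_censored=int(censored.sum()),
        min_frames=min_frames,
    )


def _exp_sum(t, *params):
    y = np.zeros_like(t, dtype=float)
    for i in range(0, len(params), 2):
        y = y + params[i] * np.exp(-params[i + 1] * t)
    return y


def fit_exponential(
    data: DwellDataset, n_components: int = 2, include_first_bin: bool = True
) -> ExpDecayFit:
    """Least-squares fit of a 1- or 2-exponential decay to the histogram.

    The fit is unweighted on histogram counts at bin centers. For the
    double fit, a fast/slow rate ratio below 2 attaches an ill-separated
    warning to the result rather than failing.
    """
    if n_components not in (1, 2):
        raise InvalidParameterError("n_components must be 1 or 2")
    centers = 0.5 * (data.bin_edges[:-1] + data.bin_edges[1:])
    y = data.counts.astype(float)
    if not include_first_bin:
        centers, y = centers[1:], y[1:]
    if int((y > 0).sum()) < 5:
        raise InsufficientDataError("need >= 5 nonzero histogram bins")

    mean_rate = 1.0 / float(data.dwells.mean())
    amp0 = max(float(y.max()), 1.0)
    if n_components == 1:
        p0 = [amp0, mean_rate]
    else:
        p0 = [amp0, 3.0 * mean_rate, 0.5 * amp0, 0.3 * mean_rate]
    try:
        popt, _ = curve_fit(
            _exp_sum, centers, y, p0=p0, bounds=(1e-12, np.inf), maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(
            f"{n_components}-exponential fit did not converge",
            diagnostics={"n_bins": len(y), "n_events": data.n, "cause": str(exc)},
        ) from exc
    resid = y - _exp_sum(centers, *popt)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise FitFailureError("flat histogram: R^2 undefined")
    r2 = 1.0 - float((resid**2).sum()) / ss_tot

    comps = sorted(
        ((popt[2 * i + 1], popt[2 * i]) for i in range(n_components)), reverse=True
    )
    rates = tuple(c[0] for c in comps)
    amps = tuple(c[1] for c in comps)
    fractions = _area_fractions(amps, rates)
    warns: tuple[str, ...] = ()
    if n_components == 2:
        if rates[0] / rates[1] < 2.0:
            warns += (ILL_SEPARATED,)
        if min(fractions) < MIN_COMPONENT_FRACTION:
            warns += (MINOR_COMPONENT,)
    return ExpDecayFit(
        n_components=n_components,
        amplitudes=amps,
        rates=rates,
        fractions=fractions,
        r_squared=r2,
        n_events=data.n,
        warnings=warns,
    )


def component_fractions(fit: ExpDecayFit) -> tuple[float, ...]:
    """Area-ratio fractions f_i = (A_i/k_i) / Σ_j (A_j/k_j)."""
    return _area_fractions(fit.amplitudes, fit.rates)


def select_decay_model(
    fit1: ExpDecayFit, fit2: ExpDecayFit, tie_tolerance: float = 0.005
) -> ExpDecayFit:
    """Choose between single- and double-exponential fits of one dataset.

    The double model wins on a strict R² improvement and also on a tie
    (two binding modes are the default physical picture); a tied or better
    double fit is still rejected if its rates are ill-separated or one
    component's area share is negligible — both patterns of a second
    exponential that merely absorbs counting noise.
    """
    if fit1.n_components != 1 or fit2.n_components != 2:
        raise InvalidParameterError("expected (single, double) fits in that order")
    better_or_tied = fit2.r_squared >= fit1.r_squared - tie_tolerance
    if better_or_tied and not fit2.warnings:
        return fit2
    return fit1


def bleach_correct(fit: ExpDecayFit, bleach_rate: float) -> ExpDecayFit:
    """Subtract the photobleaching rate from every fitted rate.

    Observed disappearance is the sum of true dissociation and bleaching,
    so k_true ≈ k_obs − k_bleach, floored at a small positive value. The
    fractions are recomputed from the corrected areas. If the bleach rate
    is not well below the slowest observed rate the correction is flagged
    unreliable.
    """
    if bleach_rate < 0:
        raise InvalidParameterError("bleach_rate must be >= 0")
    if bleach_rate == 0:
        return fit
    # Descending floors keep fast > slow even if both rates hit the floor.
    corrected = tuple(
        max(k - bleach_rate, RATE_FLOOR * (fit.n_components - i))
        for i, k in enumerate(fit.rates)
    )
    warns = fit.warnings
    if bleach_rate >= min(fit.rates):
        warns = warns + (UNRELIABLE_BLEACH,)
    return replace(
        fit,
        rates=corrected,
        fractions=_area_fractions(fit.amplitudes, corrected),
        bleach_corrected=True,
        warnings=warns,
    )
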