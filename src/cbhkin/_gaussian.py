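"""Histogram least-squares fitting of sums of Gaussians.

Both the binding-rate-constant distributions and the translational-rate
distributions are analysed the same way: histogram the per-fibril (or
per-track) values, fit a sum of 1..k Gaussian functions by nonlinear least
squares, and select the smallest component count whose R² is not improved
by more than a threshold by adding another component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitFailureError, InsufficientDataError, InvalidParameterError

# Adjacent fitted peaks closer than this many combined SDs are treated as
# one unresolved peak and the higher-order model is rejected.
MIN_SEPARATION_WIDTHS = 1.5


@dataclass(frozen=True)
class GaussianMixtureFit:
    """A sum-of-Gaussians fit to a histogram; components sorted by peak."""

    n_components: int
    peaks: tuple[float, ...]
    widths: tuple[float, ...]
    amplitudes: tuple[float, ...]
    r_squared: float
    bin_width: float
    n_values: int

    def __post_init__(self):
        if self.n_components != len(self.peaks):
            raise InvalidParameterError("n_components inconsistent with peaks")
        if list(self.peaks) != sorted(self.peaks):
            raise InvalidParameterError("peaks must be sorted ascending")
        if any(w <= 0 for w in self.widths) or any(a <= 0 for a in self.amplitudes):
            raise InvalidParameterError("widths and amplitudes must be > 0")

    @property
    def smallest_peak(self) -> float:
        return self.peaks[0]

    @property
    def largest_peak(self) -> float:
        return self.peaks[-1]


def _gauss_sum(x, *params):
    y = np.zeros_like(x, dtype=float)
    for i in range(0, len(params), 3):
        a, m, s = params[i : i + 3]
        y = y + a * np.exp(-((x - m) ** 2) / (2.0 * s**2))
    return y


def freedman_diaconis_width(values: np.ndarray) -> float:
    """Freedman–Diaconis histogram bin width; 0 for degenerate samples."""
    q75, q25 = np.percentile(values, [75, 25])
    return 2.0 * (q75 - q25) / len(values) ** (1.0 / 3.0)


def _fit_k(x, y, k, x_lo, x_hi, sd, bin_width):
    p0, lo, hi = [], [], []
    amp0 = max(float(y.max()), 1e-12)
    for i in range(k):
        mean0 = x_lo + (i + 0.5) / k * (x_hi - x_lo)
        sigma0 = max(sd / max(k, 1), bin_width)
        p0 += [amp0, mean0, sigma0]
        # A component narrower than one bin is not resolvable on the
        # histogram and only fits counting noise.
        lo += [0.0, x_lo - sd, bin_width]
        hi += [np.inf, x_hi + sd, np.inf]
    popt, _ = curve_fit(_gauss_sum, x, y, p0=p0, bounds=(lo, hi), maxfev=20000)
    resid = y - _gauss_sum(x, *popt)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise FitFailureError("flat histogram: R^2 undefined")
    r2 = 1.0 - float((resid**2).sum()) / ss_tot
    comps = sorted(
        ((popt[3 * i + 1], popt[3 * i + 2], popt[3 * i]) for i in range(k)),
        key=lambda c: c[0],
    )
    # Adjacent peaks must be mutually resolvable; otherwise the extra
    # component is just splitting one peak to absorb counting noise.
    for (m1, w1, _), (m2, w2, _) in zip(comps, comps[1:]):
        if m2 - m1 < MIN_SEPARATION_WIDTHS * (w1 + w2):
            raise FitFailureError("components not resolvable")
    return comps, r2


def fit_gaussian_mixture(
    values,
    bin_width: float | None = None,
    max_components: int = 3,
    n_components: int | None = None,
    improvement_threshold: float = 0.01,
    min_values: int = 10,
) -> GaussianMixtureFit:
    """Fit 1..max_components Gaussians to the histogram of ``values``.

    With ``n_components`` given, fit exactly that many. Otherwise fit each
    k and return the smallest k whose R² is within ``improvement_threshold``
    of the next larger model's R² (i.e. adding a component buys less than
    the threshold).
    """
    values = np.asarray(values, dtype=float)
    if len(values) < min_values:
        raise InsufficientDataError(
            f"need >= {min_values} values for a distribution fit, got {len(values)}"
        )
    if bin_width is None:
        bin_width = freedman_diaconis_width(values)
        span = float(values.max() - values.min())
        # FD can give very coarse bins on multimodal samples (the IQR spans
        # the modes); keep at least 20 bins so narrow peaks stay resolved.
        if span > 0 and bin_width > 0:
            bin_width = min(bin_width, span / 20.0)
    if not bin_width > 0:
        raise FitFailureError(
            "degenerate histogram (zero bin width)",
            diagnostics={"n": len(values), "sd": float(values.std())},
        )
    edges = np.arange(values.min(), values.max() + bin_width, bin_width)
    if len(edges) < 4:
        edges = np.linspace(values.min(), values.max(), 4)
    counts, edges = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    sd = float(values.std()) or bin_width

    ks = [n_components] if n_components is not None else list(range(1, max_components + 1))
    fits: dict[int, tuple[list, float]] = {}
    failures: dict[int, str] = {}
    for k in ks:
        if 3 * k > len(centers):
            failures[k] = "fewer bins than parameters"
            continue
        try:
            fits[k] = _fit_k(
                centers, counts.astype(float), k, values.min(), values.max(), sd, bin_width
            )
        except (RuntimeError, FitFailureError, ValueError) as exc:
            failures[k] = str(exc)
    if not fits:
        raise FitFailureError("no Gaussian fit converged", diagnostics=failures)

    if n_components is not None:
        chosen = n_components
    else:
        chosen = max(fits)
        for k in sorted(fits):
            nxt = k + 1
            if nxt not in fits or fits[k][1] >= fits[nxt][1] - improvement_threshold:
                chosen = k
                break
    comps, r2 = fits[chosen]
    return GaussianMixtureFit(
        n_components=chosen,
        peaks=tuple(c[0] for c in comps),
        widths=tuple(abs(c[1]) for c in comps),
        amplitudes=tuple(c[2] for c in comps),
        r_squared=r2,
        bin_width=float(bin_width),
        n_values=len(values),
    )
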