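"""Kinetic-table assembly, Michaelis–Menten fitting and derived quantities.

The per-construct kinetic record combines the single-bundle binding rate
constant (kon_total) with the dwell-time decomposition: the binding rate is
split between the fast and slow dissociation modes in proportion to their
area fractions (kon_i = kon_total × f_i), and each mode's dissociation
constant is Kd_i = koff_i / kon_i (units M μm, inheriting the per-length
normalization of kon). Rendered tables use 2 significant figures, and
fold-ratios between constructs are computed from the rendered values, the
convention under which the published comparisons are exactly recovered.
"""

from __future__ import annotations

import decimal
import math
import warnings as _warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    FitFailureError,
    IncompleteInputError,
    InvalidParameterError,
)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures, halves away from zero
    (0 stays 0). Half-up matches how printed kinetic tables are rounded."""
    x = float(x)
    if x == 0:
        return 0.0
    exponent = sig - 1 - int(math.floor(math.log10(abs(x))))
    quantum = decimal.Decimal(1).scaleb(-exponent)
    d = decimal.Decimal(repr(x)).quantize(quantum, rounding=decimal.ROUND_HALF_UP)
    return float(d)


@dataclass(frozen=True)
class KineticComponent:
    """One dissociation mode of a construct."""

    label: str  # "fast" or "slow"
    koff: float
    fraction: float
    kon_component: float
    Kd: float


@dataclass(frozen=True)
class KineticRow:
    """Full kinetic record of one construct (both dissociation modes)."""

    construct: str
    kon_total: float
    components: tuple[KineticComponent, ...]

    def __post_init__(self):
        total_frac = sum(c.fraction for c in self.components)
        if abs(total_frac - 1.0) > 1e-9:
            raise InvalidParameterError("component fractions must sum to 1")
        for c in self.components:
            if abs(c.kon_component - self.kon_total * c.fraction) > 1e-9 * self.kon_total:
                raise InvalidParameterError(
                    f"{self.construct}/{c.label}: kon_component != kon_total * fraction"
                )
            if abs(c.Kd * c.kon_component - c.koff) > 1e-9 * c.koff:
                raise InvalidParameterError(
                    f"{self.construct}/{c.label}: Kd * kon_component != koff"
                )

    def component(self, label: str) -> KineticComponent:
        for c in self.components:
            if c.label == label:
                return c
        raise KeyError(label)


@dataclass(frozen=True)
class MMFit:
    """Michaelis–Menten fit of a bulk hydrolysis assay."""

    kcat: float
    Km: float
    r_squared: float
    enzyme_conc: float | None = None

    def __post_init__(self):
        if not (self.kcat > 0 and self.Km > 0):
            raise InvalidParameterError("kcat and Km must be > 0")


def split_kon(kon_total: float, fractions: dict[str, float]) -> tuple[float, float]:
    """Split a total binding rate constant by the dissociation-mode
    fractions: kon_i = kon_total × f_i. Returns (kon_fast, kon_slow)."""
    if not kon_total >= 0:
        raise InvalidParameterError("kon_total must be >= 0")
    f_fast, f_slow = fractions["fast"], fractions["slow"]
    for f in (f_fast, f_slow):
        if not (0.0 <= f <= 1.0):
            raise InvalidParameterError(f"fraction {f} outside [0, 1]")
    if abs(f_fast + f_slow - 1.0) > 1e-9:
        raise InvalidParameterError("fractions must sum to 1")
    return kon_total * f_fast, kon_total * f_slow


def dissociation_constants(koff: float, kon: float) -> float:
    """Kd = koff / kon, in M μm (per-fibril-length normalization)."""
    if kon == 0:
        raise InvalidParameterError(
            "kon is zero: dissociation constant undefined (no binding observed)"
        )
    return koff / kon


def build_kinetic_row(
    construct: str,
    kon_total: float,
    koff_fast: float,
    koff_slow: float,
    frac_fast: float,
    frac_slow: float,
) -> KineticRow:
    kon_f, kon_s = split_kon(kon_total, {"fast": frac_fast, "slow": frac_slow})
    return KineticRow(
        construct=construct,
        kon_total=kon_total,
        components=(
            KineticComponent("fast", koff_fast, frac_fast, kon_f,
                             dissociation_constants(koff_fast, kon_f)),
            KineticComponent("slow", koff_slow, frac_slow, kon_s,
                             dissociation_constants(koff_slow, kon_s)),
        ),
    )


def build_kinetic_table(
    results: dict[str, dict[str, float]]
) -> tuple[list[KineticRow], pd.DataFrame]:
    """Assemble kinetic rows for several constructs and render them.

    ``results`` maps construct name → dict with keys kon_total, koff_fast,
    koff_slow, frac_fast, frac_slow. The rendered table rounds every
    derived cell to 2 significant figures.
    """
    required = {"kon_total", "koff_fast", "koff_slow", "frac_fast", "frac_slow"}
    rows: list[KineticRow] = []
    for name, res in results.items():
        missing = required - set(res)
        if missing:
            raise IncompleteInputError(f"construct {name}: missing {sorted(missing)}")
        rows.append(build_kinetic_row(name, **{k: res[k] for k in required}))
    rendered = pd.DataFrame(
        [
            (
                r.construct,
                c.label,
                round_sig(r.kon_total),
                round_sig(c.koff),
                round(100.0 * c.fraction),
                round_sig(c.kon_component),
                round_sig(c.Kd),
            )
            for r in rows
            for c in r.components
        ],
        columns=["construct", "component", "kon_total", "koff", "fraction_pct",
                 "kon_component", "Kd"],
    )
    return rows, rendered


def fold_ratio(
    rendered: pd.DataFrame,
    construct_a: str,
    construct_b: str,
    component: str,
    quantity: str = "Kd",
) -> float:
    """Ratio of a rendered cell between two constructs (a over b).

    Computed from the 2-significant-figure rendered values, the convention
    that reproduces the published fold-changes.
    """
    sel_a = rendered[(rendered.construct == construct_a) & (rendered.component == component)]
    sel_b = rendered[(rendered.construct == construct_b) & (rendered.component == component)]
    if len(sel_a) != 1 or len(sel_b) != 1:
        raise IncompleteInputError(f"constructs {construct_a!r}/{construct_b!r} not in table")
    return float(sel_a[quantity].iloc[0] / sel_b[quantity].iloc[0])


def _mm(s, kcat, km):
    return kcat * s / (km + s)


def fit_michaelis_menten(data: pd.DataFrame, enzyme_conc: float | None = None) -> MMFit:
    """Nonlinear least-squares fit of v = kcat·S/(Km+S) to a bulk assay
    table with columns ``conc`` (mg/ml) and ``rate`` (s⁻¹)."""
    s = data["conc"].to_numpy(dtype=float)
    v = data["rate"].to_numpy(dtype=float)
    if len(np.unique(s)) < 3:
        raise InvalidParameterError("need >= 3 distinct substrate concentrations")
    if np.allclose(v, 0):
        raise FitFailureError("all rates are zero: degenerate assay data")
    try:
        popt, _ = curve_fit(
            _mm, s, v, p0=[max(v.max(), 1e-6), float(np.median(s))],
            bounds=(1e-12, np.inf), maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(
            "Michaelis-Menten fit did not converge", diagnostics={"cause": str(exc)}
        ) from exc
    resid = v - _mm(s, *popt)
    ss_tot = float(((v - v.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else float("nan")
    return MMFit(kcat=float(popt[0]), Km=float(popt[1]), r_squared=r2,
                 enzyme_conc=enzyme_conc)


def productive_fraction(kcat_bulk: float, k_single: float) -> float:
    """Fraction of molecules bound productively: bulk turnover per enzyme
    divided by the single-molecule turnover of a productively bound one."""
    if not (kcat_bulk > 0 and k_single > 0):
        raise InvalidParameterError("kcat_bulk and k_single must be > 0")
    if kcat_bulk > k_single:
        _warnings.warn(
            "bulk kcat exceeds the single-molecule rate; fraction > 1 is unphysical",
            stacklevel=2,
        )
    return kcat_bulk / k_single


def render_percent(fraction: float) -> int:
    """Whole-percent rendering of a fraction."""
    return round(100.0 * fraction)


def kinetic_rows_to_json(rows: list[KineticRow]) -> list[dict]:
    return [
        {
            "construct": r.construct,
            "kon_total": r.kon_total,
            "components": [
                {"label": c.label, "koff": c.koff, "fraction": c.fraction,
                 "kon_component": c.kon_component, "Kd": c.Kd}
                for c in r.components
            ],
        }
        for r in rows
    ]
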