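"""Domain types for single-molecule cellulase kinetics.

The tabular objects exchanged between modules (event tables, trajectory
tables, fibril fields) are plain :class:`pandas.DataFrame` objects with fixed
column sets declared here; the small scalar records (imaging conditions,
simulation ground truth) are frozen dataclasses that validate their own
invariants on construction.

Units follow the conventions of single-molecule TIRF work on crystalline
cellulose: fibril lengths in μm, coordinates in nm, times in s, enzyme
concentration in molar, binding rate constants in M⁻¹ μm⁻¹ s⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

# Canonical column orders for the CSV interchange formats.
EVENT_COLUMNS = ["fibril_id", "molecule_id", "t_bind", "t_end", "end_cause", "mode"]
TRAJECTORY_COLUMNS = ["track_id", "frame", "t", "x", "y", "truth_state"]
FIBRIL_COLUMNS = ["fibril_id", "length_um", "n_bundles", "x1", "y1", "x2", "y2"]

END_CAUSES = ("dissociation", "bleach", "movie_end")
MODES = ("fast", "slow", "unknown")
TRUTH_STATES = ("processive", "diffusive", "static", "unknown")


@dataclass(frozen=True)
class Fibril:
    """One cellulose microfibril deposited on the coverslip.

    ``start``/``end`` are the endpoint coordinates in nm; their Euclidean
    separation must agree with ``length_um`` (×1000) to within 0.1%.
    ``n_bundles`` is the number of elementary fibrils in the bundle, which
    multiplies the binding arrival rate.
    """

    fibril_id: str
    length_um: float
    n_bundles: int
    start: tuple[float, float]
    end: tuple[float, float]

    def __post_init__(self):
        if not self.length_um > 0:
            raise InvalidParameterError(f"fibril length must be > 0, got {self.length_um}")
        if self.n_bundles < 1:
            raise InvalidParameterError(f"n_bundles must be >= 1, got {self.n_bundles}")
        seg = math.dist(self.start, self.end)
        if not math.isclose(seg, self.length_um * 1000.0, rel_tol=1e-3):
            raise InvalidParameterError(
                f"fibril {self.fibril_id}: endpoint separation {seg:.1f} nm "
                f"inconsistent with length {self.length_um} um"
            )

    @property
    def axis(self) -> np.ndarray:
        """Unit vector along the fibril, start → end."""
        v = np.subtract(self.end, self.start, dtype=float)
        return v / np.linalg.norm(v)


@dataclass(frozen=True)
class FibrilField:
    """A collection of fibrils in one field of view."""

    fibrils: tuple[Fibril, ...]

    def __len__(self) -> int:
        return len(self.fibrils)

    def __iter__(self):
        return iter(self.fibrils)

    def get(self, fibril_id: str) -> Fibril:
        for f in self.fibrils:
            if f.fibril_id == fibril_id:
                return f
        raise KeyError(fibril_id)

    @property
    def ids(self) -> list[str]:
        return [f.fibril_id for f in self.fibrils]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (f.fibril_id, f.length_um, f.n_bundles, f.start[0], f.start[1], f.end[0], f.end[1])
            for f in self.fibrils
        ]
        return pd.DataFrame(rows, columns=FIBRIL_COLUMNS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FibrilField":
        fibrils = tuple(
            Fibril(
                fibril_id=str(r.fibril_id),
                length_um=float(r.length_um),
                n_bundles=int(r.n_bundles),
                start=(float(r.x1), float(r.y1)),
                end=(float(r.x2), float(r.y2)),
            )
            for r in df.itertuples(index=False)
        )
        return cls(fibrils)


@dataclass(frozen=True)
class ImagingConditions:
    """Acquisition parameters of one movie.

    ``bleach_rate`` is the Cy3 photobleaching rate under the movie's laser
    power; ``loc_precision_x``/``_y`` are the localization precisions (nm);
    ``labeling_ratio`` is the fraction of molecules carrying an active dye
    (binding rates are corrected by this factor downstream).
    """

    frame_rate: float
    duration: float
    bleach_rate: float = 0.0
    loc_precision_x: float = 0.0
    loc_precision_y: float = 0.0
    enzyme_conc: float = 50e-12
    labeling_ratio: float = 1.0

    def __post_init__(self):
        if not self.frame_rate > 0:
            raise InvalidParameterError("frame_rate must be > 0")
        if self.duration < 2.0 / self.frame_rate:
            raise InvalidParameterError("duration must cover at least two frames")
        if self.bleach_rate < 0:
            raise InvalidParameterError("bleach_rate must be >= 0")
        if self.loc_precision_x < 0 or self.loc_precision_y < 0:
            raise InvalidParameterError("localization precisions must be >= 0")
        if not self.enzyme_conc > 0:
            raise InvalidParameterError("enzyme_conc must be > 0")
        if not (0.0 < self.labeling_ratio <= 1.0):
            raise InvalidParameterError("labeling_ratio must lie in (0, 1]")

    @property
    def frame_interval(self) -> float:
        return 1.0 / self.frame_rate


@dataclass(frozen=True)
class GroundTruth:
    """Kinetic ground truth used by the simulator.

    ``kon_total`` is the binding rate constant per bundle (M⁻¹ μm⁻¹ s⁻¹);
    dissociation is a two-mode exponential mixture (``frac_fast`` of events
    leave at ``koff_fast``, the rest at ``koff_slow``); ``v_proc`` is the
    processive sliding velocity, ``v_diff`` the apparent first-to-last rate
    of surface-diffusing molecules, ``tau_move`` the mean processive run
    time; ``kcat``/``Km`` parameterize the bulk Michaelis–Menten activity.
    """

    kon_total: float
    frac_fast: float
    frac_slow: float
    koff_fast: float
    koff_slow: float
    v_proc: float = 11.6
    v_diff: float = 25.3
    tau_move: float = 4.6
    kcat: float = 2.4
    Km: float = 0.51

    def __post_init__(self):
        if abs(self.frac_fast + self.frac_slow - 1.0) > 1e-12:
            raise InvalidParameterError("frac_fast + frac_slow must equal 1")
        if not (0.0 <= self.frac_fast <= 1.0):
            raise InvalidParameterError("frac_fast must lie in [0, 1]")
        if not (self.koff_fast > self.koff_slow > 0):
            raise InvalidParameterError("require koff_fast > koff_slow > 0")
        for name in ("kon_total", "v_proc", "v_diff", "tau_move", "kcat", "Km"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be > 0")


def validate_event_table(df: pd.DataFrame, duration: float | None = None) -> None:
    """Check the EventTable invariants; raise on violation."""
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidParameterError(f"event table missing columns {sorted(missing)}")
    if len(df) == 0:
        return
    if not (df["t_bind"] >= 0).all() or not (df["t_bind"] < df["t_end"]).all():
        raise InvalidParameterError("event table requires 0 <= t_bind < t_end")
    if duration is not None:
        if not (df["t_end"] <= duration + 1e-9).all():
            raise InvalidParameterError("event t_end exceeds movie duration")
        ended = df["end_cause"] == "movie_end"
        if not np.allclose(df.loc[ended, "t_end"], duration):
            raise InvalidParameterError("movie_end events must end at the movie duration")
    bad = ~df["end_cause"].isin(END_CAUSES)
    if bad.any():
        raise InvalidParameterError(f"unknown end_cause values: {df.loc[bad, 'end_cause'].unique()}")
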