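"""Synthetic single-molecule experiments with known ground truth.

Emulates the statistical structure of TIRF movies of fluorescently labeled
cellulases on surface-deposited crystalline cellulose microfibrils:

* binding arrivals are Poisson, homogeneous in time, with per-fibril rate
  kon_total × n_bundles × enzyme concentration × fibril length;
* each bound molecule dissociates from a two-mode exponential mixture
  (fast/slow), in competition with exponential photobleaching and with
  censoring at the end of the movie;
* moving molecules either slide processively along the fibril axis at a
  constant velocity for an exponentially distributed run time, or diffuse
  on the surface with a fast apparent first-to-last displacement rate;
* every localization carries independent Gaussian noise.

No camera/PSF model is involved: the simulator produces the event and
trajectory tables that a spot-tracking pipeline would output.
"""

from __future__ import annotations

import math
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .models import (
    EVENT_COLUMNS,
    TRAJECTORY_COLUMNS,
    Fibril,
    FibrilField,
    GroundTruth,
    ImagingConditions,
)

DEFAULT_TAU_MOVE_DIFFUSIVE = 2.0  # s; mean run time of surface-diffusing tracks


def make_fibril_field(
    n_fibrils: int,
    length_mean: float,
    length_sd: float,
    bundle_weights: Mapping[int, float],
    seed: int,
    field_size_um: float = 50.0,
) -> FibrilField:
    """Lay down ``n_fibrils`` straight microfibrils in a square field.

    Lengths are drawn from a normal truncated at zero (a zero SD gives the
    mean exactly); bundle multiplicities are drawn from ``bundle_weights``,
    a mapping {n_bundles: probability}. Positions and orientations are
    uniform; geometry only matters for trajectory simulation.
    """
    if n_fibrils < 1:
        raise InvalidParameterError("n_fibrils must be >= 1")
    if not length_mean > 0:
        raise InvalidParameterError("length_mean must be > 0")
    if length_sd < 0:
        raise InvalidParameterError("length_sd must be >= 0")
    counts = np.asarray(sorted(bundle_weights), dtype=int)
    probs = np.asarray([bundle_weights[int(c)] for c in counts], dtype=float)
    if (counts < 1).any():
        raise InvalidParameterError("bundle counts must be positive integers")
    if probs.min() < 0 or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
        raise InvalidParameterError("bundle_weights must be a probability vector")

    rng = np.random.default_rng(seed)
    if length_sd == 0:
        lengths = np.full(n_fibrils, length_mean)
    else:
        lengths = rng.normal(length_mean, length_sd, n_fibrils)
        while True:
            bad = lengths <= 0
            if not bad.any():
                break
            lengths[bad] = rng.normal(length_mean, length_sd, int(bad.sum()))
    bundles = rng.choice(counts, size=n_fibrils, p=probs)
    centers = rng.uniform(0.0, field_size_um * 1000.0, size=(n_fibrils, 2))
    angles = rng.uniform(0.0, math.pi, size=n_fibrils)

    fibrils = []
    for i in range(n_fibrils):
        half = 500.0 * lengths[i] * np.array([math.cos(angles[i]), math.sin(angles[i])])
        fibrils.append(
            Fibril(
                fibril_id=f"f{i:04d}",
                length_um=float(lengths[i]),
                n_bundles=int(bundles[i]),
                start=tuple(centers[i] - half),
                end=tuple(centers[i] + half),
            )
        )
    return FibrilField(tuple(fibrils))


def simulate_binding(
    truth: GroundTruth,
    field: FibrilField,
    cond: ImagingConditions,
    seed: int,
) -> pd.DataFrame:
    """Simulate one binding movie and return its event table.

    Arrivals on each fibril are Poisson with rate
    ``truth.kon_total * n_bundles * cond.enzyme_conc * length_um`` per
    second; a ``cond.labeling_ratio`` fraction of arrivals carries a dye and
    is emitted. Each visible molecule draws a binding mode (fast with
    probability ``frac_fast``), a true dwell ~ Exp(koff_mode) and an
    independent bleach time ~ Exp(bleach_rate); the spot disappears at the
    earliest of dwell end, bleaching and movie end, with the cause recorded.
    """
    rng = np.random.default_rng(seed)
    T = cond.duration
    rows: list[tuple] = []
    mol = 0
    for f in field:
        lam = truth.kon_total * f.n_bundles * cond.enzyme_conc * f.length_um * T
        n_arrivals = rng.poisson(lam)
        if n_arrivals == 0:
            continue
        visible = rng.random(n_arrivals) < cond.labeling_ratio
        n_vis = int(visible.sum())
        if n_vis == 0:
            continue
        t_bind = np.sort(rng.uniform(0.0, T, n_vis))
        fast = rng.random(n_vis) < truth.frac_fast
        koff = np.where(fast, truth.koff_fast, truth.koff_slow)
        dwell = rng.exponential(1.0 / koff)
        if cond.bleach_rate > 0:
            bleach = rng.exponential(1.0 / cond.bleach_rate, n_vis)
        else:
            bleach = np.full(n_vis, np.inf)
        t_end_raw = t_bind + np.minimum(dwell, bleach)
        for j in range(n_vis):
            if t_end_raw[j] >= T:
                t_end, cause = T, "movie_end"
            elif bleach[j] < dwell[j]:
                t_end, cause = t_end_raw[j], "bleach"
            else:
                t_end, cause = t_end_raw[j], "dissociation"
            rows.append(
                (f.fibril_id, f"m{mol:06d}", t_bind[j], t_end, cause,
                 "fast" if fast[j] else "slow")
            )
            mol += 1
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def _processive_track(rng, truth, fibril, cond, max_frames):
    run = rng.exponential(truth.tau_move)
    n_frames = min(int(math.floor(run * cond.frame_rate)) + 1, max_frames)
    t = np.arange(n_frames) / cond.frame_rate
    frac0 = rng.uniform(0.0, 1.0)
    start = np.asarray(fibril.start) + frac0 * (np.asarray(fibril.end) - np.asarray(fibril.start))
    direction = fibril.axis * (1.0 if rng.random() < 0.5 else -1.0)
    pos = start[None, :] + truth.v_proc * t[:, None] * direction[None, :]
    return t, pos


def _diffusive_track(rng, truth, fibril, cond, tau_move_diffusive, max_frames):
    run = rng.exponential(tau_move_diffusive)
    n_frames = min(int(math.floor(run * cond.frame_rate)) + 1, max_frames)
    t = np.arange(n_frames) / cond.frame_rate
    frac0 = rng.uniform(0.0, 1.0)
    start = np.asarray(fibril.start) + frac0 * (np.asarray(fibril.end) - np.asarray(fibril.start))
    n_steps = n_frames - 1
    if n_steps > 0:
        # Per-axis step SD chosen so that E[first-to-last displacement] /
        # span equals v_diff for this track's step count: the net
        # displacement of an n-step walk is Rayleigh with scale sd*sqrt(n),
        # whose mean is sd*sqrt(n*pi/2).
        span = n_steps / cond.frame_rate
        sd = truth.v_diff * span / math.sqrt(n_steps * math.pi / 2.0)
        steps = rng.normal(0.0, sd, size=(n_steps, 2))
        pos = start[None, :] + np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
    else:
        pos = start[None, :]
    return t, pos


def simulate_trajectories(
    truth: GroundTruth,
    field: FibrilField,
    cond: ImagingConditions,
    n_tracks: int,
    frac_processive: float,
    seed: int,
    tau_move_diffusive: float = DEFAULT_TAU_MOVE_DIFFUSIVE,
) -> pd.DataFrame:
    """Simulate a motility movie and return its trajectory table.

    A ``frac_processive`` fraction of tracks slides along the axis of a
    randomly chosen fibril at ``truth.v_proc`` for a run ~ Exp(tau_move);
    the remainder performs an unbiased random walk calibrated so its
    expected first-to-last displacement rate is ``truth.v_diff``, for a run
    ~ Exp(tau_move_diffusive). Every sampled position receives independent
    Gaussian localization noise. Tracks shorter than one frame interval are
    emitted as single-frame tracks; filtering is an analysis decision.
    """
    if n_tracks < 1:
        raise InvalidParameterError("n_tracks must be >= 1")
    if not (0.0 <= frac_processive <= 1.0):
        raise InvalidParameterError("frac_processive must lie in [0, 1]")
    if not tau_move_diffusive > 0:
        raise InvalidParameterError("tau_move_diffusive must be > 0")
    rng = np.random.default_rng(seed)
    max_frames = int(cond.duration * cond.frame_rate) + 1
    fibrils = list(field)
    rows: list[tuple] = []
    for k in range(n_tracks):
        fibril = fibrils[rng.integers(len(fibrils))]
        processive = rng.random() < frac_processive
        if processive:
            t, pos = _processive_track(rng, truth, fibril, cond, max_frames)
            state = "processive"
        else:
            t, pos = _diffusive_track(rng, truth, fibril, cond, tau_move_diffusive, max_frames)
            state = "diffusive"
        noise = rng.normal(
            0.0, [cond.loc_precision_x, cond.loc_precision_y], size=pos.shape
        )
        pos = pos + noise
        tid = f"t{k:05d}"
        for i in range(len(t)):
            rows.append((tid, i, t[i], pos[i, 0], pos[i, 1], state))
    return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)


def simulate_mm(
    truth: GroundTruth,
    substrate_concs: list[float],
    noise_sd: float,
    n_reps: int,
    seed: int,
) -> pd.DataFrame:
    """Simulate a bulk hydrolysis assay: rate = kcat·S/(Km+S) + noise, ≥ 0."""
    concs = np.asarray(list(substrate_concs), dtype=float)
    if concs.size == 0:
        raise InvalidParameterError("substrate_concs must be non-empty")
    if (concs <= 0).any():
        raise InvalidParameterError("substrate concentrations must be > 0")
    if noise_sd < 0 or n_reps < 1:
        raise InvalidParameterError("noise_sd must be >= 0 and n_reps >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_reps):
        for s in concs:
            v = truth.kcat * s / (truth.Km + s)
            if noise_sd > 0:
                v = max(v + rng.normal(0.0, noise_sd), 0.0)
            rows.append((s, v))
    return pd.DataFrame(rows, columns=["conc", "rate"])
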