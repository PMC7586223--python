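"""End-to-end orchestration: simulate/load → kon → koff → motion → table.

The pipeline is configured by a single mapping (usually loaded from YAML or
JSON): per construct, either simulation parameters with a kinetic ground
truth, or paths to event/fibril/trajectory CSVs plus the imaging conditions
under which they were recorded. The report collects every fitted parameter
and derived quantity together with the seed and package version, so a run
is reproducible from its own output.
"""

from __future__ import annotations

import dataclasses
import zlib
from pathlib import Path

import numpy as np

from . import __version__, io
from .dwelltime import (
    bleach_correct,
    collect_dwells,
    fit_exponential,
    select_decay_model,
)
from .errors import CbhkinError, IncompleteInputError, PipelineStageError
from .models import GroundTruth, ImagingConditions
from .motility import (
    fit_ktr_distribution,
    fit_moving_time,
    load_tracks,
    processivity,
    single_molecule_rate,
    translational_rates,
)
from .onrate import fit_kon_distribution, kon_per_fibril, smallest_peak
from .simulate import make_fibril_field, simulate_binding, simulate_mm, simulate_trajectories
from .summary import (
    build_kinetic_table,
    fit_michaelis_menten,
    kinetic_rows_to_json,
    productive_fraction,
    render_percent,
)


def derive_seed(base_seed: int, *tags) -> int:
    """Stable per-stage sub-seed below 2**31 (process-independent)."""
    entropy = [int(base_seed)] + [zlib.crc32(str(t).encode()) for t in tags]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % 2**31)


def _conditions(cfg: dict) -> ImagingConditions:
    return ImagingConditions(**cfg)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except CbhkinError as exc:
                raise PipelineStageError(name, str(exc)) from exc

        return inner

    return wrap


def _load_or_simulate(name: str, cfg: dict, seed: int):
    """Return (events, field, binding_cond, traj, motility_cond)."""
    sim = cfg.get("simulate")
    inputs = cfg.get("inputs", {})
    if sim is not None:
        truth = GroundTruth(**cfg["truth"])
        field = make_fibril_field(seed=derive_seed(seed, name, "field"), **sim["field"])
        bcond = _conditions(sim["binding"])
        events = simulate_binding(truth, field, bcond, derive_seed(seed, name, "binding"))
        traj = mcond = None
        if "motility" in sim:
            mcond = _conditions(sim["motility"])
            traj = simulate_trajectories(
                truth, field, mcond,
                n_tracks=sim.get("n_tracks", 500),
                frac_processive=sim.get("frac_processive", 1.0),
                seed=derive_seed(seed, name, "motility"),
                tau_move_diffusive=sim.get("tau_move_diffusive", 2.0),
            )
        return events, field, bcond, traj, mcond
    if "events" not in inputs or "fibrils" not in inputs:
        raise IncompleteInputError(
            f"construct {name}: need either 'simulate' or input paths 'events' and 'fibrils'"
        )
    events = io.read_events(inputs["events"])
    field = io.read_fibril_field(inputs["fibrils"])
    bcond = _conditions(cfg["binding_conditions"])
    traj = mcond = None
    if "trajectories" in inputs:
        traj = io.read_trajectories(inputs["trajectories"])
        mcond = _conditions(cfg["motility_conditions"])
    return events, field, bcond, traj, mcond


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Execute the configured analyses and return the report dict.

    Stages per construct: binding-rate estimation and peak decomposition,
    dwell-time decomposition (with optional model selection and bleach
    correction), optional motility analysis; then the kinetic table across
    constructs, an optional Michaelis–Menten fit, and the derived
    processivity / productive-fraction quantities.
    """
    seed = int(config.get("seed", 0))
    analysis_defaults = dict(
        min_frames=1, koff_components="auto", bleach_correct=False,
        kon_bin_width=None, kon_max_components=3, ktr_components=None,
        tail_threshold=10.0, moving_bin_width=1.0, product_length=1.0,
        min_track_frames=2, static_threshold_mult=3.0,
    )
    report: dict = {"version": __version__, "seed": seed, "constructs": {}}
    table_inputs: dict[str, dict[str, float]] = {}

    for name, cfg in config.get("constructs", {}).items():
        opts = analysis_defaults | cfg.get("analysis", {})
        events, field, bcond, traj, mcond = _stage("load")(_load_or_simulate)(
            name, cfg, seed
        )
        entry: dict = {"n_events": int(len(events)), "n_fibrils": len(field)}

        # --- binding rate constant ---
        sample = _stage("kon")(kon_per_fibril)(events, field, bcond)
        kon_fit = _stage("kon")(fit_kon_distribution)(
            sample, bin_width=opts["kon_bin_width"],
            max_components=opts["kon_max_components"],
        )
        kon_total = smallest_peak(kon_fit)
        entry["kon"] = dataclasses.asdict(kon_fit) | {"smallest_peak": kon_total}

        # --- dissociation rate constants ---
        dwells = _stage("koff")(collect_dwells)(events, bcond, opts["min_frames"])
        if opts["koff_components"] == "auto":
            fit1 = _stage("koff")(fit_exponential)(dwells, 1)
            fit2 = _stage("koff")(fit_exponential)(dwells, 2)
            decay = select_decay_model(fit1, fit2)
        else:
            decay = _stage("koff")(fit_exponential)(dwells, int(opts["koff_components"]))
        if opts["bleach_correct"]:
            decay = bleach_correct(decay, bcond.bleach_rate)
        entry["koff"] = dataclasses.asdict(decay)

        if decay.n_components == 2:
            table_inputs[name] = dict(
                kon_total=kon_total,
                koff_fast=decay.k_fast, koff_slow=decay.k_slow,
                frac_fast=decay.frac_fast, frac_slow=decay.frac_slow,
            )

        # --- motility ---
        if traj is not None:
            tracks = _stage("motion")(load_tracks)(
                traj, mcond, min_frames=opts["min_track_frames"],
                static_threshold_mult=opts["static_threshold_mult"],
            )
            motion = _stage("motion")(translational_rates)(tracks)
            motion = _stage("motion")(fit_ktr_distribution)(
                motion, n_components=opts["ktr_components"]
            )
            tail = _stage("motion")(fit_moving_time)(
                motion.moving_times, mode="tail_gt_threshold",
                threshold=opts["tail_threshold"], bin_width=opts["moving_bin_width"],
            )
            full = _stage("motion")(fit_moving_time)(
                motion.moving_times, mode="full_excl_first_bin",
                bin_width=opts["moving_bin_width"],
            )
            proc = processivity(motion.slow_peak, tail.tau, opts["product_length"])
            entry["motion"] = {
                "n_tracks": len(tracks), "n_static": tracks.n_static,
                "n_too_short": tracks.n_too_short,
                "ktr_fit": dataclasses.asdict(motion.fit),
                "moving_time_tail": dataclasses.asdict(tail),
                "moving_time_full": dataclasses.asdict(full),
                "processivity": dataclasses.asdict(proc),
                "single_molecule_rate": single_molecule_rate(
                    motion.slow_peak, opts["product_length"]
                ),
            }
        elif cfg.get("require_motion"):
            raise PipelineStageError("motion", f"construct {name}: no trajectory input")

        report["constructs"][name] = entry

    # --- kinetic table across constructs ---
    if table_inputs:
        rows, rendered = build_kinetic_table(table_inputs)
        report["kinetic_table"] = kinetic_rows_to_json(rows)
        report["kinetic_table_rendered"] = rendered.to_dict(orient="records")
    else:
        rendered = None

    # --- bulk Michaelis-Menten ---
    mm_cfg = config.get("mm")
    if mm_cfg:
        if "data" in mm_cfg:
            import pandas as pd

            assay = pd.read_csv(mm_cfg["data"])
        else:
            truth = GroundTruth(**mm_cfg["truth"])
            assay = simulate_mm(
                truth, mm_cfg["substrate_concs"], mm_cfg.get("noise_sd", 0.0),
                mm_cfg.get("n_reps", 1), derive_seed(seed, "mm"),
            )
        mm_fit = _stage("mm")(fit_michaelis_menten)(assay)
        report["mm"] = dataclasses.asdict(mm_fit)
        for name, entry in report["constructs"].items():
            if "motion" in entry:
                frac = productive_fraction(
                    mm_fit.kcat, entry["motion"]["single_molecule_rate"]
                )
                entry["productive_fraction"] = {
                    "value": frac, "percent": render_percent(frac),
                }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_json(report, out / "report.json")
        if rendered is not None:
            rendered.to_csv(out / "kinetic_table.csv", index=False)
    return report
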