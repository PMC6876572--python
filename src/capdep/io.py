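"""Readers and writers for the package's on-disk formats.

Tables are TSV with unit-suffixed headers (time_s, length_subunits,
intensity_au, ...); parameter sets and results are JSON with
unit-suffixed keys; image stacks are multi-frame TIFF, one file per
channel.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import KineticParams
from .simulate import FilamentTrajectory, IntensityTrace
from .traces import DwellSet


def write_trajectory(traj: FilamentTrajectory, path) -> None:
    df = pd.DataFrame(
        {
            "time_s": traj.times,
            "length_subunits": traj.length_observed,
            "length_true_subunits": traj.length_true,
            "bound_truth": traj.bound_state.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_trajectory(path) -> FilamentTrajectory:
    df = pd.read_csv(path, sep="\t")
    times = df["time_s"].to_numpy()
    dt = float(np.median(np.diff(times))) if times.size > 1 else 0.065
    true = df.get("length_true_subunits", df["length_subunits"]).to_numpy()
    bound = df.get("bound_truth", pd.Series(np.zeros(len(df)))).to_numpy().astype(bool)
    return FilamentTrajectory(
        times=times,
        length_true=true,
        length_observed=df["length_subunits"].to_numpy(),
        bound_state=bound,
        events=[],
        frame_interval=dt,
    )


def write_trace(trace: IntensityTrace, path) -> None:
    cols = {"time_s": trace.times, "intensity_au": trace.intensity}
    if trace.truth_occupied is not None:
        cols["bound_truth"] = trace.truth_occupied.astype(int)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_trace(path) -> IntensityTrace:
    df = pd.read_csv(path, sep="\t")
    times = df["time_s"].to_numpy()
    dt = float(np.median(np.diff(times))) if times.size > 1 else 0.065
    truth = df["bound_truth"].to_numpy().astype(bool) if "bound_truth" in df else None
    return IntensityTrace(times, df["intensity_au"].to_numpy(), dt, truth)


def write_dwells(ds: DwellSet, path) -> None:
    pd.DataFrame(
        [
            {"start_s": s, "end_s": e, "duration_s": e - s}
            for s, e in ds.dwells
        ]
    ).to_csv(path, sep="\t", index=False)


def params_to_json(params: KineticParams) -> dict:
    return {
        "k_on_per_M_per_s": params.k_on,
        "k_off_per_s": params.k_off,
        "c_M": params.c,
        "v_bound_subunits_per_s": params.v_bound,
        "v_unbound_subunits_per_s": params.v_unbound,
        "productive_fraction": params.productive_fraction,
    }


def params_from_json(d: dict) -> KineticParams:
    return KineticParams(
        k_on=d["k_on_per_M_per_s"],
        k_off=d["k_off_per_s"],
        c=d["c_M"],
        v_bound=d.get("v_bound_subunits_per_s", 53.0),
        v_unbound=d.get("v_unbound_subunits_per_s", 0.43),
        productive_fraction=d.get("productive_fraction", 1.0),
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_stack(stack: np.ndarray, path) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32), photometric="minisblack")


def read_stack(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)
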