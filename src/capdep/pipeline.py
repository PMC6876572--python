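"""End-to-end orchestration: simulate -> analyze -> report.

A run is described by a single JSON-serializable :class:`RunConfig`.
Each stochastic stage receives a seed derived deterministically from
the master seed, so a run is bit-reproducible and any stage can be
re-executed from saved intermediates with identical output.

The default configuration reproduces the study conditions: 83 nM
hexamer on Cofilin-decorated filaments, 77.9% labeled hexamers,
saturation series out to 500 nM.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as cio
from .kinetics import (
    KineticParams,
    LabelingModel,
    MMFitResult,
    catalytic_efficiency,
    subunits_per_event,
)
from .photobleach import analyze_staircase, fit_labeling
from .simulate import (
    render_intensity_trace,
    simulate_end_dynamics,
    simulate_photobleach_traces,
    simulate_velocity_dataset,
)
from .traces import detect_dwells, estimate_binding_kinetics, estimate_koff, smooth_trace
from .velocity import fit_mm, occupancy_velocity_table

log = logging.getLogger("capdep")

ALL_STAGES = ("photobleach", "traces", "velocity", "report")


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    seed: int = 1
    out_dir: str = "capdep_run"
    stages: tuple[str, ...] = ALL_STAGES
    # ground truth of the two-state end model (units in key names at I/O)
    k_on: float = 1.1e7  # M^-1 s^-1
    k_off: float = 0.45  # s^-1
    c: float = 83e-9  # M
    v_bound: float = 53.0
    v_unbound: float = 0.43
    productive_fraction: float = 1.0
    # labeling
    p_site: float = 0.2223
    n_sites: int = 6
    # photobleach stage
    pb_n_traces: int = 300
    pb_unit_intensity: float = 1.0
    pb_noise_sd: float = 0.2  # SNR 5
    pb_k_bleach: float = 0.2
    # single-molecule trace stage
    sm_n_filaments: int = 5
    sm_duration: float = 300.0
    sm_frame_interval: float = 0.065
    sm_unit_intensity: float = 1.0
    sm_noise_sd: float = 0.15
    sm_k_bleach: float = 0.05
    # velocity stage
    vel_concentrations_nM: tuple[float, ...] = (10, 25, 50, 100, 150, 300, 500)
    vel_K_M_nM: float = 50.0
    vel_k_cat: float = 53.0
    vel_noise_cv: float = 0.15
    vel_n_per_c: int = 30
    # comparison table
    table_concentrations_nM: tuple[float, ...] = (8.3, 83.0)

    @property
    def truth(self) -> KineticParams:
        return KineticParams(
            k_on=self.k_on,
            k_off=self.k_off,
            c=self.c,
            v_bound=self.v_bound,
            v_unbound=self.v_unbound,
            productive_fraction=self.productive_fraction,
        )

    @property
    def labeling(self) -> LabelingModel:
        return LabelingModel(p_site=self.p_site, n_sites=self.n_sites)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw = dict(d)
        for k in ("stages", "vel_concentrations_nM", "table_concentrations_nM"):
            if k in kw:
                kw[k] = tuple(kw[k])
        return cls(**kw)

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir")  # where results go must not change what they are
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds from the master seed."""
    rng = np.random.default_rng(seed)
    return {name: int(rng.integers(2**31)) for name in ALL_STAGES}


def stage_photobleach(cfg: RunConfig, seed: int, outdir: Path | None = None) -> dict:
    """Simulate staircases, count steps, fit the labeling model."""
    traces, true_counts = simulate_photobleach_traces(
        cfg.pb_n_traces,
        cfg.labeling,
        unit_intensity=cfg.pb_unit_intensity,
        k_bleach=cfg.pb_k_bleach,
        noise_sd=cfg.pb_noise_sd,
        seed=seed,
    )
    observed = []
    n_censored = 0
    for tr in traces:
        n, censored = analyze_staircase(tr, unit_intensity=cfg.pb_unit_intensity)
        if censored or n == 0:
            n_censored += 1
            continue
        observed.append(n)
    model, summary = fit_labeling(observed, n_sites=cfg.n_sites)
    res = {
        "f_hat": summary.f_hat,
        "se_f": summary.se_f,
        "ci_f_95": list(summary.ci_f),
        "p_site_hat": summary.p_site_hat,
        "n_traces": summary.n_traces,
        "n_censored_or_zero": n_censored,
        "step_histogram": {str(k): v for k, v in sorted(summary.counts.items())},
        "f_true": cfg.labeling.f,
    }
    if outdir is not None:
        cio.write_json(res, outdir / "labeling.json")
    return res


def stage_traces(cfg: RunConfig, seed: int, outdir: Path | None = None, f: float | None = None) -> dict:
    """Simulate end-binding traces, detect dwells, estimate k_off and k_on."""
    if f is None:
        f = cfg.labeling.f
    rng = np.random.default_rng(seed)
    dwellsets = []
    for i in range(cfg.sm_n_filaments):
        traj = simulate_end_dynamics(
            cfg.truth,
            duration=cfg.sm_duration,
            seed=int(rng.integers(2**31)),
            frame_interval=cfg.sm_frame_interval,
            labeling=cfg.labeling,
        )
        trace = render_intensity_trace(
            traj,
            unit_intensity=cfg.sm_unit_intensity,
            k_bleach=cfg.sm_k_bleach,
            noise_sd=cfg.sm_noise_sd,
            seed=int(rng.integers(2**31)),
        )
        ds = detect_dwells(smooth_trace(trace), raw_trace=trace)
        dwellsets.append(ds)
        if outdir is not None:
            cio.write_dwells(ds, outdir / f"dwells_filament{i}.tsv")
    naive = estimate_koff(dwellsets)
    koff, kon = estimate_binding_kinetics(
        dwellsets, f=f, c=cfg.c, k_bleach=cfg.sm_k_bleach, labeling=cfg.labeling
    )
    res = {
        "n_dwells": koff.n,
        "n_gaps": kon.n,
        "mean_dwell_s": 1.0 / naive.value,
        "k_off_naive_per_s": naive.value,
        "k_off_per_s": koff.value,
        "se_k_off_per_s": koff.se,
        "k_on_per_M_per_s": kon.value,
        "se_k_on_per_M_per_s": kon.se,
        "f_used": f,
        "c_M": cfg.c,
        "k_on_true_per_M_per_s": cfg.k_on,
        "k_off_true_per_s": cfg.k_off,
    }
    if outdir is not None:
        cio.write_json(res, outdir / "rate_constants.json")
    return res


def stage_velocity(cfg: RunConfig, seed: int, outdir: Path | None = None) -> dict:
    """Simulate the saturation series and fit the Michaelis–Menten curve."""
    truth_fit = MMFitResult(K_M=cfg.vel_K_M_nM * 1e-9, k_cat=cfg.vel_k_cat)
    df = simulate_velocity_dataset(
        [c * 1e-9 for c in cfg.vel_concentrations_nM],
        truth_fit,
        noise_cv=cfg.vel_noise_cv,
        n_per_c=cfg.vel_n_per_c,
        seed=seed,
    )
    fit = fit_mm(df)
    res = {
        "K_M_nM": fit.K_M * 1e9,
        "se_K_M_nM": fit.se_K_M * 1e9,
        "k_cat_subunits_per_s": fit.k_cat,
        "se_k_cat_subunits_per_s": fit.se_k_cat,
        "n_points": fit.n_points,
        "K_M_true_nM": cfg.vel_K_M_nM,
        "k_cat_true_subunits_per_s": cfg.vel_k_cat,
    }
    if outdir is not None:
        df.to_csv(outdir / "velocity_dataset.tsv", sep="\t", index=False)
        cio.write_json(res, outdir / "mm_fit.json")
    return res


def _derived(results: dict, cfg: RunConfig) -> dict:
    """Catalytic efficiency, processivity, and the occupancy table."""
    vel = results["velocity"]
    tra = results["traces"]
    fit = MMFitResult(
        K_M=vel["K_M_nM"] * 1e-9,
        k_cat=vel["k_cat_subunits_per_s"],
        se_K_M=vel["se_K_M_nM"] * 1e-9,
        se_k_cat=vel["se_k_cat_subunits_per_s"],
    )
    eff = catalytic_efficiency(fit)
    spe = subunits_per_event(
        eff.value, tra["k_on_per_M_per_s"], eff.se, tra["se_k_on_per_M_per_s"]
    )
    params = KineticParams(
        k_on=tra["k_on_per_M_per_s"], k_off=tra["k_off_per_s"], c=cfg.c
    )
    table = occupancy_velocity_table(
        params, fit, [c * 1e-9 for c in cfg.table_concentrations_nM]
    )
    return {
        "catalytic_efficiency_per_M_per_s": eff.value,
        "se_catalytic_efficiency_per_M_per_s": eff.se,
        "subunits_per_event": spe.value,
        "se_subunits_per_event": spe.se,
        "filament_nm_per_event": spe.value * 2.7,
        "occupancy_velocity_table": [
            {
                "c_nM": row.concentration_M * 1e9,
                "occupancy_fraction": row.occupancy_fraction,
                "velocity_fraction": row.velocity_fraction,
            }
            for row in table.itertuples(index=False)
        ],
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order.

    Writes per-stage tables, a machine-readable ``results.json``, the
    effective config, and a log with seeds and the config hash under
    ``config.out_dir``.  Returns the results dict.
    """
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.time()
    results: dict = {"seed": config.seed, "config_hash": config.config_hash()}
    cio.write_json(config.to_dict(), outdir / "config.json")
    log.info("run start: seed=%s hash=%s stages=%s", config.seed, results["config_hash"], config.stages)
    try:
        if "photobleach" in config.stages:
            results["photobleach"] = stage_photobleach(config, seeds["photobleach"], outdir)
            log.info("photobleach: f_hat=%.4f", results["photobleach"]["f_hat"])
        if "traces" in config.stages:
            f = results.get("photobleach", {}).get("f_hat", config.labeling.f)
            results["traces"] = stage_traces(config, seeds["traces"], outdir, f=f)
            log.info(
                "traces: k_off=%.3f k_on=%.3e",
                results["traces"]["k_off_per_s"],
                results["traces"]["k_on_per_M_per_s"],
            )
        if "velocity" in config.stages:
            results["velocity"] = stage_velocity(config, seeds["velocity"], outdir)
            log.info(
                "velocity: K_M=%.1f nM k_cat=%.1f",
                results["velocity"]["K_M_nM"],
                results["velocity"]["k_cat_subunits_per_s"],
            )
        if "report" in config.stages and "velocity" in results and "traces" in results:
            results["derived"] = _derived(results, config)
    except Exception:
        log.exception("stage failed; partial outputs preserved in %s", outdir)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    results["elapsed_s"] = round(time.time() - t0, 3)
    out = dict(results)
    out.pop("elapsed_s")  # keep results.json byte-identical across runs
    cio.write_json(out, outdir / "results.json")
    if "derived" in results:
        (outdir / "report.txt").write_text(make_report(out))
    return results


def make_report(results: dict) -> str:
    """Human-readable summary table of estimated vs generative constants."""
    lines = ["constant                         estimate        truth/reference"]
    rows = []
    tra = results.get("traces", {})
    pb = results.get("photobleach", {})
    vel = results.get("velocity", {})
    der = results.get("derived", {})
    if pb:
        rows.append(("labeled fraction f", f"{pb['f_hat']:.3f} ± {pb['se_f']:.3f}", f"{pb['f_true']:.3f}"))
    if tra:
        rows.append(("k_off (1/s)", f"{tra['k_off_per_s']:.3f} ± {tra['se_k_off_per_s']:.3f}", f"{tra['k_off_true_per_s']:.3f}"))
        rows.append(("k_on (1/M/s)", f"{tra['k_on_per_M_per_s']:.3e} ± {tra['se_k_on_per_M_per_s']:.1e}", f"{tra['k_on_true_per_M_per_s']:.3e}"))
    if vel:
        rows.append(("K_M (nM)", f"{vel['K_M_nM']:.1f} ± {vel['se_K_M_nM']:.1f}", f"{vel['K_M_true_nM']:.1f}"))
        rows.append(("k_cat (subunits/s)", f"{vel['k_cat_subunits_per_s']:.1f} ± {vel['se_k_cat_subunits_per_s']:.1f}", f"{vel['k_cat_true_subunits_per_s']:.1f}"))
    if der:
        rows.append(("k_cat/K_M (subunits/M/s)", f"{der['catalytic_efficiency_per_M_per_s']:.2e} ± {der['se_catalytic_efficiency_per_M_per_s']:.1e}", ""))
        rows.append(("subunits per binding event", f"{der['subunits_per_event']:.0f} ± {der['se_subunits_per_event']:.0f}", ""))
        for row in der.get("occupancy_velocity_table", []):
            rows.append(
                (
                    f"occupancy vs velocity @ {row['c_nM']:g} nM",
                    f"{row['occupancy_fraction']:.2f} / {row['velocity_fraction']:.2f}",
                    "",
                )
            )
    if not rows:
        return "(no results to report)\n"
    for name, est, truth in rows:
        lines.append(f"{name:<32} {est:<15} {truth}")
    return "\n".join(lines) + "\n"
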