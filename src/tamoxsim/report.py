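"""Run configuration, output writers and figures for the virtual trial."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .params import (InputError, ParameterSet, default_parameter_set,
                     load_parameter_set)
from .pkmodel import COMPOUNDS
from .trial import ArmResult, BenchmarkCtss, TrialConfig, TrialResult, \
    run_virtual_trial

__all__ = ["RunConfig", "reproduce_trial", "plot_arm", "write_outputs"]

log = logging.getLogger("tamoxsim")


@dataclass(frozen=True)
class RunConfig:
    """End-to-end run configuration; all randomness flows from ``seed``."""

    seed: int
    out_dir: Path
    n_per_arm: int = 1000
    parameter_path: Path | None = None   # None => shipped calibrated set
    arm_filter: tuple[str, ...] = ()
    figures: bool = False

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise InputError("n_per_arm must be >= 1")

    def parameter_set(self) -> ParameterSet:
        if self.parameter_path is None:
            return default_parameter_set()
        return load_parameter_set(self.parameter_path)


def plot_arm(result: ArmResult, benchmark_bands: dict[str, BenchmarkCtss] |
             None, path: Path) -> Path:
    """Four-panel figure (TAM, NDM, 4OH, END): median trough curve with the
    benchmark 5-95 percentile band shaded; holiday region annotated."""
    if set(result.median_series) != set(COMPOUNDS):
        raise InputError("arm result is missing a compound series")
    fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharex=True)
    days = np.arange(1, len(result.median_series["END"]) + 1)
    protocol = result.protocol
    for ax, compound in zip(axes.flat, COMPOUNDS):
        ax.plot(days, result.median_series[compound], lw=1.2,
                color="tab:blue", label="median trough")
        if benchmark_bands and compound in benchmark_bands:
            b = benchmark_bands[compound]
            ax.axhspan(b.p5, b.p95, color="tab:gray", alpha=0.25,
                       label="benchmark p5-p95")
            ax.axhline(b.value, color="tab:gray", lw=0.8, ls="--")
        if protocol.holiday_end_day > protocol.run_in_end_day:
            ax.axvspan(protocol.run_in_end_day, protocol.holiday_end_day,
                       color="tab:red", alpha=0.12, label="drug holiday")
        ax.set_title(compound)
        ax.set_ylabel("trough conc. (µg/L)")
    for ax in axes[-1]:
        ax.set_xlabel("time (days)")
    axes[0, 0].legend(fontsize=7, loc="lower right")
    fig.suptitle(f"{result.spec.arm_id}: time to endoxifen steady state "
                 f"(reported: {result.reported} d)")
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None} if path.suffix == ".svg" else None)
    plt.close(fig)
    return path


def _benchmark_bands(trial: TrialResult) -> dict[str, BenchmarkCtss]:
    """Per-compound steady-state bands of the EM standard-tamoxifen arm
    (the shaded reference areas of the arm figures)."""
    from .dosing import ArmSpec, build_protocol
    from .population import population_for
    from .trial import patient_ctss, run_arm
    protocol = build_protocol(ArmSpec("A", "EM", "control", 0,
                                      "20TAM", "20TAM"))
    pop = population_for(trial.config.parameter_set, "EM",
                         trial.config.n_per_arm, trial.config.seed)
    matrix = run_arm(protocol, pop)
    bands = {}
    for compound in COMPOUNDS:
        per_patient = patient_ctss(matrix, compound)
        p5, p25, med, p75, p95 = np.percentile(per_patient,
                                               [5, 25, 50, 75, 95])
        if trial.config.n_per_arm == 1:
            p5 = p25 = p75 = p95 = med
        bands[compound] = BenchmarkCtss(float(med), float(p5), float(p25),
                                        float(p75), float(p95),
                                        trial.config.seed,
                                        trial.config.n_per_arm,
                                        protocol.horizon_day)
    return bands


def write_outputs(trial: TrialResult, config: RunConfig) -> dict[str, str]:
    """Write trial_summary.csv, benchmark.json, figures and the manifest.

    Returns the manifest (file name -> description).  Deterministic:
    rerunning with the same config reproduces byte-identical CSV/JSON.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    summary = trial.summary()
    summary.to_csv(out / "trial_summary.csv", index=False,
                   float_format="%.6g")
    manifest["trial_summary.csv"] = ("per-arm time to endoxifen steady state "
                                     "and holiday-end troughs")

    b = trial.benchmark
    (out / "benchmark.json").write_text(json.dumps({
        "median_ug_per_L": b.value, "p5": b.p5, "p25": b.p25,
        "p75": b.p75, "p95": b.p95, "n": b.n, "seed": b.seed,
        "horizon_days": b.horizon}, indent=2, sort_keys=True))
    manifest["benchmark.json"] = ("median steady-state endoxifen trough of "
                                  "fully adherent EMs on 20 mg/d tamoxifen")

    from .dosing import arm_registry
    (out / "arms.json").write_text(json.dumps(arm_registry(), indent=2))
    manifest["arms.json"] = "registry of the 20 arm definitions"

    if config.figures:
        bands = _benchmark_bands(trial)
        fig_dir = out / "figures"
        fig_dir.mkdir(exist_ok=True)
        for arm_id, result in trial.arms.items():
            p = plot_arm(result, bands, fig_dir / f"{arm_id}.svg")
            manifest[f"figures/{p.name}"] = f"median trough curves, {arm_id}"

    ps = trial.config.parameter_set
    run_record = {
        "seed": config.seed, "n_per_arm": config.n_per_arm,
        "parameter_set_version": ps.version,
        "parameter_set_checksum": ps.checksum(),
        "epsilon": trial.config.epsilon,
        "files": manifest,
    }
    (out / "manifest.json").write_text(json.dumps(run_record, indent=2,
                                                  sort_keys=True))
    manifest["manifest.json"] = "run record (seed, versions, checksums)"
    return manifest


def reproduce_trial(config: RunConfig) -> TrialResult:
    """End-to-end driver: run the benchmark arm and all 20 trial arms with
    the configured parameter set and write the artifact bundle."""
    ps = config.parameter_set()
    log.info("running virtual trial: n_per_arm=%d seed=%d params=%s/%s",
             config.n_per_arm, config.seed, ps.version, ps.checksum())
    trial = run_virtual_trial(TrialConfig(
        parameter_set=ps, n_per_arm=config.n_per_arm, seed=config.seed,
        arm_filter=config.arm_filter))
    for arm_id, r in trial.arms.items():
        log.info("  %-22s time-to-target %s", arm_id, r.reported)
    write_outputs(trial, config)
    return trial
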