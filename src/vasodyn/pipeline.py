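"""Reproducible simulate → quantify → aggregate → statistics runs.

A run is described by a single YAML-style configuration (stages, one
config block per stage, a global seed and an output directory). Stages
execute in order, write every intermediate as a file, and a JSON
manifest records the fully-defaulted configuration, the seed, and a
SHA-256 checksum of every input and output file — so a run is
self-describing and two runs with identical configuration are
byte-identical.

The global seed is split deterministically into per-stage substreams
(one spawn key per stage name), so a stage can be re-run in isolation
and reproduce its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .asl import buxton_cbf, compute_cvr, pairwise_delta, roi_timeprofile, smooth_profile
from .dynamics import (
    VasomotionResult,
    average_fov_vasomotion,
    compute_pulsatility_freqpeak,
    compute_vasomotion_peak,
    estimate_heart_rate,
    estimate_rbc_velocity,
)
from .io import (
    read_asl_series,
    read_kymograph_tiff,
    read_trace_csv,
    write_asl_series,
    write_csv,
    write_kymograph_tiff,
    write_trace_csv,
)
from .stats import model_ledger
from .synthetic import (
    ASLSimConfig,
    CohortSimConfig,
    TraceSimConfig,
    gen_asl_series,
    gen_cohort,
    gen_diameter_trace,
    gen_linescan_kymograph,
)

__all__ = ["RunConfig", "run_pipeline", "aggregate"]

logger = logging.getLogger("vasodyn")

STAGES = ("simulate", "vasomotion", "pulsatility", "velocity", "asl", "aggregate", "stats")

#: stages that must precede each stage
_DEPENDENCIES = {
    "vasomotion": {"simulate"},
    "pulsatility": {"simulate"},
    "velocity": {"simulate"},
    "asl": {"simulate"},
    "aggregate": {"vasomotion"},
    "stats": {"aggregate"},
}

_DEFAULT_MODELS = [
    "log10(Vasomotion) ~ 1 + (1|Mouse) + (1|FOV)",
    "log10(Vasomotion) ~ Abeta + (1|Mouse) + (1|FOV)",
    "log10(Vasomotion) ~ Abeta + Age + (1|Mouse) + (1|FOV)",
    "log10(Vasomotion) ~ Abeta + Age + Genotype + (1|Mouse) + (1|FOV)",
    "log10(Vasomotion) ~ Abeta + Age * Genotype + (1|Mouse) + (1|FOV)",
]


@dataclass
class RunConfig:
    """Validated pipeline run configuration with defaults filled in."""

    stages: list[str]
    out_dir: Path
    seed: int = 0
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)
    vasomotion: dict = field(default_factory=dict)
    pulsatility: dict = field(default_factory=dict)
    velocity: dict = field(default_factory=dict)
    asl: dict = field(default_factory=dict)
    aggregate: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        seen: set[str] = set()
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}; valid: {STAGES}")
            missing = _DEPENDENCIES.get(s, set()) - seen
            if missing:
                raise ValueError(
                    f"stage {s!r} requires {sorted(missing)} to run before it"
                )
            seen.add(s)
        sim = {
            "cohort": {},
            "n_vessels_per_fov": 2,
            "trace": {"duration": 300.0, "sampling_rate": 2.0, "noise_sd": 0.01},
            "pulse_trace": {
                "duration": 4.0, "sampling_rate": 200.0,
                "vasomotion_amplitude": 0.0, "cardiac_amplitude": 0.02,
                "cardiac_frequency": 10.0, "noise_sd": 0.005,
            },
            "linescan": {"velocity": 2.0, "modulation_depth": 0.3,
                         "modulation_hz": 10.0, "n_lines": 2048, "noise_sd": 0.05},
            "asl": {"n_pairs": 150, "pair_interval": 4.0, "stimulus_onset": 300.0,
                    "true_cbf": 100.0, "cvr": 0.4, "noise_sd": 2.0},
        }
        for k, v in self.simulate.items():
            if isinstance(v, dict) and isinstance(sim.get(k), dict):
                sim[k] = {**sim[k], **v}
            else:
                sim[k] = v
        self.simulate = sim
        self.pulsatility = {"reference_heart_rate": 600.0, **self.pulsatility}
        self.stats = {"models": list(_DEFAULT_MODELS), **self.stats}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(raw) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["out_dir"] = str(self.out_dir)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([seed, STAGES.index(stage)])


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, out: Path) -> list[Path]:
    sim = cfg.simulate
    ss = _stage_seed(cfg.seed, "simulate")
    sub = ss.generate_state(6)  # independent 32-bit sub-seeds
    files: list[Path] = []

    cohort_cfg = CohortSimConfig(seed=int(sub[0] % 2**31), **sim["cohort"])
    table, truth = gen_cohort(cohort_cfg)
    files.append(write_csv(table, out / "cohort_truth.csv"))

    # one diameter trace per vessel per FOV-session, planted at the
    # FOV-session's true vasomotion amplitude
    trace_dir = out / "traces"
    counter = 0
    for _, row in table.iterrows():
        for v in range(int(sim["n_vessels_per_fov"])):
            tcfg = TraceSimConfig(
                vasomotion_amplitude=float(row.vasomotion_peak),
                seed=int((sub[1] + counter) % 2**31),
                **sim["trace"],
            )
            counter += 1
            trace, _ = gen_diameter_trace(
                tcfg,
                mouse_id=row.mouse_id,
                fov_id=row.fov_id,
                vessel_id=f"{row.fov_id}-V{v + 1}",
                age_days=float(row.age) * 30.0,
            )
            files.append(
                write_trace_csv(
                    trace, trace_dir / f"{row.fov_id}_age{row.age:g}_V{v + 1}.csv"
                )
            )

    # high-rate pulsatility traces: one per FOV-session
    pulse_dir = out / "pulse_traces"
    for i, (_, row) in enumerate(table.iterrows()):
        pcfg = TraceSimConfig(seed=int((sub[2] + i) % 2**31), **sim["pulse_trace"])
        trace, _ = gen_diameter_trace(
            pcfg, mouse_id=row.mouse_id, fov_id=row.fov_id,
            vessel_id=f"{row.fov_id}-V1", age_days=float(row.age) * 30.0,
        )
        files.append(
            write_trace_csv(trace, pulse_dir / f"{row.fov_id}_age{row.age:g}.csv")
        )

    # one line-scan kymograph (cardiac-modulated velocity)
    ls = sim["linescan"]
    n_lines = int(ls["n_lines"])
    t = np.arange(n_lines) * 1e-3
    v = ls["velocity"] * (1.0 + ls["modulation_depth"] * np.sin(2 * np.pi * ls["modulation_hz"] * t))
    kymo, _ = gen_linescan_kymograph(
        velocity=v, n_lines=n_lines, noise_sd=ls["noise_sd"],
        seed=int(sub[3] % 2**31),
    )
    files.append(write_kymograph_tiff(kymo, out / "linescan.tiff"))

    # one ASL acquisition
    acfg = ASLSimConfig(seed=int(sub[4] % 2**31), **sim["asl"])
    series, _ = gen_asl_series(acfg)
    files.extend(write_asl_series(series, out / "asl.nii"))
    return files


def _stage_vasomotion(cfg: RunConfig, sim_dir: Path, out: Path) -> list[Path]:
    rows = []
    for f in sorted((sim_dir / "traces").glob("*.csv")):
        trace = read_trace_csv(f)
        res = compute_vasomotion_peak(trace)
        rows.append(
            {
                "mouse_id": trace.mouse_id, "fov_id": trace.fov_id,
                "vessel_id": trace.vessel_id, "age": trace.age_days / 30.0,
                "peak_amplitude": res.peak_amplitude,
                "peak_frequency": res.peak_frequency,
            }
        )
    if not rows:
        raise FileNotFoundError(f"no trace CSVs found under {sim_dir / 'traces'}")
    return [write_csv(pd.DataFrame(rows), out / "vasomotion.csv")]


def _stage_pulsatility(cfg: RunConfig, sim_dir: Path, out: Path) -> list[Path]:
    ref = float(cfg.pulsatility["reference_heart_rate"])
    rows = []
    for f in sorted((sim_dir / "pulse_traces").glob("*.csv")):
        trace = read_trace_csv(f)
        res = compute_pulsatility_freqpeak(trace, reference_heart_rate=ref)
        rows.append(
            {
                "mouse_id": trace.mouse_id, "fov_id": trace.fov_id,
                "vessel_id": trace.vessel_id, "age": trace.age_days / 30.0,
                "auc_metric": res.auc_metric,
                "freq_peak_amplitude": res.freq_peak_amplitude,
                "estimated_heart_rate": res.estimated_heart_rate,
                "included": res.included,
            }
        )
    if not rows:
        raise FileNotFoundError(f"no pulse-trace CSVs under {sim_dir / 'pulse_traces'}")
    return [write_csv(pd.DataFrame(rows), out / "pulsatility.csv")]


def _stage_velocity(cfg: RunConfig, sim_dir: Path, out: Path) -> list[Path]:
    kymo = read_kymograph_tiff(sim_dir / "linescan.tiff")
    vt = estimate_rbc_velocity(kymo, window=64, step=8)
    try:
        hr = estimate_heart_rate(vt)
    except ValueError:  # trace too short for a spectral heart-rate estimate
        hr = None
    vel = pd.DataFrame({"time_s": vt.times, "velocity_mm_s": vt.velocity})
    files = [write_csv(vel, out / "velocity.csv")]
    good = vt.velocity[np.isfinite(vt.velocity)]
    summary = pd.DataFrame(
        [{"mean_velocity_mm_s": good.mean() if good.size else np.nan,
          "heart_rate_bpm": hr if hr is not None else np.nan}]
    )
    files.append(write_csv(summary, out / "velocity_summary.csv"))
    return files


def _stage_asl(cfg: RunConfig, sim_dir: Path, out: Path) -> list[Path]:
    series = read_asl_series(sim_dir / "asl.nii")
    delta = pairwise_delta(series)
    cbf_maps = np.stack([buxton_cbf(d, series.m0t, series.params) for d in delta])
    roi = np.ones(series.m0t.shape, dtype=bool)
    profile = roi_timeprofile(cbf_maps, roi, series.pair_times, roi_id="global")
    cleaned = smooth_profile(profile)
    cvr = compute_cvr(cleaned)
    prof_df = pd.DataFrame(
        {"time_s": cleaned.times, "cbf": cleaned.cbf, "missing": cleaned.missing_mask}
    )
    files = [write_csv(prof_df, out / "cbf_profile.csv")]
    base = cleaned._window_values(cleaned.baseline_window).mean()
    files.append(
        write_csv(
            pd.DataFrame([{"roi_id": "global", "baseline_cbf": base, "cvr_percent": cvr}]),
            out / "cvr.csv",
        )
    )
    return files


def aggregate(results_dir: str | Path, out_path: str | Path | None = None) -> tuple[pd.DataFrame, dict]:
    """Join per-vessel results into one FOV-session cohort table.

    Reads ``vasomotion.csv`` (required) and ``pulsatility.csv``
    (optional) from ``results_dir``: vasomotion peaks are averaged over
    the vessels of each FOV-session; pulsatility rows flagged
    ``included = False`` are dropped with a logged count; metadata
    columns (genotype, amyloid coverage) are joined from
    ``cohort_truth.csv`` when present. Duplicate (FOV, session) keys
    with conflicting metadata are rejected.

    Returns (table, counts) where counts records every dropped row.
    """
    results_dir = Path(results_dir)
    vaso_path = results_dir / "vasomotion.csv"
    if not vaso_path.exists():
        raise FileNotFoundError(f"no vasomotion results under {results_dir}")
    vaso = pd.read_csv(vaso_path)
    if vaso.empty:
        raise ValueError("vasomotion results are empty")
    dup = vaso.duplicated(subset=["fov_id", "age", "vessel_id"], keep=False)
    if dup.any():
        keys = vaso.loc[dup, ["fov_id", "age", "vessel_id"]].drop_duplicates()
        raise ValueError(f"conflicting duplicate keys in vasomotion results:\n{keys}")

    grouped = (
        vaso.groupby(["mouse_id", "fov_id", "age"], as_index=False)
        .agg(vasomotion_peak=("peak_amplitude", "mean"), n_vessels=("vessel_id", "count"))
    )
    counts = {"pulsatility_excluded": 0}

    pulse_path = results_dir / "pulsatility.csv"
    if pulse_path.exists():
        pulse = pd.read_csv(pulse_path)
        n_excl = int((~pulse["included"]).sum())
        counts["pulsatility_excluded"] = n_excl
        if n_excl:
            logger.info("aggregate: dropped %d pulsatility rows (exclusion rule)", n_excl)
        kept = (
            pulse[pulse["included"]]
            .groupby(["fov_id", "age"], as_index=False)
            .agg(pulsatility_auc=("auc_metric", "mean"))
        )
        grouped = grouped.merge(kept, on=["fov_id", "age"], how="left")

    meta_path = results_dir / "cohort_truth.csv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path)[["fov_id", "age", "genotype", "abeta_coverage"]]
        grouped = grouped.merge(meta, on=["fov_id", "age"], how="left")

    grouped = grouped.sort_values(["mouse_id", "fov_id", "age"], kind="mergesort").reset_index(drop=True)
    if out_path is not None:
        write_csv(grouped, out_path)
    return grouped, counts


def _stage_aggregate(cfg: RunConfig, work: Path, out: Path) -> tuple[list[Path], dict]:
    table, counts = aggregate(work, out / "cohort.csv")
    return [out / "cohort.csv"], counts


def _stage_stats(cfg: RunConfig, work: Path, out: Path) -> list[Path]:
    table = pd.read_csv(work / "aggregate" / "cohort.csv")
    ledger, _ = model_ledger(table, cfg.stats["models"])
    return [write_csv(ledger, out / "ledger.csv")]


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig | dict | str | Path) -> dict:
    """Execute the configured stages in order and write the run manifest.

    Every stage's outputs are checksummed; a stage failure aborts the
    run with the failing stage named, retaining partial outputs and
    flagging them in the manifest. Returns the manifest dict (also
    written to ``<out_dir>/manifest.json``).
    """
    if isinstance(config, (str, Path)):
        config = RunConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = RunConfig.from_dict(config)
    out_dir = config.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level)

    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest: dict = {
        "vasodyn_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "stages": {},
        "dropped_rows": {},
        "status": "ok",
    }
    # stage workspace: simulate writes under out/simulate, quantification
    # stages read from there and write flat result CSVs under out/
    sim_dir = out_dir / "simulate"
    try:
        for stage in config.stages:
            logger.info("stage %s", stage)
            stage_out = out_dir / stage
            stage_out.mkdir(parents=True, exist_ok=True)
            if stage == "simulate":
                files = _stage_simulate(config, stage_out)
            elif stage == "vasomotion":
                files = _stage_vasomotion(config, sim_dir, out_dir)
            elif stage == "pulsatility":
                files = _stage_pulsatility(config, sim_dir, out_dir)
            elif stage == "velocity":
                files = _stage_velocity(config, sim_dir, out_dir)
            elif stage == "asl":
                files = _stage_asl(config, sim_dir, out_dir)
            elif stage == "aggregate":
                # aggregate reads the flat result CSVs + simulate metadata
                for needed in ("vasomotion.csv",):
                    if not (out_dir / needed).exists():
                        raise FileNotFoundError(f"aggregate input {needed} missing")
                if (sim_dir / "cohort_truth.csv").exists():
                    import shutil

                    shutil.copy(sim_dir / "cohort_truth.csv", out_dir / "cohort_truth.csv")
                files, counts = _stage_aggregate(config, out_dir, stage_out)
                manifest["dropped_rows"].update(counts)
            elif stage == "stats":
                files = _stage_stats(config, out_dir, stage_out)
            manifest["stages"][stage] = {
                "outputs": {str(f.relative_to(out_dir)): _sha256(f) for f in sorted(files)}
            }
    except Exception as exc:
        manifest["status"] = f"failed at stage {stage!r}: {exc}"
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        logger.removeHandler(handler)
        handler.close()
        raise RuntimeError(manifest["status"]) from exc

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.removeHandler(handler)
    handler.close()
    return manifest
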