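"""File round-tripping for the pipeline's standard formats.

Image stacks and kymographs are multi-page TIFF (tifffile); ASL series
are NIfTI-1 with a JSON sidecar for timing and quantification constants
(nibabel); diameter traces, cohort tables and truth records are CSV.
CSV floats are written with repr-exact precision so that repeated runs
of a seeded pipeline are byte-identical.

CSV column dictionaries
-----------------------
trace CSV: ``time_s, diameter_um`` plus constant metadata columns
``mouse_id, fov_id, vessel_id, age_days, vessel_class``.

cohort CSV: ``mouse_id, fov_id, genotype, age, abeta_coverage,
vasomotion_peak`` (and optionally ``log10_vasomotion``,
``pulsatility_auc``, ``normalized_diameter``, ``rbc_velocity``).

ASL JSON sidecar keys: ``pld_ms, tau_ms, t1b_ms, t1t_ms, alpha,
lambda_ml_per_g, label_order, pair_interval_s``.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .asl import ASLParams, ASLSeries
from .dynamics import DiameterTrace, Kymograph

__all__ = [
    "write_csv",
    "write_trace_csv",
    "read_trace_csv",
    "write_stack_tiff",
    "read_stack_tiff",
    "write_kymograph_tiff",
    "read_kymograph_tiff",
    "write_asl_series",
    "read_asl_series",
]

_FLOAT_FMT = "%.17g"


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a DataFrame with deterministic float formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_trace_csv(trace: DiameterTrace, path: str | Path) -> Path:
    df = pd.DataFrame(
        {
            "time_s": trace.timestamps,
            "diameter_um": trace.diameter,
            "mouse_id": trace.mouse_id,
            "fov_id": trace.fov_id,
            "vessel_id": trace.vessel_id,
            "age_days": trace.age_days,
            "vessel_class": trace.vessel_class,
        }
    )
    return write_csv(df, path)


def read_trace_csv(path: str | Path) -> DiameterTrace:
    df = pd.read_csv(path)
    meta = {}
    for col, attr in [
        ("mouse_id", "mouse_id"), ("fov_id", "fov_id"), ("vessel_id", "vessel_id"),
        ("age_days", "age_days"), ("vessel_class", "vessel_class"),
    ]:
        if col in df.columns and len(df):
            v = df[col].iloc[0]
            meta[attr] = v if not pd.isna(v) else ("" if df[col].dtype == object else np.nan)
    return DiameterTrace(
        timestamps=df["time_s"].to_numpy(),
        diameter=df["diameter_um"].to_numpy(),
        **meta,
    )


def write_stack_tiff(stack: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))
    return path


def read_stack_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def write_kymograph_tiff(kymo: Kymograph, path: str | Path) -> Path:
    """Kymograph as single-page TIFF with pitch/period in the JSON description."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "line_period_s": kymo.line_period,
        "pixel_pitch_um": kymo.pixel_pitch,
        "vessel_id": kymo.vessel_id,
    }
    tifffile.imwrite(
        path, kymo.intensity.astype(np.float32), description=json.dumps(meta)
    )
    return path


def read_kymograph_tiff(path: str | Path) -> Kymograph:
    with tifffile.TiffFile(path) as tf:
        img = tf.asarray().astype(float)
        desc = tf.pages[0].description
    meta = json.loads(desc)
    return Kymograph(
        intensity=img,
        line_period=meta["line_period_s"],
        pixel_pitch=meta["pixel_pitch_um"],
        vessel_id=meta.get("vessel_id", ""),
    )


def write_asl_series(series: ASLSeries, path: str | Path) -> tuple[Path, Path, Path]:
    """NIfTI-1 4-D series + M0 volume + JSON sidecar.

    ``path`` is the series file; the M0 and sidecar live next to it as
    ``<stem>_m0.nii`` and ``<stem>.json``. Returns the three paths.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    # nibabel expects spatial-first axes: (x, y, z, t)
    data = np.moveaxis(series.volumes, 0, -1)
    nib.save(nib.Nifti1Image(data.astype(np.float64), affine), path)
    m0_path = path.with_name(path.stem.replace(".nii", "") + "_m0.nii")
    nib.save(nib.Nifti1Image(series.m0t.astype(np.float64), affine), m0_path)
    p = series.params
    pair_interval = float(np.mean(np.diff(series.pair_times))) if series.n_pairs > 1 else 0.0
    sidecar = {
        "pld_ms": p.pld,
        "tau_ms": p.tau,
        "t1b_ms": p.t1b,
        "t1t_ms": p.t1t,
        "alpha": p.alpha,
        "lambda_ml_per_g": p.lambda_bbpc,
        "label_order": series.label_order,
        "pair_interval_s": pair_interval,
        "pair_times_s": [float(t) for t in series.pair_times],
    }
    sidecar_path = path.with_name(path.stem.replace(".nii", "") + ".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path, m0_path, sidecar_path


def read_asl_series(
    path: str | Path, m0_path: str | Path | None = None,
    sidecar_path: str | Path | None = None,
) -> ASLSeries:
    path = Path(path)
    stem = path.stem.replace(".nii", "")
    m0_path = Path(m0_path) if m0_path else path.with_name(stem + "_m0.nii")
    sidecar_path = Path(sidecar_path) if sidecar_path else path.with_name(stem + ".json")
    sidecar = json.loads(sidecar_path.read_text())
    data = np.asanyarray(nib.load(path).dataobj).astype(float)
    volumes = np.moveaxis(data, -1, 0)
    m0 = np.asanyarray(nib.load(m0_path).dataobj).astype(float)
    params = ASLParams(
        lambda_bbpc=sidecar["lambda_ml_per_g"],
        t1b=sidecar["t1b_ms"],
        t1t=sidecar["t1t_ms"],
        alpha=sidecar["alpha"],
        pld=sidecar["pld_ms"],
        tau=sidecar["tau_ms"],
    )
    if "pair_times_s" in sidecar:
        pair_times = np.asarray(sidecar["pair_times_s"], dtype=float)
    else:
        pair_times = np.arange(volumes.shape[0] // 2) * sidecar["pair_interval_s"]
    return ASLSeries(
        volumes=volumes,
        m0t=m0,
        params=params,
        pair_times=pair_times,
        label_order=sidecar.get("label_order"),
    )
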