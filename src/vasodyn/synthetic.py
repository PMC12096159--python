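"""Synthetic-data generators with known ground truth.

Every input the quantification chain consumes can be generated here
with a *truth record* — a plain dict (or DataFrame) carrying the
planted quantities — so each downstream estimator can be tested against
an exact oracle. The generators emulate the statistical structure of a
longitudinal two-photon + MRI study of cerebral amyloid angiopathy
(CAA) in a transgenic mouse model:

* 5-minute vessel-diameter traces containing a slow (~0.1 Hz)
  vasomotion oscillation, cardiac pulsation (~10 Hz ≈ 600 bpm mouse
  heart rate), linear drift and additive Gaussian noise;
* fluorescence movies of a vessel whose cross-section is a plateau of
  the true diameter convolved with a Gaussian wall profile, so that a
  full-width-at-half-maximum readout is exact by construction;
* line-scan kymographs with dark RBC streaks of known slope
  (velocity × line_period / pixel_pitch px/line);
* pCASL label/control series whose differences are produced by
  inverting the Buxton equation at the voxel's true CBF, scaled by
  (1 + CVR) after stimulus onset;
* per-mouse / per-FOV longitudinal cohorts with random intercepts and
  an age × genotype interaction on the log10(vasomotion) scale.

All generators are pure functions of their configuration including the
seed: identical config ⇒ bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import erf

from .asl import ASLParams, ASLSeries, buxton_delta_m
from .dynamics import DiameterTrace, Kymograph

__all__ = [
    "TraceSimConfig",
    "ASLSimConfig",
    "CohortSimConfig",
    "gen_diameter_trace",
    "gen_vessel_movie",
    "gen_linescan_kymograph",
    "gen_asl_series",
    "gen_cohort",
]


# ---------------------------------------------------------------------------
# diameter traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceSimConfig:
    """Configuration of a synthetic vessel-diameter trace.

    Amplitudes, drift and noise are fractions of the baseline diameter;
    ``drift_slope`` is fraction per minute. The sampling rate must
    exceed twice every frequency actually present (amplitude > 0).
    """

    duration: float = 300.0  # s
    sampling_rate: float = 2.0  # Hz
    baseline_diameter: float = 20.0  # µm
    vasomotion_amplitude: float = 0.05
    vasomotion_frequency: float = 0.1  # Hz
    cardiac_amplitude: float = 0.0
    cardiac_frequency: float = 10.0  # Hz (~600 bpm mouse heart rate)
    drift_slope: float = 0.0  # fraction of baseline per minute
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.baseline_diameter <= 0:
            raise ValueError("baseline_diameter must be positive")
        for name in ("vasomotion_amplitude", "cardiac_amplitude", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        freqs = [
            f
            for f, a in [
                (self.vasomotion_frequency, self.vasomotion_amplitude),
                (self.cardiac_frequency, self.cardiac_amplitude),
            ]
            if a > 0
        ]
        if freqs and self.sampling_rate <= 2.0 * max(freqs):
            raise ValueError(
                f"Nyquist violation: sampling_rate {self.sampling_rate} Hz must "
                f"exceed 2 x {max(freqs)} Hz"
            )


def gen_diameter_trace(
    config: TraceSimConfig, **trace_meta
) -> tuple[DiameterTrace, dict]:
    """Simulate a diameter trace; returns (trace, truth record).

    The diameter is
    ``D0 * (1 + A_v sin(2π f_v t) + A_c sin(2π f_c t) + drift·t/60 + ε)``
    with ε ~ N(0, noise_sd²). The truth record carries every planted
    component.
    """
    n = int(round(config.duration * config.sampling_rate))
    t = np.arange(n) / config.sampling_rate
    rng = np.random.default_rng(config.seed)
    rel = (
        config.vasomotion_amplitude * np.sin(2 * np.pi * config.vasomotion_frequency * t)
        + config.cardiac_amplitude * np.sin(2 * np.pi * config.cardiac_frequency * t)
        + config.drift_slope * t / 60.0
    )
    noise = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else np.zeros(n)
    diameter = config.baseline_diameter * (1.0 + rel + noise)
    trace = DiameterTrace(timestamps=t, diameter=diameter, **trace_meta)
    truth = {
        "config": asdict(config),
        "relative_components": rel,
        "noise": noise,
        "true_vasomotion_amplitude": config.vasomotion_amplitude,
        "true_vasomotion_frequency": config.vasomotion_frequency,
        "true_cardiac_amplitude": config.cardiac_amplitude,
        "true_cardiac_frequency": config.cardiac_frequency,
    }
    return trace, truth


# ---------------------------------------------------------------------------
# vessel movies
# ---------------------------------------------------------------------------

def _vessel_profile(
    x: np.ndarray, center: float, diameter: float, wall_sd: float
) -> np.ndarray:
    """Plateau of width ``diameter`` convolved with a Gaussian of ``wall_sd``.

    The convolution is evaluated analytically via the error function,
    so the profile's FWHM equals the plateau width exactly (for
    symmetric walls) and the extraction oracle is exact. ``x``,
    ``center``, ``diameter`` and ``wall_sd`` share units (µm).
    """
    if wall_sd <= 0:
        return ((x >= center - diameter / 2) & (x <= center + diameter / 2)).astype(float)
    a = (x - (center - diameter / 2)) / (wall_sd * np.sqrt(2))
    b = (x - (center + diameter / 2)) / (wall_sd * np.sqrt(2))
    return 0.5 * (erf(a) - erf(b))


def gen_vessel_movie(
    trace: DiameterTrace,
    pixel_size: float = 0.5,
    fov_shape: tuple[int, int] = (32, 128),
    wall_profile_sd: float = 1.0,
    background_noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Render a diameter trace as a fluorescence movie; returns (stack, truth).

    The vessel runs along the rows (axis 1) of every frame, centred in
    the columns; each frame's cross-vessel intensity profile is a
    plateau of the frame's true diameter convolved with a Gaussian of
    ``wall_profile_sd`` (µm). Additive Gaussian background noise is
    optional. The truth record carries the per-frame diameter.
    """
    n_rows, n_cols = fov_shape
    max_d = np.nanmax(trace.diameter)
    if max_d + 6 * wall_profile_sd >= n_cols * pixel_size:
        raise ValueError(
            f"vessel (max diameter {max_d:.1f} µm) does not fit inside the "
            f"{n_cols * pixel_size:.1f} µm field of view"
        )
    x = (np.arange(n_cols) + 0.5) * pixel_size
    center = n_cols * pixel_size / 2.0
    rng = np.random.default_rng(seed)
    stack = np.empty((trace.diameter.size, n_rows, n_cols))
    for i, d in enumerate(trace.diameter):
        profile = _vessel_profile(x, center, d, wall_profile_sd)
        stack[i] = profile[None, :]
    if background_noise_sd > 0:
        stack = stack + rng.normal(0.0, background_noise_sd, stack.shape)
    truth = {
        "true_diameter": trace.diameter.copy(),
        "timestamps": trace.timestamps.copy(),
        "pixel_size": pixel_size,
        "center_um": center,
        "wall_profile_sd": wall_profile_sd,
    }
    return stack, truth


# ---------------------------------------------------------------------------
# line-scan kymographs
# ---------------------------------------------------------------------------

def gen_linescan_kymograph(
    velocity: float | np.ndarray,
    line_period: float = 1e-3,
    pixel_pitch: float = 0.5,
    n_lines: int = 2048,
    n_pixels: int = 128,
    streak_density: float = 0.05,
    streak_width_px: float = 1.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Kymograph, dict]:
    """Simulate a line-scan kymograph with RBC streaks of known slope.

    ``velocity`` (mm/s, signed) may be a scalar or an array of length
    ``n_lines`` (e.g. cardiac-modulated). Dark Gaussian streaks of
    width ``streak_width_px`` move at the planted velocity on a bright
    background; streak positions wrap around the scan line so the
    density stays constant. The streak slope is
    ``velocity × line_period / pixel_pitch`` px/line and must be 0 or
    within the resolvable range [0.05, 20] px/line in magnitude.

    Returns (kymograph, truth record) with the per-line velocity course.
    """
    v = np.broadcast_to(np.asarray(velocity, dtype=float), (n_lines,)).copy()
    # slope in px/line; velocity mm/s -> µm/s via 1e3
    slope = v * 1e3 * line_period / pixel_pitch
    nonzero = slope[slope != 0]
    if nonzero.size:
        mag = np.abs(nonzero)
        if mag.min() < 0.05 or mag.max() > 20.0:
            raise ValueError(
                "unresolvable streak slope: |velocity * line_period / pixel_pitch| "
                f"spans [{mag.min():.3f}, {mag.max():.3f}] px/line, outside [0.05, 20]"
            )
    rng = np.random.default_rng(seed)
    n_streaks = max(1, int(round(streak_density * n_lines)))
    x0 = rng.uniform(0, n_pixels, n_streaks)
    # cumulative lateral displacement (px) of every streak at each line
    disp = np.concatenate([[0.0], np.cumsum(slope[:-1])])
    cols = np.arange(n_pixels)
    img = np.ones((n_lines, n_pixels))
    for s in range(n_streaks):
        pos = np.mod(x0[s] + disp, n_pixels)
        d = np.abs(cols[None, :] - pos[:, None])
        d = np.minimum(d, n_pixels - d)  # wrap-around distance
        img -= 0.8 * np.exp(-0.5 * (d / streak_width_px) ** 2)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    kymo = Kymograph(intensity=img, line_period=line_period, pixel_pitch=pixel_pitch)
    truth = {
        "true_velocity": v,
        "true_slope_px_per_line": slope,
        "line_times": np.arange(n_lines) * line_period,
    }
    return kymo, truth


# ---------------------------------------------------------------------------
# ASL series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ASLSimConfig:
    """Configuration of a synthetic pCASL acquisition.

    ``true_cbf_map`` (mL/100 g/min) and ``cvr_map`` (fractional CBF
    increase) are per-voxel arrays of shape ``grid_shape``; scalars are
    broadcast. After ``stimulus_onset`` seconds the voxel's CBF is
    scaled by (1 + CVR). Outliers perturb a volume's time point by
    ``outlier_scale × noise_sd`` with random sign.
    """

    grid_shape: tuple[int, int, int] = (4, 4, 2)
    true_cbf: float | np.ndarray = 100.0
    cvr: float | np.ndarray = 0.4
    n_pairs: int = 150
    pair_interval: float = 4.0  # s
    stimulus_onset: float = 300.0  # s
    params: ASLParams = field(default_factory=ASLParams)
    m0_value: float = 1000.0
    noise_sd: float = 0.0
    outlier_prob: float = 0.0
    outlier_scale: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be at least 1")
        if not 0.0 <= self.outlier_prob <= 1.0:
            raise ValueError("outlier_prob must lie in [0, 1]")
        if not 0.0 <= self.stimulus_onset <= self.n_pairs * self.pair_interval:
            raise ValueError("stimulus_onset must lie within the series duration")
        if self.m0_value <= 0:
            raise ValueError("m0_value must be positive")
        # ASLParams validates its own positivity constraints on construction


def gen_asl_series(config: ASLSimConfig) -> tuple[ASLSeries, dict]:
    """Simulate a pCASL label/control series; returns (series, truth record).

    Control volumes sit at M0; label volumes at M0 − ΔM with ΔM obtained
    by inverting the Buxton equation at the voxel's current true CBF, so
    that noise-free quantification round-trips exactly. Gaussian noise
    is added per volume; outlier time points are perturbed with random
    sign.
    """
    shape = config.grid_shape
    cbf0 = np.broadcast_to(np.asarray(config.true_cbf, dtype=float), shape)
    cvr = np.broadcast_to(np.asarray(config.cvr, dtype=float), shape)
    m0 = np.full(shape, config.m0_value)
    pair_times = np.arange(config.n_pairs) * config.pair_interval
    stim = pair_times >= config.stimulus_onset

    rng = np.random.default_rng(config.seed)
    volumes = np.empty((2 * config.n_pairs, *shape))
    true_cbf_t = np.empty((config.n_pairs, *shape))
    for i in range(config.n_pairs):
        cbf_i = cbf0 * (1.0 + cvr) if stim[i] else cbf0
        true_cbf_t[i] = cbf_i
        dm = buxton_delta_m(cbf_i, m0, config.params)
        volumes[2 * i] = m0 - dm  # label
        volumes[2 * i + 1] = m0  # control
    if config.noise_sd > 0:
        volumes = volumes + rng.normal(0.0, config.noise_sd, volumes.shape)
    outlier_mask = np.zeros(2 * config.n_pairs, dtype=bool)
    if config.outlier_prob > 0:
        outlier_mask = rng.random(2 * config.n_pairs) < config.outlier_prob
        signs = rng.choice([-1.0, 1.0], size=2 * config.n_pairs)
        bump = config.outlier_scale * config.noise_sd
        volumes[outlier_mask] += (signs[outlier_mask] * bump)[:, None, None, None]

    series = ASLSeries(
        volumes=volumes,
        m0t=m0,
        params=config.params,
        pair_times=pair_times,
        label_order="label_first",
    )
    truth = {
        "true_cbf_baseline": np.asarray(cbf0).copy(),
        "true_cvr": np.asarray(cvr).copy(),
        "true_cbf_timecourse": true_cbf_t,
        "stimulus_mask": stim,
        "outlier_volumes": outlier_mask,
    }
    return series, truth


# ---------------------------------------------------------------------------
# longitudinal cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSimConfig:
    """Configuration of a longitudinal vasomotion cohort.

    Fixed effects act on the log10(vasomotion) scale:

        log10(v) = intercept + beta_abeta·abeta + beta_age·age
                   + beta_genotype·Tg + beta_age_x_genotype·age·Tg
                   + b_mouse + b_fov + ε

    with mouse and FOV random intercepts and Gaussian residuals. Ages
    are in months. Amyloid coverage (% of the vessel wall) grows
    linearly with age after onset in transgenic animals and is
    identically zero in wildtypes. Defaults mirror a small two-genotype
    study (4 mice per genotype, 4 FOVs, monthly sessions from 6 to
    12 months, ≈128 measurements); the planted interaction slope of
    −0.097 log10-units per month is the size of decline the pipeline is
    designed to detect.
    """

    n_mice_per_genotype: int = 4
    n_fov_per_mouse: int = 4
    sessions_ages: tuple[float, ...] = (6.0, 8.0, 10.0, 12.0)  # months
    intercept: float = -1.0
    beta_abeta: float = 0.0
    beta_age: float = 0.0
    beta_genotype: float = 0.87
    beta_age_x_genotype: float = -0.097
    sd_mouse_intercept: float = 0.1
    sd_fov_intercept: float = 0.1
    sd_residual: float = 0.15
    abeta_onset_age: float = 8.0  # months
    abeta_growth: float = 8.0  # % coverage per month after onset (Tg only)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sd_mouse_intercept", "sd_fov_intercept", "sd_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        ages = np.asarray(self.sessions_ages, dtype=float)
        if ages.size < 1 or np.any(np.diff(ages) <= 0):
            raise ValueError("sessions_ages must be strictly increasing")
        if self.n_mice_per_genotype < 2:
            raise ValueError(
                "need at least 2 mice per genotype for the model ledger to be fittable"
            )
        if self.abeta_growth < 0:
            raise ValueError("abeta_growth must be non-negative")


def gen_cohort(config: CohortSimConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate a longitudinal cohort table; returns (table, truth record).

    One row per FOV per session with mouse id, genotype, age (months),
    % amyloid coverage and vasomotion peak (the response is generated
    on the log10 scale and exponentiated). The truth record carries all
    drawn random effects and the planted fixed effects.
    """
    rng = np.random.default_rng(config.seed)
    ages = np.asarray(config.sessions_ages, dtype=float)
    rows = []
    mouse_effects: dict[str, float] = {}
    fov_effects: dict[str, float] = {}
    for geno in ("WT", "Tg"):
        is_tg = 1.0 if geno == "Tg" else 0.0
        for m in range(config.n_mice_per_genotype):
            mouse = f"{geno}{m + 1}"
            b_mouse = rng.normal(0.0, config.sd_mouse_intercept)
            mouse_effects[mouse] = b_mouse
            for f in range(config.n_fov_per_mouse):
                fov = f"{mouse}-F{f + 1}"
                b_fov = rng.normal(0.0, config.sd_fov_intercept)
                fov_effects[fov] = b_fov
                for age in ages:
                    if is_tg:
                        abeta = config.abeta_growth * max(0.0, age - config.abeta_onset_age)
                        abeta = min(abeta, 100.0)
                    else:
                        abeta = 0.0
                    eps = rng.normal(0.0, config.sd_residual)
                    log10_v = (
                        config.intercept
                        + config.beta_abeta * abeta
                        + config.beta_age * age
                        + config.beta_genotype * is_tg
                        + config.beta_age_x_genotype * age * is_tg
                        + b_mouse
                        + b_fov
                        + eps
                    )
                    rows.append(
                        {
                            "mouse_id": mouse,
                            "fov_id": fov,
                            "genotype": geno,
                            "age": age,
                            "abeta_coverage": abeta,
                            "log10_vasomotion": log10_v,
                            "vasomotion_peak": 10.0 ** log10_v,
                        }
                    )
    table = pd.DataFrame(rows)
    truth = {
        "fixed_effects": {
            "intercept": config.intercept,
            "beta_abeta": config.beta_abeta,
            "beta_age": config.beta_age,
            "beta_genotype": config.beta_genotype,
            "beta_age_x_genotype": config.beta_age_x_genotype,
        },
        "mouse_effects": mouse_effects,
        "fov_effects": fov_effects,
        "sd_mouse_intercept": config.sd_mouse_intercept,
        "sd_fov_intercept": config.sd_fov_intercept,
        "sd_residual": config.sd_residual,
    }
    return table, truth
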