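"""Vessel-dynamics quantification.

Extracts diameter and red-blood-cell (RBC) velocity signals from
two-photon image data and computes three per-vessel statistics used in
longitudinal studies of arteriolar function:

* the *vasomotion peak* — the maximum one-sided spectral amplitude of
  the normalized diameter trace in a low-frequency band (default
  0.04–0.13 Hz), capturing spontaneous smooth-muscle-driven diameter
  oscillations;
* the *beat-to-beat pulsatility* of high-rate diameter traces, as a
  time-normalized absolute AUC of the detrended normalized trace and as
  the spectral amplitude at the cardiac frequency, with an exclusion
  rule when the spectral heart-rate estimate disagrees with an
  independent reference by more than 50 %;
* RBC velocity from line-scan kymographs via Radon-projection angle
  maximization, from which the heart rate is estimated.

Spectral amplitudes are one-sided, ``2|X_k|/N``, computed on the
mean-normalized, mean-subtracted trace, with no taper. All statistics
are therefore dimensionless fractions of the mean diameter and
invariant to amplitude rescaling of the raw trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as _signal
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "DiameterTrace",
    "VasomotionResult",
    "Kymograph",
    "PulsatilityResult",
    "VelocityTrace",
    "NormalROI",
    "VASOMOTION_BAND",
    "CARDIAC_BAND_HZ",
    "subtract_bleedthrough",
    "extract_diameter_trace",
    "compute_vasomotion_peak",
    "average_fov_vasomotion",
    "estimate_rbc_velocity",
    "estimate_heart_rate",
    "compute_pulsatility_auc",
    "compute_pulsatility_freqpeak",
    "compute_caa_coverage",
]

#: Default vasomotion frequency band (Hz).
VASOMOTION_BAND = (0.04, 0.13)

#: Cardiac search band, 300–1000 bpm expressed in Hz.
CARDIAC_BAND_HZ = (5.0, 50.0 / 3.0)


@dataclass
class DiameterTrace:
    """A time-stamped vessel-diameter series.

    Parameters
    ----------
    timestamps : array of float
        Sample times in seconds, strictly increasing and uniformly
        spaced (within a relative tolerance of 1e-3 on the step).
    diameter : array of float
        Vessel diameter in micrometres. NaN marks a missing frame.
    """

    timestamps: np.ndarray
    diameter: np.ndarray
    mouse_id: str = ""
    fov_id: str = ""
    vessel_id: str = ""
    age_days: float = np.nan
    vessel_class: str = "arteriole"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.diameter = np.asarray(self.diameter, dtype=float)
        if self.timestamps.ndim != 1 or self.timestamps.shape != self.diameter.shape:
            raise ValueError("timestamps and diameter must be 1-D arrays of equal length")
        if self.timestamps.size < 2:
            raise ValueError("a trace needs at least two samples")
        dt = np.diff(self.timestamps)
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.ptp(dt) > 1e-3 * dt.mean():
            raise ValueError("timestamps must be uniformly spaced")
        finite = self.diameter[np.isfinite(self.diameter)]
        if finite.size and np.any(finite <= 0):
            raise ValueError("diameter must be positive")

    @property
    def sampling_rate(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / float(np.mean(np.diff(self.timestamps)))

    @property
    def duration(self) -> float:
        """Trace duration in seconds (span plus one sample period)."""
        return float(self.timestamps[-1] - self.timestamps[0]) + 1.0 / self.sampling_rate


@dataclass
class VasomotionResult:
    """Band-peak statistic of a diameter trace.

    ``peak_amplitude`` is dimensionless (fraction of the mean
    diameter); ``peak_frequency`` is the frequency (Hz) of the maximal
    in-band amplitude bin.
    """

    peak_amplitude: float
    peak_frequency: float
    band: tuple[float, float] = VASOMOTION_BAND
    mouse_id: str = ""
    fov_id: str = ""
    vessel_id: str = ""


@dataclass
class Kymograph:
    """Space-time intensity matrix from repeated line scans.

    ``intensity`` has shape (lines, pixels): each row is one scan of
    the line at successive times.
    """

    intensity: np.ndarray
    line_period: float  # s
    pixel_pitch: float  # µm
    vessel_id: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("kymograph intensity must be 2-D (lines x pixels)")
        if self.line_period <= 0 or self.pixel_pitch <= 0:
            raise ValueError("line_period and pixel_pitch must be positive")


@dataclass
class PulsatilityResult:
    """Frequency-domain pulsatility with the heart-rate exclusion rule.

    ``included`` is False exactly when the spectral heart-rate estimate
    differs from the reference by strictly more than 50 %.
    """

    auc_metric: float
    freq_peak_amplitude: float
    estimated_heart_rate: float  # bpm
    reference_heart_rate: float  # bpm
    included: bool


@dataclass
class VelocityTrace:
    """Windowed RBC velocity estimates from a kymograph (mm/s, signed)."""

    times: np.ndarray
    velocity: np.ndarray  # NaN where a window was flagged missing
    vessel_id: str = ""

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.times)))


@dataclass
class NormalROI:
    """Axis-aligned region over which the cross-vessel profile is taken.

    The vessel is assumed to run along ``segment_axis`` of the frame;
    the intensity profile is averaged along the segment and read out
    along the normal (the other axis).

    Parameters
    ----------
    segment : (int, int)
        Half-open index range along the segment axis to average over.
    normal : (int, int)
        Half-open index range along the normal axis containing the full
        vessel cross-section plus background margins.
    segment_axis : int
        0 if the vessel runs along rows, 1 if along columns.
    """

    segment: tuple[int, int]
    normal: tuple[int, int]
    segment_axis: int = 0


# ---------------------------------------------------------------------------
# image-level operations
# ---------------------------------------------------------------------------

def subtract_bleedthrough(
    signal_channel: np.ndarray, blue_channel: np.ndarray, factor: float = 1.0
) -> np.ndarray:
    """Remove dye bleed-through of a second channel from the signal channel.

    The amyloid channel (methoxy-XO4, blue) bleeds into the vascular dye
    channels; its scaled intensity is subtracted and the result clamped
    at zero.
    """
    sig = np.asarray(signal_channel, dtype=float)
    blue = np.asarray(blue_channel, dtype=float)
    if sig.shape != blue.shape:
        raise ValueError(f"shape mismatch: {sig.shape} vs {blue.shape}")
    if factor < 0:
        raise ValueError("factor must be non-negative")
    return np.clip(sig - factor * blue, 0.0, None)


def _fwhm_from_profile(profile: np.ndarray, pixel_size: float) -> float:
    """Sub-pixel full width at half maximum of a background-subtracted profile.

    Background is the median of the outer 10 % of samples on each side.
    Half-maximum crossings are located by linear interpolation; NaN is
    returned when no crossing pair brackets the peak.
    """
    p = np.asarray(profile, dtype=float)
    n = p.size
    edge = max(1, n // 10)
    background = np.median(np.concatenate([p[:edge], p[-edge:]]))
    p = p - background
    peak_idx = int(np.argmax(p))
    peak = p[peak_idx]
    if peak <= 0:
        return np.nan
    half = peak / 2.0

    left = np.nan
    for i in range(peak_idx, 0, -1):
        if p[i - 1] < half <= p[i]:
            left = (i - 1) + (half - p[i - 1]) / (p[i] - p[i - 1])
            break
    right = np.nan
    for i in range(peak_idx, n - 1):
        if p[i] >= half > p[i + 1]:
            right = i + (p[i] - half) / (p[i] - p[i + 1])
            break
    if np.isnan(left) or np.isnan(right):
        return np.nan
    return (right - left) * pixel_size


def extract_diameter_trace(
    stack: np.ndarray,
    roi: NormalROI,
    pixel_size: float,
    smoothing_sd: float = 0.0,
    frame_rate: float = 2.0,
    **trace_meta,
) -> DiameterTrace:
    """Per-frame vessel diameter from an image stack by sub-pixel FWHM.

    For each frame the intensity profile normal to the vessel is
    averaged along the ROI segment, optionally smoothed with a Gaussian
    of ``smoothing_sd`` (µm), and the diameter taken as the full width
    at half maximum of the background-subtracted profile, with the
    half-maximum crossings located by linear interpolation. Frames
    where the vessel is lost (no crossing pair) are flagged missing
    (NaN), never fabricated.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be 3-D (frames, rows, cols)")
    r0, r1 = roi.segment
    n0, n1 = roi.normal
    if roi.segment_axis == 0:
        sub = stack[:, r0:r1, n0:n1]
        profiles = sub.mean(axis=1)
    elif roi.segment_axis == 1:
        sub = stack[:, n0:n1, r0:r1]
        profiles = sub.mean(axis=2)
    else:
        raise ValueError("segment_axis must be 0 or 1")
    if profiles.shape[1] < 5:
        raise ValueError("ROI normal range too narrow to locate a vessel profile")

    if smoothing_sd > 0:
        profiles = gaussian_filter1d(profiles, smoothing_sd / pixel_size, axis=1)

    diameters = np.array([_fwhm_from_profile(p, pixel_size) for p in profiles])
    timestamps = np.arange(stack.shape[0]) / frame_rate
    return DiameterTrace(timestamps=timestamps, diameter=diameters, **trace_meta)


# ---------------------------------------------------------------------------
# spectral helpers
# ---------------------------------------------------------------------------

def _relative_trace(trace: DiameterTrace, max_missing_frac: float = 0.05) -> np.ndarray:
    """Mean-normalized, mean-subtracted diameter with missing frames interpolated.

    Raises if more than ``max_missing_frac`` of frames are missing.
    """
    d = trace.diameter.copy()
    missing = ~np.isfinite(d)
    if missing.any():
        frac = missing.mean()
        if frac > max_missing_frac:
            raise ValueError(
                f"{frac:.1%} of frames missing exceeds the {max_missing_frac:.0%} limit"
            )
        good = ~missing
        d[missing] = np.interp(
            trace.timestamps[missing], trace.timestamps[good], d[good]
        )
    mean = d.mean()
    if mean <= 0:
        raise ValueError("trace mean must be positive")
    return d / mean - 1.0


def amplitude_spectrum(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum ``2|X_k|/N`` and its frequency grid.

    No taper is applied; for a sinusoid completing an integer number of
    cycles in the window the amplitude at its bin equals the sinusoid's
    amplitude exactly.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    amp = 2.0 * np.abs(np.fft.rfft(x)) / n
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, amp


def _band_peak(
    x: np.ndarray, fs: float, band: tuple[float, float]
) -> tuple[float, float]:
    """(amplitude, frequency) of the maximal spectral bin inside ``band``."""
    freqs, amp = amplitude_spectrum(x, fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise ValueError(f"no frequency bin falls inside the band {band}")
    idx = np.flatnonzero(in_band)
    k = idx[np.argmax(amp[idx])]
    return float(amp[k]), float(freqs[k])


# ---------------------------------------------------------------------------
# vasomotion
# ---------------------------------------------------------------------------

def compute_vasomotion_peak(
    trace: DiameterTrace, band: tuple[float, float] = VASOMOTION_BAND
) -> VasomotionResult:
    """Peak one-sided spectral amplitude of the normalized diameter in ``band``.

    The trace is divided by its mean and mean-subtracted, the FFT taken
    over the full window with no taper, and the maximum of ``2|X_k|/N``
    over bins with frequency in ``[band_low, band_high]`` returned with
    its frequency. The trace must span at least one period of the band's
    lower edge; up to 5 % missing frames are linearly interpolated.
    """
    lo, hi = band
    if not (0 < lo < hi):
        raise ValueError("band must satisfy 0 < low < high")
    if trace.duration < 1.0 / lo:
        raise ValueError(
            f"trace duration {trace.duration:.1f} s cannot resolve {lo} Hz "
            f"(needs >= {1.0 / lo:.1f} s)"
        )
    x = _relative_trace(trace)
    amp, freq = _band_peak(x, trace.sampling_rate, band)
    return VasomotionResult(
        peak_amplitude=amp,
        peak_frequency=freq,
        band=band,
        mouse_id=trace.mouse_id,
        fov_id=trace.fov_id,
        vessel_id=trace.vessel_id,
    )


def average_fov_vasomotion(results: Sequence[VasomotionResult]) -> float:
    """Arithmetic mean of vasomotion peak amplitudes over one field of view.

    Averaging the 2–4 arteriolar segments within a FOV avoids
    pseudoreplication in the downstream longitudinal models. All
    results must come from the same FOV (when FOV ids are set).
    """
    if len(results) == 0:
        raise ValueError("cannot average an empty list of vasomotion results")
    fovs = {r.fov_id for r in results if r.fov_id}
    if len(fovs) > 1:
        raise ValueError(f"results span multiple FOVs: {sorted(fovs)}")
    return float(np.mean([r.peak_amplitude for r in results]))


# ---------------------------------------------------------------------------
# pulsatility
# ---------------------------------------------------------------------------

def _check_cardiac_sampling(trace: DiameterTrace) -> None:
    if trace.sampling_rate <= 2.0 * CARDIAC_BAND_HZ[0]:
        raise ValueError(
            f"sampling rate {trace.sampling_rate:.1f} Hz is below the cardiac "
            f"Nyquist requirement (> {2 * CARDIAC_BAND_HZ[0]:.0f} Hz)"
        )


def compute_pulsatility_auc(trace: DiameterTrace) -> float:
    """Time-normalized absolute AUC of the detrended normalized diameter.

    The trace is divided by its mean, linearly detrended (least
    squares), and the statistic is the mean of the absolute values —
    the time-normalized integral over the scan duration, which for
    uniform sampling reduces to the arithmetic mean and is exactly
    invariant to repeating a periodic trace. For a pure sinusoid of
    relative amplitude ``a`` over an integer number of cycles the value
    is ``2a/π``.
    """
    _check_cardiac_sampling(trace)
    x = _relative_trace(trace)
    x = _signal.detrend(x, type="linear")
    return float(np.mean(np.abs(x)))


def compute_pulsatility_freqpeak(
    trace: DiameterTrace,
    reference_heart_rate: float,
    band: tuple[float, float] = CARDIAC_BAND_HZ,
) -> PulsatilityResult:
    """Spectral pulsatility at the heart rate with the 50 % exclusion rule.

    The one-sided amplitude spectrum of the normalized, detrended trace
    is maximized over the cardiac search band (default 5–16.7 Hz,
    i.e. 300–1000 bpm); its frequency times 60 is the spectral
    heart-rate estimate. The measurement is excluded (``included``
    False) when that estimate differs from ``reference_heart_rate`` by
    strictly more than 50 % — a mismatch of exactly 50 % is kept.
    """
    if reference_heart_rate <= 0:
        raise ValueError("reference_heart_rate must be positive (bpm)")
    _check_cardiac_sampling(trace)
    x = _relative_trace(trace)
    x = _signal.detrend(x, type="linear")
    auc = float(np.mean(np.abs(x)))
    amp, freq = _band_peak(x, trace.sampling_rate, band)
    est_bpm = freq * 60.0
    mismatch = abs(est_bpm - reference_heart_rate) / reference_heart_rate
    return PulsatilityResult(
        auc_metric=auc,
        freq_peak_amplitude=amp,
        estimated_heart_rate=est_bpm,
        reference_heart_rate=reference_heart_rate,
        included=bool(mismatch <= 0.5),
    )


# ---------------------------------------------------------------------------
# RBC velocimetry
# ---------------------------------------------------------------------------

def _shear_projection_variance(window: np.ndarray, slope: float) -> float:
    """Variance of the Radon projection of ``window`` along slope ``slope``.

    The projection along the direction (1 line, ``slope`` px) is
    computed by shearing each line by ``-slope * line_index`` with
    linear interpolation and averaging over lines — the Radon
    projection at angle arctan(slope) in the slope parameterization,
    which keeps the search grid uniform in velocity rather than in
    angle. For steep slopes a streak crosses the scan line in a few
    lines, so the window is split into sub-blocks short enough that at
    least half the columns keep full support, and the per-block
    projection variances are averaged.
    """
    n_lines, n_pix = window.shape
    if slope == 0:
        block = n_lines
    else:
        block = int(n_pix / (2.0 * abs(slope)))
        block = max(4, min(block, n_lines))
    n_blocks = n_lines // block
    w = window[: n_blocks * block].reshape(n_blocks, block, n_pix)

    cols = np.arange(n_pix)[None, :] + slope * np.arange(block)[:, None]
    base = np.floor(cols).astype(int)
    frac = cols - base
    full = np.all((base >= 0) & (base + 1 <= n_pix - 1), axis=0)  # per column
    if full.sum() < 8:
        return 0.0
    idx0 = np.clip(base, 0, n_pix - 1)[:, full]
    idx1 = np.clip(base + 1, 0, n_pix - 1)[:, full]
    fr = frac[:, full]
    rows = np.arange(block)[None, :, None]
    sheared = (1 - fr) * w[:, rows[0], idx0] + fr * w[:, rows[0], idx1]
    proj = sheared.mean(axis=1)  # (n_blocks, n_full_cols)
    return float(np.var(proj, axis=1).mean())


_MIN_SLOPE = 0.05  # px/line
_MAX_SLOPE = 20.0  # px/line
_COARSE_RATIO = (_MAX_SLOPE / _MIN_SLOPE) ** (1 / 39)


def _slope_candidates() -> np.ndarray:
    mags = np.geomspace(_MIN_SLOPE, _MAX_SLOPE, 40)
    return np.concatenate([-mags[::-1], [0.0], mags])


def _estimate_window_slope(window: np.ndarray, min_contrast: float = 0.4) -> float:
    """Streak slope (px/line) of one mean-subtracted window, NaN if flat.

    A window is flat when its best-aligned projection retains less than
    ``min_contrast`` of the total window variance — alignment of real
    streaks preserves their contrast, while pure noise averages away.
    """
    total_var = float(np.var(window))
    coarse = _slope_candidates()
    var = np.array([_shear_projection_variance(window, s) for s in coarse])
    if total_var <= 0 or var.max() / total_var < min_contrast:
        return np.nan
    best = int(np.argmax(var))
    s0 = coarse[best]
    if s0 == 0.0:
        lo, hi = -_MIN_SLOPE, _MIN_SLOPE
    else:
        lo, hi = s0 / _COARSE_RATIO, s0 * _COARSE_RATIO
        if lo > hi:
            lo, hi = hi, lo
    fine = np.linspace(lo, hi, 41)
    fvar = np.array([_shear_projection_variance(window, s) for s in fine])
    if fvar.max() > var[best]:
        return float(fine[int(np.argmax(fvar))])
    return float(s0)


def estimate_rbc_velocity(
    kymo: Kymograph, window: int = 64, step: int = 32
) -> VelocityTrace:
    """Windowed RBC velocity (mm/s, signed) from line-scan streak angles.

    Successive windows of ``window`` lines (advanced by ``step``) are
    mean-subtracted and the streak angle estimated as the
    Radon-projection angle maximizing projection variance; the velocity
    is ``pixel_pitch / line_period`` times the tangent of that angle
    (i.e. the streak slope in px/line), signed by the angle's side.
    Windows without streak contrast are flagged missing (NaN).
    """
    if window < 32:
        raise ValueError("window must be at least 32 lines")
    if step < 1:
        raise ValueError("step must be positive")
    img = kymo.intensity
    n_lines = img.shape[0]
    if n_lines < window:
        raise ValueError("kymograph shorter than one window")
    starts = np.arange(0, n_lines - window + 1, step)
    times = np.empty(starts.size)
    vel = np.empty(starts.size)
    # px/line -> mm/s: (µm/px) / (s/line) * 1e-3
    scale = kymo.pixel_pitch / kymo.line_period * 1e-3
    for i, s in enumerate(starts):
        w = img[s : s + window].astype(float)
        w = w - w.mean()
        slope = _estimate_window_slope(w)
        vel[i] = slope * scale
        times[i] = (s + window / 2.0) * kymo.line_period
    return VelocityTrace(times=times, velocity=vel, vessel_id=kymo.vessel_id)


def estimate_heart_rate(
    velocity: VelocityTrace,
    band: tuple[float, float] = CARDIAC_BAND_HZ,
    min_peak_ratio: float = 3.0,
) -> float | None:
    """Heart rate (bpm) from the spectral peak of an RBC velocity trace.

    Returns the frequency of the maximal one-sided spectral amplitude
    in the cardiac band times 60, or None when no peak rises at least
    ``min_peak_ratio`` above the median in-band amplitude (no cardiac
    modulation detectable above the noise floor).
    """
    t, v = velocity.times, velocity.velocity
    if t[-1] - t[0] < 1.0:
        raise ValueError("velocity trace must span at least 1 s")
    fs = velocity.sampling_rate
    if fs <= 2.0 * band[0]:
        raise ValueError("velocity trace sampling rate below cardiac Nyquist")
    good = np.isfinite(v)
    x = v.copy()
    if not good.all():
        x[~good] = np.interp(t[~good], t[good], v[good])
    x = x - x.mean()
    freqs, amp = amplitude_spectrum(x, fs)
    in_band = (freqs >= band[0]) & (freqs <= min(band[1], fs / 2))
    if not in_band.any():
        return None
    amps = amp[in_band]
    med = np.median(amps)
    if med <= 0 or amps.max() / med < min_peak_ratio:
        return None
    return float(freqs[in_band][np.argmax(amps)] * 60.0)


# ---------------------------------------------------------------------------
# amyloid coverage
# ---------------------------------------------------------------------------

def compute_caa_coverage(
    wall_mask: np.ndarray, amyloid_channel: np.ndarray, threshold: float
) -> float:
    """Percent of vessel-wall pixels whose amyloid intensity reaches ``threshold``.

    A fixed-threshold pixel fraction on a user-supplied wall mask:
    100 × (wall pixels with amyloid ≥ threshold) / (wall pixels).
    """
    mask = np.asarray(wall_mask, dtype=bool)
    amyloid = np.asarray(amyloid_channel, dtype=float)
    if mask.shape != amyloid.shape:
        raise ValueError(f"shape mismatch: {mask.shape} vs {amyloid.shape}")
    n_wall = int(mask.sum())
    if n_wall == 0:
        raise ValueError("wall mask is empty")
    return 100.0 * float((amyloid[mask] >= threshold).sum()) / n_wall
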