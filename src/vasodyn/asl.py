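"""pCASL cerebral blood flow and cerebrovascular reactivity quantification.

Quantifies CBF from pseudo-continuous arterial spin labelling (pCASL)
label/control pairs with the single-compartment Buxton perfusion model,

    CBF = λ · ΔM · e^(PLD/T1b) / (2 · α · T1t · M0t · (1 − e^(−τ/T1t))),

where λ is the blood–brain partition coefficient (mL/g), ΔM the
control − label signal difference, T1b and T1t the longitudinal
relaxation times of blood and tissue, α the labelling efficiency, PLD
the post-labelling delay, τ the labelling duration and M0t the
equilibrium tissue magnetization. With λ in mL/g and T1t in seconds
the expression yields mL/g/s; a factor of 6000 converts to the
conventional mL/100 g/min.

CBF time profiles extracted over a region of interest are smoothed by
a two-step rule — values beyond 2 SD of the profile are removed, then a
centred three-point moving average is applied over the remaining
points — and cerebrovascular reactivity (CVR) is the relative CBF
increase during a hypercapnic stimulus block over the baseline block
(defaults: baseline minute 1–5, stimulus minute 6–10).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ASLParams",
    "ASLSeries",
    "CBFProfile",
    "BASELINE_WINDOW",
    "STIMULUS_WINDOW",
    "pairwise_delta",
    "buxton_cbf",
    "buxton_delta_m",
    "roi_timeprofile",
    "smooth_profile",
    "compute_cvr_profile",
    "compute_cvr",
]

#: Default baseline block, "minute 1-5" as the half-open interval [60 s, 300 s).
BASELINE_WINDOW = (60.0, 300.0)
#: Default stimulus block, "minute 6-10" as [300 s, 600 s).
STIMULUS_WINDOW = (300.0, 600.0)

#: mL/g/s -> mL/100 g/min
_UNIT_FACTOR = 6000.0


@dataclass(frozen=True)
class ASLParams:
    """Quantification constants of the Buxton perfusion model.

    All times in milliseconds. Defaults carry the study constants
    λ = 0.9 mL/g, T1b = 2430 ms (blood T1 at 9.4 T) and α = 0.80;
    T1t, PLD and τ are sequence-specific and must be supplied from the
    acquisition configuration.
    """

    lambda_bbpc: float = 0.9  # mL/g
    t1b: float = 2430.0  # ms
    t1t: float = 1900.0  # ms
    alpha: float = 0.80
    pld: float = 300.0  # ms
    tau: float = 3000.0  # ms

    def __post_init__(self) -> None:
        for name in ("lambda_bbpc", "t1b", "t1t", "alpha", "pld", "tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ASL parameter {name} must be strictly positive")
        if self.alpha > 1.0:
            raise ValueError("labelling efficiency alpha must lie in (0, 1]")


@dataclass
class ASLSeries:
    """Alternating label/control volumes with an M0 reference.

    ``volumes`` is a 4-D array in acquisition order (time first);
    ``label_order`` states which of each consecutive pair comes first
    and is read from metadata — when absent, even-index = label is
    assumed with a warning.
    """

    volumes: np.ndarray
    m0t: np.ndarray
    params: ASLParams
    pair_times: np.ndarray  # s from series start, one per pair
    label_order: str | None = "label_first"  # or "control_first"

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.m0t = np.asarray(self.m0t, dtype=float)
        self.pair_times = np.asarray(self.pair_times, dtype=float)
        if self.volumes.ndim != 4:
            raise ValueError("volumes must be 4-D (time, x, y, z)")
        if self.volumes.shape[0] % 2 != 0:
            raise ValueError("series must contain an even number of volumes")
        if self.m0t.shape != self.volumes.shape[1:]:
            raise ValueError("M0t must match the spatial shape of the volumes")
        if self.pair_times.size != self.volumes.shape[0] // 2:
            raise ValueError("need one pair_time per label/control pair")
        if np.any(np.diff(self.pair_times) <= 0):
            raise ValueError("pair_times must be increasing")

    @property
    def n_pairs(self) -> int:
        return self.volumes.shape[0] // 2


@dataclass
class CBFProfile:
    """A per-ROI CBF time course with baseline and stimulus block windows.

    ``missing_mask`` flags time points excluded by cleaning (True =
    missing); ``cbf`` keeps NaN at those points.
    """

    times: np.ndarray
    cbf: np.ndarray  # mL/100 g/min
    roi_id: str = ""
    baseline_window: tuple[float, float] = BASELINE_WINDOW
    stimulus_window: tuple[float, float] = STIMULUS_WINDOW
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cbf = np.asarray(self.cbf, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.cbf)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if not (self.times.shape == self.cbf.shape == self.missing_mask.shape):
            raise ValueError("times, cbf and missing_mask must share shape")

    def _window_values(self, window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        sel = (self.times >= lo) & (self.times < hi) & ~self.missing_mask
        return self.cbf[sel]


def pairwise_delta(series: ASLSeries) -> np.ndarray:
    """Per-pair perfusion-weighted difference volumes, ΔM = control − label.

    Returns an array of shape (n_pairs, *spatial). The label/control
    order is taken from the series metadata; a missing order falls back
    to even-index = label with a warning.
    """
    order = series.label_order
    if order is None:
        warnings.warn(
            "label_order missing from metadata; assuming even-index volumes are labels",
            stacklevel=2,
        )
        order = "label_first"
    if order not in ("label_first", "control_first"):
        raise ValueError(f"unknown label_order {order!r}")
    first = series.volumes[0::2]
    second = series.volumes[1::2]
    if order == "label_first":
        return second - first
    return first - second


def buxton_cbf(
    delta_m: np.ndarray,
    m0t: np.ndarray,
    params: ASLParams,
    m0_threshold: float = 0.0,
) -> np.ndarray:
    """CBF (mL/100 g/min) from ΔM and M0t via the Buxton model.

    Voxels with ``m0t <= m0_threshold`` are masked out (NaN), never
    divided. Scalar inputs return a scalar array.
    """
    delta_m = np.asarray(delta_m, dtype=float)
    m0t = np.asarray(m0t, dtype=float)
    p = params
    t1t_s = p.t1t / 1000.0
    numer = p.lambda_bbpc * delta_m * np.exp(p.pld / p.t1b)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = 2.0 * p.alpha * t1t_s * m0t * (1.0 - np.exp(-p.tau / p.t1t))
        cbf = _UNIT_FACTOR * numer / denom
    return np.where(m0t > m0_threshold, cbf, np.nan)


def buxton_delta_m(cbf: np.ndarray, m0t: np.ndarray, params: ASLParams) -> np.ndarray:
    """Forward Buxton model: the ΔM that quantifies to ``cbf`` (mL/100 g/min).

    Exact algebraic inverse of :func:`buxton_cbf`; used by the
    synthetic generator so that noise-free series round-trip to the
    true CBF.
    """
    cbf = np.asarray(cbf, dtype=float)
    m0t = np.asarray(m0t, dtype=float)
    p = params
    t1t_s = p.t1t / 1000.0
    denom = 2.0 * p.alpha * t1t_s * m0t * (1.0 - np.exp(-p.tau / p.t1t))
    return cbf * denom / (_UNIT_FACTOR * p.lambda_bbpc * np.exp(p.pld / p.t1b))


def roi_timeprofile(
    cbf_maps: np.ndarray,
    roi_mask: np.ndarray,
    pair_times: np.ndarray,
    roi_id: str = "",
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    stimulus_window: tuple[float, float] = STIMULUS_WINDOW,
) -> CBFProfile:
    """Mean CBF over an ROI per time point.

    ``cbf_maps`` has shape (n_pairs, *spatial); masked-out (NaN) voxels
    are excluded from each mean. A time point with no finite voxel in
    the ROI is flagged missing.
    """
    cbf_maps = np.asarray(cbf_maps, dtype=float)
    mask = np.asarray(roi_mask, dtype=bool)
    if mask.shape != cbf_maps.shape[1:]:
        raise ValueError("ROI mask must match the spatial shape of the CBF maps")
    if not mask.any():
        raise ValueError("ROI mask is empty")
    vals = cbf_maps[:, mask]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        profile = np.nanmean(vals, axis=1)
    return CBFProfile(
        times=np.asarray(pair_times, dtype=float),
        cbf=profile,
        roi_id=roi_id,
        baseline_window=baseline_window,
        stimulus_window=stimulus_window,
    )


def smooth_profile(profile: CBFProfile, sd_factor: float = 2.0) -> CBFProfile:
    """Outlier removal and three-point moving average of a CBF profile.

    A single pass marks points with ``|value − mean| > sd_factor × SD``
    missing, with the mean and SD computed once from all non-missing
    points; then a centred three-point moving average is applied,
    shrinking to the available neighbours at the edges and across
    missing points. Removed points stay missing (NaN), not
    interpolated. The operation is idempotent on profiles with no
    point beyond the SD bound.
    """
    if profile.times.size < 3:
        raise ValueError("profile needs at least 3 time points to smooth")
    cbf = profile.cbf.copy()
    missing = profile.missing_mask.copy()
    good = ~missing
    vals = cbf[good]
    mean, sd = vals.mean(), vals.std(ddof=0)
    outlier = good & (np.abs(cbf - mean) > sd_factor * sd)
    missing |= outlier
    cbf[missing] = np.nan
    if missing.all():
        raise ValueError("all points removed by the outlier rule")

    w = (~missing).astype(float)
    v = np.where(missing, 0.0, cbf)
    kernel = np.ones(3)
    num = np.convolve(v, kernel, mode="same")
    den = np.convolve(w, kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        smoothed = num / den
    smoothed[missing] = np.nan
    return CBFProfile(
        times=profile.times,
        cbf=smoothed,
        roi_id=profile.roi_id,
        baseline_window=profile.baseline_window,
        stimulus_window=profile.stimulus_window,
        missing_mask=missing,
    )


def compute_cvr_profile(profile: CBFProfile) -> CBFProfile:
    """CBF profile normalized to its baseline-window mean (dimensionless).

    Every value is divided by the mean CBF over the baseline window;
    the baseline block then reads ~1 and the stimulus block 1 + CVR.
    """
    base = profile._window_values(profile.baseline_window)
    if base.size == 0:
        raise ValueError("baseline window contains no usable points")
    base_mean = base.mean()
    if base_mean <= 0:
        raise ValueError("baseline mean must be positive to normalize")
    return CBFProfile(
        times=profile.times,
        cbf=profile.cbf / base_mean,
        roi_id=profile.roi_id,
        baseline_window=profile.baseline_window,
        stimulus_window=profile.stimulus_window,
        missing_mask=profile.missing_mask.copy(),
    )


def compute_cvr(profile: CBFProfile) -> float:
    """Block-averaged cerebrovascular reactivity in percent.

    100 × (mean CBF over the stimulus window / mean CBF over the
    baseline window − 1).
    """
    base = profile._window_values(profile.baseline_window)
    stim = profile._window_values(profile.stimulus_window)
    if base.size == 0 or stim.size == 0:
        raise ValueError("baseline or stimulus window empty after cleaning")
    base_mean = base.mean()
    if base_mean <= 0:
        raise ValueError("baseline mean must be positive")
    return 100.0 * (stim.mean() / base_mean - 1.0)
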