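"""Per-cell intensity traces and normalized recruitment curves.

Pipeline order (fixed): DoG filter → extract (medMax + nucleus mean) →
bleaching correction → optional 3-point smoothing → RFI / ΔI → FMR.

Quantities
----------
medMax
    Median of the 20 brightest pixels in the damage ROI — a noise-robust
    peak statistic.  The ROI deliberately covers some undamaged area (to
    tolerate cell movement), so a plain mean would dilute the signal,
    while the single maximum is too noisy at low excitation power.
corrected
    medMax divided by the whole-nucleus mean at the same frame, which
    cancels global photobleaching.
RFI
    corrected / I0 with I0 the mean corrected intensity over all
    pre-damage frames: the fold change over the pre-damage level.
ΔI
    corrected − I0, the background-subtracted alternative.
FMR
    (RFI − 1) / (max RFI − 1): kinetics rescaled so the pre-damage level
    is 0 and the curve maximum is 1, independent of amplitude.
t50
    Time (s from damage) of the first post-damage frame with FMR ≥ 0.5.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .core import AcquisitionMeta, NucleusMask, RectROI, TimeLapseMovie
from .filtering import DoGParams, dog_filter


class NoRecruitmentError(ValueError):
    """Raised when a curve shows no recruitment (max RFI ≈ pre-damage level)."""


@dataclasses.dataclass
class IntensityTrace:
    """Raw per-frame statistics for one cell/channel."""

    time_s: np.ndarray
    raw_medmax: np.ndarray
    nucleus_mean: np.ndarray
    meta: AcquisitionMeta
    channel_label: str = ""
    corrected: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.time_s)
        if len(self.raw_medmax) != n or len(self.nucleus_mean) != n:
            raise ValueError("trace arrays must share length")


@dataclasses.dataclass
class RecruitmentCurve:
    """Normalized series and scalar kinetics for one cell/channel."""

    rfi: np.ndarray
    delta: np.ndarray
    fmr: np.ndarray | None
    i0: float
    max_rfi: float
    t_max: float
    t50: float | None
    final_fmr: float | None
    flags: tuple[str, ...] = ()


def med_max(values, n: int = 20) -> float:
    """Median of the ``n`` largest values.

    With fewer than ``n`` values available, the median of all of them is
    returned with a warning.  Medians of even counts are the midpoint of
    the two central order statistics.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("med_max of empty input")
    if values.size < n:
        warnings.warn(
            f"med_max: only {values.size} values for top-{n}; using all",
            stacklevel=2,
        )
        top = values
    else:
        top = np.partition(values, values.size - n)[values.size - n :]
    return float(np.median(top))


def extract_trace(
    movie: TimeLapseMovie,
    damage: RectROI,
    nucleus: NucleusMask,
    use_dog: bool = True,
    dog: DoGParams | None = None,
    medmax_n: int = 20,
) -> IntensityTrace:
    """Per-frame damage-ROI medMax and whole-nucleus mean.

    Frames are DoG-filtered first unless ``use_dog`` is false (the
    nucleus mean is then taken on the same filtered frame, keeping one
    consistent intensity scale through the bleaching correction).
    """
    damage.validate_in(movie.frame_shape)
    if nucleus.mask.shape != movie.frame_shape:
        raise ValueError("nucleus mask shape does not match frames")
    nucleus.check_contains(damage)
    if use_dog and dog is None:
        dog = DoGParams(pixel_size=movie.meta.pixel_size)
    T = movie.n_frames
    raw_medmax = np.empty(T)
    nucleus_mean = np.empty(T)
    sy, sx = damage.slices
    for i in range(T):
        frame = dog_filter(movie.frames[i], dog) if use_dog else movie.frames[i]
        raw_medmax[i] = med_max(frame[sy, sx], n=medmax_n)
        nucleus_mean[i] = float(frame[nucleus.mask].mean())
    return IntensityTrace(
        time_s=movie.times,
        raw_medmax=raw_medmax,
        nucleus_mean=nucleus_mean,
        meta=movie.meta,
        channel_label=movie.channel_label,
    )


def bleach_correct(trace: IntensityTrace) -> np.ndarray:
    """Divide the damage signal by the nucleus mean at each frame.

    Global photobleaching multiplies both series by the same factor, so
    the ratio is bleaching-free.  A non-positive nucleus mean signals an
    empty mask or over-filtering and is an error.
    """
    if np.any(trace.nucleus_mean <= 0):
        raise ValueError(
            "non-positive nucleus mean: empty mask or over-filtered frames"
        )
    corrected = trace.raw_medmax / trace.nucleus_mean
    trace.corrected = corrected
    return corrected


def smooth3(series) -> np.ndarray:
    """3-point moving average: each point averaged with its two neighbours.

    Endpoints use the mean of the available two terms.  Disabled in the
    fast-imaging mode, where temporal resolution matters more than noise.
    """
    s = np.asarray(series, dtype=np.float64)
    if s.size <= 1:
        return s.copy()
    out = np.empty_like(s)
    out[1:-1] = (s[:-2] + s[1:-1] + s[2:]) / 3.0
    out[0] = (s[0] + s[1]) / 2.0
    out[-1] = (s[-2] + s[-1]) / 2.0
    return out


def _i0(series: np.ndarray, meta: AcquisitionMeta) -> float:
    return float(series[: meta.damage_frame].mean())


def rfi(corrected, meta: AcquisitionMeta) -> tuple[np.ndarray, float]:
    """Relative fluorescence intensity I_t / I_0 and the I_0 used.

    I_0 is the mean corrected intensity over all pre-damage frames; the
    pre-damage mean of the returned series is exactly 1.
    """
    corrected = np.asarray(corrected, dtype=np.float64)
    i0 = _i0(corrected, meta)
    if i0 <= 0:
        raise ValueError("pre-damage intensity I0 must be > 0")
    return corrected / i0, i0


def delta_intensity(corrected, meta: AcquisitionMeta) -> np.ndarray:
    """Background-subtracted intensity I_t − I_0."""
    corrected = np.asarray(corrected, dtype=np.float64)
    return corrected - _i0(corrected, meta)


def fmr(rfi_series, meta: AcquisitionMeta, eps: float = 1e-6) -> np.ndarray:
    """Fraction of maximum recruitment: RFI rescaled to [0, 1].

    0 is the pre-damage RFI level (1 by construction) and 1 the maximum
    post-damage RFI.  Noisy pre-damage frames may dip below 0; they are
    reported as-is.  Raises :class:`NoRecruitmentError` when the curve
    never rises above the pre-damage level.
    """
    r = np.asarray(rfi_series, dtype=np.float64)
    max_rfi = float(r[meta.damage_frame :].max())
    if max_rfi <= 1.0 + eps:
        raise NoRecruitmentError("no recruitment detected (max RFI <= 1)")
    return (r - 1.0) / (max_rfi - 1.0)


def time_to_half_max(
    fmr_series, meta: AcquisitionMeta, interpolate: bool = False
) -> float | None:
    """t50: time from damage of the first post-damage frame with FMR ≥ 0.5.

    ``interpolate=True`` instead interpolates linearly between the
    bracketing frames.  ``None`` when 0.5 is never reached.
    """
    f = np.asarray(fmr_series, dtype=np.float64)
    post = f[meta.damage_frame :]
    above = np.nonzero(post >= 0.5)[0]
    if above.size == 0:
        return None
    k = int(above[0])
    t = k * meta.frame_interval
    if interpolate and k > 0:
        f0, f1 = post[k - 1], post[k]
        t = (k - 1 + (0.5 - f0) / (f1 - f0)) * meta.frame_interval
    return float(t)


def curve_stats(
    rfi_series, fmr_series, meta: AcquisitionMeta, interpolate_t50: bool = False
) -> tuple[float, float, float | None, float | None]:
    """(max RFI, its time, t50, final FMR); ties at the maximum take the
    earliest frame."""
    r = np.asarray(rfi_series, dtype=np.float64)
    post = r[meta.damage_frame :]
    k = int(np.argmax(post))  # argmax returns the earliest tie
    max_rfi = float(post[k])
    t_max = float(k * meta.frame_interval)
    t50 = None
    final = None
    if fmr_series is not None:
        t50 = time_to_half_max(fmr_series, meta, interpolate=interpolate_t50)
        final = float(np.asarray(fmr_series)[-1])
    return max_rfi, t_max, t50, final


def compute_curve(
    trace: IntensityTrace,
    smooth: bool = True,
    interpolate_t50: bool = False,
    eps: float = 1e-6,
) -> RecruitmentCurve:
    """Full normalization of one trace into a :class:`RecruitmentCurve`.

    Runs bleaching correction, optional smoothing, RFI/ΔI and FMR; a
    curve without detectable recruitment is flagged ``no_recruitment``
    and carries ``fmr = t50 = None``.
    """
    corrected = bleach_correct(trace)
    series = smooth3(corrected) if smooth else corrected
    rfi_series, i0 = rfi(series, trace.meta)
    delta = delta_intensity(series, trace.meta)
    flags: tuple[str, ...] = ()
    try:
        fmr_series: np.ndarray | None = fmr(rfi_series, trace.meta, eps=eps)
    except NoRecruitmentError:
        fmr_series = None
        flags = ("no_recruitment",)
    max_rfi, t_max, t50, final = curve_stats(
        rfi_series, fmr_series, trace.meta, interpolate_t50=interpolate_t50
    )
    return RecruitmentCurve(
        rfi=rfi_series,
        delta=delta,
        fmr=fmr_series,
        i0=i0,
        max_rfi=max_rfi,
        t_max=t_max,
        t50=t50,
        final_fmr=final,
        flags=flags,
    )
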