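"""Ciliary beat-frequency estimation from time-lapse stacks.

A kymograph resamples a time-lapse stack along a fixed line ROI: one
column per frame, one row per position along the line.  The beat trace
is the spatial mean of the kymograph; its periodicity is quantified two
independent ways — by counting prominent peaks (each peak one beat) and
by the dominant component of the discrete Fourier spectrum.  The two
estimates cross-check each other: a disagreement beyond a tolerance sets
a quality flag on the estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as scipy_signal
from skimage.measure import profile_line

from .errors import InvalidParameterError

__all__ = [
    "ImageStack",
    "LineROI",
    "Kymograph",
    "BeatEstimate",
    "extract_kymograph",
    "peak_frequency",
    "spectral_frequency",
    "estimate_beat",
    "summarize_recording",
]

#: default peak prominence as a fraction of the trace range
DEFAULT_MIN_PROMINENCE = 0.2

#: minimum peak separation in seconds is 0.3 / f_max, with f_max the highest
#: admissible beat frequency (Nyquist by default)
PEAK_SEPARATION_FACTOR = 0.3

#: |peak - spectral| beyond this (Hz) sets the disagreement flag
DEFAULT_AGREEMENT_TOL_HZ = 0.5

#: kymograph band width (pixels perpendicular to the ROI line)
DEFAULT_LINEWIDTH = 3


@dataclass
class ImageStack:
    """T x H x W intensity stack with acquisition metadata."""

    frames: np.ndarray
    fps: float
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise InvalidParameterError("stack must be T x H x W with T >= 2")
        if not np.all(np.isfinite(self.frames)):
            raise InvalidParameterError("stack intensities must be finite")
        if self.fps <= 0:
            raise InvalidParameterError("fps must be positive")
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass
class LineROI:
    """Line ROI in pixel coordinates (x across, y down)."""

    x0: float
    y0: float
    x1: float
    y1: float
    roi_id: str = "roi0"


@dataclass
class Kymograph:
    array: np.ndarray  # space x time
    fps: float
    roi: LineROI

    @property
    def n_frames(self) -> int:
        return int(self.array.shape[1])

    def trace(self) -> np.ndarray:
        """Beat trace: mean intensity over the spatial axis, one value per frame."""
        return self.array.mean(axis=0)


@dataclass
class BeatEstimate:
    freq_peaks_hz: float
    freq_spectral_hz: float
    n_peaks: int
    roi_id: str
    flags: set[str] = field(default_factory=set)
    image_id: str = ""
    animal_id: str = ""


def extract_kymograph(
    stack: ImageStack, roi: LineROI, linewidth: int = DEFAULT_LINEWIDTH, order: int = 1
) -> Kymograph:
    """Sample the stack along ``roi`` in every frame.

    Intensities are linearly interpolated (``order=1``; ``order=0`` for
    nearest-pixel) and averaged over a band of ``linewidth`` pixels
    perpendicular to the line.  Column t of the result is frame t.
    """
    t, h, w = stack.frames.shape
    for x, y in ((roi.x0, roi.y0), (roi.x1, roi.y1)):
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            raise InvalidParameterError(
                f"ROI endpoint ({x}, {y}) outside {w}x{h} frame bounds"
            )
    # profile_line takes (row, col) = (y, x) endpoints
    src, dst = (roi.y0, roi.x0), (roi.y1, roi.x1)
    columns = [
        profile_line(frame, src, dst, linewidth=linewidth, order=order,
                     mode="constant", reduce_func=np.mean)
        for frame in stack.frames
    ]
    return Kymograph(array=np.stack(columns, axis=1), fps=stack.fps, roi=roi)


def peak_frequency(
    trace: np.ndarray,
    fps: float,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    max_freq_hz: float | None = None,
) -> tuple[float, int, set[str]]:
    """Beat frequency by peak counting: ``freq = n_peaks / duration``.

    Peaks must exceed ``min_prominence`` times the trace range and be at
    least ``0.3 / max_freq_hz`` seconds apart (``max_freq_hz`` defaults
    to Nyquist).  A flat trace yields 0 Hz with a ``low_snr`` flag.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or trace.size < 3:
        raise InvalidParameterError("trace must be 1-D with >= 3 samples")
    if fps <= 0:
        raise InvalidParameterError("fps must be positive")
    rng = float(np.ptp(trace))
    if rng <= 0 or not math.isfinite(rng):
        return 0.0, 0, {"low_snr"}
    if max_freq_hz is None:
        max_freq_hz = fps / 2.0
    distance = max(1, int(round(PEAK_SEPARATION_FACTOR / max_freq_hz * fps)))
    peaks, _ = scipy_signal.find_peaks(
        trace, prominence=min_prominence * rng, distance=distance
    )
    duration = trace.size / fps
    n = int(peaks.size)
    flags: set[str] = set() if n > 0 else {"low_snr"}
    return n / duration, n, flags


def spectral_frequency(trace: np.ndarray, fps: float) -> float:
    """Frequency of the dominant non-zero spectral component.

    The trace is mean-detrended; the dominant rFFT bin is refined by
    parabolic interpolation of the log-magnitude of its neighbours, so
    the estimate is not limited to the bin grid.  Returns NaN for a flat
    trace.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or trace.size < 3:
        raise InvalidParameterError("trace must be 1-D with >= 3 samples")
    if fps <= 0:
        raise InvalidParameterError("fps must be positive")
    if np.ptp(trace) <= 0:
        return float("nan")
    x = trace - trace.mean()
    mag = np.abs(np.fft.rfft(x))
    if mag.size < 2:
        return float("nan")
    k = int(np.argmax(mag[1:])) + 1
    # parabolic refinement using log magnitudes of the three bins around k
    if 1 <= k < mag.size - 1 and mag[k - 1] > 0 and mag[k + 1] > 0:
        la, lb, lc = np.log(mag[k - 1]), np.log(mag[k]), np.log(mag[k + 1])
        denom = la - 2.0 * lb + lc
        delta = 0.5 * (la - lc) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return (k + delta) * fps / trace.size


def estimate_beat(
    kymo: Kymograph,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    agreement_tol_hz: float = DEFAULT_AGREEMENT_TOL_HZ,
    image_id: str = "",
    animal_id: str = "",
) -> BeatEstimate:
    """Run both estimators on a kymograph's beat trace and cross-check them."""
    trace = kymo.trace()
    f_peaks, n_peaks, flags = peak_frequency(trace, kymo.fps, min_prominence)
    f_spec = spectral_frequency(trace, kymo.fps)
    if math.isnan(f_spec):
        flags = set(flags) | {"low_snr"}
    elif abs(f_peaks - f_spec) > agreement_tol_hz:
        flags = set(flags) | {"disagreement"}
    return BeatEstimate(
        freq_peaks_hz=f_peaks,
        freq_spectral_hz=f_spec,
        n_peaks=n_peaks,
        roi_id=kymo.roi.roi_id,
        flags=set(flags),
        image_id=image_id,
        animal_id=animal_id,
    )


def summarize_recording(estimates: list[BeatEstimate], use: str = "peaks"):
    """Hierarchical beat-frequency summary: ROI -> image -> animal.

    ROIs are averaged within each image, image means within each animal;
    the per-animal s.e.m. is computed across image means.  Returns a
    pandas DataFrame indexed by animal with columns ``mean_hz``,
    ``sem_hz``, ``n_images`` and ``n_rois``.
    """
    import pandas as pd

    if not estimates:
        raise InvalidParameterError("no beat estimates to summarise")
    attr = {"peaks": "freq_peaks_hz", "spectral": "freq_spectral_hz"}.get(use)
    if attr is None:
        raise InvalidParameterError("use must be 'peaks' or 'spectral'")
    rows = [
        {
            "animal_id": e.animal_id or "animal0",
            "image_id": e.image_id or "image0",
            "freq_hz": getattr(e, attr),
        }
        for e in estimates
    ]
    df = pd.DataFrame(rows)
    image_means = (
        df.groupby(["animal_id", "image_id"])["freq_hz"].mean().rename("image_mean")
    )
    per_animal = image_means.groupby("animal_id").agg(["mean", "sem", "count"])
    per_animal.columns = ["mean_hz", "sem_hz", "n_images"]
    per_animal["sem_hz"] = per_animal["sem_hz"].fillna(0.0)
    per_animal["n_rois"] = df.groupby("animal_id")["freq_hz"].count()
    return per_animal
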