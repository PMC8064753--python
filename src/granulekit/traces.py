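"""Time-series analyses: dF/F calcium traces, dose-response endpoints,
nascent-translation foci time courses, and fixed-ROI reporter intensities.

The calcium convention follows GCaMP practice: the baseline F0 is the mean
of the frames acquired before the stimulus (four by default, matching
30-s-interval acquisitions where treatment is added after four frames) and
traces are reported as (F(t) - F0) / F0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import NamedTuple, Sequence

import numpy as np

from .image import ImageField, as_stack

__all__ = [
    "CalciumTrace",
    "FociCounts",
    "EndpointChange",
    "delta_f_over_f",
    "endpoint_change",
    "foci_timecourse_normalize",
    "reporter_intensity",
]


@dataclass
class CalciumTrace:
    """ROI-averaged indicator intensity over time.

    Parameters
    ----------
    values : ndarray
        Ordered raw intensities F(t), strictly positive.
    frame_interval : float
        Seconds between frames (30 for the emulated acquisitions).
    stimulus_frame : int
        Index of the frame at which the stimulus was added.
    roi_area : float or None
        ROI area in um^2, metadata only.
    """

    values: np.ndarray
    frame_interval: float = 30.0
    stimulus_frame: int = 4
    roi_area: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("trace values must be a non-empty 1D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")

    @property
    def n_frames(self) -> int:
        return int(self.values.size)

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class FociCounts:
    """Per-movie ordered counts of cells showing nascent-translation foci."""

    movies: list[np.ndarray] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        cleaned = []
        for m in self.movies:
            arr = np.asarray(m)
            if arr.ndim != 1 or arr.size == 0:
                raise ValueError("each movie must be a non-empty 1D count series")
            if np.any(arr < 0) or not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValueError("foci counts must be non-negative integers")
            cleaned.append(arr.astype(float))
        self.movies = cleaned


class EndpointChange(NamedTuple):
    """Dose-response endpoint on the t0-normalized scale."""

    difference: float  # normalized-scale difference, f_end/f_start - 1
    normalized: float  # f_end / f_start (t0 set to 1)
    difference_raw: float  # f_end - f_start on the raw scale


class FociSummary(NamedTuple):
    normalized: list[np.ndarray]  # per retained movie, max-normalized
    mean: np.ndarray  # across-movie mean per frame
    sem: np.ndarray  # across-movie SEM per frame (n-1 denominator)
    n_movies: int


def delta_f_over_f(trace: CalciumTrace, n_baseline: int = 4) -> np.ndarray:
    """(F(t) - F0) / F0 with F0 the mean of the first ``n_baseline`` frames.

    The mean of the first ``n_baseline`` output values is exactly 0.
    """
    if n_baseline < 1:
        raise ValueError("n_baseline must be >= 1")
    if trace.n_frames < n_baseline:
        raise ValueError(
            f"trace has {trace.n_frames} frames, fewer than n_baseline={n_baseline}"
        )
    if trace.stimulus_frame < n_baseline:
        raise ValueError(
            "baseline frames must precede the stimulus "
            f"(stimulus_frame={trace.stimulus_frame} < n_baseline={n_baseline})"
        )
    f0 = float(np.mean(trace.values[:n_baseline]))
    if f0 <= 0:
        raise ValueError(f"baseline F0 must be > 0, got {f0}")
    return (trace.values - f0) / f0


def endpoint_change(f_t0: float, f_t30: float) -> EndpointChange:
    """Endpoint change between two timepoints, t0 normalized to 1.

    Returns the difference on the normalized scale (``f_t30/f_t0 - 1``),
    the normalized endpoint ``f_t30/f_t0``, and the raw difference.
    """
    if f_t0 <= 0:
        raise ValueError(f"f_t0 must be > 0, got {f_t0}")
    normalized = f_t30 / f_t0
    return EndpointChange(normalized - 1.0, normalized, f_t30 - f_t0)


def foci_timecourse_normalize(counts: FociCounts) -> FociSummary:
    """Normalize each movie's foci counts to its own maximum.

    Each retained movie maps its maximum to exactly 1; movies with all-zero
    counts carry no signal and are excluded with a warning.  Across-movie
    mean and SEM (sample SD / sqrt(n)) are computed per frame.
    """
    retained: list[np.ndarray] = []
    for i, movie in enumerate(counts.movies):
        peak = movie.max()
        if peak == 0:
            warnings.warn(f"movie {i} has all-zero foci counts; excluded", stacklevel=2)
            continue
        retained.append(movie / peak)
    if not retained:
        raise ValueError("no movie with nonzero foci counts")
    lengths = {m.size for m in retained}
    if len(lengths) != 1:
        raise ValueError(f"movies have unequal lengths: {sorted(lengths)}")
    stack = np.vstack(retained)
    mean = stack.mean(axis=0)
    n = stack.shape[0]
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(stack.shape[1])
    return FociSummary(retained, mean, sem, n)


def reporter_intensity(
    field: ImageField | Sequence[ImageField] | np.ndarray,
    rois: Sequence[tuple[int, int, int, int]],
) -> np.ndarray:
    """Mean intensity in fixed-area boxes, on a max projection for stacks.

    ``rois`` are ``(row0, col0, height, width)`` boxes; each must lie fully
    inside the field.  When a stack (list of fields or 3D array) is given,
    a per-pixel maximum-intensity projection is computed first.
    """
    if isinstance(field, ImageField):
        img = np.asarray(field.data, dtype=float)
    else:
        img = as_stack(field).max(axis=0)
    h, w = img.shape
    means = []
    for row0, col0, height, width in rois:
        if row0 < 0 or col0 < 0 or height <= 0 or width <= 0 or row0 + height > h or col0 + width > w:
            raise ValueError(
                f"ROI ({row0},{col0},{height},{width}) outside field of shape {(h, w)}"
            )
        means.append(float(img[row0 : row0 + height, col0 : col0 + width].mean()))
    return np.asarray(means)
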