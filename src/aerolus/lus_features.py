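"""Quantitative image statistics for lung-ultrasound (LUS) cine clips.

A lung-ultrasound image of a partially aerated lung is dominated by artifacts:
horizontal A-line reverberations (aerated pleural surface) and vertical B-line
streaks (liquid between aerated alveoli).  Within manually placed rectangular
regions of interest (ROIs) below the pleural line, four statistics summarise
those artifacts per frame:

* **MPI** — mean pixel intensity of the ROI;
* **CoV** — coefficient of variation (population SD / mean) of pixel intensity;
* **AUC parallel** — area under the 1-D Fourier power spectrum computed along
  the direction parallel to the pleural line (across image columns), within a
  fixed spatial-frequency band; sensitive to vertical B-line streaks;
* **AUC perpendicular** — the same along the depth direction (down image
  rows); sensitive to horizontal A-line bands.

Per-frame values are averaged over the clip within each ROI and then combined
across ROIs by an area-weighted mean.  When ROIs at several depths are
supplied, MPI and the spectral AUCs are taken from the 4-cm ROIs and CoV from
the 2-cm ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import ConfigurationError, DomainError, UndefinedStatisticError

#: Default spatial-frequency band (cycles/cm) for the spectral AUC statistics.
#: The low edge excludes DC; the high edge brackets the A-line spacing
#: (about 1 / pleural depth) and typical B-line streak widths.
DEFAULT_BAND: tuple[float, float] = (0.1, 2.0)

Axis = Literal["parallel", "perpendicular"]


@dataclass
class UltrasoundClip:
    """A multi-frame grayscale ultrasound cine loop.

    ``frames`` has shape (n_frames, height, width) with 8-bit intensities.
    Row index increases with depth below the transducer face.
    """

    frames: np.ndarray
    pixel_spacing_cm_per_px: float
    frame_rate_hz: float = 15.0
    gain: float = 74.0
    true_grade: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise DomainError("frames must be a (n_frames, height, width) stack")
        if self.frames.min() < 0 or self.frames.max() > 255:
            raise DomainError("frame intensities must lie within [0, 255]")
        if self.pixel_spacing_cm_per_px <= 0:
            raise DomainError("pixel spacing must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    def mean_frame(self) -> np.ndarray:
        """Time-averaged frame (float), used by the rule-based grader."""
        return self.frames.mean(axis=0)


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular lung-area region of interest below the pleural line.

    ``top_row``/``left_col`` are 0-based pixel coordinates (row 0 at the
    transducer face, rows increase with depth).  ``depth_cm`` is the physical
    depth extent; it must convert to a whole number of rows at the clip's
    pixel spacing.
    """

    top_row: int
    left_col: int
    depth_cm: float
    width_px: int

    def __post_init__(self) -> None:
        if self.width_px < 8:
            raise DomainError("ROI width must be at least 8 px")
        if self.depth_cm <= 0:
            raise DomainError("ROI depth must be positive")
        if self.top_row < 0 or self.left_col < 0:
            raise DomainError("ROI origin must be non-negative")

    def n_rows(self, pixel_spacing_cm_per_px: float) -> int:
        rows = self.depth_cm / pixel_spacing_cm_per_px
        if abs(rows - round(rows)) > 1e-9:
            raise DomainError(
                f"ROI depth {self.depth_cm} cm is not a whole number of rows "
                f"at {pixel_spacing_cm_per_px} cm/px"
            )
        return int(round(rows))

    @property
    def area_px(self) -> float:
        """Area in px² per cm of pixel spacing is not known without spacing;
        use :meth:`area` with an explicit spacing instead."""
        raise AttributeError("use RoiSpec.area(pixel_spacing_cm_per_px)")

    def area(self, pixel_spacing_cm_per_px: float) -> int:
        return self.n_rows(pixel_spacing_cm_per_px) * self.width_px


@dataclass(frozen=True)
class FeatureVector:
    """Per-clip pooled imaging statistics."""

    mpi: float
    cov: float
    auc_parallel: float
    auc_perpendicular: float
    roi_area_px: int
    n_frames: int = 0

    def __post_init__(self) -> None:
        if self.cov < 0 or self.auc_parallel < 0 or self.auc_perpendicular < 0:
            raise DomainError("CoV and spectral AUC values must be non-negative")


def extract_roi(frame: np.ndarray, roi: RoiSpec, pixel_spacing_cm_per_px: float) -> np.ndarray:
    """Cut the ROI block out of a single frame, values untouched."""
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise DomainError("frame must be 2-D")
    rows = roi.n_rows(pixel_spacing_cm_per_px)
    bottom = roi.top_row + rows
    right = roi.left_col + roi.width_px
    if bottom > frame.shape[0] or right > frame.shape[1]:
        raise DomainError(
            f"ROI ({roi.top_row}:{bottom}, {roi.left_col}:{right}) exceeds "
            f"frame bounds {frame.shape}"
        )
    return frame[roi.top_row:bottom, roi.left_col:right]


def mean_pixel_intensity(block: np.ndarray) -> float:
    """Arithmetic mean of all pixels in the block."""
    block = np.asarray(block, dtype=float)
    if block.size == 0:
        raise DomainError("cannot compute MPI of an empty block")
    return float(block.mean())


def coefficient_of_variation(block: np.ndarray) -> float:
    """Population standard deviation divided by the mean.

    Undefined when the mean is zero or negative (all-dark block).
    """
    block = np.asarray(block, dtype=float)
    if block.size == 0:
        raise DomainError("cannot compute CoV of an empty block")
    mean = block.mean()
    if mean <= 0:
        raise UndefinedStatisticError("CoV undefined for a block with non-positive mean")
    return float(block.std(ddof=0) / mean)


def power_spectrum_auc(
    block: np.ndarray,
    axis: Axis,
    band: tuple[float, float] = DEFAULT_BAND,
    pixel_spacing_cm_per_px: float = 0.01,
    window: bool = False,
) -> float:
    """Band-integrated directional Fourier power of an ROI block.

    1-D power spectra (``|DFT|^2 / N``) are computed along the stated
    direction for every line, averaged over the orthogonal direction, and
    integrated over ``band`` (cycles/cm, DC excluded) with the trapezoid rule.

    ``axis='parallel'`` transforms across columns (the pleural-line
    direction, sensitive to vertical B-line streaks); ``'perpendicular'``
    transforms down rows (the depth direction, sensitive to horizontal
    A-line bands).
    """
    block = np.asarray(block, dtype=float)
    if block.ndim != 2:
        raise DomainError("block must be 2-D")
    if axis not in ("parallel", "perpendicular"):
        raise DomainError(f"unknown axis {axis!r}")
    fft_axis = 1 if axis == "parallel" else 0
    n = block.shape[fft_axis]
    if n < 16:
        raise DomainError("block must span at least 16 px in the transform direction")
    lo, hi = band
    if lo <= 0:
        raise DomainError("band must exclude zero frequency")
    freqs = np.fft.rfftfreq(n, d=pixel_spacing_cm_per_px)
    nyquist = freqs[-1]
    if hi > nyquist + 1e-12:
        raise DomainError(
            f"band upper edge {hi} cycles/cm exceeds Nyquist {nyquist:.6g} cycles/cm"
        )
    if window:
        w = np.hanning(n)
        shape = [1, 1]
        shape[fft_axis] = n
        block = block * w.reshape(shape)
    spectra = np.abs(np.fft.rfft(block, axis=fft_axis)) ** 2 / n
    mean_spectrum = spectra.mean(axis=1 - fft_axis)
    sel = (freqs >= lo - 1e-12) & (freqs <= hi + 1e-12)
    if sel.sum() < 2:
        raise DomainError(
            f"band ({lo}, {hi}) cycles/cm contains fewer than two spectral "
            f"samples at this block size"
        )
    return float(np.trapezoid(mean_spectrum[sel], freqs[sel]))


# Depth assignment used when ROIs at several depths are available:
# MPI and the spectral AUCs from 4-cm ROIs, CoV from 2-cm ROIs.
_DEPTH_FOR_STAT = {"mpi": 4.0, "cov": 2.0, "auc_parallel": 4.0, "auc_perpendicular": 4.0}


def _rois_for_stat(stat: str, rois: Sequence[RoiSpec]) -> list[RoiSpec]:
    depths = {roi.depth_cm for roi in rois}
    if len(depths) == 1:
        return list(rois)
    wanted = _DEPTH_FOR_STAT[stat]
    chosen = [roi for roi in rois if roi.depth_cm == wanted]
    if not chosen:
        raise ConfigurationError(
            f"no ROI at the required depth {wanted} cm for statistic {stat!r} "
            f"(depths supplied: {sorted(depths)})"
        )
    return chosen


def clip_features(
    clip: UltrasoundClip,
    rois: Sequence[RoiSpec],
    band: tuple[float, float] = DEFAULT_BAND,
    window: bool = False,
) -> FeatureVector:
    """Pool the four statistics over the clip.

    For each statistic: per-ROI per-frame values are averaged over frames
    within the ROI, then combined across ROIs by an area-weighted mean.
    """
    rois = list(rois)
    if not rois:
        raise DomainError("at least one ROI is required")
    spacing = clip.pixel_spacing_cm_per_px

    def pooled(stat: str, fn) -> float:
        chosen = _rois_for_stat(stat, rois)
        values = []
        weights = []
        for roi in chosen:
            per_frame = [fn(extract_roi(f, roi, spacing)) for f in clip.frames]
            values.append(float(np.mean(per_frame)))
            weights.append(roi.area(spacing))
        return float(np.average(values, weights=weights))

    mpi = pooled("mpi", mean_pixel_intensity)
    cov = pooled("cov", coefficient_of_variation)
    auc_par = pooled(
        "auc_parallel",
        lambda b: power_spectrum_auc(b, "parallel", band, spacing, window),
    )
    auc_perp = pooled(
        "auc_perpendicular",
        lambda b: power_spectrum_auc(b, "perpendicular", band, spacing, window),
    )
    total_area = sum(roi.area(spacing) for roi in rois)
    return FeatureVector(
        mpi=mpi,
        cov=cov,
        auc_parallel=auc_par,
        auc_perpendicular=auc_perp,
        roi_area_px=total_area,
        n_frames=clip.n_frames,
    )


def features_to_row(clip_id: str, fv: FeatureVector) -> dict:
    """Flatten a FeatureVector into a CSV-ready record."""
    return {
        "clip_id": clip_id,
        "mpi": fv.mpi,
        "cov": fv.cov,
        "auc_parallel": fv.auc_parallel,
        "auc_perpendicular": fv.auc_perpendicular,
        "n_frames": fv.n_frames,
        "total_roi_area_px": fv.roi_area_px,
    }
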