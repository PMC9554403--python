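"""Ground-truth lung aeration from reconstructed CT gray-value volumes.

On high-resolution (phase-contrast) CT of a partially aerated lung, air has
a distinctly lower linear attenuation (gray value, m^-1 scale) than liquid
or tissue.  The proportion of air in the most superficial 1 cm of lung —
the region an ultrasound beam actually interrogates — is computed by:

1. thresholding gray values strictly below an air threshold (default
   0.15 m^-1) inside a supplied lung mask;
2. restricting to lung voxels within 1 cm (Euclidean distance, anisotropic
   voxel sizes respected) of the probe-facing lung boundary (the pleural
   surface), a depth that excludes large deep vessels and airways;
3. dividing air-voxel count by total voxel count in that region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DomainError

#: Gray value (m^-1) strictly below which a voxel counts as air.
DEFAULT_AIR_THRESHOLD = 0.15
#: Depth of the superficial region below the pleural surface, in mm.
DEFAULT_SUPERFICIAL_DEPTH_MM = 10.0


@dataclass
class CtVolume:
    """Reconstructed CT gray values with a lung boundary mask.

    ``probe_axis`` is the array axis along which the ultrasound probe looks
    into the volume; index 0 along that axis is nearest the probe.
    """

    voxels: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    lung_mask: np.ndarray
    probe_axis: int = 0
    true_superficial_air_fraction: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.lung_mask = np.asarray(self.lung_mask).astype(bool)
        if self.voxels.ndim != 3:
            raise DomainError("voxels must be a 3-D array")
        if self.voxels.shape != self.lung_mask.shape:
            raise DomainError(
                f"voxels {self.voxels.shape} and lung_mask {self.lung_mask.shape} "
                "must have identical dimensions"
            )
        if any(s <= 0 for s in self.voxel_size_mm):
            raise DomainError("voxel sizes must all be positive")
        if not 0 <= self.probe_axis <= 2:
            raise DomainError("probe_axis must be 0, 1 or 2")


@dataclass(frozen=True)
class AirProportionResult:
    air_voxels: int
    region_voxels: int

    def __post_init__(self) -> None:
        if not 0 <= self.air_voxels <= self.region_voxels:
            raise DomainError("air voxel count must lie in [0, region voxel count]")

    @property
    def proportion(self) -> float:
        return self.air_voxels / self.region_voxels


def segment_air(volume: CtVolume, threshold: float = DEFAULT_AIR_THRESHOLD) -> np.ndarray:
    """Binary mask of lung voxels with gray value strictly below ``threshold``."""
    if threshold <= 0:
        raise DomainError("air threshold must be positive")
    return (volume.voxels < threshold) & volume.lung_mask


def superficial_region(
    volume: CtVolume, depth_mm: float = DEFAULT_SUPERFICIAL_DEPTH_MM
) -> np.ndarray:
    """Lung voxels within ``depth_mm`` of the probe-facing pleural surface.

    The background for the distance transform is the set of non-lung voxels
    lying in front of the lung along the probe axis (plus a virtual plane at
    the volume face, so a lung touching the face still has a surface there).
    Deep and lateral lung boundaries deliberately do not contribute: depth is
    measured from the pleural surface the ultrasound beam enters through.
    """
    if depth_mm <= 0:
        raise DomainError("depth must be positive")
    lung = volume.lung_mask
    if not lung.any():
        raise DomainError("lung mask is empty")
    axis = volume.probe_axis
    lung_m = np.moveaxis(lung, axis, 0)
    n0 = lung_m.shape[0]
    has_lung = lung_m.any(axis=0)
    # index of the first lung voxel along the probe axis, per transverse column
    first = np.argmax(lung_m, axis=0)
    idx = np.arange(n0).reshape(-1, 1, 1)
    probe_background = (idx < first[None]) & has_lung[None]
    # pad one background plane at the probe face
    feature = ~probe_background
    feature = np.concatenate([np.zeros((1,) + feature.shape[1:], bool), feature], axis=0)
    sampling = list(volume.voxel_size_mm)
    sampling.insert(0, sampling.pop(axis))
    dist = ndimage.distance_transform_edt(feature, sampling=sampling)[1:]
    region_m = lung_m & (dist <= depth_mm + 1e-9)
    return np.moveaxis(region_m, 0, axis)


def air_proportion(air_mask: np.ndarray, region_mask: np.ndarray) -> AirProportionResult:
    """Air voxel count over total voxel count within the region."""
    air_mask = np.asarray(air_mask).astype(bool)
    region_mask = np.asarray(region_mask).astype(bool)
    if air_mask.shape != region_mask.shape:
        raise DomainError("air and region masks must have identical shapes")
    n_region = int(region_mask.sum())
    if n_region == 0:
        raise DomainError("region mask is empty")
    n_air = int((air_mask & region_mask).sum())
    return AirProportionResult(air_voxels=n_air, region_voxels=n_region)


def measure_superficial_air(
    volume: CtVolume,
    threshold: float = DEFAULT_AIR_THRESHOLD,
    depth_mm: float = DEFAULT_SUPERFICIAL_DEPTH_MM,
) -> AirProportionResult:
    """Convenience composition: threshold, restrict to superficial 1 cm, count."""
    return air_proportion(segment_air(volume, threshold), superficial_region(volume, depth_mm))
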