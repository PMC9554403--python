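"""Synthetic paired lung-ultrasound clips and CT phantoms with known aeration.

The generator emulates the data a pressure-titration experiment in newborn
lambs produces: for each lung, a schedule of static airway pressures is
applied (inflation up to 50 cmH2O, then deflation, then suction), and at each
step a 3-s ultrasound cine clip and a CT volume of the underlying lung region
are acquired.  The ground truth is the proportion of air in the most
superficial 1 cm of lung, which drives both the appearance of the rendered
ultrasound artifacts and the voxel composition of the CT phantom.

Ultrasound grades rendered (air fraction bins, defaults 0 / 0.15 / 0.50 / 0.85):

* grade 0   — "hepatization": dim homogeneous tissue texture, no pleural echo;
* grade 0.5 — "speckled pleural line": discontinuous bright segments at
  varying depths, no established pleural line;
* grade 1   — "white-out": continuous pleural line over a confluent bright
  field that dims and develops column structure as air increases;
* grade 2   — distinct vertical B-line streaks over a darkening background,
  plus horizontal A-line reverberation bands at integer multiples of the
  pleural depth with geometrically decaying intensity;
* grade 3   — A-line bands only over a near-anechoic background.

All images carry two dark vertical rib-shadow bands and multiplicative
log-normal speckle.  Clip-level rendering jitter (artifact brightness, B-line
count) and the speckle dispersion are inflated by a configurable multiplier
during deflation and suction, emulating the weaker image/aeration coupling
observed when lungs deflate.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit

from .ct_aeration import CtVolume
from .errors import DomainError
from .lus_features import RoiSpec, UltrasoundClip

GRADE_LEVELS = (0.0, 0.5, 1.0, 2.0, 3.0)

# 8-bit rendering levels (background tissue, pleural echo, artifact ranges)
_BACKGROUND = 40.0
_PLEURAL = 215.0


class Phase(str, enum.Enum):
    INFLATION = "inflation"
    DEFLATION = "deflation"
    SUCTION = "suction"


@dataclass(frozen=True)
class SimulationConfig:
    """Geometry, artifact, noise and CT parameters of the generator.

    ``pixel_spacing_cm_per_px`` defaults to 0.01 cm/px so a 4-cm ROI is
    400 px deep; :meth:`desk_scale` returns a coarser, smaller configuration
    suitable for fast cohort-level runs.
    """

    image_height_px: int = 512
    image_width_px: int = 384
    pixel_spacing_cm_per_px: float = 0.01
    frames_per_clip: int = 45
    frame_rate_hz: float = 15.0
    pleural_depth_cm: float = 1.0
    aline_decay: float = 0.6
    bline_count_max: int = 5
    speckle_sigma: float = 0.30
    deflation_noise_multiplier: float = 1.5
    grade_thresholds: tuple[float, float, float, float] = (0.0, 0.15, 0.50, 0.85)
    air_gray_value: float = 0.05
    tissue_gray_value: float = 0.40
    air_threshold: float = 0.15
    ct_shape: tuple[int, int, int] = (64, 64, 64)
    ct_voxel_size_mm: tuple[float, float, float] = (0.5, 0.5, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        t = self.grade_thresholds
        if len(t) != 4 or any(t[i] >= t[i + 1] for i in range(3)):
            raise DomainError("grade_thresholds must be four strictly increasing values")
        if not (0 <= t[0] and t[3] < 1):
            raise DomainError("grade_thresholds must lie in [0, 1)")
        if not self.air_gray_value < self.air_threshold < self.tissue_gray_value:
            raise DomainError("need air_gray_value < air_threshold < tissue_gray_value")
        if self.frames_per_clip < 1:
            raise DomainError("frames_per_clip must be at least 1")
        if min(self.image_height_px, self.image_width_px) < 16:
            raise DomainError("image dimensions must be at least 16 px")
        if not 0 < self.aline_decay < 1:
            raise DomainError("aline_decay must lie in (0, 1)")
        if self.speckle_sigma < 0:
            raise DomainError("speckle_sigma must be non-negative")
        if self.deflation_noise_multiplier < 1:
            raise DomainError("deflation_noise_multiplier must be >= 1")

    @classmethod
    def desk_scale(cls, **overrides) -> "SimulationConfig":
        """Coarse configuration for cohort-scale runs and tests:
        208 x 160 px at 0.025 cm/px (4-cm ROI = 160 rows), 32^3 CT at 1 mm."""
        base = dict(
            image_height_px=208,
            image_width_px=160,
            pixel_spacing_cm_per_px=0.025,
            ct_shape=(32, 32, 32),
            ct_voxel_size_mm=(1.0, 1.0, 1.0),
        )
        base.update(overrides)
        return cls(**base)

    @property
    def pleural_row(self) -> int:
        return int(round(self.pleural_depth_cm / self.pixel_spacing_cm_per_px))

    @property
    def shadow_width_px(self) -> int:
        return max(3, self.image_width_px // 10)


def grade_from_air_fraction(
    air_fraction: float, thresholds: Sequence[float] = (0.0, 0.15, 0.50, 0.85)
) -> float:
    """Bin an air fraction into the ordinal grade scale {0, 0.5, 1, 2, 3}."""
    if not 0 <= air_fraction <= 1:
        raise DomainError(f"air fraction {air_fraction} outside [0, 1]")
    t0, t1, t2, t3 = thresholds
    if air_fraction <= t0:
        return 0.0
    if air_fraction < t1:
        return 0.5
    if air_fraction < t2:
        return 1.0
    if air_fraction < t3:
        return 2.0
    return 3.0


@dataclass(frozen=True)
class PressureSchedule:
    """Ordered (pressure cmH2O, phase) steps of a titration experiment."""

    steps: tuple[tuple[float, Phase], ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise DomainError("schedule must contain at least one step")
        last_inf = -math.inf
        last_def = math.inf
        seen_suction = False
        for pressure, phase in self.steps:
            if not 0 <= pressure <= 50:
                raise DomainError(f"pressure {pressure} outside [0, 50] cmH2O")
            if seen_suction:
                raise DomainError("suction steps must come last")
            if phase == Phase.INFLATION:
                if pressure < last_inf:
                    raise DomainError("inflation pressures must be non-decreasing")
                last_inf = pressure
            elif phase == Phase.DEFLATION:
                if pressure > last_def:
                    raise DomainError("deflation pressures must be non-increasing")
                last_def = pressure
            else:
                seen_suction = True

    def __len__(self) -> int:
        return len(self.steps)

    @classmethod
    def default(cls) -> "PressureSchedule":
        """Inflation 0 then 15 to 50 cmH2O in 5-cmH2O steps, deflation in
        10-cmH2O steps, final suction."""
        inflation = [(float(p), Phase.INFLATION) for p in (0, 15, 20, 25, 30, 35, 40, 45, 50)]
        deflation = [(float(p), Phase.DEFLATION) for p in (40, 30, 20, 10)]
        return cls(tuple(inflation + deflation + [(0.0, Phase.SUCTION)]))


@dataclass
class PairedObservation:
    """One pressure step of one lung: LUS clip + CT phantom + ground truth."""

    lamb_id: str
    lung_side: str
    pressure_cmH2O: float
    phase: Phase
    true_air_fraction: float
    true_grade: float
    clip: UltrasoundClip
    ct: CtVolume


# ---------------------------------------------------------------------------
# Ultrasound clip rendering


def _clip_jitter(rng: np.random.Generator, mult: float) -> dict:
    """Clip-level rendering jitter, inflated by ``mult`` during deflation."""
    return {
        "gain": rng.normal(0.0, 0.04 * mult),
        "bright": rng.normal(0.0, 0.07 * mult),
        "streak": rng.normal(0.0, 0.07 * mult),
        "aline": rng.normal(0.0, 0.12 * mult),
        "nb": rng.normal(0.0, 0.8 * mult),
    }


def _band_half_rows(spacing: float) -> int:
    """Half-thickness (rows) of echo bands: about 0.08 cm, at least 1 row."""
    return max(1, int(round(0.04 / spacing)))


def _add_alines(
    base: np.ndarray, r_p: int, i0: float, decay: float, spacing: float
) -> None:
    """Additive horizontal reverberation bands at depths m*d_pleura, m >= 2,
    with intensity i0 * decay^(m-1)."""
    h = base.shape[0]
    hw = _band_half_rows(spacing)
    m = 2
    while m * r_p + hw < h:
        rows = slice(m * r_p - hw, m * r_p + hw + 1)
        base[rows, :] += i0 * decay ** (m - 1)
        m += 1


def _render_base(
    config: SimulationConfig, air_fraction: float, rng: np.random.Generator, mult: float
) -> np.ndarray:
    """Noise-free (pre-speckle) frame template for one clip."""
    h, w = config.image_height_px, config.image_width_px
    r_p = config.pleural_row
    sw = config.shadow_width_px
    t0, t1, t2, t3 = config.grade_thresholds
    spacing = config.pixel_spacing_cm_per_px
    hw = _band_half_rows(spacing)
    j = _clip_jitter(rng, mult)
    base = np.full((h, w), _BACKGROUND)
    grade = grade_from_air_fraction(air_fraction, config.grade_thresholds)
    pleural_rows = slice(max(0, r_p - hw), r_p + hw + 1)
    below = r_p + hw + 1

    if grade == 0.5:
        # discontinuous pleural segments at varying depths
        n_seg = 3 + int(round(10 * air_fraction))
        seg_w = max(4, w // 5)
        for _ in range(n_seg):
            depth_cm = rng.uniform(0.3, 2.0)
            row = int(round(depth_cm / spacing))
            col = int(rng.integers(sw, max(sw + 1, w - sw - seg_w)))
            level = (170.0 + 400.0 * air_fraction) * (1 + j["bright"])
            seg = base[row : row + 2 * hw + 1, col : col + seg_w]
            np.maximum(seg, level, out=seg)
    elif grade == 1.0:
        # white-out: continuous pleural line over a confluent bright field
        # whose brightness falls and column structure grows as air increases
        v = (air_fraction - t1) / (t2 - t1)
        base[pleural_rows, :] = _PLEURAL
        field = (190.0 - 40.0 * v) * (1 + j["bright"])
        amp = (5.0 + 15.0 * v) * (1 + j["streak"])
        x_cm = np.arange(w) * spacing
        modulation = amp * np.sin(2 * np.pi * 0.9 * x_cm + rng.uniform(0, 2 * np.pi))
        base[below:, :] = np.maximum(field + modulation[None, :], 0.0)
    elif grade == 2.0:
        # distinct B-line streaks + A-line bands over a darkening background
        u = (air_fraction - t2) / (t3 - t2)
        base[pleural_rows, :] = _PLEURAL
        base[below:, :] = (130.0 - 60.0 * u) * (1 + j["bright"])
        n_b = max(1, int(round(config.bline_count_max * (1 - u) + j["nb"])))
        s_level = (190.0 + 60.0 * u) * (1 + j["streak"])
        # streaks widen and brighten as aeration grows
        streak_w = max(2, int(round((0.08 + 0.10 * u) / spacing)))
        interior = w - 2 * sw - streak_w
        n_b = min(n_b, max(1, interior // (2 * streak_w)))
        # quasi-periodic streak placement: even spacing, random offset+jitter
        pitch = interior / n_b
        offset = rng.uniform(0, pitch)
        for k in range(n_b):
            col = sw + int(offset + k * pitch + rng.normal(0, 0.08 * pitch))
            col = int(np.clip(col, sw, w - sw - streak_w))
            block = base[below:, col : col + streak_w]
            np.maximum(block, s_level, out=block)
        i0 = (150.0 + 100.0 * u) * (1 + j["aline"])
        _add_alines(base, r_p, i0, config.aline_decay, spacing)
    elif grade == 3.0:
        # A-lines only over a near-anechoic background
        base[pleural_rows, :] = 220.0
        base[below:, :] = 30.0
        i0 = 250.0 * (1 + j["aline"])
        _add_alines(base, r_p, i0, config.aline_decay, spacing)
    # grade 0: homogeneous background, no pleural echo

    base *= 1 + j["gain"]
    # rib shadows: two dark vertical bands at the lateral image edges
    base[:, :sw] *= 0.15
    base[:, w - sw :] *= 0.15
    return np.clip(base, 0.0, 255.0)


def generate_clip(
    config: SimulationConfig, air_fraction: float, phase: Phase | str, seed: int
) -> UltrasoundClip:
    """Render one cine clip at a given superficial air fraction.

    Identical (config, air_fraction, phase, seed) reproduce identical frames.
    """
    if not 0 <= air_fraction <= 1:
        raise DomainError(f"air fraction {air_fraction} outside [0, 1]")
    phase = Phase(phase)
    mult = (
        config.deflation_noise_multiplier
        if phase in (Phase.DEFLATION, Phase.SUCTION)
        else 1.0
    )
    rng = np.random.default_rng(seed)
    base = _render_base(config, air_fraction, rng, mult)
    sigma = config.speckle_sigma * mult
    frames = np.empty(
        (config.frames_per_clip, config.image_height_px, config.image_width_px), np.uint8
    )
    for i in range(config.frames_per_clip):
        if sigma > 0:
            # mean-preserving multiplicative log-normal speckle
            speckle = np.exp(
                sigma * rng.standard_normal(base.shape) - 0.5 * sigma**2
            )
        else:
            speckle = 1.0
        frames[i] = np.clip(np.round(base * speckle), 0, 255).astype(np.uint8)
    grade = grade_from_air_fraction(air_fraction, config.grade_thresholds)
    return UltrasoundClip(
        frames=frames,
        pixel_spacing_cm_per_px=config.pixel_spacing_cm_per_px,
        frame_rate_hz=config.frame_rate_hz,
        true_grade=grade,
        metadata={
            "air_fraction": air_fraction,
            "phase": phase.value,
            "seed": int(seed),
        },
    )


# ---------------------------------------------------------------------------
# CT phantom


def generate_ct_phantom(
    config: SimulationConfig, air_fraction: float, seed: int
) -> CtVolume:
    """Voxel phantom whose superficial 1-cm region holds an exact air fraction.

    The lung is a slab with a 2-voxel exterior margin; the probe looks along
    axis 0.  Air voxels are drawn near ``air_gray_value`` and tissue voxels
    near ``tissue_gray_value`` with noise clipped so thresholding at
    ``air_threshold`` is error-free.  A bright "vessel" block is buried below
    the superficial region.  The realized superficial air-voxel proportion is
    recorded on the returned volume.
    """
    if not 0 <= air_fraction <= 1:
        raise DomainError(f"air fraction {air_fraction} outside [0, 1]")
    rng = np.random.default_rng(seed)
    nz, ny, nx = config.ct_shape
    vz = config.ct_voxel_size_mm[0]
    margin = 2
    z0, z1 = margin, nz - margin
    lung = np.zeros(config.ct_shape, bool)
    lung[z0:z1, margin : ny - margin, margin : nx - margin] = True

    sup_layers = int(round(10.0 / vz))
    sup_end = min(z1, z0 + sup_layers)
    sup = np.zeros_like(lung)
    sup[z0:sup_end] = lung[z0:sup_end]
    n_sup = int(sup.sum())
    if n_sup == 0:
        raise DomainError("grid too small: empty superficial region")
    n_air_sup = int(round(air_fraction * n_sup))
    if abs(n_air_sup / n_sup - air_fraction) > 0.02:
        raise DomainError(
            f"air fraction {air_fraction} unreachable within 0.02 on a grid "
            f"with {n_sup} superficial voxels"
        )

    # deep bright vessel, strictly below the superficial region
    vessel = np.zeros_like(lung)
    v_start = sup_end + max(2, int(round(4.0 / vz)))
    v_end = min(z1, v_start + max(2, int(round(5.0 / vz))))
    if v_end > v_start:
        cy, cx = ny // 2, nx // 2
        ry, rx = max(2, ny // 8), max(2, nx // 8)
        vessel[v_start:v_end, cy - ry : cy + ry, cx - rx : cx + rx] = True
        vessel &= lung

    air = np.zeros_like(lung)
    sup_idx = np.flatnonzero(sup)
    chosen = rng.choice(sup_idx, size=n_air_sup, replace=False)
    air.ravel()[chosen] = True
    deep = lung & ~sup & ~vessel
    n_deep = int(deep.sum())
    if n_deep:
        deep_idx = np.flatnonzero(deep)
        n_air_deep = int(round(air_fraction * n_deep))
        chosen = rng.choice(deep_idx, size=n_air_deep, replace=False)
        air.ravel()[chosen] = True

    thr = config.air_threshold
    voxels = np.clip(
        rng.normal(config.tissue_gray_value, 0.02, config.ct_shape), thr + 0.05, 1.0
    ).astype(np.float32)
    voxels[air] = np.clip(
        rng.normal(config.air_gray_value, 0.015, int(air.sum())), 0.0, thr - 0.03
    )
    voxels[vessel] = np.clip(rng.normal(0.8, 0.02, int(vessel.sum())), thr + 0.05, 1.5)

    return CtVolume(
        voxels=voxels,
        voxel_size_mm=config.ct_voxel_size_mm,
        lung_mask=lung,
        probe_axis=0,
        true_superficial_air_fraction=n_air_sup / n_sup,
        metadata={"requested_air_fraction": air_fraction, "seed": int(seed)},
    )


# ---------------------------------------------------------------------------
# Cohort generation


def _aeration_curve(pressure: float, af_max: float, p50: float, slope: float) -> float:
    """Saturating monotone pressure response, normalized to 0 at 0 cmH2O and
    af_max at 50 cmH2O."""
    lo = expit((0.0 - p50) / slope)
    hi = expit((50.0 - p50) / slope)
    f = (expit((pressure - p50) / slope) - lo) / (hi - lo)
    return af_max * float(f)


def generate_cohort(
    n_lambs: int,
    schedule: PressureSchedule,
    config: SimulationConfig,
    seed: int,
) -> list[PairedObservation]:
    """Simulate a full pressure-titration experiment.

    Two lungs per lamb.  Each lung gets its own saturating pressure-aeration
    curve (random maximum around 0.64, half-aeration pressure around
    27 cmH2O).  During deflation the air fraction at a given pressure exceeds
    the inflation value (hysteresis, modeled as a concave power of the
    inflation curve); suction deflates to a small residual air fraction.
    Air fractions are deterministic given the lung parameters, so hysteresis
    holds exactly; observation-level noise enters through clip rendering.
    """
    if n_lambs < 1:
        raise DomainError("n_lambs must be at least 1")
    if len(schedule) == 0:
        raise DomainError("schedule must be non-empty")
    ss = np.random.SeedSequence(seed)
    observations: list[PairedObservation] = []
    for lamb in range(n_lambs):
        for side in ("L", "R"):
            rng = np.random.default_rng(ss.spawn(1)[0])
            af_max = float(np.clip(rng.normal(0.64, 0.05), 0.45, 0.80))
            p50 = float(rng.normal(27.0, 2.0))
            slope = float(np.clip(rng.normal(7.0, 0.8), 4.0, 10.0))
            gamma = float(np.clip(rng.normal(0.4, 0.05), 0.25, 0.6))
            residual = float(rng.uniform(0.01, 0.09))
            for pressure, phase in schedule.steps:
                f = _aeration_curve(pressure, 1.0, p50, slope)
                if phase == Phase.INFLATION:
                    af = af_max * f
                elif phase == Phase.DEFLATION:
                    af = af_max * f**gamma
                else:  # suction: deflation to a small residual air fraction
                    af = residual
                af = float(np.clip(af, 0.0, 1.0))
                clip_seed = int(rng.integers(0, 2**31))
                ct_seed = int(rng.integers(0, 2**31))
                obs = PairedObservation(
                    lamb_id=f"lamb{lamb + 1:02d}",
                    lung_side=side,
                    pressure_cmH2O=float(pressure),
                    phase=phase,
                    true_air_fraction=af,
                    true_grade=grade_from_air_fraction(af, config.grade_thresholds),
                    clip=generate_clip(config, af, phase, clip_seed),
                    ct=generate_ct_phantom(config, af, ct_seed),
                )
                observations.append(obs)
    return observations


def default_rois(config: SimulationConfig, depths_cm: Sequence[float] = (2.0, 3.0, 4.0)) -> list[RoiSpec]:
    """ROIs spanning the inter-shadow lung area below the pleural line, one
    per requested depth that fits inside the frame."""
    sw = config.shadow_width_px
    top = config.pleural_row + 2
    width = config.image_width_px - 2 * sw - 2
    rois = []
    for depth in depths_cm:
        rows = depth / config.pixel_spacing_cm_per_px
        if abs(rows - round(rows)) > 1e-9:
            continue
        if top + int(round(rows)) <= config.image_height_px:
            rois.append(RoiSpec(top_row=top, left_col=sw + 1, depth_cm=depth, width_px=width))
    if not rois:
        raise DomainError("no requested ROI depth fits inside the frame")
    return rois


def observations_to_frame(observations: Sequence[PairedObservation]):
    """Cohort manifest as a pandas DataFrame (no image payloads)."""
    import pandas as pd

    rows = [
        {
            "lamb_id": o.lamb_id,
            "lung_side": o.lung_side,
            "pressure_cmH2O": o.pressure_cmH2O,
            "phase": o.phase.value,
            "true_air_fraction": o.true_air_fraction,
            "true_grade": o.true_grade,
        }
        for o in observations
    ]
    return pd.DataFrame(rows)
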