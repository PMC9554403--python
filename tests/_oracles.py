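"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain loops / explicit sums so it shares no
code path with the package: direct pixel loops for moments, a naive O(N^2)
DFT for spectra, per-voxel scans for CT masks, and exhaustive minimum
distances for the superficial region.
"""

from __future__ import annotations

import math

import numpy as np


def mpi_loop(block) -> float:
    total = 0.0
    n = 0
    for row in block:
        for value in row:
            total += float(value)
            n += 1
    return total / n


def cov_loop(block) -> float:
    mean = mpi_loop(block)
    ss = 0.0
    n = 0
    for row in block:
        for value in row:
            ss += (float(value) - mean) ** 2
            n += 1
    return math.sqrt(ss / n) / mean


def naive_power_auc(block, axis: str, band, spacing: float) -> float:
    """Direct-sum DFT power spectra per line, averaged, trapezoid over band."""
    block = np.asarray(block, dtype=float)
    if axis == "parallel":
        lines = [block[i, :] for i in range(block.shape[0])]
    else:
        lines = [block[:, j] for j in range(block.shape[1])]
    n = len(lines[0])
    n_freq = n // 2 + 1
    spectra = np.zeros(n_freq)
    for line in lines:
        for k in range(n_freq):
            re = sum(line[m] * math.cos(-2 * math.pi * k * m / n) for m in range(n))
            im = sum(line[m] * math.sin(-2 * math.pi * k * m / n) for m in range(n))
            spectra[k] += (re * re + im * im) / n
    spectra /= len(lines)
    freqs = [k / (n * spacing) for k in range(n_freq)]
    pts = [(f, s) for f, s in zip(freqs, spectra) if band[0] - 1e-12 <= f <= band[1] + 1e-12]
    auc = 0.0
    for (f1, s1), (f2, s2) in zip(pts, pts[1:]):
        auc += 0.5 * (s1 + s2) * (f2 - f1)
    return auc


def count_air_voxels_loop(voxels, lung_mask, region_mask, threshold) -> tuple[int, int]:
    """(air, total) voxel counts inside the region by per-voxel scan."""
    nz, ny, nx = voxels.shape
    air = 0
    total = 0
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if region_mask[z, y, x]:
                    total += 1
                    if lung_mask[z, y, x] and voxels[z, y, x] < threshold:
                        air += 1
    return air, total


def threshold_mask_loop(voxels, lung_mask, threshold):
    """Per-voxel air mask by explicit comparison."""
    out = np.zeros(voxels.shape, dtype=bool)
    nz, ny, nx = voxels.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                out[z, y, x] = bool(lung_mask[z, y, x]) and voxels[z, y, x] < threshold
    return out


def superficial_region_exhaustive(lung_mask, voxel_size_mm, depth_mm):
    """Exhaustive min-distance to the probe-side background (axis 0 probe).

    Background voxels are those in front of the first lung voxel of each
    transverse column (plus a virtual plane just outside the probe face).
    """
    nz, ny, nx = lung_mask.shape
    vz, vy, vx = voxel_size_mm
    background = []
    for y in range(ny):
        for x in range(nx):
            column = [lung_mask[z, y, x] for z in range(nz)]
            if any(column):
                first = column.index(True)
                background.append((-1, y, x))  # virtual face plane
                for z in range(first):
                    background.append((z, y, x))
    region = np.zeros_like(lung_mask)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not lung_mask[z, y, x]:
                    continue
                best = math.inf
                for bz, by, bx in background:
                    d = math.sqrt(
                        ((z - bz) * vz) ** 2 + ((y - by) * vy) ** 2 + ((x - bx) * vx) ** 2
                    )
                    best = min(best, d)
                region[z, y, x] = best <= depth_mm + 1e-9
    return region


def clip_features_loop(clip, rois, band, stat_depths, stats=None) -> dict:
    """Explicit double loop over frames and ROIs with area weighting.

    ``stat_depths`` maps statistic name to the ROI depth it should use when
    several depths are present.  ``stats`` restricts which statistics are
    computed (the naive DFT is quadratic and only affordable on small blocks).
    """
    spacing = clip.pixel_spacing_cm_per_px
    depths = {r.depth_cm for r in rois}

    def block(frame, roi):
        rows = int(round(roi.depth_cm / spacing))
        return frame[roi.top_row : roi.top_row + rows, roi.left_col : roi.left_col + roi.width_px]

    def pooled(fn, wanted_depth):
        chosen = [
            r for r in rois if len(depths) == 1 or r.depth_cm == wanted_depth
        ]
        num = 0.0
        den = 0.0
        for roi in chosen:
            area = int(round(roi.depth_cm / spacing)) * roi.width_px
            acc = 0.0
            for frame in clip.frames:
                acc += fn(np.asarray(frame, dtype=float)[
                    roi.top_row : roi.top_row + int(round(roi.depth_cm / spacing)),
                    roi.left_col : roi.left_col + roi.width_px,
                ])
            num += area * (acc / len(clip.frames))
            den += area
        return num / den

    fns = {
        "mpi": lambda wanted: pooled(mpi_loop, wanted),
        "cov": lambda wanted: pooled(cov_loop, wanted),
        "auc_parallel": lambda wanted: pooled(
            lambda b: naive_power_auc(b, "parallel", band, spacing), wanted
        ),
        "auc_perpendicular": lambda wanted: pooled(
            lambda b: naive_power_auc(b, "perpendicular", band, spacing), wanted
        ),
    }
    stats = stats if stats is not None else list(fns)
    return {name: fns[name](stat_depths[name]) for name in stats}


def ols_normal_equations(x, y):
    """Least squares via normal equations: returns (intercept, slope, r2, s)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1 - ss_res / ss_tot
    s = math.sqrt(ss_res / (n - 2))
    return float(beta[0]), float(beta[1]), r2, s


def paired_t_formula(a, b):
    """t = mean(d) / (sd(d)/sqrt(n)) with sample SD, two-sided p via scipy's
    t CDF (distribution function only; the statistic is hand-computed)."""
    import scipy.stats

    d = np.asarray(a, float) - np.asarray(b, float)
    n = len(d)
    sd = math.sqrt(((d - d.mean()) ** 2).sum() / (n - 1))
    t = d.mean() / (sd / math.sqrt(n))
    p = 2 * scipy.stats.t.sf(abs(t), n - 1)
    return t, p
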