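"""Image-quality and tracking-precision metrics.

gCNR is one minus the overlap of the pixel-intensity distributions of
two regions (here vessel wall vs lumen), estimated on a shared-support
histogram; it is bounded in [0, 1] and robust to the monotone intensity
transforms of B-mode display.  The regional analysis splits the wall
into 8 sectors of 45 degrees, region 1 centred on the single-probe wave
propagation axis (anterior), region 5 opposite, the rest clockwise, and
the lumen mask is eroded by a 0.6 mm disk so wall specular reflections
do not contaminate it.

Motion drift MD = mean start-to-end distance of the middle-wall-layer
points between the two end-diastoles of a cycle (a perfect tracker
returns to the start).  Elastographic SNR, SNRe = 20 log10(mu/sigma) of
the middle-layer circumferential strain at end-systole.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import binary_erosion
from skimage.morphology import disk

__all__ = [
    "QualityMetrics",
    "gcnr",
    "regional_gcnr",
    "erode_lumen",
    "motion_drift",
    "snre",
    "likert_summary",
    "paired_compare",
]


@dataclass
class QualityMetrics:
    gcnr_total: float = np.nan
    gcnr_regional: tuple = ()
    md: float = np.nan
    snre_circ: float = np.nan


def gcnr(envelope: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray, n_bins: int = 100) -> float:
    """gCNR = 1 - sum_bins min(p_a, p_b) over shared equal-width bins."""
    a = np.asarray(envelope)[np.asarray(mask_a, bool)]
    b = np.asarray(envelope)[np.asarray(mask_b, bool)]
    if a.size == 0 or b.size == 0:
        raise ValueError("empty mask")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi <= lo:
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    ovl = np.minimum(pa / a.size, pb / b.size).sum()
    return float(1.0 - ovl)


def gcnr_multi(envelope, mask_pairs, n_bins: int = 100) -> float:
    """Average gCNR over repeated segmentations (intra-variability API)."""
    return float(np.mean([gcnr(envelope, ma, mb, n_bins) for ma, mb in mask_pairs]))


def erode_lumen(mask: np.ndarray, radius_mm: float, pixel_mm: float) -> np.ndarray:
    r_px = max(int(round(radius_mm / pixel_mm)), 1)
    return binary_erosion(np.asarray(mask, bool), structure=disk(r_px))


def region_labels(shape, centroid_rc, probe_axis_angle: float = 0.0) -> np.ndarray:
    """8-sector labels (1..8) about a centroid given in (row, col).

    Region 1 is centred on the probe axis (anterior, image-up), region 5
    opposite, regions numbered clockwise; each sector spans 45 degrees.
    """
    rr, cc = np.indices(shape)
    dy = -(rr - centroid_rc[0])  # up = toward the probe
    dx = cc - centroid_rc[1]
    ang = np.arctan2(dx, dy) - probe_axis_angle  # clockwise from up
    ang = np.mod(ang + np.pi / 8, 2 * np.pi)
    return (ang // (np.pi / 4)).astype(int) + 1


def regional_gcnr(
    envelope: np.ndarray,
    wall_mask: np.ndarray,
    lumen_mask: np.ndarray,
    pixel_mm: float,
    probe_axis_angle: float = 0.0,
    erosion_mm: float = 0.6,
    n_bins: int = 100,
):
    """Per-region gCNR of the wall sectors against the shared eroded
    lumen.  Returns (list of 8 values, NaN for empty sectors)."""
    wall_mask = np.asarray(wall_mask, bool)
    lumen_e = erode_lumen(lumen_mask, erosion_mm, pixel_mm)
    rr, cc = np.nonzero(lumen_mask)
    centroid = (rr.mean(), cc.mean())
    labels = region_labels(envelope.shape, centroid, probe_axis_angle)
    out = []
    for r in range(1, 9):
        m = wall_mask & (labels == r)
        if m.sum() < 50:
            out.append(np.nan)
            continue
        out.append(gcnr(envelope, m, lumen_e, n_bins))
    return out


def motion_drift(coords_ed1: np.ndarray, coords_ed2: np.ndarray) -> float:
    """Mean Euclidean distance between matched points at the two
    end-diastoles (mm)."""
    a = np.asarray(coords_ed1, dtype=float).reshape(-1, 2)
    b = np.asarray(coords_ed2, dtype=float).reshape(-1, 2)
    if a.shape != b.shape:
        raise ValueError("mismatched point counts")
    return float(np.mean(np.linalg.norm(a - b, axis=1)))


def snre(circ_strain_middle_layer: np.ndarray) -> float:
    """20 log10(mean/std) of middle-layer circumferential strain, dB.

    sigma = 0 returns +inf; non-positive mean returns NaN (flagged
    undefined; no absolute value is taken)."""
    e = np.asarray(circ_strain_middle_layer, dtype=float).ravel()
    if e.size < 2:
        raise ValueError("need at least 2 strain values")
    mu = e.mean()
    sd = e.std(ddof=0)
    if sd == 0:
        return np.inf
    if mu <= 0:
        return np.nan
    return float(20 * np.log10(mu / sd))


def likert_summary(scores) -> dict:
    """Median, IQR (linear-interpolation quantiles), per-category counts
    and the low-quality (1-2) / acceptable (3-5) percentages."""
    s = np.asarray(scores)
    if s.size == 0 or np.any((s < 1) | (s > 5)) or not np.all(s == s.astype(int)):
        raise ValueError("scores must be integers in 1..5")
    s = s.astype(int)
    q1, q3 = np.percentile(s, [25, 75])
    counts = {k: int(np.sum(s == k)) for k in range(1, 6)}
    n = s.size
    low = counts[1] + counts[2]
    return {
        "median": float(np.median(s)),
        "iqr": float(q3 - q1),
        "counts": counts,
        "pct_low": 100.0 * low / n,
        "pct_acceptable": 100.0 * (n - low) / n,
    }


def paired_compare(sample_a, sample_b, alpha: float = 0.05) -> dict:
    """Paired t-test, or Wilcoxon signed-rank when the differences fail a
    Shapiro normality check at alpha = 0.05."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("samples must be paired with length >= 5")
    d = b - a
    if np.allclose(d, 0):
        return {"test": "degenerate", "statistic": 0.0, "p": 1.0, "significant": False}
    if np.ptp(d) == 0:  # constant nonzero difference: trivially shifted
        normal = True
    else:
        normal = stats.shapiro(d).pvalue >= 0.05
    if normal:
        res = stats.ttest_rel(b, a)
        name = "paired t"
    else:
        res = stats.wilcoxon(b, a)
        name = "wilcoxon signed-rank"
    return {
        "test": name,
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "significant": bool(res.pvalue < alpha),
    }
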