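"""Motion-accuracy and image-quality metrics.

Vessel sharpness is operationalized as follows: perpendicular intensity
profiles are sampled along the vessel centerline; on each side of the
profile peak the 20%-to-80% rise distance ``d`` (relative to the local
background-to-peak excursion) is located, the full edge width is
extrapolated as ``w = d / 0.6`` (a linear ramp rises from 20% to 80% over
60% of its width), and the per-edge sharpness is ``100 * pixel_mm / w``
capped at 100.  A one-pixel edge therefore scores 100%, an edge ramped
over exactly two pixels scores 50%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.stats import linregress, pearsonr

from .selfnav import MotionTrace, ROIMask

__all__ = [
    "QualityReport",
    "motion_error",
    "snr_cnr",
    "vessel_sharpness",
    "measure_diameter",
    "nav_agreement",
    "protocol_arithmetic",
    "error_reduction_pct",
    "nrmse",
]


@dataclass
class QualityReport:
    snr: float | None = None
    cnr: float | None = None
    vessel_sharpness_pct: float | None = None
    mean_diameter_mm: float | None = None
    motion_error_mean_mm: float | None = None
    motion_error_sd_mm: float | None = None
    relative_error_pct: float | None = None
    cc: float | None = None
    slope: float | None = None
    scan_time_s: float | None = None
    scan_efficiency_pct: float | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "extra" and v is not None}
        d.update(self.extra)
        return d


def nrmse(image: np.ndarray, reference: np.ndarray) -> float:
    """RMS error normalized by the reference intensity range."""
    image = np.abs(np.asarray(image))
    reference = np.abs(np.asarray(reference))
    rng = reference.max() - reference.min()
    if rng == 0:
        raise ValueError("reference image has zero intensity range")
    return float(np.sqrt(np.mean((image - reference) ** 2)) / rng)


def motion_error(
    est: MotionTrace, truth: MotionTrace, min_truth_mm: float = 0.5
) -> tuple[np.ndarray, float, float, float]:
    """Euclidean motion-detection error per interleave.

    Returns ``(distances_mm, mean_mm, sd_mm, relative_mean_pct)``.  The
    relative error averages ``distance / |truth|`` only over interleaves
    whose true displacement magnitude is at least ``min_truth_mm``.
    """
    if len(est) != len(truth):
        raise ValueError("trace lengths differ")
    d = np.hypot(est.dx_mm - truth.dx_mm, est.dy_mm - truth.dy_mm)
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1)) if len(d) > 1 else 0.0
    mag = truth.magnitude_mm
    sel = mag >= min_truth_mm
    rel = float(np.mean(d[sel] / mag[sel]) * 100.0) if np.any(sel) else float("nan")
    return d, mean, sd, rel


def snr_cnr(
    image: np.ndarray, roi_blood: ROIMask, roi_myo: ROIMask, roi_noise: ROIMask
) -> tuple[float, float]:
    """SNR = mean(blood)/sd(noise); CNR = (mean(blood)-mean(myo))/sd(noise)."""
    image = np.abs(np.asarray(image))
    for roi in (roi_blood, roi_myo, roi_noise):
        if image.shape != roi.grid.shape:
            raise ValueError("ROI shape does not match image")
    b = roi_blood.indices
    m = roi_myo.indices
    n = roi_noise.indices
    if np.any(b & m) or np.any(b & n) or np.any(m & n):
        raise ValueError("ROIs must be disjoint")
    sd = float(np.std(image[n], ddof=1))
    if sd == 0:
        raise ValueError("noise ROI degenerate")
    s_blood = float(np.mean(image[b]))
    s_myo = float(np.mean(image[m]))
    return s_blood / sd, (s_blood - s_myo) / sd


def _profiles(
    image: np.ndarray,
    centerline: np.ndarray,
    pixel_mm: float,
    segment_length_mm: float,
    half_len_px: float = 8.0,
    step_px: float = 0.25,
):
    """Perpendicular intensity profiles along the proximal vessel segment.

    Yields ``(offsets_px, values)`` per usable centerline point; points
    whose profile exits the image are skipped.
    """
    image = np.abs(np.asarray(image))
    cl = np.asarray(centerline, dtype=float)
    if cl.shape[0] < 3:
        raise ValueError("centerline needs at least 3 points")
    seg = np.diff(cl, axis=0)
    arclen = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    offs = np.arange(-half_len_px, half_len_px + 1e-9, step_px)
    n = image.shape[0]
    count = 0
    for i in range(cl.shape[0]):
        if arclen[i] * pixel_mm > segment_length_mm:
            break
        lo, hi = max(i - 1, 0), min(i + 1, cl.shape[0] - 1)
        tang = cl[hi] - cl[lo]
        tang = tang / (np.linalg.norm(tang) or 1.0)
        normal = np.array([-tang[1], tang[0]])
        rows = cl[i, 0] + offs * normal[0]
        cols = cl[i, 1] + offs * normal[1]
        if rows.min() < 0 or cols.min() < 0 or rows.max() > n - 1 or cols.max() > n - 1:
            continue
        vals = map_coordinates(image, [rows, cols], order=1)
        count += 1
        yield offs, vals
    if count == 0:
        raise ValueError("no usable centerline points (all profiles exit the image)")


def _edge_widths(offs: np.ndarray, vals: np.ndarray) -> list[float]:
    """20-80% rise distances (px) of the two edges around the profile peak."""
    center = len(vals) // 2
    win = max(2, len(vals) // 6)
    pk = center - win + int(np.argmax(vals[center - win : center + win + 1]))
    quarter = len(vals) // 4
    bg = min(np.min(vals[:quarter]), np.min(vals[-quarter:]))
    amp = vals[pk] - bg
    if amp <= 0:
        return []
    widths = []
    for side in (-1, +1):
        idx = np.arange(pk, -1 if side < 0 else len(vals), side)
        prof = vals[idx]
        pos = offs[idx]
        lvl_hi = bg + 0.8 * amp
        lvl_lo = bg + 0.2 * amp
        s_hi = _first_crossing(pos, prof, lvl_hi)
        s_lo = _first_crossing(pos, prof, lvl_lo)
        if s_hi is not None and s_lo is not None:
            widths.append(abs(s_lo - s_hi))
    return widths


def _first_crossing(pos: np.ndarray, prof: np.ndarray, level: float) -> float | None:
    """Position where the profile first drops through ``level`` (interp)."""
    below = prof < level
    if not below.any() or below[0]:
        return None
    j = int(np.argmax(below))
    p0, p1 = prof[j - 1], prof[j]
    if p0 == p1:
        return float(pos[j])
    t = (p0 - level) / (p0 - p1)
    return float(pos[j - 1] + t * (pos[j] - pos[j - 1]))


def vessel_sharpness(
    image: np.ndarray,
    centerline: np.ndarray,
    pixel_mm: float,
    segment_length_mm: float = 20.0,
) -> float:
    """Percent vessel sharpness over the proximal vessel segment."""
    scores = []
    for offs, vals in _profiles(image, centerline, pixel_mm, segment_length_mm):
        for d in _edge_widths(offs, vals):
            w = d / 0.6  # full edge width extrapolated from the 20-80% rise
            scores.append(min(100.0, 100.0 / w))
    if not scores:
        raise ValueError("no measurable vessel edges")
    return float(np.mean(scores))


def measure_diameter(
    image: np.ndarray,
    centerline: np.ndarray,
    pixel_mm: float,
    segment_length_mm: float = 20.0,
) -> float:
    """Mean full-width-half-maximum vessel diameter in mm."""
    widths = []
    for offs, vals in _profiles(image, centerline, pixel_mm, segment_length_mm):
        center = len(vals) // 2
        win = max(2, len(vals) // 6)
        pk = center - win + int(np.argmax(vals[center - win : center + win + 1]))
        quarter = len(vals) // 4
        bg = min(np.min(vals[:quarter]), np.min(vals[-quarter:]))
        amp = vals[pk] - bg
        if amp <= 0:
            continue
        lvl = bg + 0.5 * amp
        left = _first_crossing(offs[pk::-1], vals[pk::-1], lvl)
        right = _first_crossing(offs[pk:], vals[pk:], lvl)
        if left is not None and right is not None:
            widths.append(abs(right - left))
    if not widths:
        raise ValueError("no measurable vessel profiles")
    return float(np.mean(widths) * pixel_mm)


def nav_agreement(
    self_si: np.ndarray, reference: np.ndarray
) -> tuple[float, float, float]:
    """Pearson CC and regression of self-navigated SI motion on a reference.

    The regression slope is the subject-specific correction factor relating
    heart displacement to the reference (e.g. diaphragmatic) displacement.
    Returns ``(cc, slope, intercept)``.
    """
    self_si = np.asarray(self_si, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if self_si.shape != reference.shape or self_si.ndim != 1 or len(self_si) < 3:
        raise ValueError("need two equal-length 1D series of length >= 3")
    if np.std(self_si) == 0 or np.std(reference) == 0:
        raise ValueError("zero-variance input")
    cc = float(pearsonr(self_si, reference)[0])
    fit = linregress(reference, self_si)
    return cc, float(fit.slope), float(fit.intercept)


def protocol_arithmetic(
    selfnav_time_s: float, nav_time_s: float, nav_efficiency_pct: float
) -> tuple[float, float]:
    """Scan-time reduction (%) and scan-efficiency fold-increase.

    ``time_reduction_pct = 100 * (nav - selfnav) / nav`` and
    ``efficiency_ratio = 100 / nav_efficiency_pct`` (self-navigation keeps
    every heartbeat, i.e. 100% efficiency).
    """
    if selfnav_time_s <= 0 or nav_time_s <= 0 or nav_efficiency_pct <= 0:
        raise ValueError("times and efficiency must be positive")
    reduction = 100.0 * (nav_time_s - selfnav_time_s) / nav_time_s
    ratio = 100.0 / nav_efficiency_pct
    return reduction, ratio


def error_reduction_pct(error_baseline: float, error_improved: float) -> float:
    """Percent decrease of an error value relative to a baseline."""
    if error_baseline <= 0:
        raise ValueError("baseline error must be positive")
    return 100.0 * (error_baseline - error_improved) / error_baseline
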