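"""Synthetic phantoms, respiratory traces, and motion-corrupted radial k-space.

Motion is simulated with exact k-space phase ramps (the conjugate of the
correction ramp), so a corrupted acquisition corrected with its own trace
reproduces the static acquisition to machine precision.  That makes the
motion-detection error attributable entirely to the estimation algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .motion_correct import phase_ramp
from .recon import KSpaceData, gridding_reconstruct, nufft_forward
from .selfnav import MotionTrace
from .trajectory import RadialTrajectory

__all__ = [
    "Phantom",
    "make_phantom",
    "make_motion_trace",
    "simulate_acquisition",
    "noise_for_snr",
]


@dataclass
class Phantom:
    """A chest-like numerical phantom with a known bright vessel.

    ``image`` is the static part; ``confounder`` (optional) is a separately
    rendered feature group meant to be animated with an independent motion
    trace.  The registry records geometry in pixel units: the vessel
    centerline (ordered ``(row, col)`` points), its diameter, and suggested
    analysis ROIs.
    """

    image: np.ndarray
    pixel_mm: float
    vessel_centerline: np.ndarray
    vessel_diameter_mm: float
    registry: dict = field(default_factory=dict)
    confounder: np.ndarray | None = None

    @property
    def matrix(self) -> int:
        return self.image.shape[0]

    @property
    def total(self) -> np.ndarray:
        if self.confounder is None:
            return self.image
        return np.clip(self.image + self.confounder, 0.0, 1.0)


def _render_ellipse(grid_x, grid_y, cx, cy, a, b, angle=0.0):
    ca, sa = np.cos(angle), np.sin(angle)
    xr = (grid_x - cx) * ca + (grid_y - cy) * sa
    yr = -(grid_x - cx) * sa + (grid_y - cy) * ca
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def make_phantom(
    matrix: int,
    pixel_mm: float = 1.0,
    seed: int = 0,
    vessel_diameter_mm: float = 3.0,
    with_confounder: bool = False,
    smooth_px: float = 0.6,
) -> Phantom:
    """Deterministic chest/heart phantom with a curvilinear bright vessel.

    The layout is fixed in relative coordinates; the seed only jitters
    feature positions slightly (sub-pixel to a few pixels), so the phantom
    is reproducible given ``(matrix, pixel_mm, seed)``.
    """
    if matrix < 64:
        raise ValueError("matrix must be >= 64 to contain the phantom features")
    rng = np.random.default_rng(seed)
    L = 0.8 * matrix  # layout unit: features occupy ~80% of the FOV
    ss = 4  # supersampling factor for anti-aliased rendering
    n = matrix * ss
    yy, xx = np.mgrid[0:n, 0:n]
    xx = xx / ss
    yy = yy / ss
    jit = lambda s: float(rng.uniform(-s, s))

    img = np.zeros((n, n))
    c = matrix / 2

    # chest wall / torso
    img[_render_ellipse(xx, yy, c + jit(1), c + jit(1), 0.44 * L, 0.38 * L)] = 0.25
    # heart body
    hx, hy = c - 0.06 * L + jit(1), c + 0.02 * L + jit(1)
    img[_render_ellipse(xx, yy, hx, hy, 0.20 * L, 0.17 * L, 0.3)] = 0.45
    # ventricles
    img[_render_ellipse(xx, yy, hx - 0.06 * L, hy + 0.03 * L, 0.08 * L, 0.065 * L, 0.4)] = 0.65
    img[_render_ellipse(xx, yy, hx + 0.07 * L, hy - 0.02 * L, 0.055 * L, 0.05 * L, 0.2)] = 0.35
    # aortic blood pool (bright, used as the SNR blood ROI)
    ax, ay = hx + 0.02 * L, hy - 0.12 * L
    img[_render_ellipse(xx, yy, ax, ay, 0.045 * L, 0.045 * L)] = 0.9

    # curvilinear vessel: arc of a circle on the right side of the heart,
    # over the dim heart background
    radius_px = 0.16 * L
    vx, vy = hx + 0.14 * L + jit(0.5), hy + 0.01 * L + jit(0.5)
    arc = np.linspace(-0.45 * np.pi, 0.45 * np.pi, 64)
    cl_x = vx + radius_px * np.cos(arc) * 0.35
    cl_y = vy + radius_px * np.sin(arc)
    half_w = 0.5 * vessel_diameter_mm / pixel_mm
    dist = np.full((n, n), np.inf)
    for px, py in zip(cl_x, cl_y):
        dist = np.minimum(dist, np.hypot(xx - px, yy - py))
    img[dist <= half_w] = 1.0

    down = img.reshape(matrix, ss, matrix, ss).mean(axis=(1, 3))
    # band-limiting: real MR images carry no energy beyond the sampled
    # k-space disc; a sharp-edged phantom would alias through the ramp filter
    down = gaussian_filter(down, smooth_px)

    conf = None
    if with_confounder:
        cim = np.zeros((n, n))
        # anterior chest-wall blob, well away from the heart
        cim[_render_ellipse(xx, yy, c + 0.30 * L, c - 0.30 * L, 0.06 * L, 0.05 * L)] = 0.8
        conf = gaussian_filter(cim.reshape(matrix, ss, matrix, ss).mean(axis=(1, 3)), smooth_px)
        down = np.where(conf > 0, 0.0, down)

    centerline = np.column_stack([cl_y, cl_x])  # (row, col)
    registry = {
        "heart_center": (hx, hy),
        "heart_semiaxes": (0.24 * L, 0.21 * L),
        "blood_roi": {"center": (ax, ay), "radius": 0.03 * L},
        "myo_roi": {"center": (hx + 0.07 * L, hy - 0.02 * L), "radius": 0.03 * L},
        "noise_roi": {"corner": (int(0.02 * matrix), int(0.02 * matrix)), "size": int(0.12 * matrix)},
        "ellipses": ["torso", "heart", "lv", "rv", "aorta"],
    }
    return Phantom(
        image=np.clip(down, 0.0, 1.0),
        pixel_mm=pixel_mm,
        vessel_centerline=centerline,
        vessel_diameter_mm=vessel_diameter_mm,
        registry=registry,
        confounder=conf,
    )


def make_motion_trace(
    num_interleaves: int,
    max_amp_mm: float,
    period_beats: int = 8,
    seed: int = 0,
    pixel_mm: float = 1.0,
    anisotropy: float = 0.35,
) -> MotionTrace:
    """Quasi-periodic respiratory-like displacement trace.

    Displacement magnitudes lie in ``[0, max_amp_mm]`` with the peak at
    least ``0.85 * max_amp_mm``; the dominant axis is y (SI-like), with a
    fixed anisotropy factor mapping a fraction onto x.  The reference
    interleave (the one closest to rest) is forced to exactly (0, 0).
    """
    if max_amp_mm < 0:
        raise ValueError("max_amp_mm must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(num_interleaves)
    phase0 = rng.uniform(0, 2 * np.pi)
    s = 0.5 * (1.0 - np.cos(2 * np.pi * t / period_beats + phase0))
    s = np.clip(s + 0.06 * rng.standard_normal(num_interleaves), 0.0, 1.0)
    if s.max() > 0:
        s = s / s.max() * 0.95
    ref = int(np.argmin(s))
    s = s - s[ref]

    ux, uy = anisotropy, np.sqrt(1.0 - anisotropy**2)
    wobble = 0.05 * rng.standard_normal(num_interleaves)
    dx = max_amp_mm * s * (ux + wobble)
    dy = max_amp_mm * s * uy
    dx[ref] = dy[ref] = 0.0
    mag = np.hypot(dx, dy)
    peak = mag.max()
    if peak > max_amp_mm and peak > 0:
        f = max_amp_mm / peak
        dx, dy = dx * f, dy * f
    return MotionTrace(dx_mm=dx, dy_mm=dy, pixel_mm=pixel_mm, reference_index=ref)


def _sensitivity_maps(matrix: int, coils: int) -> np.ndarray:
    """Smooth synthetic coil sensitivities (complex, approx unit RSS)."""
    yy, xx = np.mgrid[0:matrix, 0:matrix].astype(float)
    c = matrix / 2
    maps = np.empty((coils, matrix, matrix), dtype=complex)
    for k in range(coils):
        ang = 2 * np.pi * k / coils
        cx = c + 0.55 * matrix * np.cos(ang)
        cy = c + 0.55 * matrix * np.sin(ang)
        mag = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * (0.5 * matrix) ** 2))
        ph = 2 * np.pi * 0.1 * ((xx - c) * np.cos(ang) + (yy - c) * np.sin(ang)) / matrix
        maps[k] = mag * np.exp(1j * ph)
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    return maps / np.maximum(rss, 1e-12)


def simulate_acquisition(
    phantom: Phantom,
    traj: RadialTrajectory,
    trace: MotionTrace,
    noise_sd: float = 0.0,
    coils: int = 1,
    seed: int = 0,
    confounder_trace: MotionTrace | None = None,
) -> KSpaceData:
    """Motion-corrupted interleaved radial k-space of the phantom.

    Each interleave's samples are taken from the static forward model and
    multiplied by the conjugate of the correction ramp for that
    interleave's displacement; complex Gaussian noise of ``noise_sd`` per
    sample is added afterwards.
    """
    if len(trace) != traj.num_interleaves:
        raise ValueError(
            f"trace length {len(trace)} != interleave count {traj.num_interleaves}"
        )
    if phantom.confounder is None and confounder_trace is not None:
        raise ValueError("confounder trace given but phantom has no confounder")
    rng = np.random.default_rng(seed)
    n = phantom.matrix
    maps = _sensitivity_maps(n, coils) if coils > 1 else np.ones((1, n, n))

    # mm -> nominal trajectory pixels
    dx_px = trace.dx_mm / traj.pixel_mm
    dy_px = trace.dy_mm / traj.pixel_mm

    def corrupt(y_static: np.ndarray, dxp: np.ndarray, dyp: np.ndarray) -> np.ndarray:
        y = y_static.copy()
        for m in range(traj.num_interleaves):
            if dxp[m] == 0 and dyp[m] == 0:
                continue
            for p in traj.projections_of(m):
                ramp = phase_ramp(traj, int(p), dxp[m], dyp[m])
                y[p, :] *= np.exp(-1j * ramp.phase)
        return y

    samples = np.empty(
        (maps.shape[0], traj.num_projections, traj.samples_per_readout),
        dtype=complex,
    )
    for ch in range(maps.shape[0]):
        base = nufft_forward((maps[ch] * phantom.image).astype(complex), traj)
        samples[ch] = corrupt(base, dx_px, dy_px)
        if phantom.confounder is not None:
            conf = nufft_forward((maps[ch] * phantom.confounder).astype(complex), traj)
            if confounder_trace is not None:
                conf = corrupt(
                    conf,
                    confounder_trace.dx_mm / traj.pixel_mm,
                    confounder_trace.dy_mm / traj.pixel_mm,
                )
            samples[ch] += conf
    if noise_sd > 0:
        samples += noise_sd * (
            rng.standard_normal(samples.shape) + 1j * rng.standard_normal(samples.shape)
        )
    return KSpaceData(samples=samples, trajectory=traj, noise_sd=noise_sd or None)


def noise_for_snr(
    phantom: Phantom, traj: RadialTrajectory, target_snr: float = 40.0
) -> float:
    """Noise level giving the full gridded image roughly the target SNR.

    SNR is measured as blood-ROI mean over noise-ROI standard deviation on
    the magnitude image.  Uses a single unit-noise gridding reconstruction
    to calibrate the linear response.
    """
    static = simulate_acquisition(
        phantom,
        traj,
        MotionTrace(
            dx_mm=np.zeros(traj.num_interleaves),
            dy_mm=np.zeros(traj.num_interleaves),
            pixel_mm=traj.pixel_mm,
        ),
    )
    img = gridding_reconstruct(static).pixels
    blood = phantom.registry["blood_roi"]
    yy, xx = np.mgrid[0 : phantom.matrix, 0 : phantom.matrix]
    bx, by = blood["center"]
    sel = np.hypot(xx - bx, yy - by) <= blood["radius"]
    signal = float(np.mean(img[sel]))

    rng = np.random.default_rng(12345)
    noise = rng.standard_normal(static.samples.shape) + 1j * rng.standard_normal(
        static.samples.shape
    )
    noise_img = np.abs(
        gridding_reconstruct(
            KSpaceData(samples=noise, trajectory=traj), magnitude=True
        ).pixels
    )
    nr = phantom.registry["noise_roi"]
    r0, c0 = nr["corner"]
    sd_unit = float(np.std(noise_img[r0 : r0 + nr["size"], c0 : c0 + nr["size"]]))
    return signal / (target_snr * sd_unit)
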