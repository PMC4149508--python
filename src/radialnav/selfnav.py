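"""Per-interleave 2D translational motion estimation by masked registration.

Sub-images are registered to a reference sub-image by minimizing the mean
squared error inside an ellipsoidal region of interest.  Registration runs
on magnitude images normalized to unit maximum; a coarse exhaustive search
over integer shifts precedes a fixed-step gradient descent with step
halving.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .recon import SubImage

__all__ = [
    "ROIMask",
    "MotionTrace",
    "RegistrationOptions",
    "make_ellipse_mask",
    "masked_mse",
    "translate_image",
    "register_translation",
    "extract_motion",
    "si_component",
]


@dataclass
class ROIMask:
    """Binary ellipsoidal region of interest: 1 inside, 0 elsewhere."""

    grid: np.ndarray
    center: tuple[float, float]  # (cx, cy) in pixels (column, row)
    semiaxes: tuple[float, float]  # (a, b) in pixels

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if not np.all((self.grid == 0) | (self.grid == 1)):
            raise ValueError("mask values must be exactly 0 or 1")
        if not np.any(self.grid):
            raise ValueError("mask has no nonzero pixels")

    @property
    def indices(self) -> np.ndarray:
        return self.grid.astype(bool)


@dataclass
class MotionTrace:
    """Per-interleave in-plane displacement relative to a reference interleave.

    ``dx_mm``/``dy_mm`` are arrays of length ``num_interleaves``; the entry at
    ``reference_index`` is exactly (0, 0).  ``pixel_mm`` converts to pixels.
    """

    dx_mm: np.ndarray
    dy_mm: np.ndarray
    pixel_mm: float
    reference_index: int = 0
    si_mm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dx_mm = np.asarray(self.dx_mm, dtype=float)
        self.dy_mm = np.asarray(self.dy_mm, dtype=float)
        if self.dx_mm.shape != self.dy_mm.shape or self.dx_mm.ndim != 1:
            raise ValueError("dx_mm and dy_mm must be equal-length 1D arrays")
        if not 0 <= self.reference_index < len(self.dx_mm):
            raise ValueError("reference_index out of range")

    def __len__(self) -> int:
        return len(self.dx_mm)

    @property
    def dx_px(self) -> np.ndarray:
        return self.dx_mm / self.pixel_mm

    @property
    def dy_px(self) -> np.ndarray:
        return self.dy_mm / self.pixel_mm

    @property
    def magnitude_mm(self) -> np.ndarray:
        return np.hypot(self.dx_mm, self.dy_mm)

    def to_text(self, path) -> None:
        """Export as delimited text: interleave, dx_mm, dy_mm, si_mm."""
        si = self.si_mm if self.si_mm is not None else np.full(len(self), np.nan)
        rows = np.column_stack([np.arange(len(self)), self.dx_mm, self.dy_mm, si])
        np.savetxt(
            path,
            rows,
            fmt=["%d", "%.6f", "%.6f", "%.6f"],
            header="interleave\tdx_mm\tdy_mm\tsi_mm",
            delimiter="\t",
            comments="",
        )


@dataclass
class RegistrationOptions:
    """Registration optimizer constants.

    ``smooth_px`` Gaussian-smooths both magnitude images before the cost is
    evaluated, a standard pyramid-style stabilization against noise in the
    heavily undersampled sub-images.
    """

    coarse_range: int = 8
    init_step: float = 1.0
    min_step: float = 0.01
    max_steps: int = 200
    grad_delta: float = 0.05
    smooth_px: float = 0.5


def make_ellipse_mask(
    matrix: int,
    center: tuple[float, float],
    semiaxes: tuple[float, float],
) -> ROIMask:
    """Binary mask: pixel (r, c) is 1 iff ((c-cx)/a)^2 + ((r-cy)/b)^2 <= 1."""
    cx, cy = center
    a, b = semiaxes
    if a <= 0 or b <= 0:
        raise ValueError("semiaxes must be positive")
    r = np.arange(matrix)[:, None]
    c = np.arange(matrix)[None, :]
    grid = (((c - cx) / a) ** 2 + ((r - cy) / b) ** 2 <= 1.0).astype(np.uint8)
    if not np.any(grid):
        raise ValueError("ellipse does not intersect the image grid")
    return ROIMask(grid=grid, center=(cx, cy), semiaxes=(a, b))


def masked_mse(a: np.ndarray, b: np.ndarray, mask: ROIMask) -> float:
    """Mean squared magnitude difference over mask==1 pixels only."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.shape != mask.grid.shape:
        raise ValueError("image/mask shapes do not match")
    idx = mask.indices
    return float(np.mean(np.abs(a[idx] - b[idx]) ** 2))


def translate_image(
    image: np.ndarray, dx: float, dy: float
) -> tuple[np.ndarray, np.ndarray]:
    """Shift image content by (+dx, +dy) pixels with bilinear interpolation.

    Returns the shifted image (out-of-frame pixels set to 0) and a boolean
    validity map marking pixels sampled from inside the original frame.
    """
    image = np.asarray(image)
    n_r, n_c = image.shape
    r = np.arange(n_r)[:, None] - dy
    c = np.arange(n_c)[None, :] - dx
    rr = np.broadcast_to(r, image.shape)
    cc = np.broadcast_to(c, image.shape)
    out = map_coordinates(image, [rr, cc], order=1, mode="constant", cval=0.0)
    valid = (rr >= 0) & (rr <= n_r - 1) & (cc >= 0) & (cc <= n_c - 1)
    return out, valid


def _cost(
    moving: np.ndarray, reference: np.ndarray, mask_idx: np.ndarray, d: np.ndarray
) -> float:
    shifted, valid = translate_image(moving, d[0], d[1])
    sel = mask_idx & valid
    if not np.any(sel):
        return np.inf
    return float(np.mean(np.abs(shifted[sel] - reference[sel]) ** 2))


def register_translation(
    moving: SubImage | np.ndarray,
    reference: SubImage | np.ndarray,
    mask: ROIMask,
    opts: RegistrationOptions | None = None,
) -> tuple[float, float]:
    """Displacement (dx, dy) of ``moving`` relative to ``reference``, pixels.

    Internally minimizes the masked MSE between the back-translated moving
    image and the reference (bilinear interpolation, out-of-frame pixels
    excluded from the cost); the returned value is the detected content
    displacement, i.e. ``moving ~= translate(reference, (dx, dy))``.
    """
    opts = opts or RegistrationOptions()
    mov = np.abs(moving.pixels if isinstance(moving, SubImage) else moving)
    ref = np.abs(reference.pixels if isinstance(reference, SubImage) else reference)
    if mov.shape != ref.shape:
        raise ValueError("moving/reference shapes do not match")
    mov = mov / (mov.max() or 1.0)
    ref = ref / (ref.max() or 1.0)
    if opts.smooth_px > 0:
        mov = gaussian_filter(mov, opts.smooth_px)
        ref = gaussian_filter(ref, opts.smooth_px)
    idx = mask.indices

    # coarse exhaustive search over integer shifts
    best_d = np.zeros(2)
    best_c = _cost(mov, ref, idx, best_d)
    rng = range(-opts.coarse_range, opts.coarse_range + 1)
    for sx in rng:
        for sy in rng:
            d = np.array([sx, sy], dtype=float)
            c = _cost(mov, ref, idx, d)
            if c < best_c:
                best_c, best_d = c, d

    # fixed-step gradient descent with step halving
    step = opts.init_step
    d = best_d.copy()
    cost = best_c
    h = opts.grad_delta
    for _ in range(opts.max_steps):
        if not np.isfinite(cost):
            raise RuntimeError("registration cost is non-finite")
        g = np.array(
            [
                _cost(mov, ref, idx, d + [h, 0]) - _cost(mov, ref, idx, d - [h, 0]),
                _cost(mov, ref, idx, d + [0, h]) - _cost(mov, ref, idx, d - [0, h]),
            ]
        ) / (2 * h)
        gn = np.linalg.norm(g)
        if gn == 0:
            break
        trial = d - step * g / gn
        c = _cost(mov, ref, idx, trial)
        if c < cost:
            d, cost = trial, c
        else:
            step *= 0.5
            if step < opts.min_step:
                break
    return float(-d[0]), float(-d[1])


def extract_motion(
    sub_images: list[SubImage],
    mask: ROIMask,
    reference_index: int = 0,
    opts: RegistrationOptions | None = None,
) -> MotionTrace:
    """Register every sub-image to the reference and assemble the trace."""
    if len(sub_images) < 2:
        raise ValueError("need at least 2 sub-images")
    shapes = {s.pixels.shape for s in sub_images}
    if len(shapes) != 1:
        raise ValueError("sub-images must share a common shape")
    if not 0 <= reference_index < len(sub_images):
        raise ValueError("reference_index out of range")
    ref = sub_images[reference_index]
    pixel_mm = ref.pixel_mm
    dx = np.zeros(len(sub_images))
    dy = np.zeros(len(sub_images))
    for i, sub in enumerate(sub_images):
        if i == reference_index:
            continue
        try:
            sx, sy = register_translation(sub, ref, mask, opts)
        except Exception as exc:  # annotate with interleave context
            raise RuntimeError(f"registration failed for interleave {i}: {exc}")
        dx[i], dy[i] = sx, sy
    return MotionTrace(
        dx_mm=dx * pixel_mm,
        dy_mm=dy * pixel_mm,
        pixel_mm=pixel_mm,
        reference_index=reference_index,
    )


def si_component(trace: MotionTrace, orientation: np.ndarray) -> np.ndarray:
    """Superior-inferior component of the in-plane displacements, in mm.

    ``orientation`` is the 3x3 rotation mapping patient coordinates to slice
    coordinates; in-plane displacements ``(dx, dy, 0)`` are carried through
    its inverse (transpose) and the patient z-component is returned.
    """
    R = np.asarray(orientation, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
        raise ValueError("orientation must be an orthonormal 3x3 matrix")
    v = np.stack([trace.dx_mm, trace.dy_mm, np.zeros(len(trace))])
    return (R.T @ v)[2]
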