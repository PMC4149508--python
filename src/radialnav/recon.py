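"""Linear (gridding) and TV-regularized reconstruction from radial k-space.

The non-uniform Fourier operator uses the convention

    y(f) = sum_p x(p) * exp(+2j*pi * f . p)

with pixel coordinates ``p`` centered on the matrix midpoint and sample
frequencies ``f`` in cycles per pixel.  It is implemented as Kaiser-Bessel
gridding on a 2x oversampled grid; forward and adjoint share the same
sparse interpolator and are exact algebraic transposes of each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from numpy.fft import fft2, fftshift, ifft2, ifftshift
from scipy.special import i0

from .trajectory import RadialTrajectory, density_weights

__all__ = [
    "KSpaceData",
    "SubImage",
    "ReconParams",
    "nufft_forward",
    "nufft_adjoint",
    "gridding_reconstruct",
    "tv_value",
    "cs_reconstruct",
]

_OVERSAMPLING = 2
_KERNEL_WIDTH = 12


@dataclass
class KSpaceData:
    """Complex radial samples bound to a trajectory.

    ``samples`` has shape ``(channels, P, N)``.
    """

    samples: np.ndarray
    trajectory: RadialTrajectory
    noise_sd: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.samples.ndim == 2:  # (P, N) -> single channel
            self.samples = self.samples[None]
        if self.samples.ndim != 3:
            raise ValueError("samples must have shape (channels, P, N)")
        t = self.trajectory
        if self.samples.shape[-2:] != (t.num_projections, t.samples_per_readout):
            raise ValueError(
                f"sample shape {self.samples.shape} does not match trajectory "
                f"({t.num_projections} x {t.samples_per_readout})"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("k-space samples contain non-finite values")

    @property
    def num_channels(self) -> int:
        return self.samples.shape[0]


@dataclass
class SubImage:
    """A per-interleave reconstruction (or a final combined image)."""

    pixels: np.ndarray
    interleave_id: int
    method: str  # "LN" or "CS"
    pixel_mm: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("sub-image must be a square 2D grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("sub-image contains non-finite values")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.pixels)


@dataclass
class ReconParams:
    """Parameters of the TV-regularized solve.

    ``lam`` weighs the TV prior against the data-fit term after the
    normalization described in :func:`cs_reconstruct`.
    """

    lam: float = 1e-5
    max_iters: int = 100
    tol: float = 1e-5
    tv_eps: float = 0.0
    step: float | str = "auto"
    tv_inner_iters: int = 20

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.tol < 0:
            raise ValueError("tol must be >= 0")


# ----------------------------------------------------------------------------
# NUFFT plan


def _kb_kernel(d: np.ndarray, width: int, beta: float) -> np.ndarray:
    """Kaiser-Bessel interpolation kernel sampled at grid offsets d."""
    u = 2.0 * d / width
    out = np.zeros_like(d, dtype=float)
    inside = np.abs(u) <= 1.0
    out[inside] = i0(beta * np.sqrt(1.0 - u[inside] ** 2)) / i0(beta)
    return out


class NufftPlan:
    """Precomputed gridding interpolator for a fixed set of k-space coords."""

    def __init__(self, coords: np.ndarray, matrix: int):
        coords = np.asarray(coords, dtype=float).reshape(-1, 2)
        n = int(matrix)
        G = _OVERSAMPLING * n
        w = min(_KERNEL_WIDTH, G)
        # Beatty's beta for the chosen width/oversampling
        beta = np.pi * np.sqrt(
            (w / _OVERSAMPLING) ** 2 * (_OVERSAMPLING - 0.5) ** 2 - 0.8
        )
        self.n, self.G, self.num_samples = n, G, coords.shape[0]

        # sample position on the oversampled grid
        c = coords * G + G / 2  # (K, 2)
        j0 = np.floor(c - w / 2).astype(np.int64) + 1  # first neighbor
        offs = np.arange(w)
        rows = np.repeat(np.arange(self.num_samples, dtype=np.int64), w * w)
        jx = j0[:, 0, None] + offs[None, :]  # (K, w)
        jy = j0[:, 1, None] + offs[None, :]
        wx = _kb_kernel(jx - c[:, 0, None], w, beta)
        wy = _kb_kernel(jy - c[:, 1, None], w, beta)
        # image axis 0 is y (rows), axis 1 is x (cols): ky strides by G
        vals = (wy[:, :, None] * wx[:, None, :]).reshape(-1)
        cols = (
            (np.mod(jy, G)[:, :, None] * G + np.mod(jx, G)[:, None, :])
        ).reshape(-1)
        self._interp = sp.csr_matrix(
            (vals, (rows, cols)), shape=(self.num_samples, G * G)
        )
        self._interp_t = self._interp.T.tocsr()

        # deapodization: inverse DFT of the gridding kernel on the os grid
        line = _kb_kernel(
            np.minimum(np.arange(G), G - np.arange(G)).astype(float), w, beta
        )
        q = fftshift(np.fft.fft(line).real)  # symmetric & real
        lo = G // 2 - n // 2
        self._deapod = 1.0 / np.outer(q[lo : lo + n], q[lo : lo + n])
        self._lipschitz: float | None = None

    def forward(self, image: np.ndarray) -> np.ndarray:
        """Evaluate sum_p x(p) exp(+2j pi f.p) at every planned sample."""
        if image.shape != (self.n, self.n):
            raise ValueError(f"image shape {image.shape} != ({self.n}, {self.n})")
        G, n = self.G, self.n
        xa = image * self._deapod
        pad = np.zeros((G, G), dtype=complex)
        lo = G // 2 - n // 2
        pad[lo : lo + n, lo : lo + n] = xa
        spec = fftshift(ifft2(ifftshift(pad))) * (G * G)
        return self._interp @ spec.ravel()

    def adjoint(self, samples: np.ndarray) -> np.ndarray:
        """Exact transpose of :meth:`forward`."""
        samples = np.asarray(samples, dtype=complex).ravel()
        if samples.size != self.num_samples:
            raise ValueError(
                f"sample vector length {samples.size} != {self.num_samples}"
            )
        G, n = self.G, self.n
        z = (self._interp_t @ samples).reshape(G, G)
        pad = fftshift(fft2(ifftshift(z)))
        lo = G // 2 - n // 2
        return pad[lo : lo + n, lo : lo + n] * self._deapod

    def lipschitz(self, iters: int = 20, seed: int = 0) -> float:
        """2 * largest eigenvalue of F^H F, by power iteration (cached)."""
        if self._lipschitz is None:
            rng = np.random.default_rng(seed)
            x = rng.standard_normal((self.n, self.n)) + 1j * rng.standard_normal(
                (self.n, self.n)
            )
            lam = 1.0
            for _ in range(iters):
                x = self.adjoint(self.forward(x))
                lam = np.linalg.norm(x)
                x /= lam
            self._lipschitz = 2.0 * float(lam)
        return self._lipschitz


_PLAN_CACHE: dict[tuple, NufftPlan] = {}
_PLAN_CACHE_MAX = 32


def get_plan(
    traj: RadialTrajectory, matrix: int, projections: np.ndarray | None = None
) -> NufftPlan:
    """Fetch (or build) the gridding plan for a trajectory subset."""
    key = (
        traj.token,
        int(matrix),
        None if projections is None else tuple(np.asarray(projections).tolist()),
    )
    plan = _PLAN_CACHE.get(key)
    if plan is None:
        coords = traj.coords if projections is None else traj.coords[projections]
        plan = NufftPlan(coords, matrix)
        if len(_PLAN_CACHE) >= _PLAN_CACHE_MAX:
            _PLAN_CACHE.pop(next(iter(_PLAN_CACHE)))
        _PLAN_CACHE[key] = plan
    return plan


def nufft_forward(
    image: np.ndarray, traj: RadialTrajectory, projections: np.ndarray | None = None
) -> np.ndarray:
    """k-space coefficients of ``image`` at the trajectory samples.

    Returns an array of shape ``(P_eff, N)``.
    """
    image = np.asarray(image)
    plan = get_plan(traj, image.shape[0], projections)
    return plan.forward(image.astype(complex)).reshape(
        -1, traj.samples_per_readout
    )


def nufft_adjoint(
    samples: np.ndarray,
    traj: RadialTrajectory,
    matrix: int,
    projections: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Adjoint operator ``F^H (W y)``; the gridding backbone with ramp weights."""
    samples = np.asarray(samples, dtype=complex)
    if weights is not None:
        samples = samples * weights
    plan = get_plan(traj, matrix, projections)
    return plan.adjoint(samples.ravel())


# ----------------------------------------------------------------------------
# Gridding reconstruction


def gridding_reconstruct(
    data: KSpaceData,
    interleave: int | None = None,
    matrix: int | None = None,
    magnitude: bool = True,
) -> SubImage:
    """Density-compensated gridding; root-sum-of-squares across channels.

    With ``interleave`` given, only that interleave's projections are used
    (the linear self-navigation sub-image); otherwise all projections.
    """
    traj = data.trajectory
    n = traj.samples_per_readout if matrix is None else int(matrix)
    if interleave is None:
        projections = None
        sub = data.samples
        w = density_weights(traj)
    else:
        projections = traj.projections_of(interleave)
        if projections.size == 0:
            raise ValueError(f"interleave {interleave} selects no projections")
        sub = data.samples[:, projections]
        w = density_weights(traj, projections)

    chans = [
        nufft_adjoint(sub[c], traj, n, projections, weights=w)
        for c in range(data.num_channels)
    ]
    if data.num_channels == 1:
        pixels = chans[0] if not magnitude else np.abs(chans[0])
    else:
        pixels = np.sqrt(np.sum([np.abs(c) ** 2 for c in chans], axis=0))
    return SubImage(
        pixels=pixels,
        interleave_id=-1 if interleave is None else interleave,
        method="LN",
        pixel_mm=traj.fov_mm / n,
    )


# ----------------------------------------------------------------------------
# Total variation


def _grad(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward differences with replicate boundary (zero at last row/col)."""
    gx = np.zeros_like(x)
    gy = np.zeros_like(x)
    gx[:, :-1] = x[:, 1:] - x[:, :-1]
    gy[:-1, :] = x[1:, :] - x[:-1, :]
    return gx, gy


def _div(px: np.ndarray, py: np.ndarray) -> np.ndarray:
    """Negative adjoint of :func:`_grad`: <grad x, p> = <x, -div p>."""
    d = np.zeros_like(px)
    d[:, 0] += px[:, 0]
    d[:, 1:-1] += px[:, 1:-1] - px[:, :-2]
    d[:, -1] += -px[:, -2]
    dy = np.zeros_like(py)
    dy[0, :] += py[0, :]
    dy[1:-1, :] += py[1:-1, :] - py[:-2, :]
    dy[-1, :] += -py[-2, :]
    return d + dy


def tv_value(image: np.ndarray, eps: float = 0.0) -> float:
    """Isotropic total variation: sum of gradient magnitudes."""
    gx, gy = _grad(np.asarray(image))
    mag = np.sqrt(np.abs(gx) ** 2 + np.abs(gy) ** 2 + eps**2)
    return float(np.sum(mag))


def _tv_prox(v: np.ndarray, gamma: float, iters: int = 20) -> np.ndarray:
    """prox_{gamma * TV}(v) by Chambolle's dual projection (complex-safe)."""
    if gamma <= 0:
        return v
    px = np.zeros_like(v)
    py = np.zeros_like(v)
    tau = 0.249
    for _ in range(iters):
        u = _div(px, py) - v / gamma
        gx, gy = _grad(u)
        denom = 1.0 + tau * np.sqrt(np.abs(gx) ** 2 + np.abs(gy) ** 2)
        px = (px + tau * gx) / denom
        py = (py + tau * gy) / denom
    return v - gamma * _div(px, py)


# ----------------------------------------------------------------------------
# TV-regularized reconstruction


class DivergenceError(RuntimeError):
    """Raised when the iterative solve blows past 10x its initial objective."""


def _fista_tv(
    y: np.ndarray, plan: NufftPlan, params: ReconParams
) -> tuple[np.ndarray, list[float]]:
    """Minimize ||y - F x||_2^2 + lam * TV(x) with accelerated prox-gradient.

    Returns the best iterate seen (objective never above the zero-image
    objective) together with the objective trajectory.
    """
    lam = params.lam
    L = plan.lipschitz() if params.step == "auto" else 2.0 / float(params.step)
    step = 1.0 / L

    def objective(x: np.ndarray, fx: np.ndarray) -> float:
        return float(np.sum(np.abs(y - fx) ** 2) + lam * tv_value(x, params.tv_eps))

    n = plan.n
    x = np.zeros((n, n), dtype=complex)
    z = x
    t = 1.0
    obj0 = objective(x, np.zeros_like(y))
    best_x, best_obj = x, obj0
    history = [obj0]
    prev = obj0
    for _ in range(params.max_iters):
        grad = 2.0 * plan.adjoint(plan.forward(z) - y)
        x_new = _tv_prox(z - step * grad, step * lam, params.tv_inner_iters)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = x_new + ((t - 1.0) / t_new) * (x_new - x)
        x, t = x_new, t_new
        obj = objective(x, plan.forward(x))
        history.append(obj)
        if obj > 10.0 * obj0:
            raise DivergenceError(
                f"objective {obj:.3e} exceeds 10x initial {obj0:.3e}"
            )
        if obj < best_obj:
            best_x, best_obj = x, obj
        if prev > 0 and abs(prev - obj) / max(prev, 1e-30) < params.tol:
            break
        prev = obj
    return best_x, history


def cs_reconstruct(
    data: KSpaceData,
    interleave: int,
    params: ReconParams | None = None,
    matrix: int | None = None,
) -> SubImage:
    """TV-regularized sub-image reconstruction of one interleave.

    The k-space data are normalized so the zero-filled gridding sub-image
    of the interleave has unit maximum magnitude, and the Fourier operator
    is normalized to unit spectral norm; ``params.lam`` applies to the
    functional ``||y - F x||^2 + lam * TV(x)`` in that scale.  Channels are
    solved independently and combined by root-sum-of-squares.
    """
    params = params or ReconParams()
    traj = data.trajectory
    n = traj.samples_per_readout if matrix is None else int(matrix)
    projections = traj.projections_of(interleave)
    if projections.size == 0:
        raise ValueError(f"interleave {interleave} selects no projections")
    plan = get_plan(traj, n, projections)

    grid = gridding_reconstruct(data, interleave, matrix=n, magnitude=True)
    scale = float(np.max(grid.pixels))
    if scale == 0:
        scale = 1.0
    op_norm = np.sqrt(plan.lipschitz() / 2.0)

    recons = []
    for c in range(data.num_channels):
        y = data.samples[c, projections].ravel() / (scale * op_norm)
        sol, _ = _fista_tv_scaled(y, plan, params, op_norm)
        recons.append(sol * scale)
    if data.num_channels == 1:
        pixels = recons[0]
    else:
        pixels = np.sqrt(np.sum([np.abs(r) ** 2 for r in recons], axis=0))
    return SubImage(
        pixels=pixels,
        interleave_id=interleave,
        method="CS",
        pixel_mm=traj.fov_mm / n,
    )


class _ScaledPlan:
    """View of a plan with the operator divided by a constant."""

    def __init__(self, plan: NufftPlan, s: float):
        self._plan, self._s, self.n = plan, s, plan.n

    def forward(self, x):
        return self._plan.forward(x) / self._s

    def adjoint(self, y):
        return self._plan.adjoint(y) / self._s

    def lipschitz(self):
        return self._plan.lipschitz() / self._s**2


def _fista_tv_scaled(y, plan, params, op_norm):
    return _fista_tv(y, _ScaledPlan(plan, op_norm), params)
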