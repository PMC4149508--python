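"""Interleaved 2D radial sampling patterns and density-compensation weights.

Conventions
-----------
k-space coordinates are expressed in cycles per pixel, each component in
``[-0.5, 0.5)``.  Readout sample ``k`` (``k = 0..N-1``) sits at signed radius
``(k - N/2) / N``, so the readout center is sample index ``N/2``.  Image
coordinates are in pixels with the origin at the matrix center (index
``n // 2``).
"""

from __future__ import annotations

import uuid
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RadialTrajectory",
    "make_interleaved_radial",
    "density_weights",
    "undersampling_fraction",
]


@dataclass(frozen=True, eq=False)
class RadialTrajectory:
    """An interleaved 2D radial sampling pattern.

    Attributes
    ----------
    num_projections : int
        Total number of radial projections ``P``.
    num_interleaves : int
        Number of interleaves ``M`` (``M`` divides ``P``).
    samples_per_readout : int
        Samples per projection ``N`` (even).
    fov_mm : float
        Field of view in mm.
    angles : (P,) ndarray
        Azimuth per projection, radians in ``[0, pi)``.
    interleave_of : (P,) ndarray of int
        Interleave index per projection.
    coords : (P, N, 2) ndarray
        Per-sample k-space coordinates ``(kx, ky)`` in cycles per pixel.
    """

    num_projections: int
    num_interleaves: int
    samples_per_readout: int
    fov_mm: float
    angles: np.ndarray
    interleave_of: np.ndarray
    coords: np.ndarray
    # opaque identity token used to key NUFFT plan caches
    token: str = field(default_factory=lambda: uuid.uuid4().hex)

    @property
    def projections_per_interleave(self) -> int:
        return self.num_projections // self.num_interleaves

    @property
    def pixel_mm(self) -> float:
        """Nominal pixel size, fov / N (matrix == samples_per_readout)."""
        return self.fov_mm / self.samples_per_readout

    def projections_of(self, interleave: int) -> np.ndarray:
        """Indices of the projections belonging to one interleave."""
        if not 0 <= interleave < self.num_interleaves:
            raise IndexError(
                f"interleave {interleave} out of range [0, {self.num_interleaves})"
            )
        return np.flatnonzero(self.interleave_of == interleave)


def _bit_reversed(n: int) -> np.ndarray:
    """Bit-reversal permutation of 0..n-1 (n need not be a power of two)."""
    bits = max(1, int(np.ceil(np.log2(n))))
    rev = [int(f"{i:0{bits}b}"[::-1], 2) for i in range(2**bits)]
    return np.array(sorted(range(n), key=lambda i: rev[i]), dtype=int)


def make_interleaved_radial(
    num_projections: int,
    num_interleaves: int,
    samples_per_readout: int,
    fov_mm: float,
    bit_reversed_interleaves: bool = False,
) -> RadialTrajectory:
    """Build an interleaved radial trajectory.

    The global angle set is ``{j*pi/P : j = 0..P-1}``.  Interleave ``m``
    receives the angles ``{m*pi/P + i*M*pi/P : i = 0..P/M-1}``: each
    interleave covers ``[0, pi)`` uniformly with spacing ``M*pi/P`` and a
    per-interleave offset ``m*pi/P``.

    Parameters
    ----------
    bit_reversed_interleaves : bool
        If true, interleave offsets are assigned in bit-reversed order
        instead of sequentially.
    """
    P, M, N = num_projections, num_interleaves, samples_per_readout
    if P <= 0 or M <= 0 or N <= 0:
        raise ValueError("projection/interleave/sample counts must be positive")
    if P % M != 0:
        raise ValueError(
            f"num_projections ({P}) must be divisible by num_interleaves ({M})"
        )
    if N % 2 != 0:
        raise ValueError(f"samples_per_readout ({N}) must be even")
    if fov_mm <= 0:
        raise ValueError("fov_mm must be positive")

    per = P // M
    offsets = _bit_reversed(M) if bit_reversed_interleaves else np.arange(M)
    angles = np.empty(P)
    interleave_of = np.empty(P, dtype=int)
    for m in range(M):
        sl = slice(m * per, (m + 1) * per)
        angles[sl] = offsets[m] * np.pi / P + np.arange(per) * M * np.pi / P
        interleave_of[sl] = m

    radius = (np.arange(N) - N // 2) / N  # cycles per pixel
    coords = np.empty((P, N, 2))
    coords[..., 0] = radius[None, :] * np.cos(angles)[:, None]
    coords[..., 1] = radius[None, :] * np.sin(angles)[:, None]

    return RadialTrajectory(
        num_projections=P,
        num_interleaves=M,
        samples_per_readout=N,
        fov_mm=float(fov_mm),
        angles=angles,
        interleave_of=interleave_of,
        coords=coords,
    )


def density_weights(
    traj: RadialTrajectory, projections: np.ndarray | None = None
) -> np.ndarray:
    """Ramp density-compensation weights for a (subset of a) trajectory.

    Each sample is weighted by the area of its annular wedge in k-space.
    With ``P_eff`` sampled projections, the half-lines are ``pi/P_eff``
    apart in azimuth; the sample at radial index ``m`` owns the wedge
    between radii ``(|m|-1/2)/N`` and ``(|m|+1/2)/N``, giving the ramp
    ``pi*|m| / (P_eff * N^2)``.  The outermost sample of each half-line
    owns its wedge out to the boundary of the ``[-0.5, 0.5)^2`` k-space
    square, and the ``P_eff`` coincident center samples share the analytic
    center disc ``pi/(4 N^2)``, i.e. ``pi/(4 P_eff N^2)`` each.  The
    weights therefore tile the unit k-space square: they sum to 1, so a
    fully sampled acquisition reconstructs a unit delta with unit peak.

    Returns
    -------
    (P_eff, N) ndarray of nonnegative weights, rows ordered like
    ``projections`` (all projections when omitted).
    """
    N = traj.samples_per_readout
    if projections is None:
        projections = np.arange(traj.num_projections)
    projections = np.asarray(projections)
    if projections.size == 0:
        raise ValueError("empty projection subset")
    p_eff = projections.size

    m = np.arange(N) - N // 2  # signed radial index
    theta = traj.angles[projections]  # (P_eff,)
    w = np.empty((p_eff, N))

    absm = np.abs(m).astype(float)
    ring = np.pi * absm / (p_eff * N**2)
    w[:] = ring[None, :]
    w[:, N // 2] = np.pi / (4 * p_eff * N**2)

    # outermost sample per half-line: extend the wedge to the square edge,
    # integrating the square-boundary radius over the wedge's azimuth span
    # so that the wedges tile the k-space square exactly (sum of w == 1)
    half = np.pi / (2 * p_eff)
    quad = np.linspace(-half, half, 33)[None, :]
    for k, sign in ((0, -1.0), (N - 1, 1.0)):
        phi = (theta if sign > 0 else theta + np.pi)[:, None] + quad
        r_edge = 0.5 / np.maximum(np.abs(np.cos(phi)), np.abs(np.sin(phi)))
        r_in = (absm[k] - 0.5) / N
        w[:, k] = 0.5 * np.trapezoid(r_edge**2 - r_in**2, quad, axis=1)
    return w


def undersampling_fraction(traj: RadialTrajectory) -> float:
    """Fraction of Nyquist sampling provided by a single interleave.

    Definition used here: full radial Nyquist at matrix ``N`` requires
    ``pi/2 * N`` uniformly spaced projections; one interleave supplies
    ``P/M`` of them, so the fraction is ``(P/M) / (pi/2 * N)``.
    """
    per = traj.projections_per_interleave
    return per / (np.pi / 2 * traj.samples_per_readout)
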