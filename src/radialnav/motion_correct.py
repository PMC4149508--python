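"""Per-interleave k-space phase correction and final image reconstruction.

A rigid in-plane displacement of the object multiplies each radial sample
by a linear phase; correcting an interleave applies the inverse phase ramp

    dbeta(k) = -2*pi * (k - N/2)/N * (dx*cos(theta) + dy*sin(theta))

so that ``exp(1j*dbeta)`` undoes a (+dx, +dy) pixel displacement under the
package's Fourier convention (see :mod:`radialnav.recon`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recon import KSpaceData, gridding_reconstruct
from .selfnav import MotionTrace
from .trajectory import RadialTrajectory

__all__ = [
    "PhaseRamp",
    "phase_ramp",
    "correct_interleave",
    "correct_and_reconstruct",
]


@dataclass
class PhaseRamp:
    """Per-sample correction phase (radians) for one projection."""

    phase: np.ndarray

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)


def phase_ramp(
    traj: RadialTrajectory, projection: int, dx_px: float, dy_px: float
) -> PhaseRamp:
    """Linear correction phase for one projection and a (+dx, +dy) shift."""
    if not (np.isfinite(dx_px) and np.isfinite(dy_px)):
        raise ValueError("displacement must be finite")
    if not 0 <= projection < traj.num_projections:
        raise IndexError(f"projection {projection} out of range")
    N = traj.samples_per_readout
    theta = traj.angles[projection]
    radius = (np.arange(N) - N // 2) / N
    phase = -2.0 * np.pi * radius * (dx_px * np.cos(theta) + dy_px * np.sin(theta))
    return PhaseRamp(phase=phase)


def correct_interleave(
    data: KSpaceData, interleave: int, dx_px: float, dy_px: float
) -> KSpaceData:
    """Apply the correction phase ramp to one interleave's projections.

    Returns a new :class:`KSpaceData`; all other interleaves are untouched.
    """
    traj = data.trajectory
    projections = traj.projections_of(interleave)
    samples = data.samples.copy()
    for p in projections:
        ramp = phase_ramp(traj, int(p), dx_px, dy_px)
        samples[:, p, :] *= np.exp(1j * ramp.phase)
    return KSpaceData(samples=samples, trajectory=traj, noise_sd=data.noise_sd)


def correct_and_reconstruct(
    data: KSpaceData,
    trace: MotionTrace,
    matrix: int | None = None,
) -> np.ndarray:
    """Correct every interleave with its trace entry, combine and grid.

    Per-channel gridding of the corrected k-space followed by
    root-sum-of-squares across channels; returns the final magnitude image.
    """
    traj = data.trajectory
    if len(trace) != traj.num_interleaves:
        raise ValueError(
            f"trace length {len(trace)} != interleave count {traj.num_interleaves}"
        )
    # the phase ramp lives on the trajectory's nominal pixel grid (fov/N);
    # the recon matrix only changes the output grid, not the physics
    traj_pixel_mm = traj.pixel_mm
    samples = data.samples.copy()
    radius = (np.arange(traj.samples_per_readout) - traj.samples_per_readout // 2) / (
        traj.samples_per_readout
    )
    dx_px = trace.dx_mm / traj_pixel_mm
    dy_px = trace.dy_mm / traj_pixel_mm
    for m in range(traj.num_interleaves):
        if dx_px[m] == 0 and dy_px[m] == 0:
            continue
        projections = traj.projections_of(m)
        theta = traj.angles[projections]
        proj_disp = dx_px[m] * np.cos(theta) + dy_px[m] * np.sin(theta)
        phase = -2.0 * np.pi * radius[None, :] * proj_disp[:, None]
        samples[:, projections, :] *= np.exp(1j * phase)[None]
    corrected = KSpaceData(samples=samples, trajectory=traj, noise_sd=data.noise_sd)
    return gridding_reconstruct(corrected, matrix=matrix).pixels
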