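"""Shared fixtures.

``standard_run`` performs the full desk-scale self-navigation experiment
(24 interleaves of 15 projections, matrix 160 at 1 mm pixels, displacements
drawn in 0-7 mm, SNR ~40) once per session; several acceptance properties
and module tests read from it.
"""

from __future__ import annotations

import numpy as np
import pytest

from radialnav import (
    MotionTrace,
    correct_and_reconstruct,
    cs_reconstruct,
    extract_motion,
    gridding_reconstruct,
    make_ellipse_mask,
    make_interleaved_radial,
    make_motion_trace,
    make_phantom,
    noise_for_snr,
    simulate_acquisition,
)
from radialnav.metrics import motion_error, vessel_sharpness
from radialnav.recon import ReconParams


def direct_dft_forward(image: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Brute-force evaluation of sum_p x(p) exp(+2j pi f.p) (test oracle)."""
    n = image.shape[0]
    px = np.arange(n) - n // 2
    flat = coords.reshape(-1, 2)
    out = np.empty(flat.shape[0], dtype=complex)
    for i, (kx, ky) in enumerate(flat):
        phase = np.exp(2j * np.pi * (kx * px[None, :] + ky * px[:, None]))
        out[i] = np.sum(image * phase)
    return out.reshape(coords.shape[:-1])


@pytest.fixture(scope="session")
def small_traj():
    return make_interleaved_radial(8, 2, 16, 64.0)


@pytest.fixture(scope="session")
def standard_run():
    n, fov = 160, 160.0
    px = fov / n
    params = ReconParams(max_iters=60, tv_inner_iters=10)

    traj = make_interleaved_radial(360, 24, n, fov)
    phantom = make_phantom(n, px, seed=11)
    truth = make_motion_trace(24, 7.0, seed=22, pixel_mm=px)
    noise_sd = noise_for_snr(phantom, traj, 40.0)
    data = simulate_acquisition(phantom, traj, truth, noise_sd=noise_sd, seed=33)
    static = simulate_acquisition(
        phantom, traj, make_motion_trace(24, 0.0, pixel_mm=px)
    )
    static_image = gridding_reconstruct(static).pixels

    hc = phantom.registry["heart_center"]
    ha = phantom.registry["heart_semiaxes"]
    mask = make_ellipse_mask(n, hc, ha)

    subs_ln = [gridding_reconstruct(data, m) for m in range(24)]
    subs_cs = [cs_reconstruct(data, m, params) for m in range(24)]

    def rebase(tr):
        r = tr.reference_index
        return MotionTrace(
            dx_mm=tr.dx_mm + truth.dx_mm[r] - tr.dx_mm[r],
            dy_mm=tr.dy_mm + truth.dy_mm[r] - tr.dy_mm[r],
            pixel_mm=px,
            reference_index=r,
        )

    trace_ln = rebase(extract_motion(subs_ln, mask, 0))
    trace_cs = rebase(extract_motion(subs_cs, mask, 0))
    zero = MotionTrace(dx_mm=np.zeros(24), dy_mm=np.zeros(24), pixel_mm=px)

    images = {
        "none": correct_and_reconstruct(data, zero),
        "LN": correct_and_reconstruct(data, trace_ln),
        "CS": correct_and_reconstruct(data, trace_cs),
        "oracle": correct_and_reconstruct(data, truth),
    }
    vs = {
        m: vessel_sharpness(img, phantom.vessel_centerline, px)
        for m, img in images.items()
    }
    err_ln = motion_error(trace_ln, truth)
    err_cs = motion_error(trace_cs, truth)

    return {
        "matrix": n,
        "pixel_mm": px,
        "trajectory": traj,
        "phantom": phantom,
        "truth": truth,
        "data": data,
        "static_image": static_image,
        "mask": mask,
        "subs_ln": subs_ln,
        "subs_cs": subs_cs,
        "trace_ln": trace_ln,
        "trace_cs": trace_cs,
        "images": images,
        "vessel_sharpness": vs,
        "motion_error_ln": err_ln,
        "motion_error_cs": err_cs,
    }
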