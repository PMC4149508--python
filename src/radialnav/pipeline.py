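"""Configuration, container I/O, and the end-to-end comparison runner.

A run simulates (or loads) motion-corrupted interleaved radial k-space,
then for each requested method builds sub-images, extracts a motion trace,
corrects k-space and reconstructs the final image, and evaluates image
quality.  Methods:

``none``
    No correction: gridding of the corrupted data as-is.
``LN`` / ``CS``
    Self-navigation with linearly / TV-reconstructed sub-images.
``oracle``
    Correction with the ground-truth trace.

Container schema (HDF5), one file per run:

================================  =======================================
dataset / group                   contents
================================  =======================================
``/config``                       JSON-encoded run configuration (attrs)
``/phantom/image``                static phantom image
``/phantom/vessel_centerline``    (K, 2) row/col points
``/trajectory/{angles,...}``      angles, interleave_of, coords + attrs
``/kspace/samples``               complex (C, P, N) array
``/truth_trace/{dx_mm,dy_mm}``    ground-truth displacements
``/mask/{center,semiaxes}``       suggested registration ROI
``/results/<method>/image``       final magnitude image
``/results/<method>/trace``       estimated (or used) trace
``/results/<method>/report``      JSON-encoded quality report (attr)
================================  =======================================
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import metrics as qm
from .motion_correct import correct_and_reconstruct
from .recon import KSpaceData, ReconParams, cs_reconstruct, gridding_reconstruct
from .selfnav import (
    MotionTrace,
    RegistrationOptions,
    extract_motion,
    make_ellipse_mask,
)
from .synthdata import (
    Phantom,
    make_motion_trace,
    make_phantom,
    noise_for_snr,
    simulate_acquisition,
)
from .trajectory import RadialTrajectory, make_interleaved_radial

logger = logging.getLogger("radialnav")

__all__ = [
    "RunConfig",
    "RunResult",
    "run_pipeline",
    "save_container",
    "load_container",
    "ContainerSchemaError",
    "export_image",
]


@dataclass
class RunConfig:
    """Configuration of a synthetic end-to-end comparison run."""

    matrix: int = 160
    fov_mm: float = 160.0
    projections: int = 360
    interleaves: int = 24
    samples: int | None = None  # defaults to matrix
    max_amp_mm: float = 7.0
    period_beats: int = 8
    coils: int = 1
    target_snr: float | None = 40.0
    noise_sd: float | None = None  # overrides target_snr when set
    methods: tuple[str, ...] = ("none", "LN", "CS", "oracle")
    recon: ReconParams = field(default_factory=ReconParams)
    reference: str | int = 0  # interleave index or "random"
    seed_phantom: int = 11
    seed_trace: int = 22
    seed_noise: int = 33
    seed_reference: int = 44
    registration: RegistrationOptions = field(default_factory=RegistrationOptions)
    mask_scale: float = 1.0  # scales the suggested heart ellipse

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("methods must be nonempty")
        bad = set(self.methods) - {"none", "LN", "CS", "oracle"}
        if bad:
            raise ValueError(f"unknown methods: {sorted(bad)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["methods"] = list(self.methods)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "recon" in d and isinstance(d["recon"], dict):
            d["recon"] = ReconParams(**d["recon"])
        if "registration" in d and isinstance(d["registration"], dict):
            d["registration"] = RegistrationOptions(**d["registration"])
        if "methods" in d:
            d["methods"] = tuple(d["methods"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunResult:
    method: str
    image: np.ndarray
    trace: MotionTrace
    report: qm.QualityReport


def _roi_masks(phantom: Phantom):
    n = phantom.matrix
    reg = phantom.registry
    blood = make_ellipse_mask(
        n, reg["blood_roi"]["center"], (reg["blood_roi"]["radius"],) * 2
    )
    myo = make_ellipse_mask(
        n, reg["myo_roi"]["center"], (reg["myo_roi"]["radius"],) * 2
    )
    nr = reg["noise_roi"]
    grid = np.zeros((n, n), dtype=np.uint8)
    r0, c0 = nr["corner"]
    grid[r0 : r0 + nr["size"], c0 : c0 + nr["size"]] = 1
    from .selfnav import ROIMask

    noise = ROIMask(grid=grid, center=(c0, r0), semiaxes=(nr["size"], nr["size"]))
    return blood, myo, noise


def run_pipeline(config: RunConfig) -> dict[str, RunResult]:
    """Simulate, self-navigate, correct, reconstruct and evaluate."""
    t0 = time.time()
    n = config.matrix
    samples = config.samples or n
    pixel_mm = config.fov_mm / n

    def stage(name):
        logger.info("[%6.1fs] %s", time.time() - t0, name)

    stage("simulate")
    traj = make_interleaved_radial(
        config.projections, config.interleaves, samples, config.fov_mm
    )
    phantom = make_phantom(n, pixel_mm, seed=config.seed_phantom)
    truth = make_motion_trace(
        config.interleaves,
        config.max_amp_mm,
        config.period_beats,
        seed=config.seed_trace,
        pixel_mm=pixel_mm,
    )
    if config.noise_sd is not None:
        noise_sd = config.noise_sd
    elif config.target_snr:
        noise_sd = noise_for_snr(phantom, traj, config.target_snr)
    else:
        noise_sd = 0.0
    data = simulate_acquisition(
        phantom, traj, truth, noise_sd=noise_sd, coils=config.coils,
        seed=config.seed_noise,
    )
    static = simulate_acquisition(
        phantom, traj, _zero_trace(config.interleaves, pixel_mm)
    )
    static_image = gridding_reconstruct(static, matrix=n).pixels

    hc = phantom.registry["heart_center"]
    ha = phantom.registry["heart_semiaxes"]
    mask = make_ellipse_mask(
        n, hc, (ha[0] * config.mask_scale, ha[1] * config.mask_scale)
    )
    if config.reference == "random":
        ref_index = int(
            np.random.default_rng(config.seed_reference).integers(config.interleaves)
        )
    else:
        ref_index = int(config.reference)

    blood, myo, noise_roi = _roi_masks(phantom)
    results: dict[str, RunResult] = {}
    for method in config.methods:
        stage(f"method {method}")
        try:
            results[method] = _run_method(
                method, config, data, truth, phantom, mask, ref_index,
                static_image, blood, myo, noise_roi,
            )
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{method}' failed: {exc}") from exc
    stage("done")
    return results


def _zero_trace(m: int, pixel_mm: float) -> MotionTrace:
    return MotionTrace(
        dx_mm=np.zeros(m), dy_mm=np.zeros(m), pixel_mm=pixel_mm, reference_index=0
    )


def _run_method(
    method, config, data, truth, phantom, mask, ref_index,
    static_image, blood, myo, noise_roi,
) -> RunResult:
    n = config.matrix
    pixel_mm = config.fov_mm / n
    traj = data.trajectory
    report = qm.QualityReport()

    if method == "none":
        trace = _zero_trace(config.interleaves, pixel_mm)
    elif method == "oracle":
        trace = truth
    else:
        subs = []
        for m in range(config.interleaves):
            if method == "CS":
                sub = cs_reconstruct(data, m, config.recon, matrix=n)
            else:
                sub = gridding_reconstruct(data, m, matrix=n)
            subs.append(sub)
        trace = extract_motion(subs, mask, ref_index, config.registration)
        # re-base the relative trace onto the truth's reference so that the
        # correction targets the same static position
        trace = _rebase(trace, truth)
        _, mean_mm, sd_mm, rel = qm.motion_error(trace, truth)
        report.motion_error_mean_mm = mean_mm
        report.motion_error_sd_mm = sd_mm
        report.relative_error_pct = rel
        logger.info("method %s: motion error %.3f +/- %.3f mm", method, mean_mm, sd_mm)

    image = correct_and_reconstruct(data, trace, matrix=n)

    report.snr, report.cnr = qm.snr_cnr(image, blood, myo, noise_roi)
    report.vessel_sharpness_pct = qm.vessel_sharpness(
        image, phantom.vessel_centerline, pixel_mm
    )
    try:
        report.mean_diameter_mm = qm.measure_diameter(
            image, phantom.vessel_centerline, pixel_mm
        )
    except ValueError:
        report.mean_diameter_mm = None
    report.extra["nrmse_vs_static"] = qm.nrmse(image, static_image)
    return RunResult(method=method, image=image, trace=trace, report=report)


def _rebase(est: MotionTrace, truth: MotionTrace) -> MotionTrace:
    """Shift a relative trace so its reference entry matches the truth's."""
    off_x = truth.dx_mm[est.reference_index] - est.dx_mm[est.reference_index]
    off_y = truth.dy_mm[est.reference_index] - est.dy_mm[est.reference_index]
    return MotionTrace(
        dx_mm=est.dx_mm + off_x,
        dy_mm=est.dy_mm + off_y,
        pixel_mm=est.pixel_mm,
        reference_index=est.reference_index,
        si_mm=est.si_mm,
    )


# ----------------------------------------------------------------------------
# Container I/O


class ContainerSchemaError(RuntimeError):
    """A container file is missing required datasets."""


_REQUIRED = [
    "trajectory/angles",
    "trajectory/interleave_of",
    "trajectory/coords",
    "kspace/samples",
]


def save_container(
    path,
    *,
    data: KSpaceData,
    config: RunConfig | None = None,
    phantom: Phantom | None = None,
    truth_trace: MotionTrace | None = None,
    mask_center: tuple | None = None,
    mask_semiaxes: tuple | None = None,
    results: dict[str, RunResult] | None = None,
) -> None:
    """Write a self-describing HDF5 container for one run."""
    import h5py

    traj = data.trajectory
    with h5py.File(path, "w") as f:
        if config is not None:
            f.attrs["config"] = json.dumps(config.to_dict())
        g = f.create_group("trajectory")
        g.create_dataset("angles", data=traj.angles)
        g.create_dataset("interleave_of", data=traj.interleave_of)
        g.create_dataset("coords", data=traj.coords)
        g.attrs.update(
            num_projections=traj.num_projections,
            num_interleaves=traj.num_interleaves,
            samples_per_readout=traj.samples_per_readout,
            fov_mm=traj.fov_mm,
        )
        k = f.create_group("kspace")
        k.create_dataset("samples", data=data.samples)
        if data.noise_sd is not None:
            k.attrs["noise_sd"] = data.noise_sd
        if phantom is not None:
            p = f.create_group("phantom")
            p.create_dataset("image", data=phantom.image)
            p.create_dataset("vessel_centerline", data=phantom.vessel_centerline)
            p.attrs["pixel_mm"] = phantom.pixel_mm
            p.attrs["vessel_diameter_mm"] = phantom.vessel_diameter_mm
        if truth_trace is not None:
            t = f.create_group("truth_trace")
            t.create_dataset("dx_mm", data=truth_trace.dx_mm)
            t.create_dataset("dy_mm", data=truth_trace.dy_mm)
            t.attrs["pixel_mm"] = truth_trace.pixel_mm
            t.attrs["reference_index"] = truth_trace.reference_index
        if mask_center is not None:
            mg = f.create_group("mask")
            mg.create_dataset("center", data=np.asarray(mask_center))
            mg.create_dataset("semiaxes", data=np.asarray(mask_semiaxes))
        if results:
            rg = f.create_group("results")
            for name, res in results.items():
                sub = rg.create_group(name)
                sub.create_dataset("image", data=res.image)
                sub.create_dataset("trace_dx_mm", data=res.trace.dx_mm)
                sub.create_dataset("trace_dy_mm", data=res.trace.dy_mm)
                sub.attrs["report"] = json.dumps(res.report.to_dict())


def load_container(path) -> dict:
    """Load a container; raises :class:`ContainerSchemaError` when malformed."""
    import h5py

    out: dict = {}
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ContainerSchemaError(f"not a readable HDF5 container: {exc}")
    with f:
        missing = [name for name in _REQUIRED if name not in f]
        if missing:
            raise ContainerSchemaError(
                f"container is missing required datasets: {missing}"
            )
        g = f["trajectory"]
        traj = RadialTrajectory(
            num_projections=int(g.attrs["num_projections"]),
            num_interleaves=int(g.attrs["num_interleaves"]),
            samples_per_readout=int(g.attrs["samples_per_readout"]),
            fov_mm=float(g.attrs["fov_mm"]),
            angles=g["angles"][()],
            interleave_of=g["interleave_of"][()],
            coords=g["coords"][()],
        )
        out["trajectory"] = traj
        out["data"] = KSpaceData(
            samples=f["kspace/samples"][()],
            trajectory=traj,
            noise_sd=float(f["kspace"].attrs.get("noise_sd", np.nan)) or None,
        )
        if "config" in f.attrs:
            out["config"] = RunConfig.from_dict(json.loads(f.attrs["config"]))
        if "phantom" in f:
            p = f["phantom"]
            out["phantom"] = Phantom(
                image=p["image"][()],
                pixel_mm=float(p.attrs["pixel_mm"]),
                vessel_centerline=p["vessel_centerline"][()],
                vessel_diameter_mm=float(p.attrs["vessel_diameter_mm"]),
            )
        if "truth_trace" in f:
            t = f["truth_trace"]
            out["truth_trace"] = MotionTrace(
                dx_mm=t["dx_mm"][()],
                dy_mm=t["dy_mm"][()],
                pixel_mm=float(t.attrs["pixel_mm"]),
                reference_index=int(t.attrs["reference_index"]),
            )
        if "mask" in f:
            out["mask"] = {
                "center": tuple(f["mask/center"][()]),
                "semiaxes": tuple(f["mask/semiaxes"][()]),
            }
        if "results" in f:
            out["results"] = {}
            for name, sub in f["results"].items():
                out["results"][name] = {
                    "image": sub["image"][()],
                    "trace_dx_mm": sub["trace_dx_mm"][()],
                    "trace_dy_mm": sub["trace_dy_mm"][()],
                    "report": json.loads(sub.attrs["report"]),
                }
    return out


def export_image(image: np.ndarray, path, pixel_mm: float = 1.0) -> None:
    """Export a magnitude image as NIfTI (.nii/.nii.gz) or PNG/TIFF."""
    path = str(path)
    mag = np.abs(np.asarray(image))
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag([pixel_mm, pixel_mm, 1.0, 1.0])
        nib.save(nib.Nifti1Image(mag.astype(np.float32), affine), path)
    else:
        import imageio.v3 as iio

        lo, hi = mag.min(), mag.max()
        scaled = np.zeros_like(mag) if hi == lo else (mag - lo) / (hi - lo)
        iio.imwrite(path, (scaled * 255).astype(np.uint8))
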