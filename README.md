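# radialnav

Respiratory self-navigation for interleaved 2D radial MRI, with compressed-
sensing-assisted motion detection — on fully synthetic phantom data.

During a segmented radial acquisition, each heartbeat contributes one
*interleave* of projections that uniformly (but very sparsely) covers
k-space. `radialnav` reconstructs a *sub-image* from every interleave —
either with plain density-compensated gridding (`LN`) or with a
Total-Variation-regularized iterative solve (`CS`) — registers all
sub-images to a reference inside an elliptical ROI to estimate per-beat
2D translation, corrects the k-space data with the corresponding linear
phase ramps (Fourier shift theorem), and reconstructs the final image by
conventional gridding with root-sum-of-squares channel combination.
Quality is quantified by SNR/CNR, percent vessel sharpness, vessel
diameter, motion-detection error, and navigator-agreement regression.

## Layout

| module                    | contents                                             |
| ------------------------- | ---------------------------------------------------- |
| `radialnav.trajectory`    | interleaved radial patterns, ramp density weights    |
| `radialnav.recon`         | Kaiser–Bessel gridding NUFFT, gridding recon, TV, FISTA solver |
| `radialnav.selfnav`       | elliptical ROI masks, masked-MSE registration, motion traces, SI projection |
| `radialnav.motion_correct`| per-interleave phase-ramp correction, final recon    |
| `radialnav.synthdata`     | chest phantom, respiratory traces, exact k-space motion simulation |
| `radialnav.metrics`       | SNR/CNR, %VS, FWHM diameter, motion error, CC/regression, protocol arithmetic |
| `radialnav.pipeline`      | run configuration, HDF5 container I/O, end-to-end comparison runner |

No NUFFT library is required: the non-uniform Fourier operator is built on
a sparse Kaiser–Bessel interpolator over a 2× oversampled FFT grid; the
forward and adjoint are exact algebraic transposes, and the forward agrees
with a direct DFT summation to ~1e-11.

## CLI

```sh
radialnav simulate --matrix 160 --fov-mm 160 --out run.h5     # synthetic container
radialnav navigate run.h5 --method CS --out trace.tsv         # motion trace
radialnav correct run.h5 --trace trace.tsv --out final.nii    # corrected image
radialnav reconstruct run.h5 --method LN --out image.png      # plain gridding
radialnav run --out report.json                               # full comparison
radialnav evaluate results.h5 --out report.json
```

Exit codes: 0 success, 2 configuration error, 3 numerical failure.
The full-scale setting is `--matrix 320 --fov-mm 320` (320 samples per
readout, 1 mm pixels); the default desk scale halves the matrix while
keeping 1 mm pixels so the motion-to-pixel ratio is unchanged.

## Container format

One HDF5 file per run: `/trajectory/{angles,interleave_of,coords}` (+ shape
attributes), `/kspace/samples` (complex, channels × projections × samples),
optional `/phantom`, `/truth_trace`, `/mask`, `/results/<method>`, and the
full JSON-encoded configuration in the root attributes, so a run is
reconstructible from its container alone. Images export to NIfTI or
PNG/TIFF; traces export as tab-separated text.

## Conventions

- k-space coordinates are in cycles/pixel in `[-0.5, 0.5)`; readout sample
  `k` sits at radius `(k - N/2)/N`; image origin is the matrix center.
- The forward operator is `y(f) = Σ_p x(p) · exp(+2πi f·p)`; the correction
  ramp `Δβ(k) = -2π (k - N/2)/N (dx cosθ + dy sinθ)` applied as
  `exp(i Δβ)` undoes a `(+dx, +dy)` pixel displacement, and the simulator
  corrupts with its conjugate, so correction is exact by construction.
- Density weights tile the k-space unit square exactly (ring wedges plus an
  azimuthally integrated outer cell and a shared center disc), so they sum
  to 1 and a unit delta reconstructs with unit peak.
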