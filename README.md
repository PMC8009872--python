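# tiltkit

A desk-scale toolkit for beam-image-shift cryo-electron tomography
acquisition geometry and constrained projection reconstruction:

- **Tilt schemes** — generation and validation of grouped dose-symmetric
  acquisition orders, accumulated-dose bookkeeping, shipped ±60°/±36°
  order fixtures (`tiltkit.scheme`).
- **Targeting geometry** — rotation about the tilt axis, per-ROI
  eucentric-height fitting by closed-form least squares, image-shift and
  defocus correction prediction (`tiltkit.geometry`).
- **Tracking** — cosine-stretched, band-passed cross-correlation with
  sub-pixel peaks and the iterative two-level (coarse/fine) tracking loop
  with nm thresholds and first-image referencing (`tiltkit.tracking`).
- **Virtual stage** — a seeded closed-loop acquisition simulator (grid
  scene, imprecise mechanical stage, exact image shift) producing per-ROI,
  per-tilt targeting/defocus error logs (`tiltkit.simulate`).
- **Tilted CTF** — astigmatic CTF model, synthetic tilted micrographs,
  tilt-corrected tiled power spectra with fixed (not searched) tilt
  geometry, and astigmatic defocus fitting with a fit-quality score
  (`tiltkit.ctf`).
- **Reconstruction** — per-particle defocus assignment from tomogram
  positions, projection extraction, |CC| similarity scoring, score-driven
  per-tilt isotropic-B exposure weights, weighted direct-Fourier
  reconstruction with half-maps, constrained rigid-body refinement and FSC
  (`tiltkit.recon`, synthetic data in `tiltkit.phantom`).

Everything runs on synthetic, seeded data; no external datasets or
hardware are required.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria (slower,
a few minutes total); the rest of the suite runs in well under a minute.

## CLI

All functionality is exposed through one entry point:

```sh
tiltkit scheme --max-tilt 60 --increment 3          # generate an order
tiltkit scheme --validate src/tiltkit/schemes/pm60.tlt
tiltkit simulate-session --seed 7 --out out/sess    # closed-loop session
tiltkit summarize out/sess/log.tsv
tiltkit make-fixtures --seed 3 --out out/demo       # synthetic dataset
tiltkit ctf-fit out/demo/tilted_micrograph.mrc --tilt 51 --axis 20
tiltkit score out/demo
tiltkit weights out/demo --conversion 2500
tiltkit reconstruct out/demo                        # map + half-maps + FSC
tiltkit refine out/demo --max-particles 5
tiltkit extract out/demo
tiltkit fsc out/demo/map_half1.mrc out/demo/map_half2.mrc
```

## Conventions

- Angles in degrees everywhere; stage/targeting lengths in μm; spatial
  frequencies in 1/Å; defocus in Å, underfocus positive.
- Coordinate frame: x along the tilt axis, y perpendicular in plane,
  z along the beam; positive tilt rotates +y toward +z.
- Euler angles are intrinsic ZYZ; the tilt transform composes on the left
  of the particle pose.
- Particle-table coordinates are physical (μm from the tomogram centre);
  0-based pixel indexing and half-open box intervals.
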