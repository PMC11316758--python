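# bdtem

Planning, throughput modelling, simulation and quality control for
beam-deflection TEM (bdTEM) supertile montaging.

A bdTEM scans the illumination to positions adjacent to the optic axis and
de-scans the image back onto the camera, so several image tiles (a
*supertile*, here 3×3) are acquired per mechanical stage position. This
package implements the software side of that acquisition scheme:

* **`bdtem.geometry`** — supertile/montage tiling arithmetic: overlap and
  pitch derivations, stage grids, center-out spiral deflection order, and
  the maximum rectangle / cruciform packings of full tiles inside a
  circular beam boundary.
* **`bdtem.throughput`** — per-section time model (exposure, per-tile
  software overhead, stage step-and-settle, deflection settle, section
  transition) and the derived burst / montage / net / effective imaging
  rates, duty cycle, sections per day and days-per-mm³ projections.
* **`bdtem.simulate`** — synthetic specimen generator (membrane-like
  ridges, organelle-scale blobs, band-limited background) and an
  acquisition simulator with known ground truth: per-subtile smooth
  polynomial distortion growing with deflection radius, contrast falloff,
  dose-scaled shot + read noise, optional stage jitter, and a hard
  circular beam boundary.
* **`bdtem.qc`** — radially averaged power spectra, frequency-resolved
  SNR with noise-spectrum subtraction (spectral-SNR integral), an FFT
  focus score, and NCC block-matching displacement fields.
* **`bdtem.stitch`** — translation-only registration (NCC pairwise
  offsets, weighted least-squares global positions) and feather-blended
  compositing.
* **`bdtem.io` / `bdtem.cli`** — 16-bit grayscale TIFF tiles, JSON
  manifests, TOML config, and the `bdtem` command-line tool.

## CLI

```sh
# plan a 1 mm x 1 mm section at 3 nm/pixel (6000-px tiles, 3x3, 15%/600 px overlaps)
bdtem plan --section-mm 1x1 --pixel-nm 3 --tile-px 6000 --grid 3x3 \
           --intra-overlap 0.15 --inter-overlap-px 600 --out plan.json

# rate report for that plan (fits the per-tile overhead from an observed imaging time)
bdtem throughput --plan plan.json --exposure-ms 120 --transition-min 2.2 --imaging-min 11.7

# simulate an acquisition and stitch it back together
bdtem simulate --plan small_plan.json --seed 7 --out acq/
bdtem stitch --manifest acq/manifest.json --out montage.tif

# quality control
bdtem qc ssnr --image t.tif --noise n1.tif n2.tif
bdtem qc distortion --ref a.tif --warped b.tif --grid 250 --block 128 --search 32
bdtem qc focus --image t.tif
```

The `plan` + `throughput` pair reproduces the published desk-scale
figures for the 1 mm², 3 nm/pixel configuration: 484 supertiles / 4356
tiles, 16200-px supertile side, montage 223 / net 188 / effective
142 MPix/s at 120 ms exposure, 103 sections/day, 54 days per mm³ with
four microscopes.

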