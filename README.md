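# drfparams

Automated radiographic parameter measurement for distal radius fractures
from biplane (AP + LAT) bone-segmentation label masks.

Given per-view label masks (indexed PNG, VOC palette: AP = background /
distal radius / proximal radius / ulna; LAT = background / distal radius /
proximal radius), the pipeline

1. extracts a clean closed contour per bone part (binarize, flood-fill
   holes, 3×3 Gaussian denoise, Sobel edges, largest-contour selection,
   deviation-bounded simplification);
2. fits the central shaft axis from random interior points by minimizing
   a smoothed-Manhattan (pseudo-Huber-style) loss with gradient descent
   (ulnar diaphysis in AP, radial diaphysis in LAT);
3. detects five anatomical landmarks by rotating-line search — styloid
   tip (ST), ulnar border of radius (UBR), ulnar head surface midpoint
   (UH, with ul_UBR), dorsal joint rim (DJ) and volar joint border
   (VJB) — plus a volar/dorsal displacement call;
4. computes **Radial Angle**, **Radial Length**, **Ulnar Variance** and
   **Palmar Tilt**, in px or (with a mm/px calibration) mm.

A synthetic wrist-phantom generator (`drfparams.phantom`) produces
ground-truthed mask pairs with controllable RA/RL/UV/PT, global rotation
and boundary noise, so every stage — and end-to-end parameter recovery —
is tested without clinical data. Segmentation loss primitives
(cross-entropy, focal, Dice, generalized Dice) are included as verified
numerics for a future training harness.

## CLI

```bash
# generate ground-truthed phantom cases (masks + metadata + truth JSON)
drfparams phantom --n 50 --seed 42 --out cases/

# measure one biplane pair
drfparams run --ap cases/case0000_ap.png --lat cases/case0000_lat.png \
              --meta cases/case0000_meta.json --out result.json

# process a directory: per-case JSON, batch CSV, error summary vs truth
drfparams batch --dir cases/ --out results/

# spot-check the loss primitives on a JSON record
drfparams losses eval --json record.json
```

`run`/`batch` accept `--config cfg.yaml` with nested `contour`, `axis`,
`rotating` sections plus `spacing` (mm/px); see
`drfparams.pipeline.PipelineConfig`.

Conventions: masks are canonicalized at read time (distal end up; left
wrists mirrored to right-wrist geometry). Signs: RA > 0 with the styloid
distal to UBR, UV > 0 with a relatively long ulna, PT > 0 for volar tilt.

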