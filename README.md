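# deepcenterline

Detection and tracking of overlapping swimming nematodes (*C. elegans*)
in dense microscopy video, built around three ideas:

1. **A physics-based synthetic data generator.** Worms are simulated as
   undulating slender bodies: a traveling-wave tangent-angle model
   prescribes the body-frame deformation, and resistive force theory
   (low-Reynolds-number drag with anisotropic tangential/normal
   coefficients) yields the rigid translation and rotation per time step
   from force and torque balance. A renderer converts trajectories into
   grayscale video with realistic artefacts (background texture, vignette,
   defocus blur, sensor noise), so the detector can be trained entirely
   on labeled synthetic data.
2. **Centerline-triplet detection.** A convolutional network predicts,
   per spatial anchor cell, a *triplet* of centerlines (previous, central,
   next frame) in a low-dimensional PCA shape space, together with a
   confidence score and a latent embedding from a bitwise
   flip-invariant encoder (a worm's head/tail orientation is ambiguous,
   so all shape distances and network outputs are invariant to reversing
   the centerline). Duplicate candidates are removed by non-maximum
   suppression in *latent* space: two candidates suppress each other when
   their latent pair probability `P = exp(−‖Δp‖²)` exceeds a threshold,
   which separates overlapping worms that plain spatial NMS would merge.
3. **Directed tracking.** Because each detection carries its own
   past/next centerline estimates, frame-to-frame linking can use a
   *directed* distance (my prediction of your position vs. your
   position) instead of plain proximity, which keeps identities across
   crossings. Assignment is solved optimally per frame pair, and short
   detection gaps are bridged.

Evaluation tools include the average dynamic time warping (ADTW)
curve-to-curve distance (exact O(NM) dynamic program, verified against
brute force), TP/FN matching against sparse human annotations, and the
tracking-integrity score ι (the identity-weighted fraction of a worm's
trajectory covered by its dominant track).

## Worked example

Simulate a dense scene, corrupt perfect detections with localization
noise and 2% dropout, link them into tracks, and measure identity
integrity:

```python
import numpy as np
from deepcenterline import simulator, tracking, metrics
from deepcenterline.detections import Detection

rng = np.random.default_rng(0)
trajs = simulator.simulate_population(8, (256, 256), 5.0, rng=rng, k=25)
n_frames = len(trajs[0].centerlines)

frames = []
for f in range(1, n_frames - 1):
    dets = []
    for tr in trajs:
        if rng.uniform() < 0.02:          # missed detection
            continue
        z = np.stack([tr.centerlines[f - 1], tr.centerlines[f],
                      tr.centerlines[f + 1]])
        dets.append(Detection(z=z + rng.normal(scale=0.5, size=z.shape),
                              score=1.0))
    frames.append(dets)

tracks = tracking.build_tracks(frames)
gt = {i: {f - 1: trajs[i].centerlines[f] for f in range(1, n_frames - 1)}
      for i in range(len(trajs))}
per_worm, mean_iota, se = metrics.integrity_over_dataset(tracks, gt)
print(f"{len(tracks)} tracks over {len(frames)} frames")
print(f"mean integrity = {mean_iota:.3f} ± {se:.3f}")
```

Output:

```
8 tracks over 99 frames
mean integrity = 0.953 ± 0.007
```

The same pipeline is available from the command line:

```
deepcenterline simulate --n-worms 5 --duration 2 --seed 0 --out centerlines.csv
deepcenterline synth --n-worms 3 --seed 1 --out-prefix clip       # TIFF + labels
deepcenterline train --steps 2000 --seed 0 --out model.h5
deepcenterline detect --clip clip.tiff --checkpoint model.h5 --out dets.csv
deepcenterline track --detections dets.csv --out tracks.csv
deepcenterline evaluate --labels clip_labels.csv --detections dets.csv --report report.json
```

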