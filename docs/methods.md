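# Methods

This document records the modelling assumptions, the parameters with their
units and defaults, the scope of the synthetic scene generator, and the
numerical choices made in the implementation.

## Model overview

The model simulates where and when the eyes move in a dynamic scene. It has
two coupled stages:

- a **segmentation filter** that maintains a particle-based belief over
  scene segmentations and derives a per-pixel uncertainty map, and
- a **saccadic decision stage** in which the objects of the current
  most-likely segmentation race to a shared evidence threshold
  (a multi-alternative drift-diffusion model, DDM).

Gaze closes the loop: the currently foveated object is measured with high
confidence ("prompted" cue) and incorporated into the filter, which removes
uncertainty at the gaze position and biases the next saccade toward regions
that are still uncertain.

## Assumptions

- **Object cues are given.** The filter consumes segment measurements from
  cue generators (appearance, motion, semantic, prompted). In this package
  the cues are synthesized from ground truth with configurable degradations;
  plugging in real computer-vision backends is out of scope.
- **Boundaries carry the segmentation information.** Particles are compared
  with measurements only through the geometry of their region boundaries
  (a symmetric chamfer distance between inter-pixel boundary sets), not
  through region labels; labels are arbitrary up to permutation.
- **One update per frame.** Perception and decision advance on the video
  frame grid (default 30 fps, i.e. 33.3 ms steps). Saccade durations and
  the optional saccadic dead time block evidence accumulation for their
  real-valued duration; threshold crossings are interpolated within a step.
- **Smooth pursuit is ideal.** Between saccades the gaze point is advected
  by the bilinearly interpolated ground-truth optical flow.
- **Evidence is object-based.** Drift rates are mask means of the evidence
  map times a logarithmic area factor, so large objects gain evidence faster
  but only sub-linearly in area.

## Parameters

### Segmentation filter (`FilterParams`)

| Parameter | Default | Units | Rationale |
| --- | --- | --- | --- |
| `n_particles` | 50 | – | enough diversity for multi-modal beliefs while keeping the per-frame chamfer cost low |
| `lambda_d_dva` | 2.0 | dva | boundary-distance scale of the measurement likelihood `exp(-confidence · d / lambda_d)`; ~2 dva tolerance before a particle is heavily penalized |
| `incorporate_fraction` | 0.2 | – | fraction of particles that adopt a measured segment each frame; keeps the rest of the ensemble as memory |
| `incorporate_kinds` | prompted, semantic | – | only object-level measurements overwrite particles; part-level cues act through the likelihood only |
| `pb_threshold` | 0.5 | – | majority vote when thresholding the boundary probability for the most-likely segmentation |
| `blur_sigma_dva` | 1.0 | dva | smoothing of the entropy map before rescaling, matching the scale of foveal measurements |
| `mask_window_dva` | 2.0 | dva | window around a mask-only (prompted) measurement within which boundaries are compared |

Cue confidences: global cues 1.0, the prompted (foveal) cue 4.0, so one
foveal measurement outweighs the ordinary cues in the likelihood.

### Decision stage (`ModelParams`)

| Parameter | Default | Units | Rationale |
| --- | --- | --- | --- |
| `theta` | 4.0 | evidence | decision threshold of the race; free parameter of the grid search |
| `s` | 0.3 | evidence/√frame | diffusion noise; free parameter |
| `f_min` | 0.3 | – | floor of the rescaled feature map `F' ∈ [f_min, 1]`; trades saliency against uncertainty |
| `u_min` | 1/3 | – | floor of the rescaled uncertainty map `U' ∈ [u_min, 1]`; `u_min = 1` removes the uncertainty drive entirely |
| `sigma_s_dva` | 7.0 | dva | spread of the gaze-centered Gaussian sensitivity map |
| `dt` | 1.0 | frames | one DDM update per video frame |
| `dead_time_ms` | 0.0 | ms | optional saccadic dead time; use 50 ms together with `theta = 3.5` to preserve foveation durations |
| momentum `max/min/range` | 1.0 / 0.5 / 180° | – | optional saccadic-momentum extension: sensitivity decays linearly with deviation from the previous saccade direction |
| presaccadic `trigger_fraction` | 0.3 | – | optional presaccadic attention: accumulators above `0.3 · theta` get foveal sensitivity |

Fixed laws: saccade duration `2.7 ms/dva · amplitude + 23 ms`; landing points
are sampled within the target mask proportional to `F' · S`.

### Tracking (`TrackState`)

Discounted-IoU bipartite matching over a 10-frame history with discount 0.9
and acceptance floor 0.1; retired IDs are never reused. The floor prevents
spurious matches from a single noisy overlap, the discount favours recently
confirmed identities.

## Synthetic scene generator: scope

`generate_scene` renders parametric scenes of disk- and rectangle-shaped
objects (optionally multi-part, optionally camouflaged) moving linearly over
a textured background, and returns the feature (saliency) map, ground-truth
optical flow, and object/part label rasters. `sample_scene_spec` draws the
3-object battery layout used in the tests: one moving disk, one static
two-part rectangle, one camouflaged object, with saliencies spread over
[0.5, 1] and placement constraints that keep objects separated and inside
the frame. Cue generators degrade the ground truth with boundary jitter,
object merging, and prompt-point jitter. The generator is deliberately
simple: it exists to exercise the filter and decision model under controlled
conditions, not to imitate natural video statistics.

## Numerical choices

- **Crack geometry.** Boundaries are represented as inter-pixel "cracks" on
  a 2×-upsampled integer grid (the crack between horizontally adjacent
  pixels (r, c) and (r, c+1) sits at (2r, 2c+1)); Euclidean distances on
  this grid halved are pixel-unit distances. This makes boundary sets exact
  integer point sets and the chamfer distance label-permutation invariant.
- **Chamfer distance.** The symmetric mean nearest-neighbour distance is
  computed exactly with a Euclidean distance transform on the doubled grid
  (particle→measurement direction) and KD-tree queries in which all particle
  crack sets are stacked with a third, set-separating coordinate
  (measurement→particle direction). Both paths are verified in the tests
  against a brute-force double loop; they are exact accelerations, not
  approximations.
- **Deduplicated particles.** Particle rasters are stored as
  (unique rasters, inverse index); the filter steps update this cache so
  identical particles are weighted and compared only once. Particles
  adopting a full-frame measurement receive one shared label offset —
  labels are arbitrary, only the partition matters — which keeps adopters
  byte-identical and the unique count small.
- **Boundary-free rasters.** If exactly one of two compared boundary sets is
  empty, the frame (or window) diagonal is used as a maximal-disagreement
  sentinel; two empty sets have distance 0.
- **Most-likely segmentation.** The boundary probability is thresholded,
  closed with a 3×3 structuring element, and its complement labelled; band
  pixels are assigned to the nearest region (distance transform). Pixels
  exactly equidistant from several regions (e.g. 90° corners) are resolved
  by local band consistency: the tied region whose assignment best
  reproduces the observed boundary band in the pixel's neighbourhood wins,
  which makes decoding exact for clean, converged bands.
- **Resampling.** Systematic (low-variance) resampling with a single random
  offset; weights reset to uniform afterwards.
- **DDM stepping.** Within-step threshold crossings are interpolated
  linearly, so noise-free crossing times are exact (`theta / (nu · mu)`).
  The foveation fraction `nu` of a frame is clipped into [0, 1] to absorb
  floating-point rounding on the millisecond grid. When `nu = 0` (gaze in
  flight) no random numbers are drawn, keeping seeds aligned across
  conditions.
- **Determinism.** Every stochastic component draws from
  `numpy.random.Generator` streams derived from explicit seeds; cue noise is
  keyed by (seed, frame, gaze) so the same measurement is returned for
  repeated queries. Simulations are bit-reproducible given the seed.

## Limitations

- Cues are synthesized from ground truth; the model's behavior with learned
  segmentation backends (noise statistics, systematic failure modes) is not
  characterized here.
- The generator's scenes are simple geometric objects with linear motion;
  occlusion, deformation, lighting changes and camera motion are not
  modelled.
- Head and vergence movements, microsaccades and fixational drift are out of
  scope; "foveation" covers both fixation and pursuit.
- Parameter defaults target the synthetic battery; comparisons to human
  eye-tracking data would require refitting `{s, theta, f_min, u_min}`
  against that data via the provided grid search.
- The particle filter's belief is over full-frame segmentations; with only
  50 particles the posterior is coarse, and the uncertainty map should be
  read as a qualitative signal rather than a calibrated probability.
- Two qualitative trends measured on the synthetic battery (200 scanpaths,
  ten 3-object scenes; see `tests/test_acceptance.py`) do not show the
  signatures expected from object-dense natural scenes. (a) Temporal
  inhibition of return: foveations preceding object *revisits* are longer
  than those preceding within-object saccades (median 145 vs 128 ms in a
  12-run sample), but the relative-saccade-angle profile shows no
  return-vs-forward duration gap (−1.7 ms at `u_min = 1/3`), because the
  small battery objects make within-object saccades reverse direction
  constantly and flood the return-angle bins. (b) Removing the foveal prompt
  shifts gaze time to the *background* (inspection share 0.62 → 0.21;
  background share rises instead): without prompted background patches the
  region around the gaze stays uncertain and the large background unit wins
  the evidence race. Both are consequences of the sparse synthetic scene
  composition rather than of the decision mechanism, whose per-category
  effects point in the expected directions.
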