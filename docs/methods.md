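# Methods

This note describes, in the package's own terms, how `astromito` measures the
astrocytic mitochondrial system from dual-channel time-lapse microscopy and
how the synthetic benchmark that validates every stage is constructed.

## Imaging model

A measurement is one cell imaged in two channels — green (488 nm excitation)
and red (555 nm) — as a `FrameStack` of `T` frames at a fixed frame interval
(default 1 s) and pixel size (default 0.07 µm). The channels report the
MitoTimer biosensor: the protein fluoresces green when newly synthesized and
shifts to red as it oxidizes, so the red/green ratio inside one mitochondrion
summarizes the organelle's redox history. Cells are imaged at baseline (BL)
and at post-treatment timepoints (6 h, 24 h); morphology is measured on the
first frame of each sequence and motility/dynamics on the whole sequence.

## Segmentation (`astromito.segment`)

Each channel is thresholded independently (Otsu's method by default; a fixed
threshold is available), and objects are defined on the **union** of the two
channel masks so that one object identity carries both the green and the red
measurement. 8-connected components are then filtered by:

1. area bounds (default ≥ 4 px, protecting against hot pixels),
2. minimum mean green intensity (off by default), and
3. an ROI-boundary rule removing any object with a pixel outside the analysis
   region or 4-adjacent to its edge — objects truncated by the field of view
   would bias every shape measure downward.

A constant image under Otsu has no between-class structure and is returned as
an empty mask flagged `degenerate` rather than an arbitrary split.

## Morphometry (`astromito.morphometry`)

Per object, on the first frame:

* **area** — pixel count × pixel area.
* **width** — twice the mean value of the Euclidean distance transform along
  the object's skeleton. This is the classic medial-axis ridge width; on
  digitized capsules it is near-unbiased (≈ +1% on rendered benchmarks) and,
  unlike `area / length`, remains meaningful for branched shapes.
* **length** — geodesic length of the skeleton's longest path plus one width.
  The medial axis of an elongated object stops roughly half a width short of
  each tip; adding the width restores tip-to-tip length. Objects too small to
  skeletonize (< 9 px) fall back to the fitted-ellipse axes.
* **elongation** — length / width (1 ≈ round, large ≈ filamentous).
* **branch count** — the skeleton is converted to an 8-connected pixel graph;
  removing junction pixels (degree ≥ 3) leaves one connected component per
  branch. A junction-free skeleton counts as a single branch.
* **redox ratio** — mean red / mean green within the mask after subtracting a
  per-channel background estimated as the frame median (objects cover a small
  minority of pixels). An object whose background-corrected green mean is ≤ 0
  has an undefined ratio and is excluded from ratio summaries, not imputed.

Cell-level records average these over the cell's mitochondria and carry a QC
flag: at least 50 measured mitochondria are required for a cell to enter
group statistics.

## Dynamics (`astromito.dynamics`)

Objects are linked frame-to-frame by optimal bipartite assignment on centroid
distance with a gating radius (default 1 µm); links beyond the gate are
forbidden, and unmatched objects terminate or start tracks. Motility metrics
use only tracks spanning the full sequence: **displacement** is the first-to-
last centroid distance and **speed** is path length over elapsed time.

Fusion/fission activity is estimated from the per-frame object counts: the
number of events is the sum of absolute successive count changes (drops are
fusion candidates, rises fission candidates), and dividing by the mean count
gives the **event rate per particle**. Counts `[10, 9]` give one event and a
rate of 1/9.5. Simultaneous fusion and fission within one interval cancel in
the counts, so this estimator is a lower bound on true activity.

## Change scores (`astromito.scoring`)

For each cell, parameter and post-treatment timepoint the raw change score is
the natural-log ratio to the cell's own baseline,

```
raw = log(value_t) − log(value_BL),
```

and the normalized score subtracts the mean raw score of the control group in
the same (parameter, timepoint) stratum, so the control group centers at zero
exactly. The natural log is a pure convention: any other base rescales all
scores by one constant, which cancels in group contrasts. Condition summaries
(mean ± s.e.m., n) per parameter and timepoint are the substrate of
radar-style multiparameter displays (`plot_radar`). Cells lacking a baseline
value, or with non-positive values, are excluded for that parameter with a
logged warning; a stratum without control cells is an error, never a silent
zero.

## Vesicle statistics (`astromito.ev_quant`)

Small helpers for nanoparticle-tracking (NTA) and ELISA-style quantities:

* `partition_sizes` — percentage of particles in the small (exosome-like,
  (10, 150] nm) vs large (ectosome-like, > 150 nm) class, optionally weighted
  by per-bin concentration; the split is over particles above the 10 nm cut
  and sums to 100 exactly.
* `fraction_distribution` — percentage of total tau across secretion
  fractions (free-form protein, small-EV, large-EV); scale invariant.
* `uptake_efficiency` — quantity in astrocytes × 100 / quantity added, with
  an inconsistency flag above 100%.

## Synthetic benchmark (`astromito.simulate`)

Because manual annotations cannot provide exact ground truth, validation uses
a generative model whose truth is known by construction:

* Mitochondria are unions of capsules (segments with a radius). Branched
  objects share a common endpoint and have ≥ 3 arms — a 2-arm "branch" is a
  skeleton elbow without a junction and has no well-defined branch count.
  Lengths, widths, amplitudes and redox ratios are lognormal; placement
  enforces a minimum surface-to-surface separation (0.4 µm) so objects remain
  resolvable, and rejects over-dense fields with an error.
* Rendering is additive antialiased capsule coverage, convolved with a
  Gaussian PSF (σ = 1.5 px), followed by Poisson shot noise, Gaussian read
  noise (σ = 2 DN) and 16-bit quantization. The red channel is the green
  geometry scaled by the object's redox ratio, so noise-free measured ratios
  equal the generating ratios to float precision. Additive rendering makes
  fusion conserve integrated intensity.
* Motion is uniform drift plus per-object Brownian steps; scheduled or
  Poisson-random fusion/fission events edit the object list and the true
  per-frame counts.
* `simulate_timepoint_series` applies multiplicative shifts to the lognormal
  medians at 6 h/24 h, so the true log change score of a shifted parameter is
  exactly `log(shift)`.
* `simulate_particle_sample` draws NTA-style diameters from lognormal
  mixtures for the vesicle statistics.

## Validation summary

The test suite checks each stage against independent oracles (flood-fill
labeling, exhaustive between-class-variance search, brute-force gated
matching, hand-computed scores) and the pipeline end-to-end against the
generator's ground truth: redox change-score recovery within 10% of the
injected effect, cell-mean length/elongation/ratio within 10%, branch counts
exact on ≥ 90% of noise-free branched objects, drift speed within 5% and
displacement within one pixel, Brownian MSD within 3 SE of `4Dt`, and exact
scheduled-event counts. `scripts/acceptance.py` reruns these measurements and
writes the headline numbers to JSON.

## Known limitations

* The count-based event rate is blind to compensated fusion+fission within a
  frame interval and to events among undetected objects.
* Width on hard-edged digitized masks carries a positive bias of up to about
  one pixel (half-pixel boundary convention of the distance transform); at
  the default sampling a 0.45 µm width spans only ~6 px, so sub-pixel effects
  dominate comparisons at that scale.
* Tracking assumes limited motion per frame (gating radius); identity is not
  preserved through fusion/fission, which intentionally terminates tracks.
* The simulator models rigid motion only (no bending or extension), and noise
  is spatially white.
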