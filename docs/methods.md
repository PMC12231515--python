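# Methods

## Problem setting and pipeline

The package treats a 3D CT volume as a video of axial frames and adapts
promptable video-object tracking to volumetric segmentation. A run is
defined by a scan, an organ, a start level, and a prompt condition; it
produces one predicted 3D mask and one Dice score. The pipeline stages are
independent modules behind narrow interfaces: volume I/O and windowing
(`volume_io`), prompt generation (`prompting`), propagation
(`tracking`), scoring and statistics (`evaluation`), phantom generation
(`synthetic_data`), and orchestration (`pipeline` + CLI).

Axis convention throughout: arrays are indexed `(z, y, x)`, 0-based, with
z the axial slice index increasing cranially. Prompt coordinates are
`(x, y)` pixel positions within the z-indexed frame.

## Preprocessing

CT windowing uses window level 50 HU and window width 400 HU (the standard
soft-tissue display window): values are clipped to [−150, 250] HU,
linearly rescaled to [0, 255], and rounded **half away from zero** to
8-bit integers. The rounding rule is stated because it is the only part of
the mapping not fixed by the definition, and a single fixed rule makes
frame stacks bit-reproducible across platforms (e.g. 50 HU → 127.5 →
128).

Frames default to lossless encoding (PNG on disk), which deterministic
tests require. JPEG at quality 95 is available for fidelity to
JPEG-based pipelines; it is applied as an in-memory encode/decode so
consumers see real lossy pixels. Measured on the default phantom, the
JPEG-q95 round trip deviates from lossless by a mean absolute ~1.5
intensity units per pixel.

Ground-truth masks with at most 100 voxels are excluded from analysis
before evaluation. The boundary case (exactly 100) is **excluded**; the
filter reports both partitions so exclusion counts are auditable.

## Prompt generation

* **Start slice.** The caudal/mid/cranial start levels are the
  25th/50th/75th percentiles of the organ's *occupied* slice indices,
  computed by the nearest-rank estimator (r = ⌈p/100 · n⌉). Percentiles
  over occupied slices rather than the full z bounding range make the
  choice robust to organs with interior gaps; nearest-rank guarantees the
  result is an actual occupied slice and is monotone in p. Both choices
  are this package's own, stated so tests can enumerate them exactly.
* **Positive prompts.** Up to 5 pixels drawn uniformly without
  replacement from the organ's cross-section on the start slice.
* **Negative prompts.** Up to 5 pixels drawn uniformly from the ring of
  pixels at in-plane **Chebyshev** distance 2–3 from the cross-section
  (dilation by a 7×7 square minus dilation by a 3×3 square), i.e. "2–3
  pixels outside the boundary, excluding the 1-pixel margin". The
  Chebyshev metric is used because prompts live on the pixel grid of a
  single frame; a Euclidean ring would differ at corners. An isolated
  interior pixel has exactly 40 ring candidates (7² − 3²); at a frame
  corner the ring clips to 12.
* Negative candidates are *not* filtered against other organs' masks — a
  negative may land inside a neighboring structure. This mirrors fully
  automatic prompt placement, and is exactly the mechanism the
  touching-structures phantom exploits.
* **Seeding.** Every sampling step uses a sub-seed derived by SHA-256
  from (master seed, scan, organ, level, polarity), so any run is
  reproducible in isolation and results do not depend on processing
  order. Start slices are seed-independent.

## Propagation

A backend satisfies one contract: (frames, prompt set, direction) → one
binary mask per frame from the start slice to the directional end. The
forward pass covers [start, Z−1], the reverse pass [0, start]; both passes
receive the identical prompt set (whether a real tracker should instead be
invoked once bidirectionally is backend-specific; the contract keeps the
two passes symmetric). The final mask is the voxelwise union of the two
passes — union also resolves any start-frame disagreement a stochastic
backend might produce.

The **reference backend** is an intensity-band component tracker chosen to
be the simplest mechanism that exercises every contract obligation while
remaining fully deterministic and analytically predictable:

* Band: [min(I⁺) − τ, max(I⁺) + τ] where I⁺ are the 8-bit intensities at
  the positive prompts and τ = 10 (default, configurable). The band is
  fixed on the start frame and reused for all frames of the run.
* Start frame: threshold to the band, label 8-connected components, keep
  the union of components containing a positive prompt, minus any
  component containing a negative prompt. Negatives therefore act at
  component granularity and only ever shrink the start mask.
* Subsequent frames: threshold with the same band; keep each component
  whose overlap with the previous frame's mask is ≥ max(1 pixel, 10% of
  the component's area). An empty frame stops the pass (all remaining
  frames empty).

Consequences worth knowing: a positive prompt on a background pixel
faithfully tracks the background component (garbage in, garbage out); two
same-intensity structures that touch on the start frame form one component,
so a negative prompt inside either removes both; and negative prompts can
improve accuracy only when the organ's cross-section splits into more than
one component on the start frame, one clean and one contaminated.

## Evaluation and statistics

* **DSC** is computed volume-wise over the whole 3D mask, not averaged
  per slice (organ-level scores imply volume-wise computation).
  Conventions for degenerate inputs, which the pipeline itself never
  produces with non-empty ground truth: both masks empty → 1.0; exactly
  one empty → 0.0.
* **Wilcoxon signed-rank** (two-sided, paired): zero differences are
  dropped before ranking (Wilcoxon's original treatment; the choice is
  recorded in every comparison result). With n ≤ 25 retained pairs the
  p-value is exact, computed by dynamic programming over doubled midranks
  — doubling makes tied midranks integral, so the full sign-flip null
  distribution is a convolution; this handles ties exactly, which
  off-the-shelf exact implementations decline. For n > 25 a tie-corrected
  normal approximation (no continuity correction) is used. If all
  differences are zero the comparison is flagged degenerate with p = 1.
* **Approach contrasts**: per organ, the three pairs
  caudal–mid, caudal–cranial, mid–cranial on with-negatives records,
  each tested at the Bonferroni-corrected threshold 0.05/3 ≈ 0.0167.
* **Negative-prompt ablation**: a single per-organ paired contrast at the
  caudal level (configurable), uncorrected α = 0.05; the reported mean
  difference is *without minus with*, so negative values mean removing
  negative prompts hurts.
* **Correlations**: Spearman's ρ (midrank ties, t-approximation) between
  ground-truth voxel volume and DSC, pooled across organs per start level
  on with-negatives records, plus per-organ breakdowns. The pooled
  convention — all organs' records within one level — is this package's
  reading of "overall volume–accuracy correlation".
* Pairs with a missing member (failed or filtered runs) are dropped
  pairwise, never imputed; dropped counts are logged.

## Synthetic phantoms

`PhantomSpec` describes a voxel grid, background HU, global noise SD, and
organs as unions of analytic primitives (ellipsoids; axis-aligned boxes for
constructed contact geometries). Rasterized organs must be pairwise
disjoint (touching allowed). Intensity = background mean, overwritten by
each organ's HU mean (optionally faded cranially), plus i.i.d. Gaussian
voxel noise (default SD 8 HU). Generation is a pure function of
(spec, seed).

The default "abdomen-small" spec uses a 96³ grid and eight organs whose
relative volumes echo real anatomy — liver ≈ 40k voxels down to adrenals
≈ 140, a ratio > 250× — and whose organ–background contrast is
size-graded: large organs are well contrasted (liver +170 HU over
background), while pancreas, gallbladder, and adrenals sit at +33…+42 HU,
close enough to the noise-broadened detection band that the tracker shows
the partial-failure modes small, poorly contrasted structures show in real
CT. This produces the qualitative signature expected of the method: high
DSC for large organs, lower and more variable DSC for small ones, and a
positive pooled volume–DSC correlation. Absolute HU values are not claimed
to be anatomical; contrast with surroundings is the operative quantity.

Cohorts jitter the base spec per scan (centroids ±2 voxels, semi-axes
±8%, HU means ±5) with bounded retries on collision. Two variants plant
effects for the statistical machinery:

* **cranial-fade** — organ contrast multiplied by a factor falling
  linearly from 1.0 at half the organ's z-extent to 0.3 at its cranial
  end. A cranial start then anchors the intensity band on low-contrast
  slices and loses most of the organ, so caudal-start DSC exceeds
  cranial-start DSC scan-for-scan.
* **touching-blobs** — a two-lobed box-shaped target (lobes separated
  in-plane by a 1-pixel margin) whose small lobe is edge-adjacent to a
  long same-intensity distractor vessel; box primitives keep the contact
  constant along z. When a positive prompt lands in the small lobe, its
  thresholded component includes the vessel; only a negative prompt inside
  the vessel excises that component. Removing negatives therefore lowers
  mean DSC across a cohort — some scans tie (prompt draws that miss the
  lobe or the vessel leave both conditions identical), but no scan
  improves. Cohort jitter for this spec varies HU only, preserving the
  contact geometry.

What the phantoms do **not** emulate: anatomical shape (organs are
quadrics/boxes), partial-volume effects, CT physics (beam hardening,
reconstruction kernels), inter-organ texture, or annotation error beyond
the volume filter. Passing tests demonstrate that the pipeline's
machinery — prompting geometry, propagation bookkeeping, paired
statistics — behaves correctly and that planted effects are recovered;
they say nothing about the accuracy of any particular real segmenter on
real CT, which requires real data and a real backend behind the same
contract.

## Problem sizes and runtime

Cohort experiments in the tests and the acceptance script use 12 scans of
96³ (default, fade) or 64³ (touching) voxels — 576 propagation runs for
the full default design — which completes in seconds on one CPU while
leaving every statistical test adequately powered (n = 12 pairs gives a
minimum two-sided exact Wilcoxon p of ~0.0005, far below the 0.0167
threshold).

## Known limitations

* The reference backend shares no architecture with learned video
  segmenters; it validates the pipeline contract, not model quality.
* Negative prompts influence only the start frame of each pass; real
  trackers condition on them throughout the sequence.
* Orientation handling trusts the NIfTI array's first axis to be axial
  (the affine's orientation codes are recorded in provenance but not used
  to reorient).
* The exact Wilcoxon path is O(n · Σranks) per test — fine for cohort
  sizes here; very large cohorts fall back to the normal approximation at
  n > 25 regardless.
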