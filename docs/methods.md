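# Methods

## Transform semantics

All transforms act on `H x W x 3` `uint8` rasters and move whole (R, G, B)
triplets; channels are never decoupled except by Color Flatten. The guiding
constraint is pixel-value conservation: scrambling relocates information
without changing any intensity, so the sorted multiset of pixel triplets is an
exact invariant of every shuffle (per block for the within-grid shuffle, per
region for the segmentation within shuffle).

**Probabilistic shuffling.** "Each pixel is shuffled with probability *p*" is
realized as Bernoulli(*p*) selection of locations followed by one uniform
random permutation over exactly the selected locations. This keeps unselected
pixels bit-identical and guarantees conservation. A uniform permutation may
have fixed points, so a selected pixel can land back on its own location; the
alternative reading (a derangement at *p* = 1) was considered and rejected as
the more exotic convention — it is isolated behind the single permutation
draw if anyone wants to swap it.

**Blocks.** Block transforms require the image sides to be divisible by the
block size and raise an error otherwise rather than pad or crop: silent
padding would corrupt the conservation invariant. The canonical 320-pixel
stimuli are divisible by all four grid sizes (20, 40, 80, 160). The Local
Structure Shuffle is defined as within-grid shuffle followed by grid shuffle
of the result, consuming one shared random stream sequentially.

**Superpixels.** Region shuffles segment with SLIC. We default to the SLICO
adaptive-compactness variant (`slic_zero=True`, initial compactness 10):
fixed-compactness SLIC with connectivity enforcement collapses small region
requests on low-texture images (a request of 8 can realize 1–3 regions),
whereas SLICO realizes 8/16/64 requests almost exactly across the image types
we generate. Fixed-compactness SLIC remains available via `slic_zero=False`.
The realized region count `k_actual` is always recorded alongside the request
and a warning is emitted when it falls short; the shuffles operate on
`k_actual`.

**Displacement rule.** The displacement shuffle draws one uniform permutation
over regions (fixed points allowed — "moved to another region" could be read
as a derangement, but uniform is the simpler convention and the sampler is a
single isolated draw). Region sizes differ, so moving source pixels into a
larger destination resamples the deficit uniformly *with replacement* from
the source (without replacement is impossible when the deficit exceeds the
source size, so replacement is used uniformly for consistency), and moving
into a smaller destination drops the surplus after a uniform shuffle — the
kept pixels are therefore a uniform subset. Destinations are filled in their
row-major pixel scan order; since the transferred pixels are shuffled, any
fixed fill order is equivalent in distribution, and fixing it makes outputs
seed-reproducible.

**Color Flatten display.** The flattening itself is defined exactly (three
row-major channel vectors); the 2-D rendering for human viewing is not. We
concatenate red ‖ green ‖ blue and reshape row-major to `H x W x 3` — a
deterministic, value-conserving choice isolated in `render_flattened` so a
different display convention can be substituted.

## Randomness contract

Every stochastic operation consumes draws from a `numpy.random.Generator` in
a fixed documented order: selection mask first (one uniform per pixel,
row-major), then one permutation; blocks in row-major grid order; regions in
label order; for displacement, the region permutation first, then per-region
resample indices and permutation. Equal (inputs, parameters, seed) give
bit-identical outputs, which is what makes the stimulus manifest
self-contained: every stimulus is regenerable from (source image,
condition id, per-stimulus seed). The test suite holds each transform to this
contract bit-for-bit against independent straight-line reference
implementations that share no code with the library.

## Condition grid

Condition ids are deterministic strings (`within_grid_b40_p0.5`) that
round-trip to their parameters. Enumeration order is lexicographic by
(family, spatial parameter, probability); the study design fixes the
*set* of conditions, not an order, and a deterministic order aids testing.
The stimulus builder samples source images without replacement within a
condition and, by default, uniquely across conditions (34 × 3 = 102 unique
stimuli, matching a design in which no image repeats anywhere in the study);
a flag permits reuse across conditions when fewer source images are
available.

## Statistics

* **Participant filtering** drops observers below a catch-trial accuracy
  threshold (default 2/3 — the exact catch design of the original study is
  not public, so this is a conservative, configurable default), then drops
  accuracy outliers beyond 3 × MAD from the cohort median, with the MAD
  scaled by 1.4826 so it estimates the SD under normality. A homogeneous
  cohort has MAD 0 and a zero deviation still passes.
* **Paired t-test** on matched per-condition accuracies uses the classical
  df = n − 1. A df override exists because the study this design follows
  evaluated its t statistic at df = 3 (the number of independent transform
  variables), a nonstandard convention we reproduce only on request; the
  statistic itself is unchanged. Zero-variance nonzero differences raise a
  degenerate-variance error instead of returning an infinite t.
* **Pearson r** and **OLS** are thin, validated wrappers over
  scipy/statsmodels; in simple regression R² equals r², which the suite
  checks. Pairing can be done at condition level (34) or, by aggregating
  first, at family level (8); both are supported by passing the appropriate
  series.
* **Confidence–accuracy correlation** correlates per-condition mean
  confidence with per-condition accuracy for one observer type. Network
  confidence is ingested as an opaque [0, 1] per-trial score; computing it
  from actual networks is out of scope.

## Synthetic fixtures

The fixture module generates everything the tests and demos consume:

* **Class images** — ten (shape, color) combinations (disk, square,
  triangle, …) centered on a coarse textured background, at any size
  divisible by the block grid. They emulate a 10-class recognition dataset
  only in the properties the transforms care about: distinguishable classes,
  enough color structure for SLIC, and exact divisibility. They do not mimic
  natural-image statistics, so passing tests demonstrate the transforms' and
  statistics' correctness, not claims about behavior on photographs.
* **Toy images** (≤ 64 pixels, all triplets pairwise distinct) make
  permutations exactly trackable; conservation and provenance proofs rely on
  this distinctness.
* **Manual segmentations** (halves, quadrants, bands, or explicit unequal
  sizes) bypass SLIC so the displacement rule can be tested on known
  geometry.
* **Simulated observers** carry a planted per-condition accuracy vector.
  Correctness is Bernoulli at the planted rate with wrong answers uniform
  over the nine foils. Human-like confidence is
  `clip(round(4·accuracy + 1 + N(0, 0.35)), 1, 5)` — an affine map of
  condition difficulty onto the 1–5 scale with trial noise — while
  network-like confidence is an independent uniform score; this reproduces
  the qualitative contrast between a near-unity human confidence–accuracy
  correlation and a near-zero network one. Catch trials are planted at 0.98
  accuracy.

## Problem sizes and numerical choices

The acceptance script and test suite run their conservation checks over 200
seeded transform applications (toys plus a 320 × 320 fixture), the
displacement provenance rule over 1000 seeds, Monte-Carlo uniformity checks
(permutations at *p* = 1, C(5,3) drop subsets) within 3 binomial standard
errors of enumeration, and the behavioral simulations at 34 conditions with
~100 trials per condition (1000 per condition for ranking recovery, at which
point the planted family ordering is recovered exactly, Kendall τ = 1).
Closed-form worked examples (t = 2√3, r = 0.8, slope/intercept/R² = 2/1/1)
are asserted to 1e-10. Stimulus builds in the tests use 160 × 160 sources —
divisible by the full block grid — to keep builds fast; the library itself
is size-agnostic up to divisibility.

## Limitations

* Transform correctness is proven on synthetic fixtures; behavioral numbers
  produced by the simulators characterize the analysis pipeline, not human
  subjects or trained networks.
* Network training/evaluation and real-subject data collection are out of
  scope; trial tables from either can be ingested via the documented CSV
  schema.
* JPEG inputs are accepted with a warning, but conservation guarantees hold
  only for lossless round trips.
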