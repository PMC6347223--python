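# Methods

## Descriptors

For one cell, given n detected straight filaments with lengths lᵢ (μm),
widths wᵢ (μm) and orientations αᵢ ∈ [0°, 180°) ("angle to the
horizontal"):

- resultant length R = (1/n)·√((Σ sin αᵢ)² + (Σ cos αᵢ)²), with the trig
  evaluated on the angles converted to radians and taken literally as unit
  vectors — **no axial doubling**.  Orientation data are axial by nature
  and the axial-statistics convention would double the angles first; the
  measurement convention these descriptors were defined under does not, so
  doubling is available behind a `doubled_angles` flag but off by default.
- circular standard deviation ν = √(−2 ln R), in radians.  ν = 0 ⇔ R = 1
  (parallel filaments).  When R underflows below 10⁻¹² (numerically
  isotropic set) ν is reported as +inf rather than raising, and such cells
  are excluded from downstream Δ statistics; this keeps batch processing
  alive on degenerate cells.
- F = Σ lᵢwᵢ (μm²), the empty sum being 0; L = (1/n)Σ lᵢ (μm), undefined
  for n = 0 (flagged, not raised, at the `cell_metrics` level).

Angles are stored in degrees throughout and converted only inside trig
calls.  ν enters the alteration ratio in radians; the ratio cancels the
unit, so this choice only affects how non-finite values propagate.

## Paired scoring and classification

Δ = 100(after/before − 1) per descriptor, requiring before > 0 and finite;
Δ_T = (|Δ_F| + |Δ_L| + |Δ_ν|)/3.  The apoptosis gate is strict:
Annexin-intensity SD > 6000 a.u. ⇒ positive (equality is negative).
Classification: detached ⇒ "detached"; apoptosis-negative ⇒ I; otherwise
Δ_T ≤ 10 ⇒ I, 10 < Δ_T ≤ 20 ⇒ II, Δ_T > 20 ⇒ III.  Strict published
inequalities leave the boundary points 10 and 20 unassigned; we assign
boundaries to the lower class (conservative damage call).  The thresholds
(10, 20, 6000) are configuration values with these defaults, so
sensitivity analyses need no code change.

Two deliberate edge-case policies:

- a non-detached post observation with **zero** detected filaments cannot
  yield finite Δ values; it is classed III (if apoptosis-positive) with
  flag `total_f_actin_loss`, because total loss of the network is the most
  severe alteration and exclusion would silently drop exactly the most
  damaged cells;
- detachment is taken from the manifest (explicit flag or missing post
  observation), never inferred from images.

The Annexin SD may be computed over a mask (cell ROI) or the whole frame;
mask-based is the default when a mask is given, both are supported.

## Synthetic cohorts

The generator emulates a paired pre/post design: 15 cells per replicate,
3 replicates, conditions {control, slow_1C, slow_10C, vitrified} × recovery
times {0, 15, 120} min ⇒ 540 cells by default.  Per cell:

- filament count uniform in [60, 120]; lengths log-normal with median 8 μm
  (log-sd 0.4) — stress-fibre-scale segments; widths truncated normal
  (0.4 ± 0.08 μm, bounded below at 0.05 μm), matching diffraction-scale
  apparent widths; orientations wrapped normal (mean 90°, σ = 0.45 rad)
  folded to [0°, 180°); centroids uniform in an elliptical footprint
  (30 × 20 μm semi-axes).
- damage operators (phenomenological, not biophysical):
  **buckling** replaces a Bernoulli-selected filament by k sub-segments
  whose lengths partition the parent (uniform Dirichlet), widths equal the
  parent (F conserved exactly at zero jitter), orientations jittered
  normally and re-folded, centroids on the parent axis;
  **depolymerization** deletes a Bernoulli subset plus everything whose
  centroid falls in "hole" discs; **cracking** splits filaments crossing
  a crack segment, removing a gap around the intersection and dropping
  pieces below 0.5 μm.  Depolymerization and cracking can only remove
  material, so they never increase F; cracking never increases L.
- per-stratum incidence (p_damaged, p_severe, detach probability) ships as
  presets that qualitatively mimic the published damage patterns (gentle
  slow freezing preserves networks at 0 min and deteriorates during
  recovery; fast slow freezing damages and detaches more cells;
  vitrification preserves best).  No quantitative generative model of
  cryo-injury exists, so the presets are illustrative only, and the
  package makes no claim of reproducing measured class fractions.
- apoptosis couples deterministically to damage by default (damaged ⇒
  Annexin-positive), because the classification presupposes that gate;
  `always_negative` is available, and Annexin SD targets are drawn from
  configurable positive/negative ranges (8 000–14 000 vs 500–3 000 a.u.).
  Generated pixel sets are rescaled to hit their target SD exactly, so the
  6000 a.u. gate behaves predictably.  Pre-thaw observations carry no
  Annexin value, mirroring the design (no apoptosis signal before
  cryopreservation).
- every Annexin-positive, non-detached cell's realised Δ_T is kept at
  least `margin_pct` (default 2 points) away from the 10/20 boundaries by
  an exact width rescale of the post network (which moves only Δ_F); the
  planted class is then computed from the realised alterations.  This
  makes planted-label recovery immune to round-trip floating-point noise.

Determinism: one global seed fans out through `numpy` `SeedSequence.spawn`,
one child per cell in the fixed order condition → time → replicate → cell,
so identical (config, seed) gives bit-identical tables and any subset of
the cohort regenerates independently.

Calibration note: the wrapped-normal identity R = exp(−σ²/2), hence ν = σ,
holds for the raw draws on the circle.  The fold into [0°, 180°) flips the
unit vectors of draws that leave the half-turn, which biases ν downward
once σ approaches ~0.8 rad (≈0.75 measured at σ = 0.8 even for the
best-case mean of 90°).  Calibration checks therefore evaluate ν on the
unfolded draws, where the identity is exact; generated *cohort*
orientations use σ = 0.45 rad, where the fold bias is ≈10⁻³.

### What the simulator does and does not emulate

It emulates the paired design, detachment, apoptosis gating, and the
first-order measurement signatures of buckling/loss/cracking on (ν, F, L).
It does not emulate filament curvature, junction topology, intensity
heterogeneity, segmentation errors of real micrographs, or any biophysics
of ice formation and osmotic stress.  Passing the planted-label and
directionality tests therefore demonstrates the internal consistency and
correctness of the analysis chain, not performance on real micrographs.

## Rendering and extraction

The renderer rasterizes each filament as an anti-aliased capsule of its
physical width, convolves with a Gaussian PSF (default σ = 0.8 px at
0.1 μm/px), adds constant background and optional Poisson–Gaussian noise,
and quantizes to 8 or 16 bits.  Axes: origin top-left, x rightward, y
downward, angles measured from +x and folded to [0°, 180°), identically in
renderer and detector.

The detector is deliberately simple: Hessian-based ridge enhancement
(Sato filter, scale 1.5 px) gates an intensity threshold (Otsu by default;
half-max and absolute values available), the binary is skeletonized,
junction pixels are removed so every component is a simple path, paths are
traced 8-connected and split wherever the direction over a 7-px window
turns by more than 20°.  Per segment: length = chord length; orientation
= chord angle; width = 2 × mean distance-transform value along the path
minus a 0.5 px discretization correction (distance-transform values are
measured between pixel centers and otherwise overestimate the half-width);
segments shorter than 5 px or with mean intensity below 5 (on the image's
own scale, default 8-bit) are dropped.  The window length and the width
correction were set by calibration against the renderer's ground truth,
which is the detector's stated contract; measured accuracy on noise-free
30-filament renders is count exact, L within 1 %, F within ~5 %, ν within
0.01 rad, orientation within 2°.  Crossing filaments fragment at
junctions — an accepted limitation; validation fixtures use disjoint
filaments.

## Statistics

Mann–Whitney U, two-sided (the conservative default where sidedness is
unstated), null hypothesis of equal medians.  The exact null distribution
is used when the smaller group has ≤ 8 observations and the pooled sample
is tie-free; otherwise the tie-corrected normal approximation with
continuity correction.  The approximation tracks exact enumeration within
0.01 on the branch's own domain (min(n) > 8) and within 0.02 down to
groups of 5; at groups of 3–4 the normal approximation is materially worse
(deviations up to ~0.04), which is exactly why the exact branch covers
those sizes.

Class fractions are computed per replicate and averaged unweighted across
replicates with the sample SD (ddof = 1; a single replicate reports SD 0).
Detached cells count in fractions but are excluded (with logged counts)
from Δ summaries and tests.  Quartiles use linear interpolation between
order statistics.  Direction splits (increased vs decreased) cover classes
II and III only; Δ = 0 counts as "not increased" (measure-zero under the
continuous pipeline).  Comparisons default to each cryo condition vs the
unfrozen control at the same recovery time (`all_pairs` adds cryo-vs-cryo);
p < 0.05 per comparison with no multiplicity correction, matching standard
per-comparison reporting; Bonferroni is available but off by default.

## Problem sizes

Default validation sizes — 10⁵ draws for circular-statistics calibration,
540-cell cohorts, 200-cell Monte-Carlo batches for operator
directionality, 30-filament renders at 768² px, 120 sample pairs against
exact rank-test enumeration — were chosen so the entire suite and the
acceptance script each run in well under a minute on one CPU while keeping
Monte-Carlo error far below the asserted tolerances.

## Known limitations

- The detector is not a reimplementation of any published filament-tracing
  tool; equivalence with such tools is neither attempted nor claimed.
- Damage presets are illustrative; measured class fractions of real
  cryopreserved cohorts are not a target.
- ν is undefined/unstable for nearly isotropic networks (R → 0); such
  cells are flagged and excluded from Δ statistics rather than imputed.
- The pipeline assumes pre/post pairing by cell identifier; no image
  registration or re-identification is performed.
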