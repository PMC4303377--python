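# Methods

## The localization problem

An ectopic atrial focus excites the atria from an abnormal site; the
resulting activation wavefront projects a characteristic potential
pattern onto the torso during the P-wave. With unipolar leads covering
both the front and the back of the chest, leads roughly "behind" the
spreading wavefront record negative P-waves (the wave travels away from
them), leads "ahead" of it record positive ones, and leads along the
transition record biphasic or near-flat waves. The torso quadrant with
the strongest negativity therefore faces the focus, and a fixed
correspondence between torso quadrants and atrial anatomy turns that into
an anatomical statement.

## Polarity classification

Each lead's P-wave segment is baseline-corrected by subtracting the mean
of a pre-P isoelectric window (at least 5 samples). Only the two global
extrema of the segment are measured; notched (bifid) sub-peaks are
deliberately ignored, since notch-based features are noise-sensitive and
ambiguous. The label is

* positive: `pos_amp > 2 * neg_amp` (strict),
* negative: `neg_amp > 2 * pos_amp` (strict),
* biphasic: otherwise — i.e. the secondary deflection is at least half
  the primary one, including the exact boundary,
* flat: `max(pos_amp, neg_amp) < flat_eps`.

The three non-flat rules partition the amplitude plane exactly, and the
classification is scale-invariant and antisymmetric under sign flips
(property-tested).

`flat_eps` is not part of the original rule set, so the default is
defined relative to the recording: 5% of the largest absolute peak across
all leads. This keeps the criterion unit-free and robust to global
amplitude rescaling; an absolute override (mV) is accepted everywhere.

## Quadrant scores and decision rules

Electrodes are assigned to the eight torso quadrants by face (anterior /
posterior) and by the sign of their lateral and vertical surface
coordinates relative to configurable midlines; electrodes exactly on a
midline go to the right/superior side. Scores are negative → 2, biphasic
→ 1, positive → 0. Flat leads enter the mean with the biphasic value 1
by default, because flat waves occur in the same transition band between
the positive and negative torso regions as biphasic ones; a
`flat_policy="exclude"` alternative drops them from the mean instead (a
quadrant left empty under that policy falls back to the neutral value 1).

`Sp` is computed in exact rational arithmetic (integer score sums over
integer lead counts), so score ties are exact equality and float
round-off can neither fabricate nor destroy a tie. The decision rules on
the set of quadrants attaining `Sp_max`:

1. a single maximum wins;
2. two tied quadrants sharing an in-face edge: each tied quadrant's
   remaining in-face neighbour is examined and the tied quadrant whose
   neighbour has the larger `Sp` wins;
3. three tied: the corner quadrant (adjacent to both others) wins;
4. four or more tied: the largest `Sp` among non-tied quadrants is found
   and the tied quadrant adjacent to it wins, counting the front/back
   counterpart as adjacent.

"Adjacent" otherwise means sharing an in-face edge; diagonal quadrants
are never adjacent. Cases the rules leave open are resolved by one
documented fallback — compare the mean `Sp` over each tied quadrant's
non-tied neighbours — and a persistent tie raises an explicit
`UnresolvableTieError` rather than guessing. Such unresolvable patterns
arise for foci sitting essentially on an octant boundary, where the score
pattern is exactly mirror-symmetric; they are scored as failures in the
evaluation suites.

Quadrant numbering is a convention (Qt1 anterior superior-right, Qt2
anterior superior-left, Qt3 anterior inferior-right, Qt4 anterior
inferior-left, Qt5–Qt8 posterior in the same order) and is overridable
through the correlation table, which also carries the per-variant mapping
from atrial quadrants to anatomical regions. Two variants ship with the
package, covering a textbook atrial orientation and a segmentation-derived
one.

### Sub-quadrant refinement

For each in-face neighbour of the winning quadrant, the focus is tagged
*near* the shared boundary when `Sp_max − Sp_neighbour ≤ 0.1` and *far*
otherwise; the two axes combine into a 2×2 sub-quadrant. The matching
ground-truth tag of a simulated focus is geometric: near an octant
boundary plane when the corresponding local coordinate is within half the
octant's extent along that axis.

Two quantization effects limit the refinement under the default 64-lead
layout. With exactly 8 leads per quadrant, `Sp` moves in steps of 1/8 =
0.125 > 0.1, so *near* fires only on exact ties. And `Sp` saturates at 2
when a focus drives an entire half-column of a face negative, which makes
both vertically adjacent quadrants tie at 2 and the vertical tag read
*near* even for octant-centre foci. The lateral tag remains informative,
and quadrant-level localization is unaffected (the refinement never
changes the winning quadrant), but refined-resolution success rates are
systematically below quadrant-level ones — more steeply so than the
modest drop reported for the full biophysical chain.

## Dipole tracking

The body-surface dipole is tracked at electrode resolution: per frame,
the positive pole is the lead with the maximal potential and the negative
pole the lead with the minimal one (lowest lead index on exact ties);
all-zero frames are flagged degenerate. The trajectory summary projects
pole electrodes to 2-D torso-surface coordinates (lateral x, vertical z,
plus the face tag) and carries the amplitude time courses.

## Forward model

The synthetic generator replaces a monodomain atrial model coupled to a
boundary-element torso with the cheapest chain that preserves what the
algorithm actually reads — the spatial polarity pattern:

* **Geometry.** The atrial surface is a triangulated ellipsoid with
  semi-axes 45 × 35 × 40 mm (lateral × antero-posterior × vertical),
  an icosphere at subdivision 3 (642 vertices, 1280 triangles). A fixed
  generic-position rotation is applied to the unit sphere before scaling
  so that no vertex lies exactly on an octant boundary plane. Octants are
  defined in the anatomical frame and rotate rigidly with the mesh under
  the position-variant transform.
* **Activation.** The wavefront spreads at a uniform conduction velocity
  (default 0.7 mm/ms); activation times are shortest-path distances on
  the mesh graph divided by velocity. The graph contains the mesh edges
  plus unfolded-diagonal shortcuts across each pair of adjacent
  triangles, which keeps discrete geodesics within a fraction of a
  percent of the smooth ones (antipodal sphere error ≈ 0.2%). At the
  fast pacing rate (cycle length < 500 ms) velocity is scaled by 0.9 to
  emulate rate-dependent conduction slowing; this changes P-wave timing
  and amplitude but not the polarity map.
* **Sources.** Each triangle emits a current dipole along the in-plane
  gradient of the activation time (the propagation direction), scaled by
  its area, with a raised-cosine time course of 20 ms (the order of the
  atrial upstroke). The source strength constant (default 3.0) is a pure
  amplitude calibration placing peak leads near 0.1 mV; polarity is
  invariant to it.
* **Volume conductor.** Potentials are the infinite homogeneous-medium
  dipole superposition `phi = m·r / (4π σ r³)` with σ = 0.2. Torso
  inhomogeneities (lungs, liver, spine, blood masses) modulate P-wave
  amplitudes, not polarity patterns, which justifies the homogeneous
  stand-in for a polarity-based algorithm.
* **Leads.** 64 unipolar electrodes in two 4 × 8 grids on a 140 mm-radius
  cylindrical torso centred on the atria (rows at z = ±35, ±105 mm,
  columns at ±10°…±70° from the mid-sagittal plane on each face),
  referenced against Wilson's Central Terminal — the mean potential of
  three distant limb electrodes. The layout is data, not code; any layout
  covering both faces works.
* **Pacing.** Three stimuli at cycle length 700 ms (slow) or 300 ms
  (fast); the final beat's P-wave window is returned, preceded by 20 ms
  of baseline. Beats superpose linearly; a cycle length shorter than the
  beat duration triggers an overlap warning rather than an error.
* **Noise.** Additive white Gaussian noise per lead with standard
  deviation expressed as a fraction of the recording's clean peak
  amplitude, reproducible from a seed.

## Evaluation design

The default suite samples 80 foci — 10 uniformly random surface vertices
per octant — with cycle lengths alternating 700/300 ms within each octant
and lead noise sd 0.05, mirroring a development-plus-blind-test design of
the same size. Success at quadrant level means the predicted atrial
quadrant equals the octant containing the true focus; refined success
additionally requires both near/far tags to match the geometric truth.
Every suite is bit-reproducible from its seed (focus sample and per-focus
noise seeds derive from it), simulation failures are recorded as
incorrect cases without aborting the suite, and an exact binomial 95% CI
accompanies each rate (80 trials is small). Typical quadrant-level
success is 92–100% depending on the seed; failures concentrate on foci
within a few millimetres of an octant boundary, where scores tie or the
neighbouring quadrant wins.

Noise monotonicity holds for foci away from octant boundaries (centroid
suite: 1.0 at sd 0–0.2, 0.44 at sd 0.5). On the stratified suite it can
be violated at low noise because boundary foci fail *deterministically*
at zero noise through exact score ties, which noise dithers favourably
about half the time.

## What the synthetic tests do and do not show

The generator reproduces the features the algorithm relies on: a
focus-facing negativity, a lateral polarity gradient with a biphasic
transition band, rate-invariant polarity maps, and WCT-referenced
unipolar leads. It does not emulate anatomical conduction structure
(pulmonary-vein sleeves, Bachmann's bundle, crista terminalis),
repolarization, torso inhomogeneity, gender-specific anatomy, or the
morphological richness of measured P-waves. Passing suites therefore
demonstrate the correctness and internal consistency of the localization
chain under the stated physics, not clinical performance on recorded
ECGs.

## Numerical choices

* Exact rational `Sp` comparisons (no float ties); the refinement
  threshold 0.1 is compared as the exact fraction 1/10.
* Peak times break exact amplitude ties toward the earliest sample; pole
  leads toward the lowest lead index; midline electrodes toward the
  right/superior quadrant.
* Uniform sampling step 1 ms; baseline window = the 20 ms preceding the
  final stimulus.
* Degenerate inputs fail loudly: empty quadrants, disconnected meshes,
  electrodes coincident with sources, missing WCT channels and malformed
  files raise typed exceptions rather than propagating NaNs.
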