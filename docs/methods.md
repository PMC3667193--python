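# Methods

## The measurement model

The package assumes a *fixed scene* photographed several times: camera,
arena and lighting do not move between frames, so every pixel is a
noisy sample of a constant background value except when a moving
organism covers it. Under two conditions the background is recoverable
exactly by a per-pixel minimum over frames:

1. **polarity** — organisms are strictly brighter than the substrate at
   every pixel they cover (use the maximum projection for dark
   organisms, or the median/mean with difference-mode removal when the
   contrast can go either way);
2. **coverage** — every pixel is organism-free in at least one frame.

When both hold and there is no pixel noise, the residual
`max(frame − background, 0)` is exactly the organism intensity offset
on organism pixels and 0 elsewhere, which is why counting becomes
threshold-independent: any cut between 0 and the offset yields the same
particles. With noise or partial coverage the recovery is approximate
and the residual contrast shrinks; the reliability experiment
(`reliability_curve`) measures how many pictures a given density needs
before the biosurface stops growing.

Coverage fails in two characteristic ways worth knowing: dead or
motionless animals are absorbed into the background (by design — they
are excluded from the census), and at high density the pixels organisms
occupy in *every* frame stay bright in the background, carving holes or
splits into detected particles.

## Pipeline conventions

* Pixel coordinates are `(row, col)`, 0-based, origin top-left; all
  arrays stay in the stack's integer bit depth (8-bit default).
* Grayscale conversion uses Rec.709 luminance weights
  (0.2126, 0.7152, 0.0722), rounded half up.
* Mean projection: `(2·sum + n) // (2n)` (integer round-half-up).
  Median of an even frame count: mean of the two central order
  statistics, rounded half up. These choices make every output
  bit-reproducible; they are asserted against per-pixel brute-force
  oracles in the tests.
* Otsu thresholding maximises the between-class variance over all 256
  candidate levels; when a plateau of levels is equally optimal (e.g.
  a two-valued residual) the *middle* of the plateau is returned, so
  the reported threshold sits centrally in the stable range rather than
  at its edge. A constant image raises a degenerate-input error; the
  census treats that case as "nothing moved" and counts zero.
* Foreground is strictly above (bright polarity) or strictly below
  (dark) the threshold. Default connectivity is 8 (diagonal contact
  joins particles), matching the common particle-analyzer default.
* Particle "length" is the major-axis length of the ellipse with the
  component's second moments (the ImageJ fit-ellipse convention);
  maximum Feret diameter is available via `length_metric="feret"`.
  Note the moment ellipse of a *rectangular* bar of n pixels has major
  axis `4·sqrt((n²−1)/12) ≈ 1.15·n`, longer than the bar — the
  estimator is calibrated for elliptical bodies, which real elongated
  organisms and the synthetic organisms both are. Single-pixel
  particles are assigned a length of one pixel so lengths stay
  positive.
* Registration recovers integer-pixel translations as the argmax of the
  circular cross-correlation of mean-subtracted frames, computed via
  the product of their Fourier transforms; vacated margins are filled
  from the reference frame. Sub-pixel alignment and rotation are out of
  scope: at the image scales this workflow targets, camera drift is a
  few whole pixels.
* The size histogram is left-closed (`[edge, edge+width)`), the last
  bin closed; the default 0.1–3.0 mm range in 0.02 mm steps gives 145
  classes. Out-of-range particles are tallied separately, never
  silently binned. Bin assignment tolerates 1e-9 mm of floating-point
  slack so exact-edge lengths land in the bin they name.
* Per-frame counts aggregate by the arithmetic mean (median available);
  the biosurface is the mean over frames of the summed retained
  particle areas.
* The sliding background window keeps its full length near the stack
  ends (it slides rather than shrinks), so every per-frame model pools
  the same number of frames; window = stack size reproduces the global
  pipeline bit-exactly.
* Density correction: ordinary least squares of manual count on
  biosurface over low-density boxes; the corrected count
  `slope·biosurface + intercept` is floored at 0 and always reported
  alongside the raw count. There is no automatic switch-over density —
  choosing when to trust the correction is the analyst's call.

## The synthetic-scene generator

`SceneSpec` defaults describe a small rearing box: 160×160 px at
20 px/mm (an 8×8 mm view), five pictures, 20 organisms of 0.3–0.5 mm
(uniform lengths; lognormal available), rendered as 3:1 filled ellipses
at +120 grey levels above the substrate, walking 6 px per frame in a
random direction with reflecting walls. The substrate combines a base
level of 60, a ±10 linear gradient in a random direction, Gaussian
speckle (σ = 6) and ten fixed bright debris discs — the gradient and
speckle emulate uneven lighting and substrate texture, the debris the
motionless bright grains that defeat single-image thresholding.
Optional i.i.d. Gaussian pixel noise and a per-frame illumination
offset complete the picture. Three independent seed-derived streams
(background, organisms, noise) are consumed in a fixed order, so adding
organisms never changes the background realisation and identical specs
are bit-identical.

Deliberate idealisations, and what they mean for the tests:

* **Integer centroids.** Organism centres are rounded to whole pixels
  before rasterisation, so a given organism covers the same number of
  pixels in every frame. This turns two qualitative claims into exact
  identities on synthetic data: the ground-truth centroid equals the
  rendered pixel-set centroid (tracking error is measured against truth
  with no rasterisation ambiguity), and the biosurface is
  non-decreasing in stack size whenever organisms never touch, because
  `biosurface(n) = mean frame union − |pixels occupied in all n
  frames|` with a constant union. Real animals move sub-pixel amounts
  and change posture; real reliability curves plateau, but not
  monotonically to the last decimal. At high density, where per-frame
  unions fluctuate as organisms adjoin differently in each frame, even
  the synthetic mean can dip by ~0.1% between large n; the tests
  therefore assert exact monotonicity only in the non-touching regime
  and the qualitative rising-then-plateau shape elsewhere.
* **Clip-free contrast.** The true background is clipped to
  `[0, 255 − offset]` (bright organisms) so the organism offset never
  saturates; without this, an organism crossing a bright debris grain
  would lose contrast and threshold-robustness could not hold even in
  principle. Real cameras do clip; the guarantee documents the regime
  the exactness claims live in.
* **Placement modes.** Default placement is uniform at random —
  organisms may overlap, as crowded real boxes do. `confine_to_cells`
  assigns each organism its own grid cell and reflects its walk inside
  it: with `cell_margin_px ≥ 1` organisms can never come within
  touching distance (the study condition for exact-count tests); with
  margin 0 they may touch across cell borders but never overlap.
* **No shadows, no texture, no photometric organism model.** Passing
  tests on these scenes validates the arithmetic and the pipeline
  logic, not robustness to shadows, moulted skins, reflections or
  motion blur — the known failure modes of the method on real images.

`generate_covered_scene` retries deterministically derived sub-seeds
until the coverage condition holds, making "a fully covered scene" a
constructible study condition rather than a matter of luck.

## Validation problem sizes

The acceptance script and test suite run at desk scale, chosen so the
whole suite completes in well under a minute while every regime of
interest is represented: 8×8 stacks (≤7 frames) for the projection
oracle, 160×160 boxes for census experiments (20 organisms ≈ 1.3%
occupancy for the low-density regime; 230 equal-size organisms ≈ 15%
for the high-density regime; 120 organisms over 20 frames for the
density correction, where raw counts undershoot truth by ~20–25% and
corrected counts land within a few percent), 64×64 frames with ±8 px
shifts for registration, a 200-frame 128×128 scene for tracking, and a
20-box batch for determinism.

The density-correction recovery carries a small systematic bias worth
stating: with random placement the true overlap of organisms shrinks
the union biosurface below `N × area`, so the corrected count sits a
few percent *below* truth (the bias grows with occupancy roughly as
`1 − (1 − e^{−λ})/λ` for occupancy λ). It remains far closer to truth
than the raw count, which is the method's claim.

## Known limitations

* Translation-only registration; rotation, scale and lens distortion
  are not modelled.
* No watershed splitting of merged particles: at densities where
  animals habitually touch, use the biosurface regression rather than
  raw counts.
* Single-target tracking follows the largest particle per frame; it
  will jump between animals if more than one is present. Multi-target
  identity maintenance is out of scope.
* The scene generator does not model shadows, reproduction/moulting or
  photometric organism detail; conclusions about real-image robustness
  require real images.
* Colour is carried through (per-particle mean RGB) but not used for
  detection; segmentation always runs on the grayscale residual.
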