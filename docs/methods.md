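# Methods

## Scope and model structure

The package models a guidance experiment on micropatterned thin-film
magnets in four coupled layers: (1) pattern geometry and effective landing
areas, (2) magnetostatics of the patterned film, (3) force landscapes and
kinetics of bead-labeled cells, (4) occupancy statistics. A synthetic-data
generator supplies populations, landings and tracks with the statistical
structure the analysis assumes, so every stage is testable end to end.

## Stray field of patterned films

Each magnetic shape is a uniformly magnetized rectangular prism (rotated
prisms for slanted segments). With fixed magnetization **M**, the
equivalent-surface-charge solution gives **B** outside the prism as a sum
over the eight corners of arctan (normal component) and log (tangential
components) terms; arbitrary **M** directions superpose the three
axis-aligned solutions, and patterns superpose their prisms (linearity).
The sign convention of the corner sum was pinned against an independent
Gauss–Legendre quadrature of the charged faces; agreement is ~10⁻¹¹
relative, and the far field matches a point dipole of moment |M|·V to
10⁻⁵ at 100× the largest dimension.

Assumptions and consequences:

- **Fixed, uniform magnetization** (charge-sheet model), not a
  self-consistent susceptibility solution. This matches films poled by an
  external magnet along a fixed axis: in-plane along the bar long axis for
  permalloy, out-of-plane for CoFe/Pd multilayers (represented as one
  effective layer with user-set M·t).
- **Absolute scale is free.** The induced (sub-saturation) magnetization of
  the film is not known from first principles; the default is
  µ₀|M| = 1.0 T (a permalloy-like scale) with a dimensionless
  `scale` factor. Everything the package asserts quantitatively — hot-spot
  structure, anisotropy ratios, speed ratios, occupancy fractions — is
  invariant to this scale.
- Films are computed at **true nanometre thickness**; no thickness /
  magnetization rescaling is needed because the closed form is exact. Above
  a thin film the field depends only on the sheet moment M·t — asserted as
  a regression test (halving t at fixed M halves B to < 1% at heights ≫ t).
- The model is valid strictly outside the material; evaluation points
  inside a prism raise, and points landing exactly on singular edge
  extensions are nudged 1 nm vertically.

Units are SI internally (tesla, A/m, metres); interfaces take µm in-plane,
nm for thickness, and heights "above the film top".

## Force landscapes

Below saturation the bead moment is linear in B, so the force per unit
lumped coefficient is F = (B·∇)B = ∇|B|²/2 (the second form holds because
curl B = 0 outside sources). Both forms are implemented by central
differences on the analytic field (step h = 0.01 µm, ≫ fp noise, ≪ the µm
feature scale) and cross-checked to 10⁻³ relative; the saturated-moment
form (m·∇)B is separate. The default coefficient k = 1 leaves forces in
arbitrary units: bead susceptibility and the film's absolute M are unknown,
and a calibration helper (`kinetics.calibrate_k_lin`) maps one observed
speed at one point to absolute units when needed.

**Pointwise vs grid differentiation.** Force maps differentiate the
analytic field at every node rather than applying `np.gradient` to a
sampled |B|² grid. The distinction matters: the pole-edge force peak is
~2 µm wide, and 1 µm grid differencing smears it enough to understate the
long-axis/transverse anisotropy by half a decade (10^2.4 instead of the
sampling-density-independent 10^3.05). Grid differencing remains available
and warns when the spacing is coarse.

**Hot spots** are strict local maxima of |F| above a relative threshold
(default 0.05 of the global max), 8-connected, plateaus merged to their
centroid. Maxima closer than a merge radius (default 10 µm, one cell
diameter) are clustered into one spot: at 2 µm height the magnitude has a
pair of maxima straddling each pole edge ~3 µm apart, which constitute a
single docking site for a 10 µm cell. With these defaults the in-plane bar
yields exactly two hot spots, one per pole, stable under grid refinement.

**Edge attraction** quantifies the anisotropy-direction claim: the fraction
of the pattern boundary whose force exceeds half the boundary maximum is
≈ 1 for out-of-plane magnetization (the whole top face is charged, every
edge equivalent) and ≈ 0.2 for an in-plane bar (only the two pole edges).

## Kinetics

Overdamped motion at terminal velocity u = F/(3πµD): explicit Euler with
per-step displacement capped (default 0.5 µm), positions reported at the
1 s frame interval, terminating on hot-spot capture (default radius 5 µm,
one cell radius), domain exit, or a time horizon. Choices:

- **Viscosity** defaults to 8.9·10⁻⁴ Pa·s (water-like culture medium,
  25 °C). It cancels in every ratio-type claim.
- **Drag** uses the Stokes law of the carrying body's own diameter (beads
  are small against the cell); no Faxén wall correction — a documented
  simplification that again cancels in ratios.
- **No Brownian term** by default (the deterministic drag-balance model);
  optional Gaussian per-step positional noise requires an explicit RNG.
- Speed ratios are algebraic — (m/D)_a / (m/D)_b — and exact; they carry
  the 2× (two beads vs one) and 10/2.8 ≈ 3.57× (free bead vs one-bead
  cell) predictions.
- Near the pole edge the force is nearly singular; first-order Euler
  overshoots the |B|² ridge by O(step). Trajectory tests therefore assert
  monotone field-energy ascent with a 2·10⁻³-of-peak tolerance at a 0.1 µm
  step cap (measured dips: 1.6·10⁻², 6·10⁻³, 1.1·10⁻³ at 0.5, 0.25,
  0.1 µm). Endpoint positions converge to < 0.5 µm under step halving.

## Geometry and the uniform-landing null

Footprints are exact shapely geometries; dilation by the cell-contact
margin is a true Minkowski disk buffer (32 segments/quadrant, area error
< 0.1%), with a square-edge variant available. The null probability p₀ for
the proportion test is the dilated footprint area (clipped to the unit
cell) over the unit-cell area. For the 200 × 50 µm² bar array with
150/200 µm spacings the unit cell is 350 × 250 µm², giving a nominal
fraction 10000/87500 ≈ 0.114 and, with the default 10 µm margin,
p₀ = (10000 + 500·10 + π·10²)/87500 ≈ 0.175. Brute-force 0.1 µm
rasterization agrees within 1% for all shipped presets. The line / web /
zigzag presets carry package-chosen default dimensions (10–30 µm widths,
100 µm pitch); their fractions are configuration-dependent, not fixed
constants of the method.

Axis convention: the bar array builder places the long axis along x with
the "lateral" spacing along it (the reading that reproduces the
350 × 250 µm² unit cell from the stated dimensions); `long_axis="y"` is
available, and field-line studies use a single bar with long axis y so the
poles sit at y = ±100 µm.

## Statistics

- **Velocity**: OLS of distance vs time. Default distance is net
  displacement from the start, which is unbiased under localization noise;
  cumulative path length (available as `distance="path"`) inflates the
  slope by ≈ σ²/step per frame on noisy tracks (folded-noise bias — with
  σ = 0.5 µm and 10 µm steps, +0.025 µm/s against a ~0.004 µm/s standard
  error). The two coincide for straight noiseless motion.
- **Proportion test**: exact binomial by default. The normal approximation
  with continuity correction is conservative at the scales of interest
  (exact size 0.034 at n = 100, p₀ = 0.175, vs 0.048 for the exact test
  and 0.064 uncorrected); all three variants are exposed. Calibration is
  asserted by simulation: 10,000 null draws give a type-I error inside
  0.05 ± 0.01 for the default.
- **Welch's t-test**, two-sided, α = 0.05, no multiple-testing correction;
  the degenerate zero-variance case is flagged explicitly.
- **Occupancy**: touching = centre inside the dilated footprint; hot spot
  occupied = ≥ 1 cell within the capture radius; cells-per-bar assigns
  overlap ties to the nearest bar centroid.

## Synthetic data

- **Labeling**: zero-inflated shifted Poisson — count 0 with probability
  1 − p_bind, else 1 + Poisson(λ_cond). A plain Poisson cannot match both
  a bound fraction of 0.823 and an overall mean of 2.8; the chosen law is
  the simplest two-parameter family that can, and it is pluggable. The
  overall mean is interpreted as averaging over *all* cells (bound or
  not), so λ_cond = mean/p_bind − 1: 2.40 for the streptavidin preset
  (p = 0.823, mean 2.8) and 0.575 for the IgG control (p = 0.127,
  mean 0.2).
- **Landings**: i.i.d. uniform over the substrate rectangle — exactly the
  proportion test's null.
- **Tracks**: straight constant-speed motion at 1 s frames with i.i.d.
  Gaussian localization noise, default σ = 0.5 µm (sub-pixel tracking
  scale); ground truth is returned alongside. Default scenario speed is
  10 µm/s over 5 s (the ~50 µm-in-5 s scale of a one-bead cell under a
  strong external magnet).
- Every stochastic entry point requires an explicit seed; bundles are
  byte-identical under (config, seed) and embed a config hash, seed and
  package version in their provenance record.

What the generator deliberately does **not** emulate: cell–cell and
bead–bead interactions, non-straight migration, heterogeneous per-cell
speeds, frame drop-out, and the per-experiment variance structure of
pooled calibration measurements. Passing tests therefore demonstrate
correctness of the pipeline under the stated model, not robustness to
those real-data effects.

## Problem sizes and numerical defaults

Default force maps sample a 40 µm-padded window at 1 µm spacing (~37k
nodes for the single bar); refinement checks use 0.5 µm. Oracle
rasterizations run at 0.1 µm. Calibration draws use n = 10,000 cells;
recovery studies use 100 seeds × 60 frames; test-size simulation uses
10,000 replicates. These sizes keep every quantity's Monte-Carlo error
well inside its acceptance band while the full suite runs in under a
minute.

## Known limitations

- Absolute fields (tesla) and forces (newtons) are defined only up to the
  film's induced magnetization and the bead coefficient; one measured
  speed or field value is needed to fix them.
- No micromagnetics: domain structure, hysteresis and shape-dependent
  demagnetization are outside the model; the charge-sheet picture is an
  idealization of a poled soft film.
- The external poling magnet's own gradient (which drives bulk
  magnetophoresis toward the dish edge) is not modelled; only the
  pattern's stray field acts on cells.
- 2-D overdamped kinetics on the substrate plane: sedimentation, vertical
  force components and post-capture adhesion are not simulated.
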