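# magnetoguide

Modelling toolkit for **magnetic guidance of labeled cells on micropatterned
thin-film magnets**: analytic stray fields of micro-magnet arrays, the
attraction-force landscapes they create for superparamagnetic beads, the
drag-balance kinetics of bead-decorated cells pulled across a substrate, and
the occupancy statistics used to show that guidance beats uniform landing.

It is written for bioengineers and biophysicists who pattern soft-magnetic
films (e.g. permalloy bars, or CoFe/Pd multilayers with perpendicular
anisotropy), label cells with superparamagnetic microbeads, and want a
quantitative, closed-form (no finite-element solver) model of where the cells will go — plus a
calibrated synthetic-data generator so the whole analysis pipeline is
testable without microscopy data.

## The model

**Stray field.** A uniformly magnetized rectangular prism has a closed-form
field in the surface-magnetic-charge picture: magnetization **M** deposits
charge ±|M| on the two faces it crosses, and **B** outside the prism is a
signed sum of arctan/log corner terms. Patterned films are superpositions of
such prisms (rotated segments handle zigzags and webs), computed at true
nanometre thickness. The kernel is validated against numerical
surface-charge quadrature (≤ 10⁻⁶ relative) and the point-dipole far field.

**Force.** Below saturation a bead's moment is linear in the field, so

    F = k (B·∇)B = (k/2) ∇|B|²      (curl B = 0 outside the film)

with a lumped coefficient *k* (bead volume × susceptibility / µ₀). Cells ride
uphill in |B|²; for an in-plane-magnetized bar the landscape concentrates
into two **hot spots** at the bar poles, while out-of-plane magnetization
makes the entire pattern edge attractive. At saturation F = (m·∇)B.

**Kinetics.** At Re ≪ 1 the magnetic force balances Stokes drag
F = 3πµDu₀, so an object moves at its terminal velocity and relative speeds
in a shared field reduce to moment/diameter ratios: a cell with two beads
moves 2× faster than with one; a free 2.8 µm bead moves 10/2.8 ≈ 3.6× faster
than a 10 µm cell carrying one bead. Trajectories are overdamped gradient
ascent on |B|², terminating at hot spots.

**Statistics.** Landing on the pattern is tested against the uniform null:
a cell of diameter ~10 µm touches a magnet iff its centre falls in the
footprint dilated by the contact margin, so the null probability p₀ is the
*effective* (dilated) area fraction of the unit cell. One-sample exact
binomial proportion test and Welch's t-test cover the group comparisons;
cell speeds come from OLS fits of distance vs time on 1 s frame tracks.

## Worked example

```python
import magnetoguide as mg
from magnetoguide import forces

bar = mg.single_bar()                      # 200x50 um^2, 74 nm permalloy, poles at y=+/-100
fm = forces.pattern_force_map(bar, z_um=2.0, spacing_um=1.0)
spots = mg.find_hot_spots(fm)
print("hot spots:", [(round(h.x_um, 1), round(h.y_um, 1)) for h in spots])
print("log10 anisotropy:", round(mg.anisotropy_ratio(fm, ("x", 0.0), ("y", 80.0)), 3))

bead = mg.MagneticParticle(diameter_um=2.8)
cell1 = mg.CellBody(diameter_um=10.0, n_particles=1, particle=bead)
cell2 = mg.CellBody(diameter_um=10.0, n_particles=2, particle=bead)
print("speed ratio 2-bead vs 1-bead cell:", mg.speed_ratio(cell2, cell1))
print("speed ratio free bead vs 1-bead cell:", round(mg.speed_ratio(bead, cell1), 2))

cells = mg.sample_cells(10_000, mg.MMP_SA, seed=1)
print("labeled fraction:", (cells.n_particles >= 1).mean(),
      " mean beads/cell:", round(cells.n_particles.mean(), 3))

arr = mg.build_bar_array()                 # 200x50 bars, 150/200 um spacings
af = mg.area_fractions(arr, dilation_radius_um=10.0)
print("nominal area fraction:", round(af["nominal_fraction"], 4),
      " effective (null p0):", round(af["effective_fraction"], 4))
print("proportion test p-value:",
      round(mg.proportion_test(30, 100, af["effective_fraction"])["p_value"], 5))
```

prints

```
hot spots: [(0.0, 100.0), (0.0, -100.0)]
log10 anisotropy: 3.048
speed ratio 2-bead vs 1-bead cell: 2.0
speed ratio free bead vs 1-bead cell: 3.57
labeled fraction: 0.8217  mean beads/cell: 2.785
nominal area fraction: 0.1143  effective (null p0): 0.175
proportion test p-value: 0.00218
```

Reading: the bar attracts at exactly two pole hot spots; its long-axis peak
force exceeds the transverse one by three orders of magnitude; the labeling
generator reproduces its calibration (82.3% labeled, 2.8 beads/cell); a
uniform landing would put 17.5% of cells on the dilated bar footprint, so
observing 30/100 cells on the pattern rejects uniformity (p ≈ 0.002).

A CLI wraps the same pipeline — `magnetoguide field --preset single_bar
--out run/` writes field/force grids and the hot-spot table, `magnetoguide
migrate` runs a full in-silico guidance experiment, `magnetoguide synth`
writes a reproducible synthetic bundle, and `magnetoguide stats` fits track
velocities and proportion tests. See `docs/methods.md` for model details
and parameter choices.

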