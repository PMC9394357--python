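# Methods

## Model

`dpdmix` simulates a binary mixture of coarse-grained single-tail lipids in
water with dissipative particle dynamics (DPD).  Each lipid is a linear chain
of one hydrophilic head block (NH beads of species H1 or H2) joined to one
hydrophobic tail block (NT1 or NT2 beads of species T1 or T2); water is a
single W bead.  All quantities are reduced: bead mass m = 1, interaction
range rc = 1, thermal energy kBT = 1, so the time unit is
tau = sqrt(m rc^2 / kBT).  A physical mapping (rc ≈ 0.5 nm, tau ≈ 1.88 ns for
a lipid/water system at bead volume 0.03 nm^3) is carried as metadata only.

Beads within rc interact through three pairwise forces:

* conservative soft repulsion  F^C = a_ij (1 − r/rc) r̂,
* dissipative drag             F^D = −γ w(r)^2 (r̂·v_ij) r̂,
* random kicks                 F^R = σ w(r) ζ_ij Δt^(−1/2) r̂,

with w(r) = 1 − r/rc inside the cutoff and zero beyond, and ζ_ij a
unit-variance Gaussian drawn once per pair per step with ζ_ij = ζ_ji.  The
amplitudes obey the fluctuation–dissipation relation σ² = 2γkBT (σ = 3,
γ = 4.5 by default), which makes the D+R pair a momentum-conserving
thermostat at kBT = 1.  Chain connectivity adds a harmonic bond force
F = ks (1 − r/rs) r̂ (ks = 120, rs = 0.7 rc) and a bending force derived from
U = kθ (θ − θ0)² (kθ = 6, θ0 = π) for every three consecutive beads,
including the triples spanning the head–tail junction.

The repulsion matrix encodes the chemistry: a = 25 for like beads and for the
hydrophilic contacts (head–water and head–head across species), a = 100 for
every other unlike pair (tail–water, head–tail, tail–tail across species).
Through the Flory–Huggins mapping χ = 0.286 (a_ij − a_ii) the unlike contacts
sit at χ ≈ 21.45 — deep in the strong-segregation regime, which is what
drives the tails out of water and assembles bilayers.

Integration uses the modified velocity-Verlet scheme: positions drift with
the old forces, velocities are predicted with a factor λ (default 0.5, the
standard choice; the scheme's originators leave it free), forces are
recomputed at the new positions with fresh random draws and the dissipative
term evaluated on the predicted velocities, and velocities are corrected with
the mean of old and new forces.  Δt = 0.01 τ throughout.

## Numerical design

* **Neighbour search.**  A Verlet pair list with search radius rc + skin
  (skin = 0.5 rc by default) built on a linked-cell sweep; bead arrays are
  kept sorted by spatial cell inside the integrator for cache locality and
  scattered back to canonical order at chunk boundaries.  The list is rebuilt
  whenever any bead has moved more than skin/2 since the last build — a
  sufficient condition for validity, so no interaction can be missed.  Boxes
  with fewer than three cells per axis fall back to an all-pairs loop.  A
  test asserts the two paths agree to 1e-10 per force component.
* **Random numbers.**  ζ_ij is produced by a counter-based hash
  (splitmix64 over seed, step and the canonical pair id) fed through the
  Beasley–Springer–Moro inverse normal CDF (|error| < 1e-8).  Draws are
  therefore independent of traversal order and bead renumbering, the pair
  symmetry ζ_ij = ζ_ji is exact, and a run is bitwise reproducible for a
  given seed and configuration on one worker.
* **Overlapping beads** (r = 0) are legal under the soft potential; the force
  direction is then undefined and is taken along a deterministic
  pseudo-random unit vector at the r→0 magnitude, with occurrences counted
  and logged.
* **Near-collinear angles**: for sin θ < 1e-8 the bending force is set to
  zero (the gradient direction is ill-defined and its magnitude vanishes for
  θ0 = π).
* **Energies.**  The total energy per bead reported in the logs is
  kinetic + conservative-pair + bond + angle, in kBT.  The pair potential is
  (a rc/2)(1 − r/rc)², the bond potential (ks rs/2)(1 − r/rs)², the angle
  potential kθ(θ − θ0)²; a finite-difference test pins force = −grad for all
  three.

## Initial configurations

The generators are the simulations' inputs.  `layered_bilayer_init` places all
type-I chains in the upper leaflet and all type-II chains in the lower one
(the fully unmixed start): chains are straight (bonds at rs, angles at θ0)
and normal to the membrane plane, heads outward, tails meeting at the box
midplane; lateral positions sit on a jittered square lattice (jitter ≤ 0.2
spacing) and packings tighter than 0.4 rc² per chain are rejected.  Water
fills everything outside the initial tail slab, so the short initial-stage
relaxation (water penetration, thickness equilibration) emerges from the
dynamics rather than the construction.  `random_init` disperses chains as
freely jointed walks.  Two pre-assembled fixtures exercise the analytics: a
layered bilayer pierced by a centred cylindrical pore
(`perforated_fixture`) and a closed spherical bilayer with interior and
exterior water (`vesicle_fixture`).  All builders fill to the global bead
density (3 beads/rc³), draw Maxwellian velocities at kBT = 1 with zero total
momentum, and are reproducible under a seed.

What the generators do *not* emulate: pre-equilibrated or energy-minimised
states, thermal undulations, protrusions or compositional noise of a real
bilayer.  Passing the fixture-based analytics tests therefore shows the
estimators are correct on clean geometry, not that they are robust to every
disordered configuration; the simulation-based tests cover the thermally
roughened case.

## Observables

* **Density profiles** along a box axis (slab bins, default 0.5 rc) or
  radially about a centre (spherical shells); densities times bin volumes
  re-sum exactly to the species counts.
* **P2 order parameter** (3 cos²θ − 1)/2 of the end-to-end vector of a
  selected sub-chain (head, tail or whole) against a box axis, averaged per
  spatial bin of the segment's first bead.  1 = parallel, −0.5 =
  perpendicular, 0 = isotropic.
* **Gyration tensor** per chain after unwrapping the chain across periodic
  boundaries (walking bonds with minimum-image displacements); eigenvalues
  sorted descending; the shape factor
  δ = 1 − 3(L1²L2² + L2²L3² + L1²L3²)/(L1²+L2²+L3²)² is 0 for a sphere and 1
  for a rod.
* **Leaflet mixing counts**: a chain joins the upper leaflet when its mean
  head z lies above its mean tail z (on the unwrapped chain), the lower
  otherwise; chains flatter than a configurable tilt are reported unassigned
  (pore-rim chains) rather than forced.
* **Membrane normal detection**: when the tail beads percolate one box
  plane under periodic connectivity the structure is a spanning membrane and
  its mean normal is topologically pinned to the remaining axis
  (undulations cannot tilt it), so that axis is used exactly.  A
  non-spanning slab — the edge-bounded ribbons some compositions form in
  small boxes — is free to assemble tilted; its normal is then the
  smallest-variance eigenvector of the minimum-image lipid-position
  covariance, and profiles are projections onto that direction.  Measuring
  along a box axis instead would overestimate a tilted ribbon's thickness
  by the secant of the tilt angle.  Thickness and head-chain order are
  always measured along the detected normal, with each frame centred on its
  own lipid centre (so membrane drift cannot broaden frame averages).
* **Bilayer thickness**: distance between the outermost half-maximum
  crossings of the total head-bead density along the normal, with sub-bin
  interpolation.  (If this convention ever disagrees systematically with
  peak-to-peak measures, the latter is the documented fallback.)
* **Pore detection**: tail beads within ±2.5 rc of the bilayer midplane are
  projected on an x–y grid (1 rc default); after a periodic 3×3 binary
  closing (removes single-cell thermal voids), the largest periodically
  connected empty component above a 4-cell floor is the pore; diameter
  = 2 sqrt(area/π).
* **Structure classification**: tail occupancy that percolates the x–y plane
  under periodic connectivity is a membrane (perforated if a pore is found);
  a non-spanning aggregate whose lipid-free grid complement contains an
  enclosed, water-holding cavity is a vesicle; anything else is `other`.
* **Stage segmentation**: the energy series is smoothed with an
  edge-preserving moving average (default window 50 records, capped at a
  sixth of the series) and split by an exhaustive two-change-point
  least-squares fit (prefix sums); each stage must cover at least a tenth of
  the series.  A split that explains almost no variance is flagged
  degenerate and falls back to thirds.  The three segments are reported as
  the initial, adjustment and stable stages.

## Interfacial tension

The pressure tensor follows the Irving–Kirkwood picture:
p_aa = (Σ m v_a v_a + Σ_pairs F_ij^a r_ij^a)/V, with each pairwise
contribution localised along the straight contour between the two beads —
apportioned to z-slabs by the length fraction of the segment inside each
slab — so the slab decomposition sums to the whole-box tensor exactly (an
identity the tests enforce).  Three-body bending forces are decomposed into
their two bond legs for localisation.  Only conservative pair, bond and
angle forces enter the reported stress: the thermostat's dissipative and
random forces constitute the momentum flux of the heat bath and average to
zero at equilibrium, adding only noise.  The interfacial tension is
σ_z = p_zz − (p_xx + p_yy)/2 (normal minus mean tangential), resolved over
z-slabs, over a y-window × z-slab region near a pore (pairs enter a window
by their periodic midpoint y), or averaged over the membrane-domain slabs
(lipid density above half its plateau) per dynamics stage.

## Problem sizes and presets

Two presets ship.  `full_scale_config` is the full-scale production box: 30³ rc³,
N = 81,000 beads at density 3, n1 = n2 = 900 chains, NH = 3, 300,000 steps.
`desk_config` is the reduced working preset: 15 × 15 × 30 rc³ (N = 20,250),
n1 = n2 = 225 — the same areal chain density and the same lipid bead
fraction as the full box — with layered initial conditions.  The test suite
and the acceptance script run this reduced box for 36,000 steps (360 τ) for
the symmetric NT = 9 membrane and 60,000 steps (600 τ) for the asymmetric
NT1 = 5 / NT2 = 6 composition: per-frame convergence diagnostics show the
membrane's thickness and chain order settle by ~350 τ (two independent
realisations agree at the same plateau), while the short-tail mixture
passes through a curved intermediate and only flattens around ~500 τ.
Energies are recorded every 100 steps and frames every 500–1,000 steps.

Two details of the ensemble averaging matter.  First, each frame's profile
is recentred on the bilayer midplane (circular mean of the lipid
coordinates along the normal) before frames are averaged, so slow diffusion
of the membrane along its normal does not broaden the mean profile.
Second, structural averages (thickness, order profile, gyration/shape) use
the last 12 stable-stage frames (60 τ): the energy-based change-point
detection fires early — the energy plateaus well before the slower
structural ordering (chain stretching, thickness growth) has finished — so
the late window is the converged part of the stable stage.  The energy
stage means themselves are still reported over the full segmentation.

At this reduced scale the slow collective observables of the full-scale system —
the complete 9×9 phase diagram, absolute leaflet-exchange counts, the
pore-diameter time course and the stage-resolved tension magnitudes — are
not expected to reproduce quantitatively; they are covered qualitatively
(sign, ordering, localisation) and remain available through
`full_scale_config` for full-length runs.

One finite-size effect deserves explicit mention.  The short-tail
asymmetric composition (NT1 = 5, NT2 = 6) forms a pored bilayer sheet at
full scale, with a pore of roughly 17 rc diameter — a structure that cannot
fit a 15 × 15 rc cross-section.  In the reduced box the same excess-edge
relief instead produces an edge-bounded bilayer **ribbon** spanning one
lateral axis, generally tilted with respect to the box axes (it passes
through a curved intermediate and flattens by ~500 τ).  Its chain-level
observables (shape factor ≈ 0.90) match the full-scale pored membrane; its
tilt-corrected face thickness comes out ~8.5–9 rc, somewhat below the
full-scale 10 rc — consistent with the ribbon's two curved edge rims
sequestering lipids and leaving the flat face at a larger area per lipid —
and its topology is reported honestly as `other` by the classifier rather
than pretending a pore exists.

## Known limitations

* Single linear tail per lipid; no branched/two-tail topologies, charges or
  electrostatics.
* NVT only: no barostat, so membrane area (and hence residual lateral
  stress) is set by the chain count, not self-adjusted.
* The classifier's grid heuristics (1 rc cells, 3× closing) are tuned for
  bilayer-scale structures; exotic phases (bicontinuous, wormlike) fall into
  `other`.
* Leaflet assignment by z-orientation presumes a roughly flat bilayer; use
  the radial profile machinery for vesicles.
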