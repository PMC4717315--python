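# Methods

This note records the models, numerical choices and study-design
decisions behind `tamflow`, at the level of detail a maintainer needs
to re-derive or deliberately change them.

## Volume conductor

**Model.** Quasi-static extracellular potential in anisotropic tissue:
`∇·(σ_T ∇Φ) = 0`, with conductivity tensors derived voxelwise from
diffusion tensors by `σ_T = (σ_e/d_e) D`. The ratio defaults to
`σ_e = 0.2 S/m`, `d_e = 0.7×10⁻³ mm²/s` so that a typical white-matter
tensor (mean diffusivity ≈ 0.7×10⁻³ mm²/s) maps to a mean conductivity
near 0.2 S/m; the ratio is a config parameter and belongs on any
sensitivity-analysis list, since published effective-medium values
vary.

**Discretization.** Cell-centered finite volumes on a rectilinear
(tensor-product) grid with nonuniform spacings. Face conductances use
the series (harmonic-mean) combination of the face-normal tensor
component `n·σ·n` of the two adjacent cells. Off-diagonal tensor terms
are *not* discretized: the scheme is a two-point flux approximation,
which keeps the system a symmetric positive-definite M-matrix (so the
discrete maximum principle holds and Jacobi-preconditioned conjugate
gradients converge robustly) at the cost of representing obliquely
oriented anisotropy only through its axis projections. For the mildly
curved bundles of the phantom this is an acceptable trade; a
multi-point flux scheme would be the upgrade path if tensor obliquity
ever becomes load-bearing.

**Domain and boundary.** The grid is fine near the lead (default
0.5–1 mm) and geometrically graded outward (ratio ~1.3–1.35) to a far
grounded boundary ≥ 14 cm away, emulating a large padded head volume at
negligible cost. Dirichlet conditions: cathode contact cells at −1 V
(the unit stimulus; clinical amplitudes scale the solution linearly),
anode contacts at 0 V for bipolar settings, outer boundary grounded.
The lead shaft is painted as near-insulating cells (10⁻⁶ S/m), contact
cells as metal (10⁴ S/m) so the contact–tissue face conductance is
limited by the tissue side. At solver resolutions coarser than the
0.635 mm lead radius, the embedded lead radius grows to 0.75 cells so
the shaft remains represented.

**Encapsulation sheath.** A 0.5 mm shell around the shaft with its own
conductivity. When the shell is thinner than a cell it is widened to
one cell and its conductivity rescaled by the ratio of
`ln(1 + t_eff/r) / ln(1 + t/r)`, preserving the radial resistance of
the annulus. Calibration solves the model repeatedly and bisects
(Brent) the sheath conductivity on a log scale until V/I matches the
measured impedance within 1 %; impedance is computed as the reciprocal
of the total face current leaving the cathode cells.

**Analytic benchmark.** A −1 V staircased sphere of radius `a = 3 mm`
in a homogeneous medium is solved on one octant (Neumann symmetry
planes) and compared with `Φ = −a/r` at probe radii 2a–10a in several
directions. Convergence runs during development showed the effective
electrical radius of a cell-center-staircased sphere is about half a
cell *smaller* than nominal (the jagged surface adds spreading
resistance), so Dirichlet inclusion uses radius `a + h/2`; with
`h = 0.3 mm` the maximum probe error is ≈ 1.2 %. The far boundary sits
~900 mm out (graded cells make this nearly free) because a grounded
boundary at distance R depresses the potential at radius r by roughly
r/R — at r = 30 mm even R = 300 mm would contribute a 10 % error,
swamping the discretization.

**Stimulus waveform.** Voltage-controlled stimulation is modeled as an
ideal square pulse through a series RC (electrode capacitance 6.6 µF ×
measured impedance, e.g. τ = 6.6 ms at 1 kΩ) after a fixed 42 %
interface voltage drop: during the pulse the tissue sees
`0.58·exp(−t/τ)` of the programmed amplitude; over a 90 µs pulse the
droop is ~1.4 %. Inter-pulse charge recovery is assumed complete
(pulse width ≪ τ ≪ period for all clinically used settings), so a
single pulse per period is simulated.

## Electrode geometry and seed regions

The model 3391 lead: 1.27 mm diameter, four 3 mm contacts. The printed
"4 mm inter-contact distance" is read as an edge-to-edge gap — a 4 mm
*center* spacing would overlap 3 mm contacts — giving 7 mm center
spacing. Tip-to-first-contact defaults to 1.5 mm (not printed anywhere
authoritative; configurable). Seed regions are per-active-contact
spheres of 4 mm radius over voxel centers (≤ comparison), unioned for
multi-cathode settings; on a 2 mm grid a sphere centered on a voxel
center covers exactly the 33 offsets with i²+j²+k² ≤ 4.

## Tractography

The orientation estimator is a declared simplification of Bayesian
multi-fiber fitting: direction 1 is the principal eigenvector;
direction 2 (the second eigenvector) is emitted where the planarity
coefficient `2(λ₂−λ₃)/Σλ` exceeds 0.2, which fires in voxels where two
bundle tensors blend; angular dispersion falls linearly with FA from
30° (FA 0) to 2°, and voxels with FA < 0.05 are flagged isotropic and
terminate tracking. Two caveats are inherent to eigen-decomposition:
crossing-fiber directions are exact only for near-orthogonal crossings
(oblique blends yield the bisector frame), and the container accepts
externally computed orientation fields for anyone wanting a real
multi-fiber fit.

Propagation: Euler steps of 0.5 mm along the voxel direction best
aligned with the incoming heading, perturbed by a Gaussian tangent-
plane sample of the voxel's dispersion; termination on CSF, grid exit,
per-step turns > 80°, 2000 steps, or loops. Loop detection triggers
when a streamline re-enters a voxel it has visited with a heading
within 90° of its previous heading there — cheap, kills true orbits,
spares hairpin (U) fibers. Tracking is bidirectional; the two halves
are concatenated with the seed recorded as an interior index, and each
half carries its own termination reason.

## Streamline uniqueness filter

Five critical points per streamline at arc-length fractions 0, ¼, ½,
¾, 1 (arc length, not vertex index, so the summary is independent of
step count). For a pair, the RMS of the five corresponding distances
and the midpoint distance are computed. The printed rule conflates two
criteria; it is implemented as: a streamline is excluded iff against
*every* other streamline `RMS > 10 mm OR midpoint > 5 mm` — i.e. it
survives if at least one neighbour is close under both measures, with
the stricter 5 mm bound on the midpoint. The predicate sits in one
swappable function, a brute-force evaluation of the same definition
serves as the oracle in tests, and bundles with fewer than two
streamlines are kept (the universal quantifier is vacuous).

## Axon model

A single-cable reduction of the MRG myelinated axon at 5.7 µm fiber
diameter: nodes of Ranvier (1.9 µm × 1 µm, cm 2 µF/cm²) every 0.5 mm
with fast Na⁺ (3.0 S/cm²), persistent Na⁺ (0.01), slow K⁺ (0.08) and
leak (0.007), E_Na 50 mV, E_K −90 mV, and the published MRG gate
kinetics; internodes are single passive compartments (3.4 µm axon,
myelin-lumped cm 0.002 µF/cm² ≈ 2 µF/cm² per membrane over ~2×100
lamellar wraps, g 10⁻⁵ S/cm²); axial resistivity 70 Ω·cm. The leak
reversal is set to −87.45 mV so the nodal currents balance exactly at
the −80 mV rest (the full double cable rests there with E_leak −90;
the reduction needs the small correction). With these defaults the
chronaxie is ≈ 0.36 ms — inside the plausible myelinated-fiber range
(0.05–0.5 ms) used as a gate in the tests.

The extracellular drive enters through the axial coupling of the
interpolated potential (activating function). Integration: backward
Euler on the tridiagonal compartment chain at dt = 5 µs with
Rush–Larsen exponential gate updates. Backward Euler is
unconditionally stable, so the blow-up guard flags only non-finite or
> 2000 mV values; polarization of a few hundred mV immediately beside
a contact is physical, not numerical.

**Activation and thresholds.** A fiber is active when the membrane
crosses 0 mV at *both* terminal nodes within the simulated window (the
conservative reading of "propagating action potential"; single-ended
detection is a parameter). Threshold search brackets with a geometric
amplitude ladder before bisecting, because at amplitudes far above
threshold the hyperpolarized flanks adjacent to the cathode can block
propagation — probing only at the 20 V cap would misclassify close
fibers as inexcitable. dt-halving moves thresholds by < 1 % (measured
with a 2 mV bisection tolerance so quantization does not mask the
discretization effect).

## Maps and statistics

Heat maps count active fibers per 1 mm voxel by exact segment–voxel
(Amanatides–Woo-style) traversal — each fiber at most once per voxel;
vertex sampling would miss corner-clipping segments. Region counts use
the same traversal against the label volume; a fiber counts for every
region its trajectory enters (endpoint-only counting is a flag).
Responder/non-responder comparison marks voxels with a count advantage
≥ 20 per pairing and correlates each responder's total advantage-voxel
count with their improvement (Pearson by default, Spearman by flag).

Factor analysis is unrotated correlation-matrix PCA by default
(loadings = eigenvector·√eigenvalue; standardized scores), retaining
eigenvalues > 2; varimax rotation is available by flag, and the
rotation machinery uses multiple deterministic starts because the SVD
fixed-point iteration can stall on a saddle at the identity start
(notably with two factors). Stepwise regression: forward entry at
p < 0.05, backward removal at p > 0.10 on partial-F p-values, ties
broken by larger |correlation| then name, so column order cannot
change the result; reported are standardized Betas and adjusted R².
Thresholds are the defaults of the statistics packages this analysis
family historically used.

## Synthetic data: what it emulates, what it does not

The phantom is a 64³ × 2 mm grid with three 4 mm-radius bundles whose
in-tube tensors point along the local centerline tangent at FA 0.75
over an FA 0.10 background (random axes; FA 0 gives exactly isotropic
tensors), one CSF sphere, and spherical gray-matter targets at the
bundle endpoints. Overlapping tubes blend tensors by an FA-weighted
sum renormalized to the common mean diffusivity — positive definite by
construction and a genuine two-direction test case for the orientation
estimator.

The three bundles cross the electrode corridor at different depths
(ventral "dlPFC-like" target bundle, mid "thalamus-like", dorsal
"lOFC-like" off-target), so which contacts are cathodal determines
which pathways are recruited — mirroring the clinical observation that
dorsal contacts preferentially engage lateral-orbitofrontal-bound
fibers. This separation is also what keeps the per-bundle activation
fractions from collapsing onto a single "distance to lead" factor
across a cohort, which would make factor-level attribution impossible
for any method.

Cohorts place jittered electrodes (per-axis jitter 1.8/1.8/3 mm, depth
emphasized), draw cathode sets from {0}, {1}, {2}, {0,1}, {1,2} and
amplitudes from 2–6 V, and generate outcomes as
`YBOCS% = β₀ + β_t·f_target − β_o·f_offtarget + ε` with defaults
β = (10, 40, 40) and ε ~ N(0, 6). The noise level was fixed at design
time by a power check so that a 20-patient cohort identifies the
off-target effect reliably (model R² ≈ 0.85) — a deliberately
well-powered recovery design, not an attempt to mimic clinical
effect-size uncertainty. Ground-truth fractions `f_*` are measured on
64 seeded parallel offset fibers per bundle (fraction with any point
within 4 mm of an active cathode center). With ε = 0 the generating
coefficients are identified exactly by OLS on the true fractions.

What the phantom does *not* emulate: real ALIC/NA anatomy or any
atlas, MRI physics and registration error, fanning/kissing fiber
configurations, distance bias of probabilistic counts, inter-subject
anatomical variability. Passing tests on the phantom therefore
demonstrate internal correctness of the chain (field → tracking →
activation → statistics) under a known truth, not clinical validity on
patient imaging.

In the recovery analysis the activation matrix gives each bundle four
region columns (gain-varied, 5 % multiplicative noise) and the
off-target factor is *identified* on varimax-rotated loadings — with
near-equal block eigenvalues the unrotated components mix blocks by
construction, which is an identification problem, not an estimation
one; the package default for plain factor analysis remains unrotated.

## Problem sizes

Defaults used by the shipped analyses and checks: the analytic
benchmark solves ~2.3×10⁵ cells; patient solves use 0.75–1.2 mm cores;
demonstration cohorts track 1–3 streamlines per seed voxel with a
400–600 step cap (the clinical-fidelity numbers — 1000 per voxel, 2000
steps — are the package defaults and are exercised by the parameter
validation, while the demonstrations favor minute-scale runs); the
recovery study uses 50 cohorts of n = 20. Each choice is a
problem-size decision recorded in the outputs' provenance blocks.

## Known limitations

- Two-point flux ignores tensor obliquity (see above).
- Eigen-decomposition orientation estimation cannot resolve oblique
  crossings; the bisector bias is inherited by tracking through
  blended-tensor voxels.
- Non-active contacts are modeled as insulators rather than floating
  conductors; the capacitive interface is reduced to the fixed 42 %
  drop plus the series RC.
- Single-pulse activation is the criterion; 135 Hz train-following
  fidelity is out of scope.
- The uniqueness filter is O(n²) in streamlines (blocked to bound
  memory); at the clinical 10⁵-streamline scale a spatial index would
  be the next step.
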