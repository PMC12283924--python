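# Methods

## Discretization and time integration

A deformable body is a tetrahedral mesh of `N` particles. Masses are lumped:
each tet adds `rho * V / 4` to each of its four corners, giving a diagonal
mass matrix; a pinned (boundary-condition) vertex is encoded by inverse mass
zero, the standard position-based-dynamics convention. All internal units
are SI (m, kg, s, Pa); configuration files accept Young's modulus in kPa —
the unit elastography reports — and convert at parse time.

Each frame of duration `dt` (default 1/60 s) is divided into `substeps`
equal substeps (default 64, the "small steps" regime: many cheap substeps
with a single projection sweep each converge better than few substeps with
many sweeps). Per substep of duration `h`:

1. reset all Lagrange multipliers to zero,
2. semi-implicit prediction `v += h a_ext`, `x += h v` (free vertices only),
3. optional continuous-collision clamp of the predicted motion,
4. `iterations` Gauss–Seidel sweeps over the constraint families in a fixed
   deterministic order — tet-elastic (hydrostatic then deviatoric per
   element), volume, distance, then shape matching as a positional pass —
   followed by contact projection and positional friction,
5. velocity update `v = (x - x_prev)/h`, scaled by `max(0, 1 - c_damp h)`,
6. restitution on contacts whose pre-solve normal velocity was approaching.

Multipliers are reset per substep (not per frame): with substep-rescaled
compliance `alpha_tilde = alpha / h^2` this makes material stiffness the
invariant across `(dt, substeps)` choices, which the tests verify directly
(the settled extension of a compliant link equals `m g alpha` regardless of
stepping). Determinism is a contract: identical configuration and seed give
bit-identical trajectories on one platform.

The inner sweeps are compiled numba kernels, numerically identical to the
plain-numpy per-constraint reference implementations in `constraints.py`;
a dedicated test drives both paths over a full mixed constraint set and
requires agreement to ~1e-12.

## Constraints

* **Distance** (per unique edge): `C = |x_i - x_j| - d`. Compliance default
  `1/(mu * L_rest)` — the edge network resists distortion, so the shear
  modulus sets its scale.
* **Volume** (per tet): `C = (1/6)(x21 × x31)·x41 - V`; gradients are the
  cross-product cofactors, summing to zero. Compliance default
  `1/(lambda * V_rest)` (volumetric role). At `nu = 0` (`lambda = 0`) the
  constraint is disabled (infinite compliance) rather than an error.
* **Neo-Hookean** (per tet): with deformation gradient `F = D_s D_m^{-1}`,
  a hydrostatic constraint `C_H = det F - 1` (gradient: the cofactor matrix
  of `F`, chained through `D_m^{-1}` to the vertices) and a deviatoric
  constraint `C_D = ||F||_F` (gradient `F / C_D`, chained likewise), with
  compliances `1/(lambda V)` and `1/(mu V)`. The corresponding energy is the
  simplest stable Neo-Hookean density; the square-root form of `C_D` keeps
  the compliant energy non-negative while leaving forces unchanged.
  `C_H` as written leaves a small inward force at the rest pose (the energy
  minimum of the pair sits slightly inside `F = I`); an opt-in
  `rest_correction` flag shifts the hydrostatic target by `mu/lambda`,
  which restores exact rest stability. The default keeps the uncorrected
  form; for liver-like Poisson ratios (`mu/lambda ≈ 0.1`) the rest bias is
  a few-percent isotropic shrink, visible in the quasi-static tests.
  Elements with `|det F| < 1e-8` or `C_D < 1e-8` are skipped for that visit
  (no inversion-recovery machinery).
* **Shape matching** (per cluster): the best-fit rigid transform of the
  cluster is `T =` current mass-center and `R =` the polar rotation of
  `A = Σ m_i (x_i - T) q_iᵀ` (SVD with determinant sign fix, so reflections
  are never returned; a rank-deficient `A` falls back to the previous
  rotation). Corrections `Δx_i = k (R q_i + T - x_i)` conserve the cluster's
  mass-weighted momentum exactly. This is a direct positional blend, outside
  the multiplier machinery, because it is a goal-position technique rather
  than a scalar constraint.

### Shape-matching stiffness across substeps

The cluster stiffness `k ∈ [0,1]` is defined **per frame**: the fraction of
the deviation from the rigid pose removed in one frame. Each of the
`substeps × iterations` visits applies `1-(1-k)^(1/(substeps·iterations))`.
Without this compensation a default-stiffness global cluster visited 64
times per frame freezes the body rigid and no compliant deformation
survives. Default stiffness is `nu / 0.5` clipped to `[0,1]` (more
incompressible tissue holds shape more strongly), overridable. Cluster
layouts: one global cluster, or a regular grid over the bounding box
(undersized cells are merged into their nearest neighbour so every vertex
is covered and every cluster has the ≥4 members a rotation fit needs).

## Legacy-PBD baseline

PBD mode runs the identical constraint set with no multipliers and a
per-family stiffness `k`, iteration-compensated as `k' = 1-(1-k)^(1/it)`.
Because legacy PBD projects constraints to their rest values, the
deviatoric constraint is driven toward `sqrt(3)` (its rest value), not 0 —
projecting it to zero would collapse every element.

The library default is `k = 1` (classic hard PBD). For like-for-like
comparison experiments the scenario layer instead derives a
**compliance-matched** `k` per family: for a compliant constraint a single
visit equals a PBD visit with `k_eq = D/(D + alpha/h^2)`,
`D = Σ w |∇C|^2`; the scenario uses the family median of `k_eq` at the rest
pose. This gives the baseline the same overall softness as the compliant
solver while exposing its structural limitation: one scalar per family
cannot reproduce the per-element compliance distribution (in the phantoms,
adjacent tets differ up to 2× in rest volume and hence in compliance), and
its effective stiffness shifts with timestep and iteration count. Both
effects concentrate error unevenly across neighbouring elements, which the
smoothness metric is designed to detect.

## Collisions

Vertex-vs-SDF contacts only (plane, sphere, oriented box); no
self-collision or deformable–deformable contact. A vertex closer to a
collider than the contact thickness (default 1 mm, which suppresses resting
chatter) is projected onto the thickness surface (hard inequality
constraint). Friction is Coulomb-style and positional: the substep's
tangential displacement is cancelled if shorter than `mu_f ×` (normal
correction), else shortened by that amount. Restitution reflects the
pre-solve approaching normal velocity at the velocity stage:
`v_n ← -e v_n,pre`. Continuous collision detection (off by default; 64
substeps make tunnelling unlikely at demo speeds) finds the earliest impact
along each predicted motion segment — exactly for planes, by sphere tracing
plus bisection otherwise; sphere tracing steps by the SDF value, which is
1-Lipschitz, so thin geometry cannot be skipped.

## Metrics

* **Smoothness** `S = (1/n) Σ V_min/V_max` over face-adjacent tet pairs
  ("adjacent" = sharing a triangular face; edge/vertex adjacency would make
  the pair count ambiguous). Volumes enter as absolute values so inverted
  elements degrade `S` instead of producing ratios outside (0, 1];
  inversions are counted separately. The spread reported is the population
  standard deviation of the per-pair ratios at one frame. The "maximum
  deformation" frame of a run is the frame minimizing instantaneous `S`.
* **Volume drift** `(Σ|V(t)| - ΣV_0)/ΣV_0`; **kinetic energy**
  `½ Σ m v²`; **max penetration** past the contact thickness; **RMS
  constraint residuals** per family (note the deviatoric residual is
  `sqrt(3)` at rest by construction).

## Synthetic phantoms

Patient-derived meshes are deliberately out of scope; two generators stand
in. The **box phantom** splits each cell of a structured grid into 5 tets
with a parity flip so neighbouring cells share face diagonals; its total
volume is exact. The **ellipsoid phantom** ("liver-like") keeps the cubic
cells — sized by the largest semi-axis — whose centroids satisfy the
ellipsoid equation, then splits them the same way; resolution 8 at liver
scale (8×5×6 cm semi-axes) gives 560 tets, a desk-scale stand-in for a
patient mesh. The phantoms reproduce the voxelized-volume, connectivity and
closed-surface properties of real tet meshes but not their boundary-fitted
element grading or anatomical shape detail, so passing tests demonstrate
solver behaviour, not anatomical fidelity. The 5-tet split makes the rest
smoothness itself nontrivial (central/corner tets differ 2× in volume,
`S_rest ≈ 0.77` for the ellipsoid).

## Study conditions and problem sizes

The comparative drop test uses the softest of four liver stiffness presets
measured in vivo by shear-wave elastography — (E kPa, ν) = (2.1972, 0.4597),
(5.8597, 0.4523), (6.2781, 0.4505), (36.6175, 0.4377) — density
1000 kg/m³, a 0.5 m drop onto a ground plane with friction 0.5 and
restitution 0 (drop height and contact parameters are not dictated by any
measurement; they are fixed package defaults), 64 substeps, 1 iteration,
45 frames at 60 fps, grid shape-matching clusters (3³), and a seeded
1 mm/s initial-velocity jitter. Deterministic checks (statics, ballistics,
chain) use small particle systems defined inline; their sizes (10 links,
300 settling frames, 1000 ballistic substeps) keep every check at a few
seconds on one core.

## Known limitations

Isotropic hyperelasticity only (no viscoelasticity or anisotropy); no
cutting, suturing or topology change; no self-collision; no fluid–structure
interaction; no inversion recovery beyond skipping degenerate elements;
geometric-stiffness and constraint-Hessian terms of the full Newton system
are omitted (quasi-Newton XPBD). A violent impact of very soft material at
coarse resolution shows large transient volume drift and element
inversions — physically a splat the discretization cannot resolve; the
volume constraint restores the total on settling, but local element quality
during impact is resolution-limited.
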