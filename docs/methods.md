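# Methods

This note records the model, the numerical choices, and the limits of what
the synthetic benchmarks can show. Geometry is in mm in files and at the API
surface; all field physics is evaluated in SI metres internally.

## Quasi-static model

TMS coil currents are separable, `J_TMS(r,t) = I(t) J_TMS(r)`, with the
waveform normalized to unit peak slew rate, so H-fields scale with `I(t)` and
E-fields with `I'(t)`; all spatial parts below are peak-normalized and the
scalar `dI/dt` (default 6.6e7 A/s) multiplies only the final reconstruction.
The head is a piecewise-homogeneous conductor on a tetrahedral mesh
(tags 1..5 = WM, GM, CSF, skull, scalp; 0.126, 0.275, 1.654, 0.01, 0.465 S/m),
surrounded by an insulator. The total field is `E = E_p − ∇φ` with the scalar
potential solving the pure-Neumann Poisson problem `∇·σ∇φ = ∇·σE_p`,
`n̂·(σ∇φ − σE_p) = 0` on the scalp.

**FEM.** First-order (P1) elements; per-tet constant E-fields. The stiffness
operator is singular with a constant nullspace; right-hand sides are
projected to compatibility and solutions gauge-fixed to zero mean. The
default linear solver is one shared sparse LU factorization of the
one-node-reduced system, reused across every probe, mode, and reference
solve of a session — for a compatible RHS this reproduces the projected
solution exactly, and at desk-scale meshes (≤ ~50k nodes) it is faster and
more deterministic than iterative solves. A Jacobi-preconditioned CG path is
available (`method="cg"`); residuals are checked against `tol` (default
1e-10) in either case.

## Mode basis

The reachable space of brain E-fields from any exterior quasi-static source
is probed with Gaussian white-noise magnetic surface currents, piecewise
constant on the facets of the Huygens surface (the scalp surface offset 1 mm
along angle-weighted node normals). Probe primary fields use the single-point
quadrature

    E_WP(r) = − Σ_j A_j W_j × (r − r_j) / (4π |r − r_j|³),

each probe gets one FEM solve, and the ROI (WM+GM) fields are orthogonalized
under `⟨f,g⟩ = Σ_k V_k f_k·g_k` via economic QR of the `√V_k`-weighted matrix
`Z` followed by an SVD of `R` (the modes are the columns of `QŨ` divided by
`√V_k`, ordered by singular value; truncations are therefore nested). Probe
streams are counter-based (Philox keyed by `(seed, realization)`), so
realization `i` never depends on how many realizations are requested.

**Oversampling and subspace iteration.** On finely meshed heads the probe
operator's singular spectrum decays fast and drawing exactly one probe per
requested mode recovers a near-optimal subspace. On coarse desk-scale
phantoms the spectrum has a heavy tail (a large share of it is
discretization-scale field content), and the plain range finder then wastes
much of the basis: on the default phantom a 450-mode basis built from 450
probes leaves ~26% of a coil field's energy unspanned, while the *optimal*
450-dimensional subspace leaves ~3%. `build_noise_mode_basis` therefore
draws `ceil(1.5 × n_modes)` probes and applies two rounds of randomized
subspace iteration (adjoint + forward passes through the same FEM machinery,
with a QR re-orthonormalization between rounds) before the SVD truncation;
this lands within ~0.2 percentage points of the optimal subspace.
`oversample=1, power_iterations=0` restores the plain one-probe-per-mode
construction.

## Equivalent currents and reciprocity

Each mode `M(i)`, impressed as a volume current, drives the conduction
response `σE = −σ∇φ_M` (one FEM solve per mode: "2 FEM runs per mode"
overall). The total current `J = M + σE` over the *whole* head radiates onto
the Huygens surface with single-point quadrature per tet:

    E_M(r_j) = −(μ0/4π) Σ_k V_k J_k / |r_j − c_k|        (−∂A/∂t part)
    H_M(r_j) =  (1/4π)  Σ_k V_k J_k × (r_j − c_k)/|r_j − c_k|³

and Love equivalence gives `J_S = n̂×H_M`, `K_S = −n̂×E_M`. The coefficient
for a placement is the single-point surface quadrature

    a(i) = Σ_j A_j [E_p·J_S(i) − H_p·K_S(i)]  (+ correction, below),

assembled once into a dense operator `B` (stored single precision; all
offline arithmetic is double). The sign of the `E_M` kernel is fixed by the
requirement that `a(i)` from this surface integral equals the volume
projection `⟨M(i), E_ref⟩` of a direct FEM solve — an end-to-end oracle the
test suite enforces at 2%.

**Near-field quadrature.** The Huygens gap is only 1 mm, while desk-scale
tets near the scalp are several mm across, so the centroid rule is corrected
for (facet, tet) pairs closer than 3 tet diameters by re-integrating those
contributions on a recursive 8-fold tet subdivision (depth 2). Depth 0
reproduces the pure single-point rule. The gap-to-edge ratio is the
accuracy-controlling parameter of this stage.

**Charge-consistency correction.** The exact discrete identity
`a(i) = Σ_k V_k E_p(c_k)·J_k` holds for the FEM solution, but the lumped
per-tet current is only *weakly* divergence-free, and the quasi-static
surface reciprocity identity fails at O(1) for non-solenoidal sources (a
bare point current errs by ~60%; a closed loop is exact). The irrotational
residue is compensated exactly by one extra surface term,

    a(i) += Σ_j A_j ψ_i(r_j) (E_p(r_j)·n̂_j),
    ψ_i(r) = (1/4π) Σ_k V_k J_k,i·(r − c_k)/|r − c_k|³,

i.e. the dipole potential of the lumped current, computed offline with the
same kernels and folded into the E-block of `B`. The term vanishes as the
mesh (and hence the solenoidality of `J`) is refined; with it, coefficient
errors on the default phantom drop from several percent to ~0.5%.

## Online stage

Coil primary fields are precomputed once on a Cartesian grid in the coil
frame (default 4 mm spacing; bounds derived from the Huygens circumradius, a
standoff, and a tilt budget so any admissible tangential placement stays
inside). Per placement: facet centers are mapped by `T⁻¹`, the six field
components are trilinearly interpolated (exact for affine fields;
out-of-bounds is a hard error, never extrapolation), the sampled vectors are
rotated back into the head frame, `a = B·[E_p; H_p]`, and the field at the
evaluation barycenters is `dI/dt · Σ a_i M_i`. Everything online is single
precision; stage timings are logged but never asserted.

## Synthetic data

The layered-sphere phantom stands in for MRI-derived head meshes: one
Fibonacci point lattice scaled to every interface radius (keeping points
radially aligned so Delaunay tets do not cross tissue interfaces), a coarser
graded core, a tiny deterministic jitter (tangential on interfaces) to break
Delaunay degeneracies, and tet labels assigned by centroid radius. Default
radii 70/75/78/82/85 mm; `target_edge` sets the lateral interface spacing
while radial resolution defaults to the shell thickness (3–5 mm), so
near-surface cells are anisotropic by construction; `max_radial_spacing`
inserts intermediate layers inside thick shells when a study needs several
elements through a shell (the sigma-profile-independence null test does —
with a single element per shell the interface-local FEM error stalls near 7%
in an unweighted cell norm and only converges, to ~2%, once the shells are
radially resolved and the comparison is volume-weighted). The benchmark uses a 9 mm edge (~43k
tets) — the finest resolution that keeps the full run (≈1350 probe + 450
mode + 100 reference solves plus the dense radiation kernels) around ten
minutes on one core; the generic generator default is 10 mm. The
evaluation surface is an independent triangulated sphere at the grey-matter
mid-radius (72.5 mm), mimicking a middle-grey-matter surface.

What the phantom does *not* emulate: gyral folding (fields on real cortices
have local structure the sphere lacks), anisotropic conductivity, realistic
shell thicknesses (its brain sits ~10 mm under the scalp, slightly shallower
than typical anatomy, which makes the mode spectrum decay *slower* than on
real heads — the phantom is a conservative test of basis convergence), and
mesh quality of curvature-adapted meshers. Passing benchmarks here validates
the machinery (FEM, basis, equivalence, reciprocity, interpolation) and its
internal consistency, not clinical field magnitudes.

## Accuracy on the default phantom

With the 450-mode session, the benchmark (100 random tangential placements)
gives mean GVE ≈ 2.8% (450 modes) and max GVE ≈ 3.4% / max GME ≈ 2.6% at 400
modes against the direct FEM reference; reciprocity coefficients agree with
the direct volume projections to 0.2–0.5%.
The floor is *span truncation*, not reciprocity: the continuum harmonic
content of the coil field beyond the 450-mode scale is ≈0.2%, the
reciprocity coefficients are accurate to ~0.5%, and the measured residual
matches the optimal 450-dimensional subspace residual of the discrete probe
operator. That optimal floor is dominated by FEM-discretization field
content and shrinks only slowly (~h^0.7) with mesh refinement, so pushing the
mean GVE below ~2% at 450 modes requires meshes far beyond desk scale — the
regime the method's original million-tet head models live in.

## Degenerate inputs and tie-breaks

Zero-area facets and zero-volume tets are hard errors (inverted tets are
silently reordered); rank-deficient probe sets truncate with a warning;
extrusion that flips facet normals warns and proceeds (offset surfaces of
convoluted scalps are out of scope to repair); evaluation points outside the
ROI, outside the mesh, or outside the grid are hard errors listing counts.
Placement matrices must be proper rigid transforms to 1e-10.
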