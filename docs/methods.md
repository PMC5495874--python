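# Methods

This note documents the models, numerical choices and limitations behind
`emegfem`, in the order the pipeline runs them.

## Phantoms and simulated data

**Geometry.** Heads are concentric-shell spheres rasterized onto isotropic
voxel grids (RAS mm; voxel `[i,j,k]` owns the half-open box starting at
`origin + (i,j,k)·h`). A voxel takes the label of the innermost shell whose
outer radius strictly exceeds the distance of the voxel center from the
sphere center; a center exactly on a boundary therefore joins the *outer*
side (deterministic tie-break, including "outside" at the outermost
radius). The canonical validation phantom is the 4-shell sphere with radii
92/86/80/78 mm; a seven-compartment variant (scalp, skull compacta, skull
spongiosa, dura, CSF, GM, WM) is available for thicker-shell geometries.

**Conductivities (S/m).** scalp 0.43, skull compacta 0.0033, skull
spongiosa 0.0116, dura 0.1, CSF 1.79, GM 0.33 — literature values, with the
skull pair being the individually calibrated values the calibration stage
is designed to recover. The isotropic WM reference 0.14 S/m is an
effective-medium literature value, config-exposed, since no calibrated
value exists for it.

**Sensors.** EEG electrodes and MEG coils are spread over the upper 3/4 of
the sphere's solid angle by a golden-ratio (Fibonacci) spiral — a
quasi-uniform stand-in for a cap + helmet montage (defaults 80 EEG, 275
MEG, mirroring a whole-head axial-gradiometer system). Gradiometers are
modeled directly as two-coil differences along the coil axis (baseline
50 mm); reference-coil synthetic gradiometry is out of scope.

**Diffusion tensors.** WM voxels receive axially symmetric (prolate)
tensors with exact fractional anisotropy `FA = (t−1)/√(t²+2)` via the
closed-form inversion `t = (1 + FA·√(3−2FA²))/(1−FA²)` for the eigenvalue
ratio, constant mean diffusivity 0.7·10⁻³ mm²/s, and a principal axis from
a named pattern (tangential-to-surface by default, emulating fibers running
along the cortical sheet).

**Simulated recordings.** The somatosensory template is a unimodal Gaussian
peaking 20 ms post-stimulus (σ = 4 ms); the spike template is biphasic — a
sharp Gaussian lobe (σ = 9 ms) plus a shallow opposite-signed after-wave —
with ~70 ms support, because real spike morphology is not standardized and
only the sharp-peak/slow-wave structure matters here. Two-focus discharges
delay the propagation focus by 23 ms (whole samples enforced). Noise is
white Gaussian per channel with a common standard deviation per modality,
set so that RMS(peak topography)/σ equals the requested per-trial
amplitude SNR; averaging n trials then raises SNR by √n, which the tests
verify by Monte-carlo. Real EEG/MEG noise is colored and spatially
correlated; because the inverse stage whitens per channel, white noise is
the consistent desk-scale idealization — but passing tests say nothing
about performance under unmodeled noise correlations, head-model errors or
marker jitter, which is the main caveat when extrapolating to real data.
All simulators are seeded and bit-reproducible.

## Meshing and conductivity assignment

One trilinear hexahedron per nonzero voxel, shared nodes deduplicated
(VTK corner ordering). Geometry adaptation moves every node that touches
more than one label (background = 0) toward the centroid of the adjacent
voxel centers carrying the locally *rarest* label, by `shift · (centroid −
node)` with `shift = 0.33` by default; ties between minority labels leave
the node in place. The 0.49 cap guarantees positive corner Jacobians
(asserted after construction); total element volume stays within 0.5 % of
the voxel volume for shifts ≤ 0.33.

Isotropic tensors are `σI` per tissue. The anisotropic WM mapping takes the
diffusion tensor of the element's own voxel (elements and voxels are in
1:1 correspondence, so no interpolation is needed), reuses its
eigenvectors, and scales eigenvalues so the conductivity tensor's
determinant equals `σ_iso³` (volume normalization, preserving the geometric
mean); a linear scaling mode (`σ_i ∝ d_i`) is config-exposed because the
effective-medium literature uses both. Non-positive diffusion eigenvalues
are clamped to 10⁻⁶ of the largest with a logged warning.

**Source space.** Candidates lie on an axis-aligned grid of the requested
spacing (default 2 mm; coarser in the desk-scale tests) seeded at the GM
centroid. The strict (default) admissibility requires every element
touching the candidate's nearest FE node to be GM — this keeps all Venant
loads inside gray matter. The laxer variant (candidate's own element GM) is
config-switchable because the neighborhood definition is a genuine design
choice.

## Forward solution

**Assembly.** `K_ab = Σ_e ∫ ∇φ_a·σ_e∇φ_b dV` with trilinear shape functions
and 2×2×2 Gauss quadrature, all geometry in SI meters internally. The full
matrix is symmetric positive semidefinite with the constants in its
nullspace; one node is grounded to obtain an SPD system (read-outs are
average-referenced or gradient-based, so the grounding constant is
immaterial), and solutions are returned mean-zero.

**Venant loads.** A dipole becomes monopole loads on the nodes sharing an
element with its nearest FE node, found by Tikhonov-regularized least
squares (weight 10⁻⁶) matching moments up to second order in the node
offsets scaled by a 20 mm reference length, under a *hard* zero-total-charge
constraint (solved in the sum-zero subspace, residual round-off removed).
These parameter values are validated by the moment-conservation property
(first moment within 1 % on the 2 mm phantom) rather than against printed
numbers, since the source-model literature parameterizes the method in
several ways.

**Solver.** Conjugate gradients preconditioned by an in-package
smoothed-aggregation AMG: strength threshold 0.02, greedy aggregation,
tentative prolongators smoothed by one damped-Jacobi step (ω = 4/(3ρ̂) with
ρ̂ from power iteration), Galerkin coarse operators, symmetric V(2,2)
damped-Jacobi cycles, dense Cholesky at ≤ 600 unknowns. Default relative
tolerance 10⁻⁹, iteration cap 500; non-convergence raises with the
residual history. On the 428 k-node validation phantom the hierarchy has 4
levels with grid complexity 1.04 and a solve takes a few seconds.

**Transfer matrices.** EEG: one solve per electrode with the
snapped-electrode-minus-average read-out vector as load; electrode
collocation is nearest-surface-node (no interpolation — consistent with
the mesh resolution; electrodes farther than 10 mm raise). MEG: the
secondary field of the volume currents is integrated element-wise with
one-point (centroid) quadrature, giving per-coil read-out rows
`n̂·B_sec = row·u`; one solve per channel row. Leadfield columns are then
sparse dot products of transfer rows with Venant loads, plus the analytic
primary (Biot–Savart) term for MEG. Units: µV per nA·m (EEG), fT per nA·m
(MEG). The transfer route is tested to agree with independent direct
solves to 10⁻⁸ on toy meshes and ~10⁻⁷ on the validation phantom.

**Accuracy against the oracles** (2 mm, 4-shell, tangential dipoles at
eccentricity 0.3–0.8): EEG RDM ≤ 0.02 with a systematic |lnMAG| ≈ 0.1;
MEG RDM ≤ 0.006; quasi-radial MEG leakage ≈ 0.05 % of an equal tangential
source. The EEG magnitude bias is the expected staircase effect of a
one-voxel CSF layer at this resolution and shrinks with finer meshes.

## Analytic oracles

The EEG oracle solves, per spherical-harmonic degree, the 2L−1 interface
conditions (potential and radial current continuity, insulating outer
boundary) of L concentric isotropic layers directly as a small
column-equilibrated linear system, with all radii normalized by the outer
radius for conditioning; Legendre polynomials and derivatives come from
upward recurrences. Truncation at the default 60 terms is below 10⁻¹⁰ for
eccentricities up to 0.8 (geometric tail in b/R). The single-shell closed
form — the classical (2n+1)/n-weighted free-space expansion — serves as an
independent check of the interface solve. The MEG oracle is the Sarvas
closed form, conductivity-independent by construction; its radial component
is verified against the bare-dipole Biot–Savart field (volume currents are
radially silent). Shape/magnitude errors are RDM = ‖a/‖a‖ − b/‖b‖‖ ∈ [0,2]
and lnMAG = ln(‖a‖/‖b‖).

## Skull-conductivity calibration

Per candidate compacta value σ (spongiosa = 3.5σ, the ratio of the
calibrated pair; config-exposed): MEG dipole scan at the evoked-response
peak latency fixes the position (ties broken to the lowest node index);
EEG least squares at that node fixes unit orientation and amplitude; the
goal is the *equally weighted* sum of EEG and MEG relative residual
variances of the position+orientation-fixed dipole (weighting
config-exposed — the equal weighting is the natural scale-free choice
since both residuals are already relative). The default grid is 12
log-spaced candidates spanning 0.0005–0.02 S/m. The goal-curve minimum
recovers an in-grid truth exactly in the noiseless case; a non-unimodal
curve is flagged, not raised. The residual-variance goal subsumes the
amplitude-comparison idea — a candidate whose EEG/MEG amplitudes disagree
cannot fit both topographies with one dipole — while remaining
scale-invariant.

Calibration latency defaults to the MEG global-field-power maximum of the
evoked response (the early cortical component); config-exposed.

## Inverse stage

**Averaging.** Marker-aligned mean over trials; the average's per-channel
noise σ is estimated from a pre-onset baseline window (defaults −165 to
−115 ms, before any template support).

**Whitening/fusion.** Each channel of data and leadfield is divided by the
channel's noise σ (diagonal covariance; the interface accepts per-channel
values only — full-covariance whitening is a deliberate non-goal for the
default path). Rows stack EEG-then-MEG; source spaces are hash-checked.

**sLORETA.** `F_j = ŝ_jᵀ S_j⁺ ŝ_j` with the 3×3 resolution blocks inverted
by eigendecomposition-based pseudoinverse (relative cutoff 10⁻¹⁰), which
handles the radially silent MEG direction. λ options: fixed value; relative
(`λ = rel·tr(LLᵀ)/n`, the right way to express λ→0 against the exact rank
deficiency introduced by average-referenced EEG rows); or the default SNR
rule `λ = tr(LLᵀ)/(n·SNR²)` with `SNR² = max(‖y‖²/n − 1, 10⁻⁶)` estimated
from the whitened topography (whitened noise has unit variance). F is
quadratic in the data: rescaling the topography scales the map by c² and
leaves its shape, argmax and relative thresholding unchanged.

**Clustering and ROIs.** Nodes with `F ≥ 0.85·max F` are connected within
1.5× the source spacing and grouped by connected components; clusters
smaller than `min_cluster_size` (default 5; the desk-scale demos use 1–2
because coarse source grids make focal clusters small) are discarded;
clusters sort by peak F. Each cluster peak centers an axis-aligned cuboid
ROI, default extents 160 × 82 × 28 mm — the footprint of a zoomed
high-resolution acquisition.

**Analysis latencies** default to −7 ms and −23 ms relative to the spike
peak; "middle of the rising flank" is operationalized as the half-maximum
crossing of global field power before the peak when a data-driven latency
is wanted.

## Problem sizes used in the shipped studies

The validation suite uses the 92/86/80/78 mm phantom at 2 mm
(~4.1·10⁵ elements, 32+32 sensors) for forward/Venant checks; a
80/72/66/60 mm phantom at 4 mm with a 6 mm source grid (~3.8·10³ nodes)
for the localization Monte-Carlos (50–100 seeds); and a 60/52/46/42 mm
phantom at 4 mm for the 12-candidate calibration study. These sizes keep
the full suite around seven minutes on one CPU while leaving every
acceptance property comfortably inside its tolerance; they are choices of
the package, and all scale up through configuration.

## Known limitations

- Spherical phantoms only; no realistic anatomy, no segmentation of real
  MRI, no coregistration workflow.
- Electrode collocation (no surface interpolation) and one-point secondary
  MEG quadrature bound forward accuracy at coarse resolutions; both are
  upgrade points.
- Diagonal noise whitening; colored/correlated noise is unmodeled.
- The calibration scans a single conductivity dimension (compacta, with
  spongiosa slaved); joint multi-parameter estimation is out of scope.
- sLORETA's zero-localization-error property holds for single noiseless
  sources; simultaneous correlated sources bias any linear inverse, and the
  two-focus study relies on their temporal separation.
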