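# Methods

`exciham` predicts Frenkel exciton Hamiltonians for aggregates of pigments
embedded in a classical environment, along the sequential strategy used for
chlorophylls in light-harvesting complexes: learn the vacuum excitation
energy, learn the electrostatic-embedding correction on top of it, and add
analytic polarization terms computed from transition charges.  This note
records the model, its assumptions, the numerical choices, and what the
synthetic benchmarks do and do not demonstrate.

## The exciton model

For N pigments with one bright transition each, the site basis Hamiltonian
is the symmetric N×N matrix

    H_IJ = ε_I δ_IJ + V_IJ (1 − δ_IJ)

with site energies ε_I (eV) on the diagonal and excitonic couplings V_IJ
off it.  Diagonalization gives exciton energies and the orthogonal mixing
matrix; exciton transition dipoles are the corresponding combinations of
site dipoles, so the total dipole strength Σ|μ|² is conserved exactly — a
sum rule the spectrum code is tested against.

## Sequential site-energy prediction

The site energy of an embedded pigment is decomposed as

    ε̂ = ε̂_vac(χ_CM) + ε̂_shift(χ_CM, χ_Pot) + ε_pol ,

three terms with different physics and different estimators.

**Vacuum term.**  A Gaussian process on the heavy-atom Coulomb matrix
χ_CM = {Z_i Z_j / r_ij} (flattened upper triangle, constant diagonal
dropped).  Hydrogens are excluded: they contribute permutationally
ambiguous, nearly redundant entries and encourage the regressor to
memorize.  Because the Coulomb matrix is not permutation invariant, a
canonical atom order per pigment type is enforced before descriptors are
built; inputs are reordered by atom name.  The kernel is Matérn with
ν = 5/2 (twice-differentiable sample paths — smooth enough for an
energy surface, less prone to oversmoothing than a squared exponential)
and the prior mean is the average of the training energies.

**Electrochromic shift.**  ε_shift = ε_QM/MM − ε_vac at fixed geometry is
learned from the pair (χ_CM, χ_Pot), where χ_Pot is the electrostatic
potential of the MM charges on every QM atom (e/Å, hydrogens included).
χ_Pot has fixed length regardless of environment size, and environment
residues are included whole when their minimum atom distance to the QM
subsystem is within a cutoff (default 30 Å).  The GP prior has zero mean
and the composite kernel

    κ_shift = σ₁² ⟨Φ, Φ′⟩ + σ₂² ⟨Φ, Φ′⟩ · matérn(|χ_CM − χ_CM′|; 1, ℓ).

The first term is Bayesian linear regression in the potential features —
its posterior mean is ⟨Φ*, C⟩ for effective QM response charges C, which
the package exposes (`ShiftResults.effective_charges`).  The second term
lets the response depend nonlinearly on the internal geometry, weighted by
the QM–MM interaction magnitude.  Both terms carry a factor ⟨Φ, Φ′⟩, so a
pigment in an empty environment gets a predicted shift of *exactly* zero —
a structural constraint, not a learned one, and the package asserts it as
an equality.

**Polarization term.**  Not learned.  The transition density is
represented by atom-centered transition charges {q^tr} (TrEsp); the
environment's polarizable sites carry induced dipoles obtained from the
mutual-polarization linear system

    μ_m = α_m (E_m^ext + Σ_{m'≠m} T_mm' μ_m'),

with the bare point-dipole tensor T.  The resonance contribution to the
site energy is the self-energy of that linear response,

    ε_pol = −(1/2) k_e Σ_m μ_m({q^tr}) · E_m({q^tr}) ≤ 0,

and the environment screening of a coupling is the cross term

    V_screen = −k_e Σ_m μ_m({q^tr}_J) · E_m({q^tr}_I),

symmetric in I↔J because the polarization response matrix is symmetric.
The −1/2 prefactor of ε_pol is the linear-response value; it is exposed as
a parameter for users who need a different convention.  Transition charges
in vacuo come from a per-atom Ridge regression on the Coulomb matrix
(optionally neutralized to zero total charge); the environment's effect on
them is a per-pigment-type scale factor γ supplied by configuration.

**CDC baseline.**  The charge-density-coupling estimate of the shift —
fixed difference-density charges Δq interacting bare with the environment
charges, k_e ΣΣ Δq_i q_m / r_im — is provided as the null model against
which the GP is compared.

## GP regression details

Exact GP throughout (the training sets involved are a few thousand points
at most, so no sparse approximations are needed).  Fitting solves
(K + σ²I)α = y − μ by Cholesky factorization with a fixed diagonal jitter
of 1e−10; predictions are μ + k*ᵀα with variance κ(x*,x*) − k*ᵀ(K+σ²I)⁻¹k*
clipped at zero.  Implementation is verified against an explicit
dense-inverse oracle to 1e−10 relative error.

Hyperparameters (kernel amplitudes and lengthscales, plus the noise
variance σ²) are set by maximizing the log marginal likelihood with
L-BFGS-B in log space from 5 restarts: the first start is a data-scale
heuristic (target standard deviation for amplitudes, median pairwise
descriptor distance for lengthscales), the rest are drawn log-uniformly
from the bounds with a seeded generator, so fits are deterministic given
the seed.  Default bounds are a factor 10³ around the heuristic start.
Non-finite likelihoods during a line search are treated as +∞ for the
minimizer; an error is raised only if every restart fails.

Models serialize to a single JSON file (kernel kind and parameters, noise,
prior mean, training descriptors, coefficients, schema version); loading
refuses incompatible schema versions and reproduces predictions to
machine precision.

## Units and constants

Distances Å, charges e, polarizabilities Å³, energies eV, potentials e/Å,
fields e/Å².  The Coulomb constant k_e = 14.3996454 eV·Å·e⁻² enters only
at energy-forming steps (CDC, couplings, polarization terms), keeping
descriptors O(1–100).

## Numerical choices and edge cases

- Residue cutoff uses the minimum atom–QM-atom distance; residues are kept
  or dropped whole, so the potential descriptor is additive over residues.
- An environment charge within 0.1 Å of a QM atom is a singularity error;
  chromophore pairs with atoms within 1 Å refuse to compute couplings; and
  polarizable sites within 1 Å of each other raise rather than silently
  approaching the polarization catastrophe (no Thole damping is applied —
  the guard makes the failure explicit instead).
- The mutual-polarization system is solved densely up to 3000 polarizable
  sites (9000 unknowns); beyond that, use an iterative solver externally —
  typical cutoff environments stay below this.
- "Turning off" a residue in the influence analysis zeroes its charges but
  keeps its atoms, so the 30 Å residue selection is unchanged and the
  influence is a pure difference of two shift predictions on the same
  frame.  With a pure linear kernel the influences are exactly additive
  over residues; with the composite kernel they are not, which is the
  point of the analysis.
- r² (squared Pearson correlation) is undefined for constant vectors; the
  scorer raises, and cross-validation records NaN for such folds.
- FPS breaks ties toward the lowest index and defaults to start index 0,
  making selections reproducible.
- Gaussian-broadened stick spectra use unit-area Gaussians on a 1 meV grid
  padded by 8σ, so integrated intensity equals total dipole strength; this
  is deliberately a lightweight stand-in, not a lineshape theory (no
  vibronic structure, no dynamic disorder beyond the ensemble itself).

## The synthetic benchmark and what it shows

Training the real models requires excited-state QM calculations on MD
frames.  The package ships a generator that emulates the *statistical*
structure of such data so the whole pipeline is testable end to end:

- Geometries: a 17-heavy-atom macrocycle stand-in (central Mg-like atom in
  a C/N ring, nominal bond length 1.4 Å) with per-coordinate Gaussian
  jitter (default sd 0.05 Å) plus a collective out-of-plane mode of the
  first ring nitrogen (amplitude ±0.3 Å at the default jitter), emulating
  the strong ring deformations a dihedral scan produces.  Geometries with
  atom pairs under 0.95 Å are redrawn.
- Environments: clustered residues (default 40 residues × 4 atoms) in a
  7–25 Å shell, per-residue net charges ~N(0, 0.25 e) plus zero-sum
  intra-residue spread, optional uniform polarizabilities, minimum 1.2 Å
  site spacing and 5.5 Å clearance from the pigment.
- Vacuum target: base 2.10 eV plus a linear form in the Coulomb-matrix
  deviations plus a saturating (tanh of a quadratic form) nonlinearity and
  2 meV Gaussian observation noise.  Under the default distortion this
  gives an ensemble spread of ≈0.15 eV range / ≈0.03 eV sd — the scale of
  vacuum site-energy variation of chlorophyll-like pigments across
  distorted conformations.
- Shift target: exactly k_e ⟨Φ, c(geom)⟩ with effective charges
  c = c₀ + G·ΔCM (c₀ ~ 5e−3 e per atom, geometry coupling contributing
  ≈30% of the shift variance), giving shifts of a few tens of meV, zero
  noise by default, and exactly zero for an empty environment.

Two properties make the oracle diagnostic rather than decorative.  With
G = 0 the shift target lies *inside* the linear-kernel model class, so
held-out r² ≈ 1 and recovery of c₀ (cosine ≥ 0.99) test the optimizer and
the algebra, not model adequacy.  With G ≠ 0 it lies outside the pure
linear class but inside the composite kernel's reach, so "composite beats
linear on held-out MAE" tests that the interaction-weighted nonlinear term
earns its keep.

What passing these tests does **not** show: chemical realism.  The oracle
has no electronic structure, its noise is homoscedastic, its environments
have no hydrogen-bond or ligation motifs, and real QM/MM data has
correlated geometry–environment fluctuations the generator omits.
Accuracies measured here characterize the estimator under controlled
conditions, not expected accuracy on real complexes.

## Problem sizes

Default benchmark bundles use 600 training / 200 test samples (the model
studies behind this package used thousands per pigment; the reduced scale
keeps the full pipeline runnable in minutes while leaving the GP well away
from its small-sample regime).  Verification scripts train on 500–600
samples, score on 150, and run learning curves over {50, 100, 200, 400}
with 5-fold cross-validation, reporting mean ± 2 sd bands across folds.

## Known limitations

- One GP per pigment type; no transfer or multi-task sharing between types.
- The variance of a sequential prediction sums the two GP variances,
  assuming independence of the vacuum and shift models.
- γ is a supplied constant per pigment type; its estimation is out of scope.
- No trajectory ingestion: frames arrive as pre-extracted geometries and
  charge tables.
- Polarizable screening uses dipoles induced by one pigment's transition
  density interacting with the other's field; the I↔J symmetry of the
  implementation is asserted numerically rather than assumed.
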