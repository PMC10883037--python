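# Methods

## Model

The system is a rectangular periodic box (L_z = 5.00 nm throughout) holding
`N_S_total` immobile adsorbing sites and `N_A_total` mobile rigid diatomic
adsorbates at temperature T = 300 K in the canonical ensemble.  Each site is
a vertical dimer: a binding atom *s* at z = 2.50 nm (the box midplane) and a
protecting atom *h* at z = 2.64 nm whose excluded volume blocks a second
adsorbate from reaching a bound *s*, enforcing single occupancy.  Sites form
a two-dimensional equilateral triangular lattice with a nearest-neighbour
distance of 3.5 nm and never interact with one another.  Each adsorbate is
an *a*–*h* dimer with a rigid 0.14 nm bond.  All atoms are uncharged and
interact through Lennard-Jones potentials truncated (not shifted) at
2.0 nm:

| pair | σ (nm) | ε (kJ/mol) |
|------|--------|------------|
| a·a  | 0.75   | 0.1        |
| h·h  | 0.50   | 0.1        |
| s·h  | 0.35   | 0.1        |
| a·h  | 0.35   | 0.1        |
| s·a  | 0.18   | 35.0       |

Only the s–a pair is attractive; its well depth ε_SA is the adsorption
energy and is scanned from 15 to 50 kJ/mol in the R4 series.  A site is
counted occupied when an *a* atom lies within r_sa < 0.37 nm of its *s*
(minimum image), a cutoff that brackets the first maximum of g_sa(r) at
r ≈ 0.204 nm.  Because 0.37 < 3.5/2, a bound molecule is always assigned to
exactly one site; sites hosting two molecules are still counted once and
the incident is logged (observed rates are ≲ 1e-5 per sample and zero for
the small systems).

### Units and constants

Lengths in nm, energies in kJ/mol, temperatures in K.  The gas constant
R = k_B = 0.0083145 kJ·mol⁻¹·K⁻¹, i.e. all energies are per-mole, and the
Metropolis weight is exp(−ΔU/(RT)).  The standard concentration c⊖ that
renders K dimensionless is taken as 1 mol/L = 0.602214 nm⁻³.  This choice
is an inference, not a free knob: it is the value that makes the package's
headline pair consistent — K = 214 together with an occupied fraction of
0.74 in the one-molecule, one-site, 125 nm³ system — and reproduces the
conversion 0.008 molecules/nm³ ≈ 0.013 M.

### Simulation series

* **R1**: N_A = N_S ∈ {1,2,3,4,5,6,8,10,14,30,68,120} at c_A = 0.008 nm⁻³
  (boxes from 5.0 to 54.77 nm across).
* **R2**: N_S = 4 fixed, N_A varied; **R3**: N_A = 4 fixed, N_S varied;
  in both the most abundant species is held at 0.015 nm⁻³.
* **R4**: N_A = N_S = 2 at 0.008 nm⁻³ (7.07 × 7.07 × 5 nm box) with
  ε_SA ∈ {15, 20, …, 50} kJ/mol.

Row layouts of the site lattice are near-square triangular patches (30 = 6
rows of 5, 68 = 5 rows of 8 alternating with 4 of 7, 120 = 12 rows of 10).
Because sites are mutually inert, every equilibrium quantity of the ideal
model is insensitive to the patch shape; only the 3.5 nm spacing matters.
Inside a patch the spacing is enforced exactly; across periodic images the
builder only requires enough clearance that bound-state assignment stays
unambiguous (the R2/R3 boxes at small N_A are narrower than one lattice
constant plus patch width, which is physically harmless and only warns).

## Monte Carlo

One trial move selects a molecule uniformly at random and applies a
combined rigid-body displacement and rotation: per-axis displacements
uniform in ±0.4 nm, an increment of cos θ uniform in ±0.1 (reflected at
±1, which keeps the proposal symmetric and the orientation measure uniform
on the sphere), and an azimuthal increment uniform in ±0.314 rad.  The
molecular orientation is stored as a unit vector with (θ, φ) defined in the
lab frame; the rotation pivot is the binding atom *a*, so pure rotations
leave r_sa unchanged — an efficiency choice near bound states.  Acceptance
is Metropolis, min(1, exp(−ΔU/(RT))); the acceptance counter covers the
composite move.  These conventions are validated empirically by the
acceptance-ratio anchors of the reference systems (≈ 0.162 for R2 with one
adsorbate, ≈ 0.993 for R4 at ε_SA = 15 kJ/mol), which this implementation
reproduces.

The truncated-unshifted potential leaves a small discontinuity at the
cutoff; only energy differences enter the sampling, so equilibrium
averages are unaffected.  Minimum-image periodicity applies in all three
axes — a site can in principle be approached from either side of the
z-boundary, which is faithful to the stated model.

Observables (N_SA, free N_A, vacant N_S, total energy) are recorded every
`sample_interval` moves (50 by default); the per-sample product N_A·N_S is
kept alongside because every correlation-aware estimator needs the
two-body average.  Runs are deterministic given the seed: the insertion RNG
and the compiled kernel's RNG both derive from `spec.seed`.

### Sampling sizes

The package's desk-scale defaults are 1e6 equilibration and 1e7 production
moves; the statistical tests and the acceptance script use 1e7–4e8 moves
per system, sizes chosen so that the slowest mode (binding/unbinding of a
single molecule, with residence times of order 1e5 moves at
ε_SA = 35 kJ/mol) is sampled hundreds to thousands of times.  Full-scale
schedules (1e10–1e12 moves) are opt-in through the configuration.
Statistical errors use block averaging with ≥ 20 blocks; K uncertainties
use a delete-one-block jackknife of the ratio of means (never a mean of
per-sample ratios).

## Exact occupancy statistics

For the ideal model the number of occupied sites follows the binding
polynomial p(i) ∝ C(N_A,i)·C(N_S,i)·i!·z^i with site affinity
z = K/(c⊖V).  The oracle enumerates it in log space (log-gamma binomials,
support truncated 60 nats below the mode), which keeps counts up to 1e4 and
affinities up to 1e8 exact in double precision.  z, not K, is the native
parameter so the module is independent of the c⊖ and V conventions.

Two identities anchor everything:

* **K recovery**: (⟨i⟩/⟨(N_A−i)(N_S−i)⟩)·V·c⊖ = K exactly, for every
  (N_A, N_S, z).  This is the detailed-balance relation
  (i+1)p(i+1) = z(N_A−i)(N_S−i)p(i) summed over i, and is the reason the
  correlation-aware K is size-invariant.
* **Composition from fluctuations**: multiplying the same relation by i
  before summing gives ⟨i²⟩−⟨i⟩ = z⟨i·(N_A−i)(N_S−i)⟩, from which
  1/⟨i⟩ = l(i,i) − l(i, N_A·N_S).  The package therefore treats the
  fluctuation route to ⟨N_SA⟩ as an **exact identity of the ideal model**
  (not an approximation); on simulation traces it holds within sampling
  error, with residual deviations attributable to the weak a·a/a·h/h·h
  interactions that the ideal model ignores.

## Occupancy predictors

`predict_theta_eq17` solves K·[N_A N_S − (N_A+N_S)·m + m²(1+l)] = V·c⊖·m
for m = ⟨N_SA⟩ — the exact K expression with ⟨N_SA²⟩ = m²(1+l) — taking the
smaller quadratic root (the branch continuous with m(K→0) = 0, numerically
as 2c/(b+√disc)) and iterating a damped fixed point between m and l to
1e-10.  Supplying the pmf's own l reproduces the exact mean to machine
precision, so all predictor error lives in the l approximation.

l(N_SA,N_SA) is approximated as λ·c⊖V/(K·N_X), where N_X is the more
abundant total count; the prefactor is the exact relative fluctuation
whenever the scarcer count N_Y equals one.  Two rules for λ are shipped:

* `eq20_previous`: λ = 1/N_Y.  Exact at N_Y = 1, exact in the
  independent-site limit N_X → ∞, and vanishing in the thermodynamic
  limit — but noticeably imperfect for N_A = N_S = 2–4.
* `eq21_new`: an interpolation between the two *exact* endpoints of λ that
  the enumeration yields analytically — the dilute value λ₀ = 1/N_Y (only
  the i = 0,1 states populated) and the saturation value
  λ∞ = N_X/(N_Y(N_X−N_Y+1)) (a single-vacancy fluctuation):

      λ = λ₀ + (λ∞ − λ₀)·w,   w = t^k·(1 − 0.15(1−t)),
      t = ⟨N_SA⟩/N_Y,         k = 1 + (N_Y−1)·N_Y/N_X

  The exponent k and the mid-range damping factor 0.15 were calibrated
  once against the enumerated pmf over broad (N_A ≤ 50, N_S ≤ 50,
  z ∈ [0.03, 100]) grids by minimizing the worst-case occupancy error;
  the resulting maximum |Δθ| is 0.0064 (versus 0.069 for the constant
  rule).  At N_Y = 1 both endpoints equal 1, so the rule is exact; in the
  thermodynamic limit k → ∞ drives w → 0 and λ → 1/N_Y → 0.  Because λ
  depends on the occupancy, this rule participates in the fixed point.

Two Langmuir entry points are exposed because they answer different
questions: `langmuir_theta` takes a *measured* free-adsorbate concentration
(this is what makes the 0.74-observed/0.425-predicted contrast well-posed),
while `closed_system_langmuir` solves the isotherm jointly with the mass
balance c_A = (N_A − θN_S)/V — the prediction a practitioner would make
from K and the composition alone.

`fit_isotherm` fits titrations (N_A, ⟨N_SA⟩) by nonlinear least squares of
the corrected predictor with relative-error weighting (occupancies span
decades), parameterized by log(V·c⊖/K) and log N_S — the prediction
depends on V and K only through their ratio, which is what collapses the
fit to two parameters.  N_S is treated as continuous, standard practice
for site-count estimation.  Confidence intervals use the Gauss-Newton
covariance with a Student-t quantile at the residual degrees of freedom.

## What the synthetic data does and does not cover

The Monte Carlo engine *is* the data generator: its defaults are the study
conditions (series concentrations, Table of LJ parameters, move maxima,
T = 300 K), and the exact enumeration provides iid occupancy draws for
estimator tests.  Together they emulate idealized single-occupancy
adsorption with one attractive pair interaction.  They do not emulate
adsorbate–adsorbate cooperativity, multilayer formation, solvent-mediated
effective energies, mobile or interacting sites, open-system exchange with
a reservoir, or instrument noise beyond the multiplicative noise used in
the fitting study — so passing tests certify the statistics of the ideal
closed-system model, not the photophysics of any particular experiment.

## Numerical choices and degenerate inputs

* Log-space pmf accumulation; bracketing Brent root-find on log z for
  mean-occupancy inversion (relative tolerance ~1e-12).
* Population (1/N) covariance normalization throughout; the sample/population
  distinction is immaterial at the trace lengths used but fixed for
  determinism.
* Series with ⟨N_SA⟩ = 0 give K = 0; complete conversion
  (⟨N_A·N_S⟩ = 0) and zero-mean fluctuations raise explicit errors — no
  silent NaN.
* Insertion resamples candidates whose interaction energy exceeds
  100 kJ/mol; any similar threshold is equivalent after equilibration.
* A non-finite running energy aborts the run with a diagnostic.
* The compiled kernel guards exp underflow (ΔU/(RT) > 700 rejects).

## Known limitations

* The λ interpolation is empirical between its exact limits; worst-case
  occupancy errors of ~0.006 remain near N_A = N_S = 2 at intermediate
  affinity, and predictions at strong binding undershoot slightly
  (θ = 0.9798 predicted vs 0.9979 exact at K = 7e4 for two molecules and
  two sites is the worst observed case).
* Acceptance ratios (unlike equilibrium averages) depend on the rotation
  convention; the lab-frame (θ, φ) scheme with the a-atom pivot reproduces
  the reference anchors but is not the only convention consistent with a
  verbal description of the moves.
* Desk-scale runs resolve K to a few percent; the reference-scale
  statistics (K to ±0.15%, double-occupancy rates at the 3e-6 level for
  the largest systems, the ε_SA = 50 kJ/mol point with acceptance 0.006)
  require the full 1e10–1e12-move schedules, available but not run by
  default.
* No grand-canonical or hybrid open-system ensemble: the theory and the
  sampler are strictly canonical.
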