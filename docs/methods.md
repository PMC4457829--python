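# Methods

## Reaction scheme and state space

The model describes CO binding to a heme protein that interconverts between
two tertiary conformations: r ("more reactive": fast association, slow
dissociation, favored when liganded) and t ("less reactive", favored when
unliganded).  Each conformation contributes four species — CO-bound, ligand
in the primary docking site, ligand in the secondary docking site, and
unliganded with the ligand in solvent — giving an 8-dimensional state vector
ordered `(R_CO, T_CO, R_dock1, T_dock1, R_dock2, T_dock2, R_free, T_free)`.

Direction convention: `k1`, `k2`, `k3` are r → t and the underscored partners
t → r, so `K1 = k1/k_1 < 1` expresses the liganded preference for r and
`K3 = k3/k_3 > 1` the unliganded preference for t.  The secondary docking
sites exchange only with the primary sites; photolysis deposits the ligand
only into the primary sites; `kout` is shared by both conformations.  The
t-state secondary-site migration rates are named `kd2`/`k_d2` to keep them
distinct from the thermal bond-dissociation rates `kdiss_r`/`kdiss_t`.

CO is held in pseudo-first-order excess, so the dissolved concentration
enters only through the entry fluxes `kin_x·[CO]` and the dynamics are linear
and time-invariant: `dy/dt = A y` with a generator matrix A whose columns sum
to zero.  Total protein is conserved; CO itself is not a tracked state.

## Parameters

| name | meaning | units | typical (r/t) |
|---|---|---|---|
| `k1, k_1` | bound-state interconversion | s⁻¹ | 1.3e5 / 5e5 |
| `k2, k_2` | primary-docked interconversion (tied to `k3, k_3` in fits) | s⁻¹ | — |
| `k3, k_3` | unliganded interconversion | s⁻¹ | 6e4 / 2e4 |
| `kc, k_c` | r primary↔secondary docking migration | s⁻¹ | 1e7 / 1e7 |
| `kd2, k_d2` | t primary↔secondary docking migration | s⁻¹ | 1e7 / 1e7 |
| `kg_r, kg_t` | geminate bond re-formation | s⁻¹ | 5e7 / 6e6 |
| `kdiss_r, kdiss_t` | thermal bond dissociation | s⁻¹ | derived |
| `kin_r, kin_t` | solvent entry | M⁻¹s⁻¹ | 7.8e7 / 3.0e7 |
| `kout` | escape to solvent (shared) | s⁻¹ | 1.5e8 |

Experimental conditions: CO pressure (atm) converted to dissolved
concentration with a configurable solubility of 1.0 mM/atm at 20 °C (a
standard Henry-law value for water near room temperature), photolysis yield
(default 1.0), and a scavenger flag that disables solvent re-entry to model
the stopped-flow NO-displacement experiment.

The `kdiss_x` values are pinned to measured off-rates through the branching
relation `kOFF = kdiss·kout/(kout + kg)`: after thermal bond breaking the
docked ligand either rebinds (kg) or escapes (kout); secondary-site visits
return with probability one and drop out of the branching ratio.  The
relation is exact in the separated-timescale limit (kdiss ≪ internal rates),
which holds by ~9 orders of magnitude for realistic parameters; for toy
networks with comparable rates the simulated slow eigenvalue differs from
the closed form, which is why the helper `apparent_off_rate` implements the
relation itself and simulations are compared against it only in the
separated regime.  The slower measured phase is assigned to the r pathway by
default (the liganded equilibrium favors r, which also carries the majority
dissociation amplitude); the mapping is configurable.

## Propagation

`simulate_trace` integrates `dy/dt = A y` with the implicit BDF solver
(rtol 1e-8, atol 1e-12), the default because the system is stiff (rates span
~10⁻² to 10⁸ s⁻¹).  Because the system is also linear and time-invariant, an
exact eigendecomposition propagator (`method="eig"`) is provided; it falls
back to stepwise matrix exponentials if the eigenbasis condition number
exceeds 1e10 (defective generators, e.g. one-way cycles).  Both paths agree
with direct matrix-exponential propagation to better than 1e-6 absolute in
population.  Output populations are clipped of sub-1e-9 negative round-off
and projected back onto the conservation manifold (divided by their sum), so
Σy = 1 holds exactly at every reported time; pre-projection drift beyond
1e-6 raises an error instead of being silently repaired.  The default output
grid is logarithmic, 10 ns – 1 s at 200 points per decade.

The photolysis initial state splits the pre-flash bound population
1 : (k1/k_1) between the conformers and promotes a fraction `photolysis_yield`
of each to its primary docking site.  The NO-displacement simulation starts
from the same pre-mix bound equilibrium (computed from the *unfrozen* rates),
then optionally freezes `k1, k_1, k2, k_2` during propagation.  The freeze
option exists because with bound-state interconversion at ~10⁵ s⁻¹ the two
bound conformers equilibrate within microseconds and the seconds-scale decay
would be mono-exponential, whereas measured dissociation is biphasic; frozen
interconversion keeps the two pathways kinetically independent and
biexponential.  How the fast bound-state exchange coexists with biphasic
dissociation in the real protein is left open here.

## Global fitting

Traces recorded at several CO pressures are fitted simultaneously with all
rate constants shared.  Free parameters are optimized as log10 values
(positivity plus ~12 decades of dynamic range), with `scipy.optimize.least_squares`
(TRF, `x_scale="jac"`, bounds ±6 decades around the initialization) from the
nominal start plus seeded log-normal jitter of 0.15 decades (default 3
starts, seed 1234); the best cost wins.  `x_scale="jac"` was chosen over
unit scaling because it drifts far less along weakly determined directions.
Ties (`k2 ≔ k3`, `k_2 ≔ k_3`) and derived parameters (kdiss from measured
off-rates, re-evaluated at the current `kout`/`kg`) are substituted exactly
at every function evaluation, so constraints hold bit-exactly in the result.
Traces are generated (and assumed supplied) on logarithmic time grids, which
weights every decade of the ns–s range equally in the residual.

Uncertainties follow the fitness-scan convention: each free parameter is
scanned over ±1 decade (81 grid points) with the others held at the optimum,
and the half-width where the summed squared residual reaches 1.1× its
minimum is the reported error; the grid only brackets the crossing, which is
then refined by root-finding on the actual fitness, so the closed-form
quadratic result w·√0.1 is reproduced to ~1e-6 rather than to grid
resolution.  A Gauss–Newton error-matrix estimate (covariance from JᵀJ at
the optimum) is reported alongside as a cross-check.  A parameter is flagged
weakly identified when its scan stays below the 10% increase out to the edge
of the ±1 decade range on either side, or when the half-width exceeds half
the parameter value; with the default synthetic design this flags the
docking-site migration rates `kc, k_c, kd2, k_d2`, whose kinetic signature
is a small-amplitude detour.

Multi-exponential summaries (`fit_multiexponential`) use variable projection:
lifetimes are optimized in log10 space while amplitudes are solved by
non-negative least squares at every step, from several seeded starts;
amplitudes are reported as fractions and adjacent lifetimes within a factor
1.5 trigger an ill-conditioning warning.

`derive_constants` reports the second-order binding constants two ways: the
closed-form branching estimate `kON = kin·kg/(kg + kout)` and a numerical
estimate measured as the slope, versus [CO], of the apparent bimolecular rate
fitted to pathway-isolated simulated traces (100 and 200 μM by default).
Both are exposed because published second-order constants are not always
consistent with the branching formula applied to the published microscopic
rates; the two estimators agree to <2% on all presets here.

## SVD of time-resolved spectra

A wavelength × delay matrix of difference absorbances is decomposed exactly
(`numpy.linalg.svd`); the sign ambiguity is fixed by making the
largest-magnitude element of each spectral component positive.  A component
is selected as meaningful iff its singular value is at least `sv_ratio_min`
(default 0.01) of the largest *and* both its spectral and amplitude vectors
have lag-1 autocorrelation (Σvⱼvⱼ₊₁ on the unit-norm vector) of at least
`autocorr_min` (default 0.8).  The conjunction is essential: every matrix,
including pure noise, has s₁/s₁ = 1, so a disjunctive rule would always
select the first component, while white-noise singular vectors have lag-1
autocorrelation near zero and are rejected by the smoothness clause.
Smoothness is measured by lag-1 autocorrelation rather than by correlation
with a reference kinetic trace; the latter is a reasonable alternative
definition that is not implemented.

## Synthetic data

`generate_traces` emulates the two-pressure photolysis design: 1.0 and
0.1 atm CO, 10 ns – 1 s log grid at 100 points per decade (a realistic
density for log-binned transient-absorbance data), additive i.i.d. Gaussian
noise of σ = 0.005 on the normalized signal, truncated at ±5σ so signals
stay within the physical tolerance band.  `generate_spectra` builds a rank-2
matrix from two Gaussian-band basis spectra — a deoxy-minus-carboxy Soret
difference (positive 436 nm band, 419 nm bleach, widths 8 nm) and a small
band-shift feature whose amplitude is set so the second singular value is
~2% of the first, the magnitude typically observed for the conformational
intermediate — multiplied by simulated time courses (the unliganded fraction,
and the t-conformer unliganded population, which forms and decays).  All
generators are bit-reproducible under a fixed seed.

What the synthetic data do *not* model: shot noise or wavelength-dependent
noise, instrument response and the finite laser pulse, baseline drift,
photoselection, partial photolysis heterogeneity, and any systematic model
error (the generator is the fitted model itself).  Passing recovery tests
therefore demonstrate estimator correctness and identifiability under the
stated noise, not robustness to model misspecification.

## Identifiability of the two-pressure design

The recovery harness (truth = the reference MaPgb* rate set, σ = 0.005,
free parameters perturbed ×2^U(−1,1), five seeds) shows a sharp split:

* `kin_r`, `kout`, `k3` recover to a few percent; `k_3` to ~10–40% per seed.
* `kc, k_c, kd2, k_d2` are flagged weakly identified, as expected for the
  small-amplitude docking-site detour.
* `kin_t` does **not** recover to 20%: at the truth the Fisher matrix has
  corr(kin_t, kg_t) ≈ −0.99999.  Rebinding traces constrain essentially only
  the product kON_t = kin_t·kg_t/(kg_t + kout) — the t-pathway geminate
  amplitude that would separate the factors is kg_t/(kg_t+kout) ≈ 4% of the
  ~20% t-share of the signal (≈0.8% absolute) and decays at nearly the same
  apparent rate as the r geminate phase.  The maximum-likelihood point
  therefore wanders along this valley from noise alone, and kin_t scatters
  by tens of percent regardless of optimizer quality.

Notably, the single-axis fitness scan for kin_t is *narrow* (scanning kin_t
with kg_t held fixed steps off the valley floor immediately).  Conditional
(scan) errors can thus be small for parameters whose marginal (joint)
uncertainty is large; quoting scan errors alone understates the uncertainty
of strongly correlated parameters.  This is the package's main caveat on the
error-scan convention.

## Numerical choices and edge cases

* Integration: BDF, rtol 1e-8 / atol 1e-12; conservation projection as above.
* Fit residuals on trace grids as supplied; penalty residuals (1e3) on
  integrator failure keep the optimizer away from pathological regions.
* Eigen-propagation clamps numerically positive real parts of generator
  eigenvalues to zero (they are non-positive analytically).
* Equilibrium splits: `k1 > 0` with `k_1 = 0` raises a degenerate-equilibrium
  error; `k1 = 0` is the valid single-conformation limit (all r).
* Multi-exponential fits: amplitudes constrained non-negative and normalized
  to fractions; lifetimes sorted ascending; exponent clipped at −700 to
  avoid underflow warnings.
* Scan: 81 points, ±1 decade, threshold 1.1×, all configurable; flat fitness
  reports the scan range and an unbounded flag rather than a number.
* Preset for the Trp60Ala variant derives both `kdiss` values from its single
  (monophasic) measured off-rate.

## Known limitations

* Single temperature; no Arrhenius analysis.
* No Bayesian or profile-likelihood uncertainties; the scan convention is
  kept for comparability, with the caveat above.
* The NO-displacement model treats the scavenger as perfect (no rebinding at
  all) and does not model NO association kinetics.
* SVD components are not rotated onto kinetic-model basis spectra.
* Two printed equilibrium constants in the variant tables this package's
  presets are based on are mutually inconsistent with the corresponding
  microscopic rate ratios at printed precision (Trp60Ala K3, Phe145Trp K1);
  the presets follow the microscopic rates, so `derive_constants` reproduces
  the ratio, not the rounded printed value, in those two cases.
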