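# Methods

## Model

The package evaluates membrane permeability in the inhomogeneous
solubility–diffusion framework. A permeant crossing a lamellar lipid
barrier is described by a 1D reaction coordinate z (depth, nm), a
potential of mean force ΔG(z) (kJ/mol) and a local diffusion coefficient
D(z) (nm²/ps). The single-system resistance is

    R = ∫ exp(ΔG_rel.water(z)/kT) / D(z) dz ,

where ΔG_rel.water is calibrated so each point is the transfer free
energy from the aqueous phase: the raw profile (referenced to the
decoupled/vacuum state) minus the hydration free energy of the species.
The assumptions inherited from this framework: permeation is
quasi-one-dimensional, lateral equilibration is fast, D(z) is Markovian
(memory effects are folded into the friction estimate), and flux is in
the linear-response (dilute, steady-state) regime.

The macroscopic barrier is modeled as N identical systems in series
(default N = 30, systematic spread ±6), R_total = N·R, K_P = 1/R_total.
No interfacial resistance between layers is added; the layer count's ±6
spread is reported as a deterministic K_P range, deliberately separate
from the statistical replicate SEM because it is a systematic term.

### Dynamic protonation

An ionizable permeant with one pKa is treated as a two-state system
(neutral, charged), each with its own calibrated PMF and D(z). At a
given pH:

1. the charged PMF receives the constant kT·ln10·s·(pKa − pH)
   (s = +1 acid, −1 base). The sign convention is pinned by a testable
   requirement: bulk-water populations must reproduce the
   Henderson–Hasselbalch ratio charged:neutral = 10^(s(pH−pKa)).
2. both PMFs are raised by one common constant so the global minimum is
   ≥ 0 (the zero-shift convention the resistance integral assumes); the
   state difference is untouched.
3. the combined PMF is −kT·ln[e^(−G_n/kT) + e^(−G_c/kT)] (`boltzmann`
   mode, the default: the free energy of being in *either* state). A
   `weighted` mode (p_n·G_n + p_c·G_c) is kept as an option; the two
   differ by an entropy-like term of at most kT·ln2 and are sometimes
   described as equivalent, which they are not exactly — the degenerate
   case separates them cleanly (2× vs 1× the single-state K_P) and the
   package exposes both rather than silently choosing.
4. the combined diffusion profile is p_n·D_n + p_c·D_c with local
   Boltzmann probabilities p_i(z).
5. R and K_P follow from the combined profiles.

This construction assumes protonation exchange is fast relative to
transport (local equilibrium between the states at every depth). That
assumption is *checked*, not just asserted: the two-state
master-equation oracle (below) with a finite exchange rate converges to
the combined-profile result as the rate grows, and to the sum of the
uncoupled single-state fluxes as it vanishes.

The combined PMF is not re-zeroed after step 3 by default (it may dip
below 0 by ≤ kT·ln2); a `rezero` flag exists for users who prefer the
stricter convention. Physical constants: molar gas constant
0.0083144626 kJ/mol/K; default temperature 305.15 K (skin), giving
kT = 2.5372 kJ/mol and a Henderson–Hasselbalch shift of 5.842 kJ/mol
per pH unit.

### pH-partition baseline

K_P(pH) = f_neutral(pH) · K_P(neutral), with f_neutral the bulk neutral
fraction. This is the classical "only the neutral form permeates"
hypothesis and serves as the comparator; with equal diffusion profiles
the dynamic estimate can only exceed it, since the charged channel adds
conductance.

## Numerics

* Resistance integral: trapezoidal rule on a uniform grid (~0.01 nm).
  Linear interpolation is used for resampling — at this resolution
  higher-order schemes add nothing and can overshoot near sharp wells.
  Quadrature convergence is tested (halving the spacing moves smooth-
  profile results by < 0.1%).
* All Boltzmann factors are computed in log space (logaddexp / logistic);
  charged-state barriers exceed 100 kJ/mol and naive exponentials
  overflow. State probabilities are built as p_c = expit(−ΔG/kT),
  p_n = 1 − p_c, so they sum to 1 exactly.
* Units are fixed internally (nm, kJ/mol, nm²/ps, K) and declared, never
  inferred from file headers. Conversions: 1 ps/nm = 1e-5 s/cm,
  1 nm/ps = 1e5 cm/s.
* Half-profile handling: symmetric systems may be supplied on [0, L];
  the integral is doubled (auto-detected, overridable).
* Degenerate inputs are rejected loudly: non-monotonic grids (first
  offending index named), non-positive diffusion, grossly asymmetric
  spans passed to the symmetrizer, non-uniform integration grids.

## Preprocessing

Order of operations: symmetrize → edge repair (PMFs) / rolling median
(diffusion) → resample → replicate averaging. The order is a convention
exposed in configuration, not a law of nature.

* Symmetrization folds [−L, L] onto [0, L] by arithmetic averaging of
  the ±z pair in the free-energy domain. With calibrated PMFs and
  symmetric noise this is the unbiased estimator; sampling-weighted
  alternatives would need information (bias histories) that tabulated
  profiles no longer carry.
* The rolling median window is defined by physical width (default
  0.2 nm), not point count, so it is grid-spacing invariant. It removes
  single-point spikes exactly and never leaves the input's range.
* Edge repair copies the nearest interior value outward over the
  n_edge = 2 outermost points per side — the adaptive-bias sampling
  boundary artifact is confined to those points on a 0.01 nm grid.
* Replicate averaging: pointwise mean, sem = sd/√n (ddof = 1); n = 1 is
  flagged in metadata rather than silently reporting sem = 0 as
  confidence.

## Uncertainty

K_P is log-normally distributed under additive PMF noise, so statistics
are computed on log10 K_P. The headline estimate comes from the
replicate-*averaged* PMFs (the central-estimate procedure used with the
underlying simulation data), and the error bar is the SEM of the
per-replicate log10 K_P values (matched pairing of neutral and charged
replicates by default; all-pairings mode available). The averaged-profile
estimate is preferred over the mean of per-replicate estimates because
the resistance integrand is convex in PMF noise and the zero-shift
convention couples the noisy profile minimum into K_P: both effects
shrink roughly as 1/n when the profiles are averaged first, but bias
every individual replicate estimate downward.

## The master-equation oracle

An independent validation path: the permeant hops on the depth grid with
nearest-neighbor rates k_{i→i±1} = D_{i±1/2}/Δz²·exp(∓ΔG/2kT) (symmetric
exponent splitting — second-order accurate, detailed balance exact by
construction), a source held at unit reference concentration and an
absorbing sink. The steady state is solved as a linear system in
activity variables (a symmetric series-of-conductances problem, benign
even with 60+ kJ/mol barriers); flux/concentration is the permeability.
A deterministic linear solve was chosen over stochastic trajectories
because it is exact for the chain and fast; a seeded kinetic Monte Carlo
splitting-probability estimator is included as a secondary cross-check
at coarse grids. The two-state variant adds vertical exchange edges with
attempt rate ν and detailed-balance splitting, covering both the
fast-exchange and frozen-state limits of the dynamic-protonation
construction.

## Synthetic data

The generator emulates the statistical structure of adaptive-bias
free-energy output on the half grid [0, 5.2] nm at 0.01 nm spacing:

* ground-truth PMFs as Gaussian wells/barriers — neutral: −6 kJ/mol
  chain well at 1.5 nm, +3 kJ/mol headgroup bump; charged: −12 kJ/mol
  headgroup well at 3.1 nm (window 2.9–3.3 nm), 65 kJ/mol chain barrier
  — both → 0 (the water reference) in the aqueous region. The charged
  barrier height is set high enough that permeation is dominated by the
  neutral channel in the physiological regime while both the
  excluded-state and pH-partition-agreement limits stay reachable by
  moving pH.
* five replicates per state: truth + smooth correlated noise (Gaussian-
  filtered white noise, correlation length 0.2 nm — chosen to interact
  meaningfully with the 0.2 nm median filter — marginal sd 1.0 kJ/mol,
  a realistic replicate-to-replicate variability for well-converged
  profiles) + 0.1 kJ/mol white jitter.
* diffusion: 0.05 nm²/ps baseline with a chain-region dip, multiplicative
  lognormal noise (σ = 0.15), and ×5 spikes injected at the two outermost
  points per side; PMF replicates get +8–16 kJ/mol edge spikes. These
  exercise the repair stages.
* presets `acid_like` (pKa 4.2) and `base_like` (pKa 8.0) with nominal
  hydration free energies (−40 / −260 kJ/mol) — generator conventions,
  not measurements of any real compound.

What the generator does **not** emulate: correlated errors between the
PMF and the friction estimate, depth-dependent noise amplitude (real
sampling is worse in high-barrier regions), anisotropic/laterally
heterogeneous barriers, multiprotic chemistry, and any quantitative
resemblance to a specific drug. Passing the recovery tests therefore
demonstrates the *estimator machinery* is unbiased enough under
idealized noise — not that any real compound's permeability is predicted
to that accuracy.

## Problem sizes

Default profiles are 521 points (half grid at 0.01 nm); oracle solves
use ~1 000–2 100 unknowns; recovery statistics use 100 seeded datasets
of 5 replicates each. A full test-plus-acceptance cycle runs in well
under a minute on one core.

## Known limitations

* Serial-resistance layer scaling ignores inter-layer interfaces and
  lateral heterogeneity.
* A single pKa per permeant; zwitterions and multiprotic species are out
  of scope.
* The fast-exchange (local-equilibrium) assumption is validated against
  the two-state oracle on synthetic profiles, not against microscopic
  proton-transfer kinetics.
* The ±2·SEM, n = 5 replicate interval is an ~88% interval, not 95%
  (Student-t with 4 degrees of freedom); consumers wanting calibrated
  95% coverage should scale the SEM by t₀.₉₇₅,₄/2 ≈ 1.39.
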