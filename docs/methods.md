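# Methods

## Physical model

A ligand dimer is joined by a flexible polymer modelled as a Gaussian coil
of `N` Kuhn segments of length `b`. Once one head is bound, the free head
diffuses with constant `D` in the entropic harmonic potential of the
tether, `U(r) = kappa r^2 / 2` with `kappa = 3T/(b^2 N)` (temperature `T`
in energy units, `k_B = 1`). Binding of the second head is modelled as
absorption on a sphere of radius `a` centred on the receptor of the bound
head; the tether's finite contour length imposes a reflecting sphere at
`R* = N b`. The membrane beneath the receptor is not represented: the
no-flux plane it would add complicates the solution without changing the
scaling behaviour. Nonlinear (finite-extensibility) elasticity near `R*`
is likewise ignored — strongly stretched configurations are exponentially
rare — which makes the computed capture time a slight overestimate.

The mean capture time is obtained from an equivalent steady-state problem:
particles are injected on the shell `r = R` (fixing `c(R) = 1`), absorbed
at `r = a` (`c(a) = 0`), and reflected at `R*` (zero radial current). The
mean lifetime is the steady-state population over the annihilation rate,
`T = N_ss / F`. The injection radius is fixed at the rms end-to-end
distance `R_rms = b sqrt(N)`; averaging over the full end-to-end
distribution (and membrane-induced distortions of it) is deliberately out
of scope. In the scaled radius `x = r/r0`, `r0 = b sqrt(N/3)`, the
concentration solves `c'' + (2/x + x) c' + 3c = 0` with basis solutions
`exp(-x^2/2)` (equilibrium, zero current) and
`f(x) = sqrt(pi/2) exp(-x^2/2) erfi(x/sqrt2) - 1/x` (unit current). All
reported times are scaled by `tau0 = a^2/D`.

At `N = 1` with `a = b` the start radius coincides with the capture
sphere; the coefficient solve is singular there and the code returns
`tau = 0` exactly. The Gaussian-coil picture is anyway inapplicable to
single-segment tethers; the package treats the point as an exact limit,
not a physical prediction.

## Numerical choices

- **Basis function.** `f(x)` is evaluated as
  `sqrt(2)*dawsn(x/sqrt2) - 1/x` (scipy's Dawson function). This is
  mathematically identical to the erfi form but does not overflow (the
  naive product does for `x >~ 38`). The analytic derivative
  `f'(x) = -x f(x) + 1/x^2` gives the exact current identity
  `x^2 j(x) = -B_inner` used for the flux cross-check. Note the large-`x`
  asymptote is `f(x) -> 1/x^3`: the `1/x` terms of the Dawson expansion
  cancel.
- **Overflow-safe outer term.** The outer-region coefficient
  `A_outer = exp(R_bar^2/2)` is stored in log space; the population term
  `A_outer * Delta3` is computed as the fused, scaled-erfc expression
  `y - U E + sqrt(pi/2) [erfcx(y/sqrt2) - E erfcx(U/sqrt2)]` with
  `E = exp((y^2 - U^2)/2) <= 1`, exact and bounded for arbitrarily large
  radii. The same expression provides the inner integral of the
  backward-equation oracle.
- **Quadrature.** Adaptive quadrature at absolute and relative tolerance
  1e-10; the Gaussian-moment integrals `Delta1`, `Delta3` are additionally
  checked against their erf closed form (discrepancy above 1e-9 raises an
  error). The `Delta2` integrand is written as
  `z^2 sqrt(2) dawsn(z/sqrt2)`, removing the `1/z` singularity of `f`.
- **Scaling regressions.** Power-law exponents are ordinary least-squares
  slopes in log–log space over 24-point log-spaced grids by default
  (`N` in `[1e3, 1e5]` for the `N^{3/2}` law; `b^3 c_inf` in
  `[1e-12, 1e-6]` for the cutoff law).

## Independent oracles

Two computations of the same quantity share no code with the steady-state
solution:

- **Backward-equation quadrature.** The mean first-passage time of 1-D
  radial diffusion in the potential `x^2/2` with absorbing inner and
  reflecting outer boundary,
  `T(x0) = ∫_a^{x0} dy e^{y^2/2} y^{-2} ∫_y^{R*} z^2 e^{-z^2/2} dz`, in
  units of `r0^2/D`. Agreement with `N_ss/F` to better than 1e-6 relative
  over `N` from 2 to 1e4 is the central correctness property.
- **Brownian dynamics.** Euler–Maruyama integration of the overdamped
  3-D motion: per step each coordinate moves by
  `-(D/r0^2) x dt + sqrt(2 D dt) xi`. A step ending with `|r| <= a`
  absorbs; one ending beyond `R*` is reflected by the radial mirror
  `r -> 2R* - r` (direction preserved). Trajectories start uniformly on
  the sphere `|r| = R_rms`. Defaults: `dt = 1e-4 tau0`, 2000 trajectories,
  mandatory seed; normal deviates are drawn in fixed-size batches from the
  seeded generator, so runs are bit-reproducible. The first-order
  discretization bias near the absorbing boundary is controlled by a
  step-halving check rather than higher-order boundary corrections; at
  `dt = 1e-4 tau0` it is below the statistical error of 2000 trajectories.
  The acceptance battery simulates `N` in {5, 20, 100} (about six minutes
  in total); larger `N` scales linearly in `tau(N)`.

## Three-state kinetics

The generator of the free/singly/doubly-bound chain uses rates `r_on`,
`r_off`, `r_capture = 1/tau(N)`, `r_off_double`. The backward III→II
transition, slower still than `r_off_double`, is omitted (adding it back
is a one-line change to the rate matrix but is not exposed). Steady states
come from the closed-form balance relations; transients use the exact
matrix exponential of the 3×3 generator, so probability is conserved to
machine precision. Degenerate chains are resolved as exact limits rather
than errors: `r_off_double = 0` with capture active gives `P_III = 1`;
`r_capture = inf` (instantaneous capture, `tau = 0`) empties state II and
yields the enhancement ceiling `R = 1 + Kd`. The CLI takes rates in units
of `1/tau0` so the computed `tau(N)` plugs in directly; the library itself
is unit-agnostic. The competitive-binding cutoff `tau_max` is exposed
(`tau_cutoff`) but is **not** spliced into the rate model as a floor on
`r_capture`; how free-ligand competition should enter the chain is an open
modelling question and the two effects are kept separate.

## Dose–response curve and synthetic data

The fitted form `dM(N) = (beta - gamma N^{3/2})/(1 + gamma N^{3/2})`
follows from `dM = alpha (R - 1)` with `tau ∝ N^{3/2}` when `alpha = 1`;
for `alpha ≠ 1` the numerator and denominator coefficients decouple and
the printed two-parameter form is no longer an exact consequence of the
kinetic model. The package treats the two-parameter form as the
authoritative fitting target and exposes `dm_from_kinetics` separately as
the mechanistic bridge.

The underlying cell-activity measurements are not available as numbers, so
`synth_dataset` stands in for them: points on the reference curve
(`beta = 78.5`, `gamma = 0.00063`) at nine roughly log-spaced tether
lengths in `N = 1–454`, plus independent homoscedastic Gaussian noise
(default 5 percentage points — a typical viability-assay spread). What the
generator does **not** emulate: heteroscedastic or correlated assay error,
plate effects, and the sharp activity drop for tethers below ~2 kDa, where
steric interactions between ligands invalidate the Gaussian-coil model.
Passing recovery tests therefore demonstrates estimator correctness under
the stated noise model, not fidelity to any particular experiment. The
reference analysis excluded the shortest tether (`N = 1`) from the fit;
`DoseResponseModel(..., exclude_n=[1.0])` replicates that choice.

Fitting is bounded nonlinear least squares (`scipy.optimize.curve_fit`,
`gamma >= 0`), initialized at `beta0 = max(dM)`,
`gamma0 = median(N)^{-3/2}` — a safe basin since the form is monotone in
both arguments. Parameter covariance comes from the Jacobian at the
optimum (`absolute_sigma=True` when per-point noise scales are supplied).
Monte-Carlo coverage at 5% noise: both parameters fall within 2 standard
errors of truth in ≥ 90 of 100 seeded replicates.

## Design notes and limitations

- `N` is accepted as a positive real (log-spaced grids need it);
  validation requires only `N >= 1`.
- The default unit system is `T = b = D = 1` and `a = b`; `a/b` is exposed
  as a free ratio even though the receptor radius and the Kuhn length of a
  real tether need not coincide — the package does not resolve that
  tension, it parameterizes it.
- No worm-like-chain or excluded-volume statistics; no hydrodynamic
  interactions or anisotropic diffusion; no angular dependence; no
  transient (time-dependent) concentration profiles; no receptor-density
  dynamics or ligand depletion in the kinetic model.
- Plotting is left to downstream consumers of the CSV outputs.
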