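# Methods

## Scope and conventions

`ratekit` treats the temperature dependence of rate processes whose
Arrhenius plots are curved: sub-Arrhenius (concave, quantum tunneling),
super-Arrhenius (convex, transport/glassy braking) and anti-Arrhenius
(negative apparent activation energy, stereodynamic gating).

All thermal energies are molar in cal/mol and the inverse temperature is
β = 1/(R·T) with R = 1.98720 cal mol⁻¹ K⁻¹, so that published cal/mol
parameter tables can be used verbatim. Conversion helpers cover J/mol,
hartree and per-molecule quantities. Physical constants are CODATA 2018,
held in a single frozen record.

## Phenomenological laws

Five closed-form k(T) laws are implemented (energies cal/mol, T₀ and B in
K; A carries the data's units opaquely):

| law | k(T) | apparent Ea = −d ln k/dβ |
|---|---|---|
| Arrhenius | A·exp(−Ea·β) | Ea |
| AM | A·(1 − d·ε‡·β)^(1/d) | ε‡/(1 − d·ε‡·β) |
| ASCC | A·(1 − d·ε‡/(RT + Eν))^(1/d), d = −(1/3)(Eν/2ε‡)² | ε‡(RT)²/[(RT+Eν)²(1 − d·ε‡/(RT+Eν))] |
| NTS | A·exp(−E0/(R√(T²+T0²))) | E0·T³/(T²+T0²)^{3/2} |
| VFT | A·exp(B/(T−T0)) | −B·R·T²/(T−T0)² |

The deformed exponential (1−d·x)^{1/d} is evaluated via `log1p(−d·x)/d`, so
the d → 0 limit degrades gracefully to exp(−x) at machine precision. The
ASCC deformation is always derived from (ε‡, Eν), never free — the law is a
three-parameter family. VFT is implemented exactly as written, with B
allowed negative (the super-Arrhenius fits in the bundled benchmarks need
B < 0). Evaluations outside a law's support (non-positive deformed base,
T ≤ T0) raise a `DomainError` rather than returning 0 or NaN: silent zeros
corrupt fits.

The transitivity function γ(β) = 1/Ea(β) linearizes deformed-Arrhenius
behaviour: for the AM law it is exactly affine, γ = 1/ε‡ − d·β. Points with
Ea = 0 raise a dedicated singular-transitivity error in closed form and are
flagged (NaN) in numerical tables.

## Numerical transitivity

`numerical_transitivity` differentiates ln k against β (the variable in
which the apparent activation energy is defined), using the standard
three-point unequal-spacing stencil at interior points (via `np.gradient`)
and second-order one-sided differences at the endpoints, which are flagged
lower-accuracy. Duplicate temperatures are averaged in ln k before
differencing, because derivative stencils need distinct abscissae.

Optional Savitzky–Golay smoothing (default window 7, order 2, both
user-overridable) is applied to ln k *before* differencing: differentiating
raw noisy k amplifies noise multiplicatively, while log-space smoothing
respects the positivity and the decade scale of rate data. The filter
operates on the point index; for the near-uniform temperature grids it is
intended for, this is an adequate approximation to abscissa-aware smoothing.

On noise-free 30–40-point grids spanning up to a factor ~5 in temperature,
the interior numerical γ agrees with the closed forms to a few parts in
10⁴–10³ (the acceptance suite enforces 0.5%).

## Generalized simulated annealing

The global optimizer is a Tsallis-statistics annealer over a bounded box:

- **Schedule**: T_qv(t) = T_qv(1)·(2^{qv−1}−1)/((1+t)^{qv−1}−1), with
  qv = 2.62 and a fixed T_qv(1) = 5230 (common GSA practice; an
  objective-scaled initial temperature would couple the step geometry to
  the objective's units).
- **Visiting distribution**: the 1-D Tsallis q-Gaussian for 1 < qv < 3 is a
  scaled Student-t with ν = (3−qv)/(qv−1) degrees of freedom; deviates are
  drawn exactly from that representation. Each annealing step proposes one
  joint move of all coordinates followed by one move per coordinate,
  reflected into the box. The characteristic width scales as
  T_qv^{1/(3−qv)} (capped at the box size); the distribution's power-law
  tail keeps occasional box-scale jumps alive at all times, which is what
  lets the walker re-escape basins late in the schedule.
- **Acceptance**: generalized Metropolis with qa = −5 at temperature
  T_qv(t)/t; uphill moves are accepted with probability
  [1 − (1−qa)ΔE/Ta]^{1/(1−qa)} (zero when the bracket is non-positive).
  Ties keep the earlier point, and all randomness flows through one seeded
  generator: a fixed seed reproduces the trace bitwise.

Non-finite objective values are treated as +∞, so support violations inside
the search box act as hard walls rather than crashes.

## Fitting

`fit_rate_data` minimizes the mean squared residual of the rates —
by default in log10 space, the natural choice for data spanning many
decades (linear, ln and relative spaces are selectable). The residual-space
convention for the χ² reported with a fit is therefore part of the fit
record; χ² values from other software are not comparable unless their space
is known.

The search runs over (log₁₀A, shape parameters) inside either user bounds
or data-driven default windows anchored by a straight-line Arrhenius fit of
(β, ln k): ±8 decades around the intercept for A (curved data can place the
true pre-factor several decades off the straight-line intercept),
±(5|Ea0|+2000) cal/mol for energy-like parameters, [−3, 3] for the AM
deformation, and T0 kept below the data range for VFT (support) or below
1.5·Tmax for NTS. After GSA, a bounded Nelder–Mead simplex polishes both
the annealing optimum and the deterministic data-anchored start (curvature
parameters at their neutral values), keeping the better limit — the
annealer occasionally parks on a support cliff where the simplex cannot
move.

Transitivity-plane fitting (Arrhenius, AM, VFT) minimizes the squared
residual of γ(β) built by `numerical_transitivity` at interior, defined
points. The pre-factor does not enter γ, so A is recovered afterwards as
the mean log-offset of the data from the unit-A model.

Laws with three parameters can admit multiple χ² solutions; the fit reports
the best solution for the given seed and bounds, nothing more. Informative
bounds are the supported way to inject prior knowledge.

## Transition-state theory

Partition functions use the rigid-rotor / harmonic-oscillator / ideal-gas
factorization with ZPE-referenced vibrational factors (q_vib ≥ 1).
Symmetry numbers and electronic degeneracies are explicit species fields
defaulting to 1 — they are never inferred from geometry, a classic source
of factor-of-2 errors. The barrier ε‡ defaults to the ΔZPE-corrected
electronic barrier; a flag disables the ZPE term, and per-species energy
overrides accommodate higher-level single-point energies. Bimolecular rates
are computed per molecule (cm³ molecule⁻¹ s⁻¹); the molar value is N_A
times that.

d-TST replaces the exponential barrier factor with the deformed exponential
at d = −(1/3)(hν‡/2ε‡)², where ν‡ is the magnitude of the imaginary mode.
It recovers plain TST as ν‡ → 0 and covers classical-to-moderate tunneling;
it is not intended for the deep regime.

### Tunneling corrections and regimes

Wherever the correction formulas involve the reduced quantum, ℏν‡ is taken
literally as hν‡/2π (this reproduces the Skodje–Truhlar α = 2π/hν‡
convention). The crossover temperature is Tc = hν‡/(π·kB) = c₂ν̃‡/π, and
the regime windows are negligible (T ≥ 2Tc), small (Tc ≤ T < 2Tc),
moderate (Tc/2 ≤ T < Tc) and deep (T < Tc/2) — boundaries assigned to the
milder side so the four windows partition the axis exactly.

- **Bell (1935)**: κ = [1/ℏν‡ − (1/kBT)·e^{ε‡/kBT − ε‡/ℏν‡}]/[1/ℏν‡ − 1/kBT].
  The formula has a removable 0/0 point at kBT = ℏν‡ (T = Tc/2); within a
  10⁻⁸ relative window it is evaluated by its analytic limit 1 + ε‡/ℏν‡.
  Note the high-temperature approach to κ = 1 is first order, κ ≈ 1 +
  Tc/(2T).
- **Bell (1958), one term**: κ = u/sin u with u = hν‡/(2kBT) (the quotient
  form — only it has the documented pole and κ ≥ 1 behaviour). The genuine
  pole sits at u = π, i.e. T = Tc/2; evaluation within |u − π| < 10⁻³ is
  refused with an error naming Tc. The two-term variant subtracts
  e^{ε‡(1/kBT − 1/ℏν‡)}/(kBT/ℏν‡ − 1) and shares the same pole guard.
- **Skodje–Truhlar**: branches at β = 𝕔 = π/hν‡. The high-temperature
  branch is the two-term Bell form with ε‡ − ΔH in the exponent. For the
  low-temperature branch the standard 1981 sign,
  κ = [e^{(1/kBT − 1/ℏν‡)(ε‡−ΔH)} − 1]/(1 − kBT/ℏν‡), is used — the only
  sign for which the transmission is positive on the whole branch — with
  the removable point at kBT = ℏν‡ evaluated by its limit (ε‡−ΔH)/kBT. The
  two branch formulas do not meet continuously at β = 𝕔; both are finite
  there (no pole), and the suite records the mismatch rather than hiding
  it.

## Solution-phase kinetics

Solvent viscosity follows a deformed (super-Arrhenius) law in either form
η = η₀(1 − T*/T)^p (water default η₀ = 2.7024·10⁻⁴ Poise, T* = 213.0543 K,
p = −2.75634, an experimental-data parametrization valid above T*) or
η = η₀(1 − d·ε/RT)^{1/d} with ε in J/mol; the two are the same family
re-parametrized.

**Collins–Kimball** (bimolecular): cage radii from molar volumes,
r = (3V/4πN_A)^{1/3}; Stokes–Einstein diffusion D = kBT/(6πηr) in cgs;
Smoluchowski limit k_D = 4π·r_AB·D_AB·N_A with r_AB = r_A + r_B; observed
rate 1/k_obs = 1/k_TST + 1/k_D. The reverse-diffusion step is eliminated by
the usual infinite-reaction-rate limit (k→D ≅ k←D), so only the harmonic
combination is implemented. The activated rate fed in may come from TST,
d-TST or any κ-corrected rate — caller's choice.

**Kramers** (unimolecular and pseudo-unimolecular): κ_Kr =
(√(μ²/4 + ω‡²) − μ/2)/ω‡ with ω‡ = 2πc·ν̃‡ the magnitude of the imaginary
angular frequency. The printed friction expression μ = (6πr_AB/M)η is
dimensionally ambiguous as typeset; the implementation uses the only
reading with units of s⁻¹ — the Stokes drag over the per-molecule mass,
μ = 6π·r_AB·η/(M/N_A) in cgs (r in cm, η in Poise, mass in g). Kramers'
cage radius is the transition state's own (from its molar volume), whereas
Collins–Kimball uses the sum of the reactant radii — the two roles are
distinct.

## Synthetic data and benchmarks

The generators are pure functions of their spec (seed included). Rate-table
noise is multiplicative lognormal — rates are positive and fits run in log
space, so log-normal errors are the consistent noise family. The toy
reaction systems are 2–4-atom constructs with hand-auditable partition
functions: the unimolecular template has an identical reactant and
transition state apart from a 5000 cal/mol offset (partition ratio exactly
1), and the deep-tunnel template's 1500 cm⁻¹ imaginary mode places Tc near
687 K.

The bundled benchmark registry holds published fitted parameters for four
processes spanning the phenomenology (deep-tunneling keto–enol
tautomerization, moderate-tunneling OH + H₂, super-Arrhenius enzymatic
hydride transfer, anti-Arrhenius OH + HBr) with temperature windows chosen
once as realistic for each process: 100–320 K, 200–1000 K, 278–338 K
(5–65 °C, the stated experimental range of the enzymatic study) and
200–420 K. Self-consistency — regenerate noise-free k(T) from the printed
parameters, refit, recover within 1% — is the package's main acceptance
benchmark, run at 40-point grids (seconds per fit on one CPU).

What passing these tests shows — and does not show. The synthetic data are
exact realizations of the laws being fitted, with at most lognormal noise.
Real kinetic data carry correlated errors, heteroscedastic uncertainties,
model misfit and narrow temperature windows; parameter recovery there is
limited by identifiability (three-parameter laws especially), not by the
optimizer. The suite demonstrates the machinery is correct and
deterministic, not that any particular law is the right model for a given
dataset.

## Known limitations

- No Eckart or variational-TST corrections; no hindered-rotor or
  anharmonic partition-function refinements; no pressure dependence.
- Uncertainty quantification of fitted parameters is out of scope; only
  the best-χ² solution and its seed are reported.
- The electronic-structure log reader is a minimal, fixture-tested
  extractor for the documented dialect; the structured YAML species file is
  the supported input path.
- The Bell 1958 corrections are undefined at and below their Tc/2 pole by
  construction; use d-TST, Bell 1935 or Skodje–Truhlar in the deep regime.
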