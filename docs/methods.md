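# Methods

This note documents the models, numerical choices and limitations behind
each analysis stage, in the order a study would use them.

## Orthogonal-design screening

The design is the standard L16(4⁴) orthogonal array: four factors
(A temperature 20–35 °C, B particle size 60–120 mesh, C initial pH
1.5–3.0, D inoculum volume 5–20 mL), four levels each, sixteen runs,
every level of every factor appearing exactly four times. Interactions are
not modelled; with four 3-df factors the 15 total df leave 3 df of pooled
error, against which factor mean squares are F-tested on the F(3, 3)
distribution (survival function from scipy). Flags: p < 0.01 "very
significant", p < 0.05 "significant". No multiple-testing correction is
applied, matching standard practice for this screening design.

**Rounding.** All computation is in full double precision; only the
formatted report rounds, half-up to 2 decimals. Displayed level means are
the rounded sums divided by 4 in decimal arithmetic, and displayed ranges
difference the already-rounded means — this is how printed engineering
tables are produced (e.g. a displayed range of 15.63 for temperature where
full precision gives 15.6225 → 15.62). Canonical full-precision values are
always available alongside the display variants.

**Published-value cross-check.** The bundled dataset stores only run-level
responses; every derived number is recomputed. A cross-check against the
published summary tables flags entries that cannot be reconciled with the
run-level data: the level-4 sum for factor D (printed 223.82; the runs,
and the printed mean 56.71, both give 226.82 — a transcription slip) and
the pH sum of squares (printed 365.97; the K-sum identity gives 270.95,
which also changes the total from 1348.96 to 1253.93 and F_C from 9.90 to
7.33). All other sums, ranges, superior levels, SS and F values reconcile
at display precision. The recomputed values are authoritative throughout;
the significance order A > C > D > B is unchanged either way.

## Closed-form metrics

Fe²⁺ conversion η = 100(c₀−c)/c₀ and desulfurization rate
w = 100(S_B−S_A)/S_B are dimensionless percentages on the 0–100 scale.
Molar masses are fixed constants (Fe 55.845, FeSO₄·7H₂O 278.01 g/mol), so
the 9 K medium's 44.2 g/L of heptahydrate corresponds to 8.88 g/L Fe²⁺ —
the default initial substrate concentration everywhere.

## Monod growth kinetics

Growth on Fe²⁺ couples the Monod law dC_l/dt = u_m p C_l/(K+p) with the
yield balance C_l = C_l⁰ + Y(p⁰−p), giving a single autonomous ODE for p.
Dividing through by Y shows that only the ratio C_l⁰/Y enters the
dynamics, so the fit estimates (u_m, K, C_l⁰/Y); absolute biomass and Y
are identified only when biomass observations are supplied (then Y is
resolved by a one-parameter least-squares pass over the balance). The
time unit is whatever the input series uses — u_m (default 0.0497) is per
that unit; K (0.328 g/L) and C_l⁰/Y (1.0838 g/L) are substrate-scaled.

Numerics: trajectories use LSODA at rtol 1e-10 with the state clipped to
[0, p⁰] and monotonicity enforced against roundoff; the implicit time
relation t(p) is evaluated by adaptive quadrature of the separated ODE
(the two routes agree to ~1e-6 relative and that mutual consistency is a
test invariant — an integrated closed form is deliberately not used
because the separated integral is the unambiguous definition). The fit is
trust-region least squares with bounds (u_m ≥ 0, K > 0, C_l⁰/Y ≥ 0) and a
3×3×3 coarse-grid multi-start fallback triggered on gross misfit (RSS
above 5% of the data's sum of squares) or solver failure; a constant
series short-circuits to u_m = 0 flagged degenerate. Noiseless synthetic
data are recovered to ~1e-12 relative; 0.05 g/L Gaussian noise on 20
points leaves all three parameters within ~1% of truth.

## Shrinking-core desulfurization kinetics

A spherical coal particle reacts at an unreacted core of radius
r_c = r_s(1−x)^⅓ inside a growing product layer (jarosite-type
precipitates). Quasi-steady state with external-film diffusion,
product-layer diffusion and interfacial reaction in series integrates to
t = A₁g₁(x) + A₂g₂(x) + A₃g₃(x) with g₁ = x,
g₂ = 1−⅔x−(1−x)^⅔, g₃ = 1−(1−x)^⅓. The physical mapping is
A₁ = γδρr_s/(3MC_lD₁), A₂ = γρr_s²/(2MC_lD₂), A₃ = ρr_s/(MC_lk); A₂ uses
the initial radius r_s (the lumped coefficient must be constant while r_c
shrinks — the standard shrinking-core convention). The rate law dx/dt is
defined as the reciprocal of dt/dx of the integrated form, which removes
any ambiguity about the differential statement while preserving the model.

Fitting is intercept-free OLS of t on (g₁, g₂, g₃) (numpy lstsq;
rank-deficient designs raise a singular-design error; an optional
non-negative mode uses bounded least squares for physical fits). r(Aᵢ) is
the Pearson correlation between gᵢ evaluated at the data and observed t;
the controlling step is ranked by descending |r|. R is reported as the
correlation between fitted and observed t, with R² alongside, since the
published "regression coefficient" does not say which it is. Published
regressions of this form can return negative A₁, A₂ on sign-mixed data —
the unconstrained fit reproduces that behaviour; negative coefficients
make t(x) potentially non-monotone, in which case inversion (bisection on
[0, 1−1e-9], tolerance 1e-10) refuses with the offending interval named.
x is clipped to ≤ 1−1e-9 wherever negative fractional powers of (1−x)
are evaluated.

Coupling to growth: all Aᵢ scale as 1/C_l, so with biomass C_l(t) from
the growth model the instantaneous rate is the fixed-coefficient rate
times C_l(t)/C_l(0). The joint (p, x) system is integrated together; with
u_m = 0 it reduces exactly to the fixed-coefficient model.

## Activation energy from thermogravimetry

Non-isothermal first-order decomposition at heating rate α (default 10 K
per time unit) linearizes so that ln[−ln(1−x)] is a straight line in 1/T.
Two conventions are implemented:

* **study** (default): ln[−ln(1−x)] = ln(AE/(αR)) − 5.314 − 0.1278·E/T,
  so E = −slope/0.1278. These printed constants are kept exactly as
  published even though they differ from the SI Coats–Redfern values
  (1/R = 0.1203 mol/J); energies computed under the two conventions
  therefore differ, which is why both are exposed.
* **coats-redfern**: the textbook ln[−ln(1−x)/T²] = ln(AR/(αE)) − E/(RT).

Conversion from a thermogram is fractional mass loss between m₀ and m_f
(user-supplied or window-extremal), clipped to [0, 1]. The fit is OLS on
all points with 0.01 < x < 0.99 (or a user window in K); endpoints x ∈
{0, 1} are excluded with a reported count; fewer than 3 usable points is
an error and a non-negative slope (E ≤ 0) warns. Round-trip recovery on
noiseless data is exact to ~1e-15 for E across 5e3–5e4 J/mol.

## Synthetic data

Generators produce exactly the structure each estimator assumes: forward
model plus additive Gaussian noise (no noise model is published for any
of these measurements; Gaussian is the least-assumption default), seeded
via numpy's default_rng so identical specs give identical output.

* Growth series: ODE trajectory with noise on p, clipped to
  [1e-6·p⁰, p⁰]; biomass/conversion recomputed from noisy p so the mass
  balance holds in the emitted series.
* Conversion series: t(x) plus time noise, redrawn (≤100 attempts) until
  strictly increasing. Default demonstration coefficients (10, 400, 5)
  are internal-diffusion dominant, so the recovered ranking reproduces the
  r(A₂) > r(A₃) > r(A₁) control diagnosis on data whose mechanism is
  known; demonstration noise sd 0.1 time units is small relative to the
  point spacing, consistent with the tight published regression.
* TG conversion: x(T) solving the study linearization exactly, optional
  ordinate noise (sd 0.05 in demonstrations). Because an arbitrary (E, A)
  pair can park the whole curve at x ≈ 0 or 1 inside a finite window,
  `apre_centering_halfpoint` chooses A so the decomposition half-point
  sits at the window's median 1/T — how a real TG segment is chosen.
* Design tables: grand mean + additive per-level effects + noise on the
  L16 layout; orthogonality makes the zero-noise saturated additive model
  exact (SS_Error = 0).

What passing recovery tests do **not** show about real data: real Fe²⁺
series have titration error structure, lag phases and pH-dependent u_m;
real conversion series have particle-size distributions and time-varying
jarosite coverage; real TG curves contain multiple overlapping
decomposition events, so a single-line fit is window-dependent. The
demonstration problem sizes (16 runs, 20 time points, 19 conversion
points, 30 temperatures) match the scale of the corresponding laboratory
datasets.

## Known limitations

* Units for u_m, K and the growth time axis are inherited from the input
  series; no unit conversion is attempted.
* Physical shrinking-core parameters (D₁, D₂, k, δ) are forward-mapped
  only; they are not identifiable from a single (t, x) series through the
  lumped coefficients.
* The activation energies measured on real (unavailable) thermograms are
  not reproduced — only the estimator is validated, by round-trip at the
  published energy scales (8934.3 and 31464.4 J/mol).
* Ignition-point and heat-flow-extremum detection from TG-DTG-DSC curves
  has no computable published definition and is out of scope.
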