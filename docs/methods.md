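# Methods

## Model and conventions

The genome is a chain of L binary sites plus one mutator locus.  A
symmetric fitness landscape assigns to every sequence in Hamming class l
(distance from the all-"+" reference) the growth rate f(x_l) (wild-type
mutator locus) or g(x_l) (mutator state), with x_l = 1 − 2l/L; l = 0 is
the reference class and x_0 = 1 exactly.  All rates — the per-genome
mutation rates μ₁ (wild) and μ₂ (mutator) and the switch rates α₁
(wild → mutator) and α₂ (back) — are per-genome; per-site rates are μ/L.
Class transitions carry the combinatorial coefficients: class l receives
probability flux (μ/L)(L−l+1) from class l−1 and (μ/L)(l+1) from class
l+1, and loses μ in total.  The replicator nonlinearity (subtraction of
the instantaneous mean fitness) is removed by the standard exponential
change of variables, so the steady state is the dominant eigenpair of the
linear two-chain operator and the mean fitness R is its Perron root.

Observables of a normalized state: R = Σ f(x_l)P_l + Σ g(x_l)Q_l (for the
eigenvector this equals the eigenvalue identically, because the mutation
and switch fluxes are conservative); the surplus s = E[x] over the whole
population; s₁, s₂ the per-type surpluses (reported absent, not zero,
when a type carries no mass); and the mutator fraction q = Σ Q_l.

## Dominant eigenpairs of a severely non-normal operator

The class operator's eigenvector matrix is exponentially ill-conditioned
in L: its similarity to a symmetric matrix involves the Ehrenfest weights
d_l = √C(L,l), which span e^(0.35·L) orders.  In the original basis,
dense `eigvals`, ARPACK, and residual-guided inverse iteration all return
*pseudo-eigenpairs* — vectors with residuals at machine precision whose
Rayleigh quotients are O(1) away from the true spectrum.  We therefore:

1. compute the eigenvalue in the exactly symmetrized basis.  Both chains
   are symmetrized by the same d_l; for α₁α₂ > 0 an additional
   √(α₂/α₁) scaling of the mutator block makes the full coupled operator
   symmetric pentadiagonal (in interleaved ordering), solved with the
   LAPACK banded selected eigensolver.  For α₂ = 0 the operator is block
   triangular and the spectrum is the union of the two symmetric
   tridiagonal block spectra;
2. recover the eigenvector by inverse iteration on the *original*
   operator at the now-known eigenvalue (shift λ + 10⁻¹² max(1, |λ|)).
   The shifted matrix is an M-matrix, so the solves preserve positivity;
   iterations continue until the residual is below 10⁻¹⁰ max(1, |λ|).
   This resolves components over the full double-precision range (wild
   masses down to 10⁻⁷ and far tails that underflow harmlessly to zero).

The back-transform of the symmetric eigenvector itself is *not* used for
observables: dividing by d_l amplifies endpoint roundoff by hundreds of
orders of magnitude.

Even landscapes (e.g. quadratic) make the operator parity-symmetric with
an exponentially split doublet at the top; the computed eigenvector may
then be an arbitrary mixture of the ±s peaks.  Eigenvalues and parity-even
observables (q, E|x|) are unaffected; the signed surplus of such a state
is not meaningful and tests compare E|x|.

The 2·2^L sequence-space generator (brute-force oracle, L ≤ 12) needs no
weight transform — per-site mutation is already symmetric there — and is
solved with Lanczos per block plus a sparse M-matrix solve for the driven
chain.  Its class aggregation must (and does) match the reduced operator
to 10⁻¹⁰ in R and 10⁻⁹ in the marginals; this is the exactness of the
Hamming-class reduction, not an approximation check.

## Nonlinear dynamics

`integrate_nonlinear` integrates dv/dt = Av − (r·v)v (LSODA, analytic
dense Jacobian, rtol 10⁻¹⁰ / atol 10⁻¹²) and verifies probability
conservation to 10⁻⁹ at every reported time.  Default initial condition:
all mass in the wild reference class (overridable).  Long-time mean
fitness converges to the steady-state eigenvalue; both routes are
provided and tested against each other.

## Analytic phase structure

R_∞ = max over x ∈ [−1,1] of the upper branch V₊(x) of the 2×2 matrix
with diagonal f − μ₁(1−√(1−x²)) − α₁, g − μ₂(1−√(1−x²)) − α₂ and
off-diagonal α₂, α₁ (branch maximization: 2001-point grid plus bounded
refinement; ties toward larger x).  With α₁α₂ ≠ 0 both types share the
surplus s, fixed by demanding that the zero-momentum matrix
[[f(s)−α₁, α₂], [α₁, g(s)−α₂]] have R as its top eigenvalue; its
eigenvector gives q = v₂/(v₁+v₂) (for f = g: f(s) = R and
q = α₁/(α₁+α₂)).  Note s is *not* the maximizer of V₊ — the distribution
peaks where the local growth rate equals R; we verified the distinction
numerically (linear landscape k = μ = 1, L = 2000: eigenvector surplus
0.4142 = R/k, not k/√(k²+μ²) = 0.7071).

Single-peak closed forms: R_mix = J − μ₁ − α₁, R_mu = J − μ₂, R_ns = 0;
the realized phase maximizes them, exact ties return a border label.  In
the mixed phase the wild chain is geometric, P_l = P₀J^(−l), giving the
L → ∞ mutator fraction q = 1 − (J−μ₁−a)(μ₂−μ₁−a)/((J−μ₁)(μ₂−μ₁)).  The
non-selective mean fitness 0 is adopted from the border structure (the
baseline fitness is 0 away from the peak).

## WKB analysis of the wild-allele fate (α₂ = 0, f = g)

In the mixed phase the wild chain has the stationary profile
P_l = e^{L u(x)} with momentum u′(x) = ½ ln y₊(x), where y₊ solves
(1+x)/2·y + (1−x)/(2y) = (R + μ₁ + α₁ − f(x))/μ₁; u peaks at s₁ with
f(s₁) = R + α₁.  The driven mutator chain follows the wild profile on
[s₃, 1] with amplitude a/[(μ₂−μ₁)(f(x)−R) − μ₂a]; where that denominator
vanishes — f(s₃) = R + μ₂a/(μ₂−μ₁), which is also exactly where the wild
momentum coincides with a root of the mutator-chain HJE, so the
derivative matches smoothly — the solution switches onto the homogeneous
mutator branch z₊ (same quadratic with μ₂ and no α₁), which climbs to the
mutator peak s₂ (f(s₂) = R).  The accumulated log-gain

    W = u(s₃) − ∫_{s₂}^{s₃} ½ ln z₊(x) dx  > 0

gives the exponential discriminant K = e^{−L·W} and

    q/(1−q) ≈ (α₁/Δ) √(u″(s₁)/u_Q″(s₂)) e^{L·W},   Δ = R_mix − R_mu.

The exponent is the asymptotically exact part; the prefactor (Laplace
widths, with u″(s) = f′(s)/(2μs)) is accurate to a factor of order one,
which is what the tests assert (log₁₀ agreement within 0.5 against the
exact eigenvector in the mutator-dominated regime, absolute agreement
within 0.05 in the wild-dominated regime).  We validated W itself against
the measured finite-L slope d ln(q/(1−q))/dL of the exact eigenvectors
(9.27×10⁻³ reconstructed vs ≈9.25×10⁻³ measured at k = 1, a = 0.3 after
removing the √L prefactor drift).

Small-a closed form (linear fitness, μ₂ ≫ μ₁): expanding quadratically
around the common peak s* = (√(k²+μ₁²)−μ₁)/k gives
W ≈ a²/(4k s*(μ₂−μ₁)) and the crossover genome length L* = 1/W separating
the small-L regime (q ∝ a, wild-dominated) from the exponential mutator
takeover; the exponent reaching order one marks the transition, which is
the regime-validity condition the package reports.

## Eigen-model variant

Replication and mutation are coupled: per-genome copy fidelity
Q = e^(−γ), mutator fidelity e^(−μγ); the wild chain is damped by e^(−h)
per replication with the complementary flux feeding the mutator chain.
The switch flux uses the wild-type copy-fidelity kernel (the offspring's
genome is copied by the parent's machinery); this choice is pinned by the
cross-model agreement of the mutator fractions under the generation-time
mapping.  Class reduction uses the exact two-binomial convolution kernel
(FFT convolution above L = 256); columns sum to one by the binomial
identity.  Single-peak closed forms: R_mix = A e^(−h−γ), R_mu = A e^(−μγ),
R_ns = 1, with borders μγ = ln A, h = ln A − γ, h = (μ−1)γ.  The
single-peak master-class algebra gives q; its small-parameter limit
q ≈ h/(A−1−γ) drops the mutator-chain term h/(γ(μ−1)) (relative size
~1/(μ−1), as the tests verify).  The mapping γ = τμ₁, h = τα₁,
A = e^{τJ} reproduces the parallel-model results exactly for single-peak
mean fitness (R_eigen = e^{τ R_ck}) and to first order in τ for q.

Random landscapes: 2^L i.i.d. log-normal Wrightian draws (ln r ~
Normal(m, σ²), seeded generator) behave like a single peak of height
A_max = exp(m + σ√(2L ln 2)) — the extreme-value leading order, tested
against a 300-replicate Monte-Carlo band at L = 12 — over a background of
fitness ≈ 1.

## Problem sizes and tolerances

Defaults used by tests and the acceptance script: L = 400 (quadratic
tables), L = 1000 (linear uni-directional columns), L = 5000 (single-peak
consistency), randomized oracle checks at L ≤ 10; all run in seconds.
Eigen-residual targets 10⁻¹⁰ relative, ODE tolerances 10⁻¹⁰/10⁻¹²,
WKB quadratures adaptive to 10⁻¹⁰, border bisections to 10⁻¹²; published
mean-fitness entries are compared at 10⁻³ absolute and
fraction/discriminant entries at one unit in their second significant
digit.

## Known limitations and deviations from the published tables

* Our exact L = 400 eigenvalues for the quadratic landscape lie *below*
  the published numeric row by up to 0.028; the published values agree
  with this operator at L = 100 to ≤8×10⁻⁵ on all seven columns.  We
  report the stated-L computation and flag the discrepancy rather than
  retune L.
* For the linear-fitness column k = 1, a = 0.3 the exact L = 1000
  eigenvector gives 1 − q = 4.4×10⁻⁶ (the published 6×10⁻⁷ matches
  L ≈ 1200), and the corresponding WKB K = 9.5×10⁻⁵ vs the published
  1×10⁻⁵ — our exponent matches the directly measured finite-L slope.
* The single-peak L = 5000 numeric q differs from the L → ∞ closed form
  by 0.38 % (the finite-L error decays as ~1/L and the closed form is the
  confirmed limit), larger than the published "about 0.1 %".
* The WKB prefactor is order-one accurate only; the exponent carries the
  asymptotics.
* Non-goals: finite populations, time-dependent rates, per-site
  heterogeneous mutation, four-letter alphabets.
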