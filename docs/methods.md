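# Methods

## Model

A gene expresses protein through mRNA that occupies one of K discrete
states. The reaction network is

    ∅ → mRNAᵢ            rate λᵢᵐ          (transcription into state i)
    mRNAᵢ → ∅            rate γᵢᵐ mᵢ       (per-state decay)
    mRNAᵢ → mRNAⱼ        rate q_ij mᵢ      (state transitions, i ≠ j)
    mRNAᵢ → mRNAᵢ + P    rate λᵢᵖ mᵢ       (translation)
    P → ∅                rate γᵖ n         (protein decay)

All reactions are first order, so the model is a monomolecular network:
its stationary mRNA marginals are necessarily Poisson, and the interest
lies in the protein distribution, which is *not* Poisson because protein
production is catalysed by a fluctuating mRNA pool.

Rates are accepted in arbitrary consistent time units; nothing is
converted. Validation requires every rate finite and nonnegative, γᵖ
strictly positive, and the decay-plus-transition matrix A − Qᵀ
nonsingular (reciprocal condition number above 1e−12, configurable in
`model.RCOND_THRESHOLD`): a singular system means some occupied state
never reaches degradation and no stationary distribution exists. The
diagonal of the user-supplied transition matrix is ignored and recomputed
from the off-diagonals, so inconsistent generators cannot be constructed.
An all-zero transcription vector is allowed (the stationary law is then
degenerate at zero); downstream summaries flag the degenerate case
instead of erroring so parameter sweeps stay total.

## Stationary solution

Writing the stationary generating function as G = exp(φ) and expanding φ
linearly in the mRNA variables and as a power series in (y − 1) turns the
stationary master equation into the triangular recurrence

    (A − Qᵀ) X₀ = C,
    (A − Qᵀ + n γᵖ I) Xₙ = B Xₙ₋₁,        n ≥ 1,
    aₙ = (1 / n γᵖ) Σᵢ λᵢᵖ (Xₙ₋₁)ᵢ,

solved by dense LU factorisation per order (K is small in every intended
application; no sparse machinery). Because A − Qᵀ has nonnegative
diagonal dominance structure and γᵖ > 0, the shifted systems remain
nonsingular for every n ≥ 1 (eigenvalue shift; asserted as a property
test over randomized models).

**Truncation.** The cumulant series is truncated adaptively: the order is
doubled until |a_N| · max(1, |y−1|)^N < 1e−14 for the largest requested
evaluation point, with a hard cap of 500 and a `converged` flag.
Evaluating the truncated G outside its converged range raises a
`ConvergenceError` carrying the magnitude of the last retained term. The
recurrence is triangular, so growing the order never changes
already-computed coefficients (tested exactly).

## Protein distribution

Factorial moments follow from the cumulants by
h_n = Σ_{i<n} (1 − i/n) a_{n−i} h_i with h₀ = 1, and the pmf by the
standard alternating inversion

    p(n) = Σ_{j≥0} (−1)ʲ C(n+j, n) h_{n+j}.

Numerical care:

- The inversion cancels catastrophically — terms peak near e^⟨P⟩ while
  probabilities can be far smaller — so it runs in mpmath extended
  precision (default 50 digits, automatically scaled up with the mean as
  ~1.5·⟨P⟩ + 40 digits) and is rounded to double at the end.
- Double-precision cumulants are accurate only *relatively*; the binomial
  weights amplify their absolute truncation error. The cumulant
  recurrence is therefore re-run in extended precision for pmf work,
  deep enough that neglected cumulants are invisible at the working
  precision.
- The truncation error of each alternating sum is bounded by its last
  term; if that bound exceeds 1e−12 a `PrecisionError` is raised rather
  than returning a polluted pmf. Negative round-off values above −1e−12
  are clamped to zero and counted.
- `tail_mass_bound` reports max(0, 1 − Σ pmf), the estimated probability
  mass beyond the support truncation. The default support runs to
  mean + 12 standard deviations + 25.

**Applicability limit.** The inversion converges only where the
generating function's expansion about y = 1 has radius of convergence
greater than one — roughly, sub-critical translational bursting. For
strongly bursty parameter sets (e.g. burst size λᵖ/γᵐ ≫ 1) the moment
series diverges and the implementation raises a `PrecisionError` instead
of silently summing a divergent series; means and Fano factors remain
available from the cumulants, which are always finite. The printed form
of the inversion in the source literature starts its sum at j = 1, which
would omit the h_n term itself; the standard j ≥ 0 form is implemented
and validated against the Poisson closed form and the simulator.

## Inactivation loop closed forms

For K = 2 with transcription and translation restricted to the active
state, every coefficient has a closed form in rising factorials:
γ_eff = γ₁ᵐ + q₁₂γ₂ᵐ/(γ₂ᵐ+q₂₁) is the effective decay rate; the
denominator quadratic of the coefficient recursion has real negated
roots r₁ ≥ r₂ (its discriminant is a square plus a nonnegative term);
τ = (γ₂ᵐ+q₂₁)/γᵖ. The cumulant a_n is computed through the recurrence
form a_n = λᵖ b_{n−1}^(1)/(nγᵖ) rather than the τ-normalised rising-
factorial display, which is ill-defined at τ = 0 (q₂₁ = γ₂ᵐ = 0 with no
inactivation).

The full generating function involves ₂F₂ hypergeometric factors and the
integral of one of them, done by adaptive Gauss–Kronrod quadrature at
absolute tolerance 1e−12 (the integrand is smooth on the segment). ₂F₂
itself is summed by term-ratio recurrence to relative tolerance 1e−14;
for negative arguments the partial sums cancel, and when the largest
term exceeds 10⁴ times the result the series is re-summed in extended
precision with the digit count set by the observed cancellation. The
implementation is cross-checked in the tests against an independent
library evaluation and a brute-force extended-precision partial sum.

**Noise comparison.** The baseline model replaces the loop by a single
mRNA species decaying at γ_eff, which matches both species means; then

    CV² = 1/⟨P⟩ + (1/⟨M⟩) γᵖ / (γᵖ + γ₁ᵐ + q₁₂(γᵖ+γ₂ᵐ)/(γᵖ+γ₂ᵐ+q₂₁)),
    CV₀² = 1/⟨P⟩ + (1/⟨M⟩) γᵖ / (γᵖ + γ₁ᵐ + q₁₂γ₂ᵐ/(γ₂ᵐ+q₂₁)),

and CV² < CV₀² strictly for positive rates. The reduction map fixes
⟨M⟩ = 10, ⟨P⟩ = 500, γ₁ᵐ = 1, q₁₂ = 3 and sweeps q₂₁ and γᵖ over a
100×100 log grid on [1e−2, 1e2] (the axis ranges are a package choice;
the optima are insensitive to widening them), followed by coordinate-wise
golden-section refinement within the cells adjacent to the grid minimum.
"Reduction" is reported as 100·(1 − CV²/CV₀²) percent. With a degradable
inactive mRNA (γ₂ᵐ = 1) the optimum is interior, ≈16%, at activation and
protein decay faster than mRNA decay; with a protected inactive mRNA
(γ₂ᵐ = 0) the ratio decreases monotonically as activation slows and
reaches ≈64% at the small-q₂₁ grid edge.

## Multiphasic lifetime

K sequential stages at rate Kγ_eff each give an Erlang(K, Kγ_eff)
lifetime: mean 1/γ_eff, variance 1/(Kγ_eff²). (A published description
of this model states the variance as 1/γ_eff²; that holds only at K = 1,
and the Erlang form is used here.) Closed forms: stage means
λᵐ/(Kγ_eff); first-order coefficients from the affine recursion
b₁⁽ⁱ⁾ = u + v·b₁⁽ⁱ⁻¹⁾ with u = λᵖλᵐ/(Kγ_eff(Kγ_eff+γᵖ)) and
v = Kγ_eff/(Kγ_eff+γᵖ) ∈ (0,1); cumulants a₁ = λᵖλᵐ/(γᵖγ_eff) and
a₂ = λᵖu(K + v(−1−K+vᴷ))/(2γᵖ(1−v)²); and the Fano display

    F_m = 1 + (λᵖ/γᵖ)(1 + (γ_eff/γᵖ)(−1 + (Kγ_eff/(Kγ_eff+γᵖ))ᴷ)).

vᴷ is evaluated in log space so large K degrades gracefully to the
deterministic-lifetime limit e^{−γᵖ/γ_eff}. Higher cumulants (n ≥ 3)
are available only through the generic solver; the closed forms stop at
the second moment by design. F_m is nonincreasing in K: narrowing the
lifetime distribution can only reduce protein noise.

## Stochastic simulation oracle

The simulator implements the exact direct method (not tau-leaping:
oracle status demands exactness, and desk-scale models are cheap):
propensities are recomputed after every event, the waiting time is
exponential in their total, and the reaction is chosen by linear scan.
Randomness comes from numpy's PCG64 generator; replicate streams are
spawned from a single `SeedSequence`, so a config seed reproduces every
event bit for bit across runs.

Estimation protocol (all defaults overridable):

- burn-in = 10 relaxation times, the relaxation time being the slower of
  protein decay and effective mRNA decay (total transcription divided by
  total stationary mRNA mean);
- within-replicate *time averages* over [burn-in, t_end] for first and
  second moments and for the protein dwell-time histogram, avoiding the
  autocorrelation bias of sampled snapshots;
- standard errors from the spread across replicates, never from within a
  trajectory;
- an effective sample size, replicates × span × γᵖ (protein relaxation
  times accumulated), with a warning flag below 10.

A model with no production halts in its absorbing empty state; the
trajectory is returned flagged rather than raising.

Test and acceptance runs use desk-scale protocols — order 10² replicates
of order 10² time units per model — which the package treats as its
standard verification size: ample for 3-standard-error agreement checks
on means, Fano factors and total-variation distance to the analytic pmf.

## Stem-loop data reanalysis

The bundled table carries, per 5'UTR construct and reporter (yEGFP,
ymNeonGreen), the protein mean (fluorescence-derived molecule units) and
the CV in percent with its standard deviation. Processing: CV is
converted to a fraction before squaring; F = ⟨P⟩·CV²; SDs propagate to
first order as SD_CV² = 2·CV·SD_CV and SD_F = ⟨P⟩·SD_CV². Undetermined
cells are excluded from fits, never imputed. The Fano factors are fitted
against the mean by ordinary least squares with a free intercept (the
standard reading of "simple linear regression"; an intercept-fixed-at-1
variant is also reported since the two-stage model predicts intercept 1),
and the same coefficients induce the hyperbolic CV² = F(⟨P⟩)/⟨P⟩ curve.

Data caveat: one cell (U5 construct, yEGFP) was corrupted in the
upstream source text. The shipped reconstruction (mean 261, CV 12.4%)
is the only reading consistent with F ≥ 1 and the noise-mean trend of
the neighbouring constructs; under it the ymNeonGreen slope reproduces
the originally reported 0.0141 exactly, while the yEGFP slope computes
to 0.0127 against an originally reported 0.0124 (excluding the suspect
row gives 0.0124, suggesting the original cell differed). The package
reports what it computes.

## What the synthetic conditions do and do not show

Verification rests on three mutually independent routes: closed forms,
the generic power-series solver, and exact simulation. Agreement across
them validates the mathematics and the implementation under the model's
assumptions — well-mixed kinetics, first-order reactions, constant
rates. It does not probe extrinsic noise, cell division and partitioning,
transcriptional (promoter) bursting upstream of the mRNA states, or
feedback, all of which are outside the model class. The data reanalysis
inherits the usual caveats of fluorescence-derived molecule counts:
slopes are in reporter-specific units and are not absolute rate
estimates.

## Known limitations

- pmf recovery requires sub-critical bursting (see above); otherwise
  only moments are available.
- The structural-solvability check is a conditioning test; models within
  1e−12 of singular are rejected even if formally invertible.
- The SSA is pure Python and intended for desk-scale verification, not
  large parameter sweeps.
- The noise-reduction map explores a fixed-mean slice of parameter
  space; optima quoted in percent refer to that slice.
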