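# Methods

## Model

Let S₁,…,Sₙ be species richness observed at areas A₁,…,Aₙ (any consistent
unit; replicated areas allowed; Sᵢ ≥ 1 since the transformation requires
positivity). The response is Box-Cox transformed, Zᵢ = ψ(Sᵢ; λ) =
(Sᵢ^λ − 1)/λ for λ ≠ 0 and ln Sᵢ for λ = 0, and Z is assumed to follow an
exponential-family law with density exp{[zθ − b(θ)]/φ + c(z, φ)}, common
dispersion φ, and variance Var(Z) = φ·V(μ). Three families are supported:
normal (V = 1), gamma (V = μ²) and inverse Gaussian (V = μ³); the latter
two require μ > 0 and z > 0 and accommodate variance growing with the
mean, which richness data typically show. The systematic component is
g(μᵢ) = xᵢᵀβ where xᵢ collects an optional intercept and powers of ln Aᵢ,
Aᵢ and Aᵢ⁻¹ with positive real exponents; available links are identity,
reciprocal (1/μ), inverse-squared (1/μ²) and log. The design matrix must
have full column rank, checked by a relative singular-value threshold of
1e−10 with the dependent columns named in the error.

Assumptions worth stating plainly: observations are treated as
independent, although nested quadrats are cumulative and therefore
positively dependent — the framework is a curve-fitting likelihood, not a
spatial sampling model; the dispersion is common to all areas; and the
transformed response is modelled as continuous even though richness is a
count.

### The λ = 1 convention

λ = 1 is implemented as the genuine Box-Cox member z = s − 1, not the
identity. The two conventions give identical slope estimates and an
intercept differing by exactly 1; the shifted form is the default (it makes
the λ-profile continuous and reproduces the reference coefficients for the
insect dataset), and `shift=False` exposes the identity convention.

## Estimation

For fixed λ, β is estimated by iteratively reweighted least squares with
weights wᵢ = [g′(μᵢ)]⁻²/V(μᵢ) and working response y*ᵢ = ηᵢ + (zᵢ − μᵢ)
g′(μᵢ); the update β ← (XᵀWX)⁻¹XᵀWy* is solved as a weighted least-squares
problem (lstsq, never an explicit normal-equation inverse). Initialisation
is μ⁰ = z, floored at 1e−6 for positive-support families and for links that
need a positive mean. Convergence: relative deviance change ≤ 1e−10 or 100
iterations; updates whose means leave the family support are step-halved
back toward the previous iterate (at most 20 halvings). For the
normal/identity case the first iteration is exactly ordinary least squares.
Non-convergence is flagged on the results object and warned, never silently
accepted.

Dispersion: `scale` is the Pearson estimate Σ[(zᵢ−μ̂ᵢ)²/V(μ̂ᵢ)]/(n−p),
used for standard errors and original-scale prediction; `scale_mle` is the
family MLE — RSS/n (normal), the root of the digamma equation
n[ln ν + 1 − ψ(ν)] + Σ[ln(zᵢ/μ̂ᵢ) − zᵢ/μ̂ᵢ] = 0 with ν = 1/φ (gamma,
solved by Brent on log ν), and Σ[(zᵢ−μ̂ᵢ)²/(μ̂ᵢ²zᵢ)]/n (inverse Gaussian,
closed form). The MLE enters the log-likelihood so that the λ profile and
the information criteria are genuine profile quantities.

The total log-likelihood adds the transformation Jacobian,
ℓ = Σ log f(zᵢ; μ̂ᵢ, φ̂) + (λ − 1)Σ ln sᵢ, making values at different λ
comparable on the same untransformed data. The profile ℓ_p(λ) is evaluated
on a grid (default −2 to 2 in steps of 0.05); the maximizer is refined by
bounded scalar minimisation between its two grid neighbours (tolerance
1e−6), and the 95% confidence interval inverts the likelihood-ratio test —
endpoints solve 2[ℓ_p(λ̂) − ℓ_p(λ)] = χ²₁(0.95), located by Brent's method
between bracketing grid points; if the profile never drops below the
threshold inside the grid, the grid end is returned. Isolated grid
failures become gaps with a warning; only a fully failing grid is fatal.

Coefficient covariance is φ̂·(XᵀWX)⁻¹ at convergence. Wald intervals use
Student-t quantiles on n − p degrees of freedom for the normal/identity
case, where classical linear-model theory is exact, and standard normal
quantiles otherwise. AIC = −2ℓ + 2k and BIC = −2ℓ + k ln n count
k = p + 1 (coefficients plus dispersion), plus one more when λ was
profiled; the extra unit is a documented choice (`k_params`) — λ is an
estimated parameter like any other.

## Prediction on the species scale

The naive inverse (λμ̂+1)^{1/λ} estimates a median-like quantity, not the
mean. E[S] is approximated by the second-order Taylor expansion of the
inverse map h about μ̂: E[S] ≈ h(μ̂) + ½h″(μ̂)·φV(μ̂), i.e.

- λ ≠ 0: Ŝ = (λμ̂+1)^{1/λ}·[1 + φ̂V(μ̂)(1−λ)/(2(λμ̂+1)²)]
- λ = 0: Ŝ = e^{μ̂}·(1 + φ̂V(μ̂)/2)

The correction vanishes identically at λ = 1. The expansion is validated
against a 10⁶-draw Monte-Carlo estimate of E[S] rather than a printed
formula; its error is fourth-order in √φ, so it degrades when φV(μ̂) is
large relative to (λμ̂+1)² — exactly the regime where the back-transform
domain constraint λμ̂+1 > 0 also starts to bind (a domain error is raised
at the offending areas).

Model comparison fits every candidate, ranks converged fits by AIC (ties:
BIC, then fewer coefficients), and reports MSE = Σ(sᵢ−ŝᵢ)²/n, the
variance-normalised MSE/var(S), and MAPE = (100/n)Σ|sᵢ−ŝᵢ|/sᵢ on the
original scale. Plain MSE is reported for ranking purposes; AIC decides
the ranking. A candidate whose fitted means leave the image of the inverse
transform keeps its likelihood criteria with the error summaries set to
NaN and the domain error recorded.

## Classical catalogue

Eleven named forms ship with their transformed-GLM equivalents: the power
law (λ = 0; 1 + ln A), persistence curves c·A^z·e^{kA} and c·A^z·e^{k/A}
with their "full" quadratic-exponent extensions (adding A² resp. A⁻²
terms), quadratic and cubic polynomial power-functions in ln A (λ = 0),
the linear and logarithmic curves (λ = 1), the quadratic-logarithmic curve
(b₀ + b₁ln A)² (λ = 1, expanded predictor 1 + ln A + (ln A)², which frees
the square's coefficient constraint), and the general power-logarithmic
curve (b₀ + b₁ln A)^z. The last cannot be linearised for non-integer z and
is represented through the truncated generalized-binomial expansion
(b₀ + b₁ln A)^z = Σₖ C(z,k) b₀^{z−k} (b₁ln A)^k, truncated at k = 3 by
default — consistent with keeping fitted models at no more than six
parameters — with a warning when the first omitted term exceeds a
tolerance at the largest |ln A| of interest. The full-scale builder
accepts any term combination; no particular six-term set is hard-coded.

## Synthetic data

Two generators, both fully seeded (`numpy.random.default_rng`; no global
state).

**Neutral lattice.** Metacommunity relative abundances are a symmetric
Dirichlet(θ) draw (default θ = 0.5, 80 species — a strongly uneven pool
with a long rare tail); each cell of an L×L lattice (default L = 200)
receives an independent draw from the pool, which is the
zero-dispersal-limitation limit of neutral community assembly; nested
square quadrats anchored at a corner (anchor averaging over the four
corners is an option) are counted for distinct species, giving (q²,
richness) pairs. Independence of cells admits the closed-form expectation
E[S(a)] = Σᵢ[1 − (1 − pᵢ)^a], which the test suite checks to Monte-Carlo
accuracy. What this generator does **not** emulate: conspecific
aggregation, dispersal limitation and spatial autocorrelation, which make
real SARs steeper at small areas; passing tests show the pipeline recovers
curves of the concave neutral shape, not that any single SAR form is true
in nature.

**Direct model sampler.** Given terms, family, link, β, λ and φ, draws z
from the family at μ = g⁻¹(Xβ), back-transforms, and rounds to the nearest
positive integer (richness is a count; the rounding is a deliberate,
documented deviation from the continuous model, negligible for the
richness scales used). Draws outside the image of the transformation, or
rounding below 1, are rejected and redrawn (1000 attempts per observation,
then an error naming the incompatibility). This sampler drives the
parameter-recovery, interval-coverage and test-size experiments.

## Experiment sizes

The calibration experiments use problem sizes chosen to make Monte-Carlo
error small relative to the bands being checked: 500 refits at n = 100 for
interval coverage, 1000 replicates at n = 200 for the size of the LR test
of λ, 10⁶ draws for the back-transform oracle, and 1000 lattices of side
32 against the closed-form expectation (the lattice default of L = 200 is
unnecessary there, since the expectation conditions only on the pool and
quadrat areas).

## Known limitations

- Cumulative nested-plot data violate the independence assumption; the
  likelihood is a working approximation, as in all classical SAR fitting.
- The λ profile assumes the grid brackets the maximizer; data preferring
  λ outside [−2, 2] return an endpoint interval (widen the grid).
- Gamma and inverse-Gaussian fits require the transformed response to be
  positive, which restricts usable λ for data containing S = 1 (ψ(1;λ)=0).
- Standard errors for gamma/inverse-Gaussian are asymptotic; no
  small-sample correction is attempted.
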