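# Methods

## Model abstraction

A model is (f, h, x0): state derivatives ẋ = f(x, θ, u(t), t), observation
y = h(x, θ), initial state x(t₀) = x0(θ, experiment).  An *experiment* is a
triple (initial conditions, input, sampling grid); all packaged benchmarks
are autonomous (u ≡ 0).  Simulation uses LSODA (stiff-capable, adaptive) at
rtol 10⁻⁸ / atol 10⁻¹⁰ by default; models with known analytic solutions
(bi-exponential, diagonal LTI, linear predictors) bypass integration
entirely, in vectorised form over whole sample batches.  The default
tolerances are deliberately tight: unidentifiability detection compares
γ values against a zero band of 10⁻⁸ relative, which must sit well above
integration error.

For models without closed forms, `simulate_batch` stacks ~2000 parameter
sets into a single RK45 system whose error norm spans every sample.  This
shares step-size control across the batch (accurate, but the step follows
the worst-behaved sample; chunking bounds the coupling) and is 5–50× faster
per sample than separate solves — the difference between a feasible and an
infeasible high-dimensional scan on one CPU.  A runaway state
(|x| > 10¹², or non-finite) freezes its sample and flags it as failed
instead of grinding the step-size control toward a singularity.

## Classical (eigenvalue) sloppiness

For the self-referenced least-squares cost C(θ) = Σ_t ‖y(θ\*,t) − y(θ,t)‖²
the Hessian at θ\* reduces to the Gauss–Newton form H = 2 JᵀJ, with
J = ∂y/∂θ from central finite differences (per-parameter step
10⁻⁶·max(|θᵢ|, 1)); the residual term of the exact Hessian vanishes at the
reference point.  A direct finite-difference Hessian of C is provided as a
cross-check; the two agree at θ\* to ~10⁻⁴ relative.  Log-scale Hessians
apply the chain rule ∂/∂log θᵢ = θᵢ ∂/∂θᵢ by differencing in log
coordinates — the right parameterisation when parameters span decades.
S = λ_min/λ_max with the conventional sloppy cutoff 10⁻⁶ (a config
constant, used nowhere else).  Costs are *discrete* sums over the sampling
grid throughout; continuous-time integral formulations are treated as the
same quantity up to the grid quadrature, and all oracles in the test suite
use matching discrete sums.

For a linear predictor y = Xθ everything is closed-form: H = 2XᵀX, the
squared prediction deviation of a parameter deviation δ is ε = ‖Xδ‖², and
standard errors follow the diagonal-inversion convention
σᵢ = 1/√(Σ_obs xᵢ²) — exact for orthogonal designs, an approximation
otherwise (both behaviours are exposed and tested).  The norm-bound check
reads the (ε, δ) pair against the design's singular spectrum: a deviation
of length δ can keep the output within ε iff (σ_min δ)² ≤ ε, so a singular
design reaches ε = 0 at δ > 0 — loss of identifiability.  The package does
not attempt a closed-form σ(ε, δ) relation; it inverts ε(δ) numerically,
which is what the one-parameter consistency test checks.

## Shell scanning

Given θ\*, radius δ and l shells, the scanner works per *annulus*
(δ_{k−1}, δ_k], not per nested ball: samples are drawn directly in the
annulus, so per-shell statistics describe behaviour *at* distance ≈ δ_k.
This is what makes γ_min rise with radius for identifiable models and makes
an unidentifiability radius well-defined; nested balls would make γ_min
non-increasing by construction and hide the dip.

**Sampling.**  Directions are normalised independent Gaussians (exactly
uniform on the sphere in any dimension); radii follow the n-volume law
r = (lo^n + u·(hi^n − lo^n))^{1/n}, giving uniform density in the annulus.
A plain Gaussian with σ = δ_k would concentrate mass and under-sample the
boundary in high dimension.  All random draws for one sample occupy one
contiguous generator row, so enlarging the sample size extends rather than
reshuffles the draw (doubling N provably never raises γ_min — a tested
invariant), and each shell gets its own child seed (seed, k).

**Sample growth.**  N(k+1) = N(k) + ⌈α (δ_{k+1}/δ_k)^n⌉.  Note the factor
(δ₂/δ₁)^n = 2^n makes the rule explosive in high dimension (2⁸ = 256·α
extra samples at the second shell alone); the high-dimensional benchmark
scans in the test suite therefore run with α = 0 (constant per-shell N)
at the problem sizes listed below.

**γ statistics.**  γ = Σ_t Σ_outputs (y\* − y)², min/max per shell with the
attaining parameter vectors; ψ = 1 − γ_min/γ_max (defined 0 when
γ_max = 0).  Failed simulations are excluded and counted, with a warning
above 1% per shell.

**Refinement.**  The sampled per-shell minimum is a biased-high Monte-Carlo
estimate whose error scales like the squared nearest-sample distance; near
an unidentifiability point that error straddles the zero band and makes
detection seed-dependent.  By default each shell's minimum (beyond the
innermost) is therefore polished by a deterministic constrained local
minimisation (SLSQP, annulus constraint, started at the sampled argmin):
truly unidentifiable shells collapse to ~10⁻¹⁶ relative while identifiable
shells settle at their true positive annulus minima.  Detection then does
not depend on the seed.  Maxima are left as sampled; their Monte-Carlo
error is benign (tested at 5% against dense deterministic annulus search).

**Verdicts.**  "Numerically zero" means γ_min ≤ zero_tol · global γ_max,
zero_tol = 10⁻⁸ by default.  The *innermost* shell is excluded from
unidentifiability detection: its annulus touches θ\*, where γ vanishes by
continuity regardless of identifiability, so a dip there carries no
information.  The unidentifiability radius is reported as the centre of the
first dipping shell.  (ε, δ)-sloppiness: the region is identifiable yet
γ_min at the shell containing δ is below ε; the default ε is 10⁻³ of the
outermost γ_max (ε has squared-output units, so no universal constant is
meaningful), and a user-chosen pair must satisfy δ/ε ≥ 10.  Values of
γ_min inside the zero band are beyond the resolution of any minimiser —
cost differences there fall below machine epsilon of γ — and are treated
as exactly zero wherever compared.

**Profiles and ranking.**  Retained samples are binned per parameter by
|θᵢ − θ\*ᵢ| (log-coordinates under a log scan); per bin the min and max γ
are reported, empty bins stay missing.  A parameter is ranked *insensitive*
when its γ_min profile stays below 1% of the global γ_max across the
scanned range (large moves of that coordinate always admit near-invisible
compensations) and *sensitive* otherwise, ordered by how steeply the γ_max
envelope rises over the first half of the deviation range.  These
thresholds are heuristics for a visual judgement; on models whose output is
phase-dominated (sustained oscillators) the γ_min profile rises for every
parameter at moderate radii and the insensitive class can be empty — see
limitations.

**Scales.**  scale="log" samples, measures distances, refines and bins in
log-parameter space (natural log) and exponentiates before simulation;
verdicts state the scale used.  The CLI turns log scale on automatically
when parameters span more than two decades and says so.

## Problem sizes

The two-parameter scans run the full prescription (l = 30 shells,
N₀ = 20000, α = 1000, ≈1.3 million closed-form evaluations, a few seconds).
The high-dimensional ODE benchmarks run at the package's chosen desk
scales: mitotic oscillator l = 6, N₀ = 6000, α = 0, δ = 0.3 (log),
t = 0–100 min at 1 min sampling, rtol 10⁻⁶; HIV l = 8, N₀ = 12000, α = 0,
δ = 0.5 (log), t = 0–1200 days at 10-day sampling, output = free virus.
These sizes resolve the per-shell extrema and direction structure; binned
γ_min profiles in 8–10 dimensions remain the noisiest statistic at this
density.

## What the benchmarks do and do not show

The two-parameter families exercise every verdict path against exact
oracles (swap symmetry, closed-form γ, analytic sensitivities), so passing
tests there verify the machinery itself.  The mitotic-oscillator and HIV
fixtures carry nominal parameters from their original literature sources;
they demonstrate the workflow on realistic stiff nonlinear models —
identifiability, anisotropy (ψ ≈ 1), stable maximum-deviation directions —
but their parameter-sensitivity *rankings* are properties of the fixture
values, the experiment and the ranking heuristic, not of the method, and
published rankings for these systems disagree between methods (and, for
the oscillator, between sources).  The test suite asserts the robust
qualitative properties and keeps the literature ranking comparisons as
separate, clearly failing tests rather than silently loosening them.

## Known limitations

- The scan is local by construction: it characterises one ball around one
  reference point, not all sloppy pockets of a nonlinear parameter space.
- Uniform-in-ball sampling thins exponentially with dimension; binned
  per-parameter γ_min profiles need far more samples than per-shell extrema
  and are the first statistic to degrade above ~8 parameters.
- Refinement is a local search: it polishes the basin the best sample
  found, and can miss a deeper disconnected basin exactly when sampling
  missed it too.
- γ is an unweighted sum of squares; outputs of very different magnitudes
  should be rescaled (or log-transformed) by the user before scanning.
- Batched integration couples step-size control across samples; per-sample
  accuracy is maintained by the shared error norm, at the cost of speed
  whenever one sample in a chunk is near-stiff.
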