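# Methods

## Model and assumptions

The trait is perfectly heritable (no environmental variance) and additive:
no dominance, no epistasis, no pleiotropy. The *n* loci are diallelic and
unlinked, and the population mates randomly, so the population state is
fully described by the vector of "+"-allele frequencies; linkage
equilibrium is exact for this model, not an approximation. Effect sizes are
fixed at construction (mutation toggles alleles, it does not create new
effect sizes). Selection is Gaussian stabilizing, w(z) = exp(−(s/2)(z −
z_opt)²), assumed weak on the trait scale: 1/s should be large compared to
the phenotypic variance. `SelectionRegime.check_weak_selection` warns (not
errors) when s·c₂ > 0.1, and regime validation warns when the optimum is
placed outside (0, nγ̄), where the mean cannot settle near it.

Two printed forms of the source formulas are typographically ambiguous and
are implemented in the only dimensionally consistent reading: the fitness
exponent as −(s/2)(z−z₀)² and the minor/major threshold as γ̂ = 2√(2μ/s)
(the stability condition below which the interior equilibrium p = 1/2 of an
isolated locus is stable; the per-locus cubic has interior boundary roots
only when γ² > 8μ/s).

## Parameters

| symbol | meaning | unit | reference default |
|---|---|---|---|
| n | number of loci | — | 200 |
| γ̄ | mean of exponential effect-size distribution | trait units | 0.01 |
| μ | symmetric per-locus mutation rate | 1/generation | 10⁻⁵ |
| s | stabilizing-selection strength | 1/(trait units)² | 0.1 |
| z₀, z_f | optimum before/after the shift | trait units | 0.2, 0.4 |
| N | diploid population size | individuals | 2×10⁴ |

The defaults are the human-polygenic-adaptation scale used throughout the
validation experiments (α = 2Ns = 4000, β = 2Nμ = 0.4, γ̂ = 2.83 γ̄). They
are the conditions all acceptance-level checks run under unless a check
explicitly needs a different regime (below).

## Wright–Fisher simulator

Per generation and locus: the deterministic selection + mutation update is
applied to the current frequency (with Δc₁ evaluated from the live
frequency vector and the current optimum — the frozen-Δc̃₁ form of the
expected change is used only in the diffusion formulas, where it is an
explicit assumption), the result is clipped to [0,1], and the next
generation is drawn as Binomial(2N, p*)/2N independently per locus.
Selection/mutation precede drift; the opposite order differs at O(1/N).
The simulator is frequency-based, not individual-based — exact for this
model and orders of magnitude faster.

Replicates are a batched (R × n) array advanced by one numpy Generator;
all experiment drivers derive their generator deterministically from the
master seed via `SeedSequence`, so identical (seed, parameters) reproduce
every output bit-for-bit (tested).

**Burn-in** defaults to 3N generations with the optimum held at z₀, with a
stationarity diagnostic (relative difference of mean c₂ between run
halves). Equilibrium studies initialise frequencies from the *neutral*
mutation–drift marginal Beta(2β, 2β): the per-locus mixing time,
~1/(4μ + 1/(2N)) ≈ 1.5×10⁴ generations at the reference parameters, is
comparable to 3N, and an all-½ start leaves a visible interior bias after
3N generations. The beta start is γ-independent — the selection content of
the stationary density (the exp(−2αγΔc̃₁p − αγ²pq) factor) is not
pre-loaded and must emerge from the dynamics. Optimum-shift experiments
start from the all-½ (or deterministic-equilibrium) state instead, since
their point is the transient.

## Measurement protocols

**Quasi-equilibrium deviation Δc̃₁.** Time average of c₁ − z₀ over a
post-burn-in sampling phase (default 24 000–30 000 generations, thinned
every 10), pooled over replicates. The instantaneous deviation is an
Ornstein–Uhlenbeck-like fluctuation with sd ≈ √(1/(2Ns)) ≈ 0.016 and
correlation time ≈ 1/(s c₂) ≈ 800 generations — an order of magnitude
larger than the systematic part (≈ −0.002), which is why long averages and
tens of replicates are needed, and why the acceptance check pools three
master seeds.

**Bottleneck experiment.** Burn-in at N_base (3N_base generations);
baseline = time + ensemble average over the last 2000 generations of
burn-in; then `bottleneck_gens` generations at N_bottleneck. The genetic
variance at the end is the ensemble average at the final bottleneck
generation (c₂ sums over 200 loci, so its ensemble noise is already small);
the cumulants feeding the deviation estimator are instead averaged over the
last 1000 generations, because c̃₃'s per-locus fluctuations need the extra
averaging (the window biases the still-decaying quantities upward by a few
percent, inside the reported tolerances). The *systematic* deviation is
estimated through the
quasi-equilibrium relation Δc̃₁ = −((s/2)c̃₃ + 2μz₀)/(s c̃₂ + 2μ) evaluated
with the simulated window-averaged cumulants. Rationale: during the
bottleneck the fluctuation sd grows to √(1/(2N_bn s)) ≈ 0.04, so directly
averaging the −0.002-scale signal out of it would need ~10⁵ effective
samples (tens of thousands of replicates); the cumulant route estimates the
same quantity with usable signal-to-noise because c̃₂ and c̃₃ are sums over
200 loci. The raw averaged deviation is reported alongside for
transparency. The report also carries the drift-only moment-ODE companion
c₂(t) = c₂(0)·e^{−t/2N} and the quasi-equilibrium deviation it implies.

At the reference bottleneck (2×10⁴ → 3000 for 5000 generations) this
protocol yields a variance drop of ≈ 39–44% and a deviation increase of
≈ +130–150%. The deviation increase is structural: once c₂ falls ~40%, the
quasi-equilibrium denominator s·c₂ + 2μ shrinks by a factor ≈ 1.7, and the
simulated skew decay pushes the ratio higher still. Reported survey values
near +41% for this setting are not reproduced by any estimator we examined
(systematic, raw, or fluctuation-magnitude E|Δc₁|, which scales as
√(N_base/N_bn) = 2.58); the corresponding acceptance check is left failing
rather than redefining the estimator around it.

**Density comparison (total variation).** The reference study pins one
focal effect size (γ = 0.0107) exactly into the sampled architecture and
histograms its frequency over replicates × time (20 equal bins). A single
locus decorrelates only on the ~1.5×10⁴-generation mixing time, so the
focal-only histogram carries TV sampling noise ≈ 0.1 at desk scale. The TV
statistic therefore pools loci within a ±25% effect-size window around the
focal value (≈ 25–40 loci) and compares against the exact *mixture* of
their per-locus stationary densities — the same theory, like-for-like,
with ~25× the effective sample size (pooled TV ≈ 0.01–0.03, of which
~0.02 is residual sampling noise). Focal-only histogram and density are
still computed and written. The theory density uses the measured Δc̃₁ by
default; a fully simulation-free self-consistent mode (`self_consistent_
deviation`, iterating the quasi-equilibrium relation against the density
moments, or solving the mean-balance condition) is also provided — at the
reference parameters it gives Δc̃₁ = −0.0020, against −0.0022 to −0.0027
measured.

**U vs bell shape.** The stationary density is U-shaped iff β < 1/2, a
mutation–drift property independent of N and μ separately. The bell-shape
check therefore runs at N = 2000, μ = 1.5×10⁻⁴ (β = 0.6) instead of
raising N above 2.5×10⁴, which would multiply the burn-in cost ~25-fold for
the identical mechanism (αγ² stays ≪ 1 in both settings, so the exponential
factor does not affect the shape).

## Diffusion numerics

Expectations under f(p) ∝ (pq)^{2β−1}·g(p) are computed by Gauss–Jacobi
quadrature (default 160 nodes) with the (pq)^{2β−1} endpoint behaviour
absorbed into the weight, so the integrable boundary singularities at
β < 1/2 cost nothing; the normalization is the reciprocal of the quadrature
integral and is verified against adaptive quadrature to 10⁻⁶. Bin
probabilities use adaptive quadrature, with scipy's algebraic endpoint
weighting for the two outer bins. The closed-form normalization
approximation is exposed separately and raises outside its validity range
(bracket ≤ 0). ODE integration uses RK45 with rtol 10⁻⁸ (atol 10⁻¹²),
split at optimum-shift discontinuities, round-off-scale overshoots of
[0,1] clipped (> 10⁻⁹ raises); trajectories are cross-validated against a
fixed-step Euler oracle in the tests. Decay rates are fitted as a
three-parameter exponential A·e^{−rt} + B (the deviation decays to the
quasi-equilibrium level, not to zero), seeded by a log-linear fit.

**Moment closure.** The adaptive-phase moment ODEs involve E{p²q}, which
is not closed. Default closure: a beta-distribution ansatz matched to the
current mean and variance, whose third moment is exact for beta marginals
and degrades gracefully (point-mass and two-point limits at the variance
bounds). Validated against Wright–Fisher ensembles; the neutral limit
reproduces the exact E{pq} decay at rate 1/2N.

## Regime exemplars and "all-minor" runs

The closed-form small-effects results (approach rate s·n·γ̄², equilibrium
variance n·γ̄²) presume a fully minor exponential architecture at
intermediate frequencies, where c₂(0) = Σγᵢ²/2 ≈ n·γ̄². At the reference
μ = 10⁻⁵ an exponential sample is only ~94% minor, and dropping the major
loci leaves c₂(0) ≈ 0.57·n·γ̄² — the formulas would fail for reasons that
have nothing to do with the dynamics. All-minor checks therefore raise the
mutation rate to 1.25×10⁻⁴, putting γ̂ at 10γ̄ (a 200-locus sample is
all-minor with probability 1 − 200e⁻¹⁰). The deterministic
equilibrium-variance check additionally uses n = 5000, because the check
compares against the *distribution* value n·γ̄² while a finite sample has
Σγᵢ²/2 fluctuating with relative sd √(20/n)/2 (≈ 16% at n = 200, ≈ 3% at
n = 5000); three seeds are averaged.

## Problem sizes

Acceptance-level runs: equilibrium studies with 24–32 replicates ×
(6×10⁴ burn-in + 2.4–2.5×10⁴ sampling) generations × 200 loci, three
master seeds; bottleneck with 64–96 replicates × 6.5×10⁴ generations.
These sizes put the Monte-Carlo standard errors comfortably inside each
stated tolerance (e.g. SE(Δc̃₁) ≈ 5×10⁻⁴ pooled vs a ±1.5×10⁻³ band) while
a full study runs in minutes on one CPU; the down-scaled examples use
N = 1000–2000 with proportionally raised μ so every script finishes in
seconds.

## A note on the equilibrium-variance approximation

The simulator and the stationary-density quadrature agree on the
stationary genetic variance to < 0.1% (c₂ ≈ 0.0102 at the reference
parameters, via two independent routes). The closed-form
(4β/(4β+1))·n·γ̄² = 0.0123 sits ≈ 17% above both, because it neglects the
exp(−αγ²pq) heterozygosity suppression, which is not small here
(E[αγ²] = 2αγ̄² = 0.8, and c₂ weights the large-γ loci that are suppressed
most). The formula is treated as the useful approximation it is; the
15%-agreement check against it currently fails by a fraction of a point
and is left as is rather than moving the measurement window.

## Known limitations

No linkage (hence no hitchhiking or sweep footprints on neutral
variation), no pleiotropy, no dominance/epistasis, no population structure
or migration, no environmental variance, effect sizes fixed through time.
The synthetic generator emulates the model's own assumptions — it does not
emulate real-data features such as LD between trait loci, allele-frequency
ascertainment of GWAS panels, or effect-size/frequency correlations from
past selection, so passing tests validate the theory under the model, not
those aspects of real data. Slow quasi-fixations (large-effect trajectories
completing ~10³ × after the short-term phase) are observable in
trajectories but deliberately not flagged by any classifier: no
quantitative criterion exists that does not embed an arbitrary horizon.
The large-effects approach rate is exposed only as the proportionality
s·z_f·γ̄ with constant 1, which is all the theory used here pins down.
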