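# Methods

## Model

A population of subjects each deterministically shows, or does not show, a
qualitative outcome (an effect, a trait). The fraction showing it is the
**typicality** γ (elsewhere called prevalence). A per-subject statistical
test detects the outcome imperfectly: it fires with probability β
(sensitivity) in a subject that has the outcome and with probability α
(false-positive rate) in one that does not. Subjects are sampled and tested
independently, so the number N of significant tests among M subjects is
binomial with success probability

    p = γβ + (1 − γ)α = α + (β − α)γ,

an affine, strictly increasing map of γ onto [α, β] (hence the requirement
α < β). Everything in the package derives from this mixture plus binomial
tail arithmetic.

### Typicality lower bound γc

The exact equal-tailed (Clopper–Pearson) bounds for p invert the binomial
tails: the lower bound solves P(X ≥ N | M, p) = t and the upper bound
P(X ≤ N | M, p) = t, with tail mass t = (1 − level)/2 for two-sided and
1 − level for one-sided (lower-only) intervals; p_L = 0 at N = 0 and
p_U = 1 at N = M by the standard convention. The bounds are computed
through the incomplete-beta identity (beta quantiles), and the test suite
independently re-derives them by root-finding on the defining tail
equation (agreement required at 1e-9) and against statsmodels' exact
interval. Exact bounds are conservative: coverage is at least the nominal
level at every p, which the Monte Carlo layer confirms empirically.

γc is then (p_L − α)/(β − α), clipped to [0, 1]. The raw value is kept
alongside a `clipped` flag: small samples give p_L < α (raw negative — the
zero cells of the reference tables), and β < 1 can push the raw value past
one. Because any β < 1 inflates γc without limit, the package defaults to
the conservative β = 1 and warns whenever a bound is requested with β < 1.

### Majority-rule error rates

The N-out-of-M framework declares the outcome seen in a strict majority
(threshold floor(M/2) + 1) of M subjects "representative". With outcome
probabilities (1 − ω, ω₁, …, ω_K), each outcome's count is marginally
Binomial(M, ·), and at most one outcome can reach a strict majority, so
the correct/incorrect events are disjoint:

    π = P(X_rep ≥ t),   δ = Σ_j P(X_j ≥ t),   inconclusive = 1 − π − δ.

For M = 3 with a single outlier, δ(ω) = 3ω² − 2ω³; for M = 1 the rule
degenerates to δ = ω. The single-outlier curve is restricted to
ω ∈ [0, 0.5) so the representative stays the modal outcome. The threshold
solver inverts δ by bracketed root-finding (brentq, xtol = 1e-12), and a
companion scan over integer-percent ω values reports the smallest
integer-percent typicality keeping δ at or below a target (87% at the 5%
target for 2-of-3). An exhaustive oracle sums multinomial probabilities
over all K^M ordered outcome assignments (guarded at 10^7 assignments) and
must agree with the analytic rates to 1e-12.

The per-subject test errors (α, β) are deliberately *not* folded into the
majority-rule rates: the rule operates on outcomes, and the interaction of
test error with the rule is exposed only through the simulator.

### Hypothesis tests

A hypothesized typicality γ₀ implies p₀ = α + (β − α)γ₀, and the one-sided
p-value is the upper tail P(X ≥ N | M, p₀). Along the unanimous diagonal
this reduces to p₀^M: 0.525^M for the majority null (γ₀ = 0.5 at the
default α = 0.05, β = 1) and 0.05^M for the global null (γ₀ = 0). Some
narrative sources phrase the defining event as "N or less"; the tabulated
values identify the upper tail unambiguously (1-out-of-1 under the
majority null gives 0.525, not 1), and the package implements the upper
tail and documents the wording discrepancy rather than silently resolving
it.

## Monte Carlo layer

The simulator is verification plumbing, not a model of real experiments.
`simulate_rule` draws per-subject outcomes i.i.d. from the outcome
distribution; `simulate_significance` and `coverage_check` use the
two-stage draw (carrier status at rate γ, then an imperfect test at β or
α) so that the mixture construction itself — not merely its marginal
binomial — is exercised. Each run uses one seeded `numpy.random.Generator`
with subjects varying within a replicate and replicates outermost, so a
fixed configuration is bit-reproducible. What it does **not** emulate:
dependence between subjects, heterogeneous test characteristics across
subjects, or drifting experimental conditions — so passing checks validate
the arithmetic under the stated i.i.d. model, not those aspects of real
data.

Stochastic checks accept deviations up to four binomial standard errors,
keeping the false-alarm rate of a seeded check negligible (~6e-5 per
comparison) while still detecting any real discrepancy. Default problem
sizes are 2×10^5 replicates for rate checks and 10^5 for coverage, sized
so each empirical rate carries a standard error around 10^-3 — small
against every effect of interest — while a full verification pass stays in
the seconds range.

## Numerical and emission conventions

* Bounds and roots: beta quantiles for interval bounds; brentq at
  xtol = 1e-12 for ω thresholds; agreement between analytic rates and the
  enumeration oracle required at 1e-12 (sums accumulated with `math.fsum`).
* Table emission: γc tables in percent, one decimal, ties away from zero
  (the `decimal` module, since built-in rounding is banker's); p-value
  tables at four decimals, with values below 1e-4 in scientific notation
  at three significant digits (e.g. `3.13e-7`).
* Degenerate inputs: N = 0 gives p_L = 0 hence γc = 0; N = M gives
  p_U = 1; a one-sided request for an upper bound raises
  `UnsupportedRequestError`; distributions must sum to one (1e-12) with a
  strictly modal representative; even M is supported with ties counted as
  inconclusive (strict majority keeps the correct/incorrect events
  disjoint for every M, though the reference analyses use M = 1 and 3).

## Known limitations

* The published global-null p-value table that the test suite compares
  against contains three cells ((M=5, N=3), (M=7, N=4), (M=8, N=4)) whose
  last printed digit is inconsistent with the exact binomial tail under
  any single rounding rule; the tests pin the exact values and compare
  those cells at one unit in the last printed digit.
* γc is a one-number summary: the package reports lower bounds only
  (upper typicality bounds are computed internally for the confidence-belt
  series but are not a headline output, since the use case is a
  conservative guarantee).
* All inference assumes exchangeable subjects and a test with known,
  subject-invariant α; α is under the analyst's control, but β is not
  identifiable from the data, which is precisely why the conservative
  β = 1 convention is the default.
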