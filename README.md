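# typinfer

Small-sample inference about the **typicality** (prevalence) of a
qualitative test outcome in a population, from per-subject test results —
the situation of, e.g., non-human-primate neurophysiology, where a study
tests M = 1–3 animals and reports that N of them show an effect.

Given N subjects showing an outcome out of M tested, the package answers:

* **What fraction of the population can this sample vouch for?**
  The per-subject significance probability p relates to typicality γ
  through the test's false-positive rate α and sensitivity β:

      p = γβ + (1 − γ)α = α + (β − α)γ,   hence   γ = (p − α)/(β − α).

  Substituting the exact (Clopper–Pearson) lower confidence bound for p
  gives a lower confidence bound **γc** on typicality — the conjunction-
  analysis estimate, with the conservative convention β = 1.

* **How error-prone is a majority vote over M subjects?**
  If the modal ("representative") outcome has probability 1 − ω and the
  outliers share ω, the N-out-of-M strict-majority rule is *correct*,
  *incorrect* (probability δ) or *inconclusive* with closed-form binomial
  rates; e.g. for the 2-out-of-3 rule with a single outlier type,
  δ(ω) = 3ω² − 2ω³. A threshold solver inverts δ: keeping δ ≤ 5% requires
  representative typicality of 87% or more.

* **What does the tally say about a hypothesized typicality γ₀?**
  One-sided binomial p-values P(X ≥ N | M, p₀) with p₀ = α + (β − α)γ₀,
  for the majority null (γ₀ = 0.5), the global null (γ₀ = 0, i.e. the
  effect exists in no member of the population), or any γ₀.

* **Do the formulas hold up?** A seeded Monte Carlo layer re-derives every
  analytic rate empirically, and a brute-force multinomial enumeration
  serves as an exact oracle for the majority-rule rates.

## Worked example

Two of three tested animals show an effect. What lower bound on typicality
does that support?

```sh
$ typ gammac --n 2 --m 3 --sided one
{
 "N": 2, "M": 3, "alpha": 0.05, "beta": 1.0, "level": 0.95,
 "sidedness": "one_sided_lower",
 "p_lower": 0.13535036217158386,
 "gamma_c": 0.08984248649640407,
 "gamma_c_percent": 8.984248649640406,
 ...
}
```

The one-sided 95% lower bound on the per-subject significance rate is
p_L ≈ 0.135 (the root of 3p²(1−p) + p³ = 0.05); correcting for a 5%
false-positive rate gives γc ≈ 9% — the sample only guarantees, with 95%
confidence, that at least ~9% of the population shows the effect, far
short of a majority.

How reliable would trusting the 2-of-3 majority be?

```sh
$ typ noom-error --m 3 --delta-target 0.05
{
 "M": 3, "delta_target": 0.05,
 "omega_threshold": 0.1353503621716077,
 "typicality_threshold": 0.8646496378283923,
 "min_typicality_percent": 87
}
```

The incorrect-conclusion rate δ of the 2-out-of-3 rule stays at or below
5% only while the outlier probability ω is below ≈ 13.5% — that is, only
if the representative outcome already has typicality of 87% or more.

The same facilities are available as a library:

```python
from typinfer import SampleTally, gamma_lower_bound, rule_rates, OutcomeDistribution

gamma_lower_bound(SampleTally(2, 3), sidedness="one").percent   # 8.98
rule_rates(OutcomeDistribution((0.8, 0.1, 0.05, 0.05)), 3).delta  # 0.0425
```

`typ report --which table1 ... table4 | fig1 | fig2 | fig3c | fig3d`
emits the full reference tables (γc bounds and p-value tables for
M up to 10) and the figure data series as CSV or JSON.

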