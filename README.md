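# archefda

Archetypal pattern discovery in sparse, irregular multivariate
longitudinal data — and association of the archetypes with a downstream
scalar outcome.

The motivating setting is infant growth: head circumference, body length
and weight measured a handful of times per child at child-specific ages,
with a cognitive score observed years later.  `archefda` asks which
children follow *extreme* joint growth patterns ("Generally Large",
"Catch-up", "Stunting", "Faltering") and whether those patterns carry
different outcome distributions.  The same machinery applies to any
study with several sparsely observed longitudinal traits per subject and
one scalar endpoint.

## Method

For each trait `j`, the trajectories are modeled by a Karhunen–Loève
expansion

    X[j](t) = μ_j(t) + Σ_k ξ_k[j] φ_k[j](t),

estimated from sparse noisy observations by the conditional-expectation
(PACE) scheme: a local linear smooth of the pooled scatter gives μ̂_j, a
local linear surface smooth of off-diagonal raw covariances gives
Ĝ_j(s,t), whose quadrature eigendecomposition yields (λ̂_k, φ̂_k); each
subject's component scores are best linear predictors
ξ̂_ik = λ̂_k φ̂_ik' Σ̂_i⁻¹ (X̃_i − μ̂_i) given that subject's own sparse
observations.

The per-trait scores are stacked and reduced by conventional PCA to
joint scores Z = (Z1, Z2).  A product-Gaussian kernel density estimate
on the Z-cloud defines the (1−α) highest density region (HDR); subjects
outside it are outliers, partitioned into four archetype clusters by
which scale-standardized coordinate dominates and its sign:

    S1: |Z1|/√ρ1 > |Z2|/√ρ2, Z1 > 0     (Generally Large)
    S2: |Z1|/√ρ1 < |Z2|/√ρ2, Z2 > 0     (Catch-up)
    S3: |Z1|/√ρ1 > |Z2|/√ρ2, Z1 < 0     (Stunting)
    S4: |Z1|/√ρ1 < |Z2|/√ρ2, Z2 < 0     (Faltering)

Outcome distributions across S1..S4 are compared with one-way ANOVA,
Kruskal–Wallis, and all-pairs Tukey HSD (Bonferroni / Benjamini–Hochberg
available); the headline summary is the number of *completely separated*
clusters — connected components of the graph joining subgroups whose
pairwise difference is not significant.  The same clustering applied to
a single trait's scores gives the marginal benchmark.

A fully specified synthetic-cohort generator (three traits, two Fourier
components each, a 6×6 score covariance with cross-trait dependence,
uniform sparse sampling, outcome linear in the two leading joint
components) doubles as the test harness and powers a Monte-Carlo study
of how many clusters each method separates.

## Worked example

```bash
archefda simulate --n 1000 --seed 42 --out-dir cohort/
archefda analyze --measurements cohort/measurements.csv \
                 --outcomes cohort/outcomes.csv \
                 --no-standardize --marginal --out-dir analysis/
```

or in Python:

```python
from archefda import SimConfig, simulate_subjects, analyze_sample, associate

cfg = SimConfig(n=1000)
sample, xi, z, y = simulate_subjects(cfg, seed=42)
res = analyze_sample(sample, cfg)
print(res["joint_assignment"].sizes())
# {'normal': 951, 'S1': 11, 'S2': 9, 'S3': 18, 'S4': 11}
report = associate(y, res["joint_assignment"].labels)
print(round(report.anova.F, 1), report.n_separated)
# 71.7 3
```

With α = 0.05 about 5% of the 1000 subjects fall outside the HDR and
split into the four archetype clusters (sizes above).  The ANOVA F of
71.7 on the four clusters says their mean outcomes differ strongly; the
separation count 3 means Tukey's procedure fully distinguishes three
cluster groups at the family-wise 0.05 level in this cohort.

`analysis/assignments.csv` holds one row per subject with the label,
archetype name, joint scores, density and outlier flag;
`association.json` holds the ANOVA/Kruskal–Wallis tables and pairwise
comparisons.

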