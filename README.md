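# cogtrace

Longitudinal cognitive diagnosis: track which fine-grained skills
("attributes") each student masters, and how mastery changes across repeated
test administrations, from nothing but dichotomous item responses and a
Q matrix.

Classical cognitive diagnosis models (CDMs) such as DINA classify students
cross-sectionally and need parametric estimation that degrades in small
samples. `cogtrace` implements a two-step hidden-Markov workflow whose
measurement model is a **supervised self-organizing map (SSOM)** — a
nonparametric neural classifier trained purely on the ideal responses the
Q matrix implies — so it needs no item-parameter estimation at all:

1. **Measurement step.** For a test with J items and K attributes, every
   mastery pattern α ∈ {0,1}^K has an ideal DINA response
   η_j(α) = ∏_k α_k^{q_jk}. The SSOM (input layer J nodes → competition
   grid → output layer 2^K classes) is trained on (ideal response, pattern)
   pairs: winner g = argmin_j ‖x − W_in[:,j]‖, neighborhood updates
   W ← W + η(t)(x − W) on both layers, damped by a coefficient μ when the
   winner's current prediction disagrees with the label. Each wave of
   observed responses is then classified into patterns.
2. **Transition step.** The classified pattern chains feed maximum-likelihood
   Markov estimates: initial distribution π_i = P(q₁ = s_i), transition
   matrices a_ij = P(q_t = s_j | q_{t−1} = s_i) at pattern (2^K × 2^K) and
   per-attribute (2 × 2) granularity.

The package also contains the full DINA longitudinal simulator used to
validate the workflow: wave-1 mastery profiles from an exchangeable Gaussian
copula (exact marginal mastery rates, latent correlation ρ), per-attribute
two-state Markov transitions between waves, and Bernoulli responses with
P(X_j = 1 | α) = (1 − s_j)^{η_j} g_j^{1−η_j}. Accuracy is scored by ACCR
(per-attribute agreement), PCCR (whole-pattern agreement), and true-vs-
estimated transition agreement. The reference 20-item Q matrices, slip/guess
tables and transition designs for the 3- and 6-attribute studies, and the
8-item reading-assessment Q matrix, ship as built-in fixtures.

## Worked example

```python
import cogtrace as ct

# a standard study condition: K=3 attributes, 20 items, N=500,
# high item discrimination, three waves
cond = ct.make_condition(k=3, j=20, n=500, regime="high")
sample = ct.simulate_longitudinal(cond.design, cond.q, cond.params, seed=42)

model = ct.LongitudinalCDA(sample.responses, cond.q)
results = model.fit(seed=42)
print(results.summary())
```

```
Longitudinal Cognitive Diagnosis (HMM + supervised SOM)
==========================================================
Examinees: 500   Waves: 3   Items: 20   Attributes: 3
Training policy: population   SSOM grid: (10, 10)   passes: 2
Training accuracy per pass: 0.968, 0.968

Initial pattern distribution (pi):
  000:0.464  010:0.108  011:0.024  100:0.120  101:0.038  110:0.144  111:0.102

Estimated attribute mastery by wave:
              T1     T2     T3
attribute
A1         0.404  0.610  0.648
A2         0.378  0.550  0.592
A3         0.164  0.068  0.106

Attribute transition probabilities T1 -> T2 (rows: from-state 0/1):
  A1: 0 -> [0.55, 0.45]   1 -> [0.16, 0.84]
  A2: 0 -> [0.68, 0.32]   1 -> [0.06, 0.94]
  A3: 0 -> [0.94, 0.06]   1 -> [0.89, 0.11]
...
```

The summary reads directly against the generating design: wave-1 mastery
(0.40, 0.38, 0.16) recovers the copula marginals (0.4, 0.4, 0.2); the A1
gain estimate 0.45 from non-mastery matches the generating transition row
(0.55, 0.45). Because this is a simulation, the truth is known and can be
scored:

```python
scored = results.score(sample.profiles)
for rep in scored["reports"]:
    print(rep.time_point, rep.pccr)        # 0.898, 0.920, 0.918
for agr in scored["agreements"]:
    print(agr.pairwise, agr.matrix)        # 0.824/0.979, 0.854/0.974
```

PCCR ≈ 0.92 means 92% of students are placed in exactly the right 3-bit
mastery pattern; the matrix agreement ≈ 0.98 says the estimated pattern
transition probabilities sit within ~0.02 of the true ones on average.

For observed data, build the model from CSVs (rows = students, one response
matrix per wave, plus a Q matrix) or use the CLI:

```bash
cogtrace fixtures --name q_empirical            # print a built-in table
cogtrace simulate --k 3 --j 20 --n 500 --regime high --reps 10 --seed 7 --out run/
cogtrace empirical --q q.csv --wave t1.csv --wave t2.csv --out results/
```

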