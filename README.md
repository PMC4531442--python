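# qhet

Accurate homogeneity tests for odds ratios across K independent 2×2
studies: Cochran's Q referred to a finite-sample **gamma** null
distribution, alongside the Breslow–Day/Tarone test and the conventional
chi-square-referenced Q, plus a level/power simulation engine.

## Who this is for

Meta-analysts and trial statisticians who need to test whether K two-arm
binomial studies share a common odds ratio. The standard practice —
referring Cochran's Q to χ²(K−1) — is asymptotically correct but badly
conservative for small-to-moderate studies, especially when event
probabilities are far from ½ (e.g. 10% event rates): its achieved level
can fall below 0.01 at a nominal 0.05, and its power suffers accordingly.

## The model and the test

For study *i* with treatment/control arm sizes n_Ti, n_Ci and event counts
x_i, y_i, the effect is the log odds ratio θ_i = logit(p_Ti) − logit(p_Ci),
estimated by the bias-minimising ½-corrected logits

    θ̂_i = L_½(x_i) − L_½(y_i),   L_a(x) = log[(x+a)/(n−x+a)],

with variance estimate
v̂_i = 1/(x_i+½) + 1/(n_Ti−x_i+½) + 1/(y_i+½) + 1/(n_Ci−y_i+½),
weights ŵ_i = 1/v̂_i, pooled effect θ̂_w = Σŵ_iθ̂_i/Σŵ_i and

    Q = Σ_i ŵ_i (θ̂_i − θ̂_w)².

Under homogeneity both E[Q] and Var[Q] fall *below* the chi-square values
K−1 and 2(K−1). The gamma-referenced test (`q_gamma_test`) estimates
these finite-sample moments and refers Q to the moment-matched gamma:

1. **Theoretical mean** E_th[Q]: a delta-method expansion of Q about the
   null, combining exact binomial moments (orders 1–4) of the ½-corrected
   logit with analytic derivatives of the inverse-variance weight function
   f(θ, ζ) = [(1+e^{θ+ζ})²/((n_T+1)e^{θ+ζ}) + (1+e^ζ)²/((n_C+1)e^ζ)]⁻¹,
   where ζ is the control-arm log odds. Evaluated at the plug-in null
   (θ̂_w, ζ̂_i).
2. **Calibrated moments**: (K−1) − E[Q] = 0.687[(K−1) − E_th[Q]] and
   Var[Q] = 4.74(K−1) − 12.17E[Q] + 9.42E[Q]²/(K−1), fitted regression
   constants adopted as published.
3. **Gamma matching**: shape α = E[Q]²/Var[Q], scale β = Var[Q]/E[Q];
   the p-value is the upper tail of gamma(α, β) at Q.

Comparators: `q_chisq_test` (standard Q, corrections only for zero-cell
tables, referred to χ²(K−1)) and `breslow_day_test` (observed vs expected
treatment events under the Mantel–Haenszel common odds ratio, optional
Tarone adjustment).

## Worked example

Generate a synthetic 8-study meta-analysis with rare events (10% control
probability, log OR 0.5, between-study SD τ = 0.4) and test it:

```sh
qhet fixture --k 8 --n 90 --pc 0.1 --theta 0.5 --tau 0.4 --seed 12 --out example.csv
qhet test --input example.csv
```

```
K = 8 studies
pooled log OR (1/2-corrected)  theta_w = 0.1968   (OR = 1.2176)
Mantel-Haenszel OR             psi_hat = 1.2353
Q (1/2-corrected)              Q_LOR   = 10.7812
Q (standard)                   Q_stand = 11.4218

test             statistic   p-value  reference
q_gamma            10.7812    0.0731  gamma(alpha=4.14921, beta=1.46081)
q_chisq            11.4218    0.1213  chi-square(7)
breslow_day        12.1078    0.0971  chi-square(7)
tarone             12.1075    0.0971  chi-square(7)

gamma reference chain: E_th[Q]=5.6335  E[Q]=6.0612  Var[Q]=8.8543  alpha=4.1492  beta=1.4608
```

Reading the chain: the estimated null mean of Q is 6.06, well below the
chi-square mean of K−1 = 7, and the null variance 8.85 well below
2(K−1) = 14 — the chi-square reference is too spread out for these small
rare-event studies, so its p-value (0.121) overstates the evidence for
homogeneity. The gamma reference, matched to the finite-sample moments,
gives 0.073; Breslow–Day agrees at 0.097, with Tarone essentially
identical.

The same machinery is callable as a library:

```python
from qhet import MetaDataset, StudyTable, q_gamma_test

ds = MetaDataset([StudyTable(x=28, n_t=237, y=18, n_c=228),
                  StudyTable(x=12, n_t=100, y=5, n_c=100)])
res = q_gamma_test(ds)
print(res.statistic, res.p_value, res.diagnostics["e_corr"])
```

Simulation engine, for levels and power under θ_i ~ N(θ, τ²):

```sh
qhet simulate level --k 5 --n 90 --pc 0.1 --theta 0 --reps 10000 --seed 1
qhet simulate power --k 20 --n 90 --pc 0.1 --tau 0.5 --reps 1000 --seed 1
```

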