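# seamsel

Treatment selection and confirmatory testing for two-stage **seamless phase
II/III clinical trials** with an early (surrogate) endpoint.

In the first stage of such a trial, patients are randomized to a control
`T_0` or one of `k` experimental treatments `T_1..T_k`. At an interim
analysis one experimental arm is selected to continue, together with the
control, into the second stage. Because the primary endpoint needs long
follow-up, the interim dataset typically holds the primary ("final") outcome
for only `n1` patients per group but a rapidly observable early outcome for a
larger number `N1`. Each patient's early/final pair `(X, Y)` is modelled as
bivariate normal with arm-specific means `(μ_b,i, μ_B,i)`, common SDs
`(σ0, σ)` and within-patient correlation `ρ_w`; the parameters of interest
are the final-endpoint effects `θ_i = μ_B,i − μ_B,0`.

The package implements:

- **Selection rules** — the early-endpoint rule (argmax of the standardized
  early statistics `Z̃_i`), the score-statistic rule (argmax of scores `S_i`
  that augment the `n1` observed final outcomes with all `N1` early outcomes
  via a covariate adjustment with effective information
  `I = n1 / (2σ²(1 − ρ_w²(1 − n1/N1)))`), and a **data-driven rule** that,
  when the two disagree, estimates the model parameters from the interim data
  and follows whichever rule assigns the higher plug-in selection probability
  to its own candidate.
- **Analytic selection probabilities** — marginal per-arm probabilities for
  both rules and the joint 2×2 "which rules agree" table, all via
  multivariate normal orthant integration (`seamsel.select_prob`). The joint
  law depends on the *sign* of `ρ_w` even though neither marginal does.
- **Confirmatory analysis** — closed testing over all intersection
  hypotheses, Dunnett many-to-one p-values per stage, weighted inverse-normal
  combination `C(p1,p2) = 1 − Φ(w1 Φ⁻¹(1−p1) + w2 Φ⁻¹(1−p2))`, and the
  conservative stage-2 policy (`p2(S) = 1` when the selected arm is outside
  `S`), giving strong familywise-error control at one-sided `α` for *any*
  stage-1-based selection rule (`seamsel.testing`).
- **A simulator and Monte-Carlo engine** for operating characteristics:
  selection probability, power (select the best arm *and* reject its null
  hypothesis), agreement decompositions and error rates
  (`seamsel.simulate`, `seamsel.scenarios`).

## Worked example

The packaged example is an anti-hypertensive dose-finding trial: four dose
regimens against placebo, diastolic blood pressure reduction at week 4 as the
early endpoint and at week 8 as the primary endpoint (early effects 2.3, 3.4,
3.8, 1.9 mmHg; final effects 1.0, 0.6, 3.9, 1.1 mmHg; both SDs 10 mmHg;
`ρ_w = 0.9`). With the interim at half of recruitment (`N1 = 45`, `n1 = 10`):

```python
>>> from seamsel import worked_example
>>> v = worked_example("i")
>>> [round(p, 3) for p in v["stallard"]]
[0.102, 0.072, 0.716, 0.11]
>>> [round(p, 3) for p in v["friede"]]
[0.118, 0.337, 0.468, 0.076]
```

Both rules favour the third dose regimen, but the score-statistic rule is far
more confident (0.716 vs 0.468) because regimen 2 looks good early but poor
on the primary endpoint, which only the score statistic sees. At an earlier
interim (`worked_example("ii")`, `N1 = 25`, `n1 = 5`) both vectors shrink
toward uniformity — less data, less discrimination.

The same numbers are available from the shell:

```bash
seamsel example --setting i
seamsel probs --config my_trial.yaml     # marginal + joint tables
seamsel scenario --config my_trial.yaml --reps 10000 --seed 1
```

where the YAML config mirrors the model/design fields (`mu_b`, `mu_B`,
`sigma0`, `sigma`, `rho_w`, `N1`, `n1`, `n2`, `alpha`).

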