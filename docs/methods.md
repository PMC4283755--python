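# Methods

## Trial and data model

A two-stage trial compares `k` experimental arms `T_1..T_k` with a control
`T_0` (arm index 0). Patient `j` in arm `i` contributes an early outcome
`X_ij` and a final outcome `Y_ij`, jointly bivariate normal:

    (X_ij, Y_ij) ~ N2( (μ_b,i, μ_B,i), [[σ0², ρ_w σ0 σ], [ρ_w σ0 σ, σ²]] ),

independent across patients and arms, with common SDs across arms. Larger
values encode benefit (blood-pressure *reductions* are stored positive). The
effects of interest are `θ_i = μ_B,i − μ_B,0` (final) and
`δ_i = μ_b,i − μ_b,0` (early), with one-sided hypotheses `H_0i: θ_i ≤ 0`.

At the interim, each arm has `N1` early values but only `n1 ≤ N1` final
values (the first `n1` patients per arm by convention — enrollment order is
exchangeable under the model, so this loses no generality). Stage two
recruits `n2` fresh patients per group on the selected arm and control; the
stage-2 statistic uses only those, which makes it independent of everything
computed at stage one.

## Interim statistics

All standardized statistics have unit variance and pairwise correlation 1/2
across arms (the shared control):

- early: `Z̃_i = (X̄_i − X̄_0) √(N1/2) / σ0`,
- stage-1 final: `Z_i,1 = (Ȳ_i − Ȳ_0) √(N1/2) / σ` on all `N1` finals
  (available by the time of the final analysis),
- stage-2: `Z_I,2 = (Ȳ_I − Ȳ_0) √(n2/2) / σ` on the `n2` stage-2 patients.

The score statistic for `θ_i` at the interim adjusts the observed final
means by the early-endpoint information. With `x̄_i` the early mean of the
`n1` paired patients and `X̄_i` the early mean of all `N1`,

    θ̂_i = (Ȳ_i − Ȳ_0) + (ρ_w σ/σ0) [(X̄_i − x̄_i) − (X̄_0 − x̄_0)],
    I    = n1 / (2 σ² (1 − ρ_w² (1 − n1/N1))),
    S_i  = θ̂_i √I,

so that `E[S_i] = θ_i √I`, `Var(S_i) = 1`, `Corr(S_i, S_j) = 1/2`. The
information `I` interpolates between the `n1`-patient final-only information
(ρ_w = 0) and the `N1`-patient information (n1 = N1), and grows with |ρ_w|
and `N1`. When σ, σ0 and ρ_w are unknown the plug-in version regresses the
final on the early endpoint within arms with a common pooled slope (the
common-covariance assumption makes per-arm slopes both unnecessary and
unstable at `n1 = 4`); the slope, pooled residual variance and pooled
early-endpoint variance are substituted into the formulas above. The implied
correlation estimate is clipped to ±0.99 (configurable constant) so the
plug-in information stays finite when the paired data are collinear.

Moment-based interim estimates of all five model parameters use per-arm
means (early over `N1`, final over `n1`), pooled within-arm SDs with
`Σ(n−1)` degrees of freedom, and the pooled within-arm Pearson correlation
of the pairs, clipped the same way.

## Selection rules

- Early-endpoint rule: select `argmax Z̃_i`.
- Score rule: select `argmax S_i`.
- Data-driven rule: compute both candidates from the estimated statistics.
  If they coincide, done. Otherwise evaluate each rule's *analytic* selection
  probability for its own candidate at the plug-in parameter estimates (same
  estimates for both rules, different statistic laws) and follow the rule
  with the larger value.

Argmax ties break to the lowest arm index (deterministic); an exact
probability tie goes to the score-rule candidate, which uses more of the
data. Neither choice is forced by the underlying theory; both are package
conventions and configurable in principle.

## Selection probabilities

`P(rule selects arm i)` is the orthant probability that the `k−1`
differences against arm `i` are all ≤ 0: a multivariate normal CDF with
difference variances 1 and correlations 1/2, difference means
`(δ_j − δ_i)√(N1/2)/σ0` (early rule) or `(θ_j − θ_i)√I` (score rule). The
equicorrelated structure admits an exact one-dimensional reduction

    P(T_i is max) = ∫ φ(v) Π_{j≠i} Φ(v + √2 (m_i − m_j)) dv,

which the package evaluates on a fixed 401-point Simpson grid over [−9, 9]
(machine-precision accurate for this entire, rapidly decaying integrand, and
vectorizable over simulation batches). Property tests verify equality with
direct multivariate-normal integration.

The joint probability that *both* rules select arm `i` needs the
2(k−1)-dimensional law of (early differences, score differences). Their
cross-covariance follows from `Cov(S_i, Z̃_j) = γ(1 + [i=j])` with

    γ = ρ_w σ √( I / (2 N1) ),

giving a cross block `γ(1 + [j=l])` between difference vectors. `γ` is odd
in ρ_w: the agreement probability depends on the sign of the within-patient
correlation although both marginals are sign-invariant (the score marginal
depends on ρ_w only through ρ_w²). At ρ_w = +1 with proportional effects the
two rules agree almost surely; at ρ_w = −1 they agree with probability zero.

### Numerical integration

`mvn_orthant` dispatches on the covariance rank:

- full rank: scipy's quasi-Monte-Carlo multivariate normal CDF with a fixed
  internal seed (`abseps` 2e-7, maxpts 10⁶ per dimension) — deterministic
  and accurate to ~1e-6;
- rank 1: exact interval probability;
- rank 2 (the |ρ_w| = 1 joint laws with k = 3): the polytope probability is
  computed by adaptive quadrature over one latent dimension with an exact
  normal-CDF interval in the other — eigen-truncation, no jitter, so the
  degenerate limits are reproduced exactly;
- rank ≥ 3: scrambled Sobol integration (2²⁰ points, fixed seed).

Indefinite or asymmetric covariances are rejected rather than repaired.

## Confirmatory analysis

Closed testing over all `2^k − 1` intersection hypotheses (exhaustive
enumeration, refused for `k > 20`; intended use is `k ≤ 10`). For each
subset `S`: the stage-1 p-value is the Dunnett tail probability of
`max_{i∈S} Z_i,1` over `|S|` equicorrelated (1/2) standard normals (same
one-dimensional reduction as above); the stage-2 p-value is `1 − Φ(Z_I,2)`
if `I ∈ S`, else 1; the two are combined by the weighted inverse-normal
rule with weights satisfying `w1² + w2² = 1`. Default weights square-
proportionally to the stagewise per-group sample sizes (`N1`, `n2`) — the
standard convention; literal proportionality followed by normalization gives
the identical pair. `H_0i` is rejected iff every containing subset's
combined p-value is ≤ α (default one-sided 0.025). Known-σ z statistics are
used throughout the confirmatory path; estimated-parameter statistics appear
only inside the data-driven selection rule.

Because the stage-2 p-value is conditionally uniform given all stage-1 data
and the conservative policy handles de-selected subsets, the procedure
controls the familywise error rate strongly for any stage-1-based selection
rule — including the data-driven rule, whose selection depends on the same
interim data in a complicated way.

## Simulation engine

`run_scenario` simulates complete trials in vectorized chunks (default
2,000 replicates per chunk): one shared stage-1 dataset per replicate, all
three rules applied to it, stage-2 data drawn per *arm* so rules selecting
the same arm share stage-2 data while differing selections get independent
draws, then the closed test per rule. Default replicate count is 10,000.
Reported per rule: probability of selecting `T_1` (by convention the
presumed best arm), power in the joint sense (select `T_1` and reject
`H_01`), and the any-rejection rate (the familywise error rate under the
global null). Also reported: the decomposition of data-driven selections of
`T_1` by which candidate(s) proposed it, the 2×2 agreement table of the two
standalone rules for `T_1` (cross-validated against the analytic joint law),
the upper bound `P(at least one standalone rule selects T_1)` and the
coin-flip benchmark (average of the two standalone selection probabilities).

Reproducibility: single-trial simulation derives independent substreams from
`(seed, replicate, stream)` via `numpy.random.SeedSequence` spawn keys,
where stream 0 is stage one and stream `1 + arm` is stage two for a given
selected arm. The batch engine consumes one master stream per scenario;
`(configuration, seed)` fixes every reported number bit for bit.

### What the generator does and does not emulate

The generator draws exactly from the model above: bivariate-normal pairs,
common variances, independence across patients and arms, complete follow-up
in deterministic enrollment order. Real trials add staggered accrual,
dropout, non-normal and heteroscedastic outcomes, and drifting effects —
none of which are modelled. Passing tests therefore demonstrate correctness
of the methodology *under its own model assumptions*, not robustness to
their violation.

## Parameter conventions and defaults

| Parameter | Meaning | Default / convention |
|---|---|---|
| `α` | one-sided familywise level | 0.025 |
| `w1, w2` | combination weights | `√(N1/(N1+n2))`, `√(n2/(N1+n2))` |
| `n2` | per-group stage-2 recruits | user-set; 64 in the standard simulation design |
| correlation clip | plug-in ρ̂_w bound | ±0.99 |
| `n_reps` | scenario replicates | 10,000 |
| orthant accuracy | absolute | 1e-6 (fixed internal seed) |

The standard simulation design used in tests and the error-rate study is
`k = 3`, `n1 = 4`, `N1 = 32`, `n2 = 64`, unit SDs, with arm effects
(1, 1/2, 1/4) × the arm-1 effect on each endpoint; the packaged worked
example uses the blood-pressure parameters listed in the README.

## Known limitations

- Selection of exactly one arm, two stages, one early endpoint; equal
  allocation and equal variances across arms; normal endpoints with known σ
  in the confirmatory path (no small-sample t versions).
- The data-driven rule's plug-in probabilities inherit the noise of interim
  estimates; at `n1 = 4` per arm the correlation estimate is crude, and the
  rule's benefit shows mainly when the two candidate rules disagree often
  (negative or small ρ_w).
- Analytic power (selection *and* rejection) is not computed; power is
  estimated by simulation only.
- The rank-≥3 degenerate integration path is plain QMC (~1e-4 accuracy),
  coarser than the nondegenerate and rank-2 paths.
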