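# Methods

## Problem and scope

`nmasplit` evaluates *local inconsistency* in network meta-analysis (NMA)
of binary outcomes: for every treatment comparison that has both direct
(head-to-head) and independent indirect evidence, it estimates the two
effects inside one Bayesian model, summarises their disagreement through
the inconsistency factor IF (direct minus indirect log odds ratio), and
interprets the disagreement through a Kullback–Leibler (KL) index with an
explicit "acceptably low" threshold. The package covers the whole chain:
arm-level data model and screening, network geometry, the node-splitting
model and sampler, the interpretation index and verdicts, a synthetic
network generator, and an orchestration layer with a CLI.

## Node-splitting model

One-stage binomial-logit random-effects NMA. For study *i* with baseline
arm *b* (the lowest-coded treatment in the study):

    r_ik ~ Binomial(p_ik, n_ik)
    logit(p_ik) = mu_i + delta_ik        (delta_ib = 0)

Contrast vectors `delta_i` are jointly normal with common between-study
standard deviation tau: `Var = tau^2`, pairwise `Cov = tau^2/2` (the
conditional-normal construction for multi-arm studies under a common tau).
Treatments are coded by sorted label; effects are log ORs of the higher-
versus the lower-coded treatment; basic parameters `d[t]` are relative to
the first treatment.

Splitting comparison (x, y):

* two-arm x–y studies have their contrast mean replaced by a free direct
  parameter `d_dir`;
* every other study keeps the consistency means `d[t_k] − d[t_b]`;
* `d_ind = d[y] − d[x]` and `IF = d_dir − d_ind`, evaluated per draw.

### Which comparisons are split

A comparison is enumerated as a split node iff (i) at least one two-arm
x–y study exists and (ii) x and y stay connected through a path that does
not use the x–y edge once those studies are removed. Multi-arm studies
containing both x and y are *not* severed: they remain intact on the
network side. This is a deliberate design choice. Diverting the x–y
contrast of such a study to `d_dir` removes, in sparse networks, the only
likelihood path to the indirect functional — in the minimal example of one
three-arm A/B/C study plus one two-arm A–B study, `d[B]` would be informed
by nothing but its prior, so no comparison could be split at all, although
the A–B edge plainly has direct evidence independent of the three-arm
design. Keeping the multi-arm study whole makes that A–B split well
identified (and makes A–C and B–C correctly unsplittable, because they
have no severable direct evidence). The trade-off: when a multi-arm study
contains the split pair, its internal x–y contrast stays in the "indirect"
side, so the severance is partial for such designs. `n_direct_studies`
counts the severed studies, i.e. what actually informs `d_dir`.

### Priors

* Baselines `mu_i`, basic parameters `d[t]`, and `d_dir`: Normal(0, 100²)
  (configurable via `effect_prior_sd`).
* `tau²`: log-normal, default location −2.56 and scale 1.74 — the
  empirical predictive distribution for pharmacological-versus-placebo
  comparisons with subjective/semi-objective outcomes. A small catalogue
  of published alternatives by (comparison type, outcome type) is exposed
  through `PriorSpec.empirical`; a half-normal prior on tau is also
  available. These are configuration, not constants: empirical values
  differ by outcome family and new tables appear regularly.

### Sampler

Metropolis-within-Gibbs, chosen because the conditional structure makes
most of the model either conjugate or embarrassingly parallel across
studies:

1. `mu_i`: vectorised random-walk Metropolis, one scalar block per study
   (independent given the contrasts).
2. `delta_i`: vectorised random-walk Metropolis per study block, using the
   closed-form inverse `Sigma^{-1} = (2/tau²)(I − J/(k+1))` so the
   multivariate prior density costs O(k) per study.
3. `(d, d_dir)`: exact multivariate-normal Gibbs draw — given the
   contrasts and tau the basic parameters are conjugate.
4. `log tau`: scalar random-walk Metropolis.

Proposal scales adapt toward acceptance rates 0.44 (scalar) / 0.35
(blocks) in batches of 50 during burn-in only and are frozen afterwards,
so the post-burn-in chain is a fixed Markov kernel. Kept draws are the
post-burn-in iterations that are multiples of `thin`. Defaults mirror
standard practice for this model class: 3 chains, 20 000 iterations, 2 000
burn-in, thinning 10 (1 800 kept draws per chain). All randomness flows
from a single integer seed via `numpy.random.SeedSequence`; per-chain and
per-node streams are spawned deterministically, so reruns are bitwise
identical.

Convergence is summarised by the Gelman–Rubin potential scale reduction
factor, computed from the textbook between/within-chain variance ratio
(`sqrt(((n−1)/n·W + B/n)/W)`); a split-chain variant is available. Results
with any monitored R̂ ≥ 1.1 are flagged `converged=False`, never silently
accepted. The sampler was cross-validated against an independent JAGS
(rjags) implementation of the identical model on a six-study triangle
fixture: all four monitored posteriors agree within three combined
Monte-Carlo standard errors (`tests/reference/`).

## Interpretation index

With normal approximations N(mu_D, s_D²) and N(mu_I, s_I²) of the direct
and indirect posteriors,

    D_DI = 1/2 [ s_D²/s_I² + (mu_D−mu_I)²/s_I² − 1 + ln(s_I²/s_D²) ]
    D_ID = 1/2 [ s_I²/s_D² + (mu_D−mu_I)²/s_D² − 1 + ln(s_D²/s_I²) ]
    D    = (D_DI + D_ID)/2

D is non-negative, zero only for identical approximations, and — at fixed
variances — an exact parabola in the mean difference with no linear term
and leading coefficient `(1/s_D² + 1/s_I²)/4`. A histogram KL estimator on
raw draws (`kld_between_draws`) is provided as an audit of the normality
reduction.

**Threshold.** Under consistency-on-average with `Var_D = tau²` and
`Var_I = 2 tau²`, the absolute direct-indirect difference is half-normal
with scale `sqrt(3)·tau`; its median is `Phi^{-1}(0.75)·sqrt(3)·tau`,
which rounds to the conventional `1.17·tau`. Substituting that median and
those variances into D gives a tau-free threshold. The canonical value
uses the two-decimal multiplier 1.17 exactly, giving 0.638338… (printed as
0.64); with the unrounded multiplier the value is 0.6368. Classification
uses the full-precision value by default (ties at the threshold are
material); the rounded 0.64 and the unrounded-multiplier variant are both
reachable through arguments, because boundary behaviour should be a
visible choice, not an accident of rounding. A clinically anchored variant
replaces the half-normal median with a user-chosen log-OR difference at
the same variance profile (`threshold_from_clinical_delta`), vectorised
over a (delta, tau) grid for sensitivity analysis.

**Verdicts.** Per node: *material* iff D ≥ threshold, else *acceptably
low*; *conclusive* iff the 95% CrI of IF excludes zero. Per network:
*potentially inconsistent* iff any node is material or conclusive;
*consistent* iff all nodes are below threshold; the CrI framework alone is
*inconclusive* iff every interval contains zero. Heterogeneity bands on
the log-OR scale: low (tau ≤ 0.1), reasonable (0.1 < tau < 0.5), fairly
high (0.5 ≤ tau ≤ 1.0), fairly extreme (tau > 1.0).

## Screening rules

* **Event-risk filter**: a study is removed when any arm's observed risk
  is strictly below 0.15 or strictly above 0.85 (separation guard for the
  logit link); arms exactly at the bounds are kept. Connectivity after
  removal is judged against the original treatment set, so a stranded
  treatment counts as broken connectivity. Removing every study is
  reported as outright exclusion.
* **Eligibility**: ≥ 3 treatments, #studies ≥ #treatments, connectivity,
  and at least one closed loop not informed exclusively by a single
  multi-arm design spanning the whole loop. The first two thresholds are
  configurable (`EligibilityRules`) because published selection wordings
  disagree — one phrasing implies "≥ 3 treatments and at least as many
  studies", another "≥ 4 treatments and strictly more studies"; the
  package defaults to the permissive reading and hard-codes neither.

## Synthetic networks

The generator draws, per study: a uniform baseline risk (default window
(0.25, 0.65), inside the filter band); study-level contrasts from the same
common-tau conditional-normal construction the model assumes; and binomial
events. Loop inconsistency is injected as a log-OR offset omega added to
the two-arm studies of one target comparison — exactly the evidence the
node-split severs — so the estimand IF equals omega by construction and
parameter recovery is a well-posed test. Presets: `consistent-triangle`
(5 two-arm studies per edge, tau = 0.1), `single-study-edge`,
`multi-arm-plus-independent-edge`, `inconsistent` (omega = 1.5 on A–B, 10
studies per edge of 800–1200 participants per arm, tau = 0.1) and
`high-tau` (identical but tau = 0.7). The offset presets use a lower
baseline window (0.18, 0.35) so offset arms stay inside the 15–85% band.

What the generator does *not* emulate: real networks' irregular
geometries, arm-size skew, baseline-risk heterogeneity beyond a uniform
window, selective reporting, or rare-event data. Passing recovery and
calibration tests therefore demonstrates internal coherence of model and
method — not performance on arbitrary published networks.

## Verification strategy and problem sizes

* Closed forms (KL divergence, threshold, parabola) are tested against
  numerical quadrature and exact polynomial solves.
* The sampler is tested four independent ways: a frozen JAGS reference run
  on a fixture network; null calibration (the 95% CrI of IF covers zero in
  95% ± 6% of 100 consistent-triangle replicates); recovery (IF within 0.3
  of omega = 1.5, material index, in ≥ 90% of 20 seeds); and the
  qualitative masking property (median index falls when generator tau
  rises from 0.1 to 0.7 at fixed omega).
* Replicated runs use a reduced chain geometry (3 × 4000 iterations, 1000
  burn-in, thinning 5), chosen once as the smallest configuration whose
  Monte-Carlo error is negligible against the tolerances above; single-fit
  checks use the full default geometry.

## Known limitations

* The severance rule leaves the x–y contrast of multi-arm studies
  containing the split pair on the network side (partial severance); in
  networks dominated by such designs the "indirect" estimate retains some
  direct information.
* The index inherits every weakness of IF: imprecise direct or indirect
  estimates (single-study nodes, large tau) shrink the divergence and can
  mask true inconsistency — the masking test demonstrates the direction.
* The normal reduction of posteriors is conventional; heavy-tailed or
  skewed posteriors are only diagnosed, not handled, by the draw-based KL
  audit.
* One common tau across comparisons; no rare-event corrections; odds
  ratios only.
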