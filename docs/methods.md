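# Methods

## Data model

A panel is a genes × samples grid of quantification cycles (Ct). Ct is
log2-scale abundance: one cycle earlier means roughly twice the template,
so all arithmetic is additive on the Ct scale and multiplicative on the
linear scale. Amplification efficiency is fixed at 2 throughout; the
package targets designs without standard curves, matching how the four
stability applets treat pasted Ct tables.

Platform censoring is modeled with two numbers: a detection *threshold*
(default 27 cycles) above which a reaction is unreliable, and a detection
*limit* (default 28, roughly single-copy on OpenArray-class instruments)
used as the imputation floor. Preprocessing applies, in a fixed order:

1. **Presence calling** on the raw detections: a gene is absent in a
   condition when more than ⌊n/2⌋ of its n samples are above the threshold
   or missing (the two-of-three rule at n = 3). Presence is judged on the
   "beyond threshold" predicate, so calling it before or after flooring is
   equivalent; the pipeline calls it first to keep the report in raw cycles.
2. **Flooring**: missing values and values above the threshold are set to
   the limit. Idempotent.
3. **Candidate filtering**: a gene is retained for an analysis scope only
   if present in every condition of the scope. The spike-in channel is
   never a candidate but is carried along for the next step.
4. **Spike-in equalization**: sample j receives mean(spike) − spike_j,
   absorbing technical handling differences tracked by the exogenous
   spike. Floored values are shifted like any other value — the floor is an
   imputation, not a measurement, and keeping it fixed would destroy the
   within-sample differences downstream methods rely on.
5. **Global-mean equalization**: sample j receives
   grand mean − mean(candidate Ct in j), absorbing RNA-input differences.
   The spike is excluded from the means.

Both equalizations are per-sample additive shifts, so they change no
within-sample Ct difference: geNorm, ΔCt and NormFinder statistics are
invariant to them (this is property-tested), while BestKeeper — which
measures raw dispersion — is not, which is exactly why equalization must
precede it.

## Stability algorithms

All sample standard deviations use the n − 1 denominator; with three
donors per condition the estimator choice is material, so it is fixed
once, here.

**geNorm.** V_jk = SD over samples of (Ct_j − Ct_k); M_j = mean of V_jk
over remaining partners. The gene with the highest M is removed and M
recomputed until two genes remain. A gene's reported metric is its M at
removal; the final two genes both carry the final-round M, equal by
construction since each has only the other as partner — so the final pair
always shares rank 1. Exclusion ties remove the gene later in input order
(deterministic). Ranks are the competition ranking of the metric. The
V_n/V_{n+1} criterion for the optimal *number* of references is out of
scope.

**Comparative-Ct (ΔCt) method.** The same mean-pairwise-SD statistic
without stepwise exclusion; algebraically identical to every gene's
pre-exclusion geNorm M, which the tests assert to 1e−12 via an
independent pair-by-pair computation.

**NormFinder.** Ct values are treated as log-scale data y_ij under the
additive model y_ij = a_i + b_j + e_ij. Two-way residuals
r_ij = y_ij − ȳ_i· − ȳ_·j + ȳ_·· give raw per-gene variances
s²_i = Σ_j r²_ij/(n−1), which underestimate each gene's own variance
because every residual absorbs a share of all k genes' errors:
E[s²_i] = σ²_i(1 − 2/k) + Σ_l σ²_l / k². Summing over genes yields
Σ_i s²_i = (Σσ²)(1 − 1/k), so the total is estimated first and each σ²_i
solved and clamped at zero; the stability value is σ̂_i. This requires
k ≥ 3 (the 1 − 2/k factor degenerates at k = 2). In two-group mode the
per-gene intergroup difference d̂_ig is the gene's group-mean deviation
(after per-sample centering) relative to its overall mean, shrunk by the
empirical-Bayes factor γ̂²/(γ̂² + σ̂²_ig/n_g) with
γ̂² = max(0, var_i(d̂_ig) − mean_i(σ̂²_ig)/n_g) (ddof = 1 variance over
genes — the estimating equations do not fix the denominator; this is the
package's choice). The two-group score is the mean over groups of
|d̃_ig| + σ̂_ig/√n_g. The default mode is single-group for every scope,
including the merged one, matching how a user pastes one table into the
applet; two-group mode is available explicitly.

**BestKeeper.** Per gene: geometric and arithmetic mean, min, max,
SD(±Ct) and CV%. SD(±Ct) is the mean absolute deviation from the
arithmetic mean — the classical definition — with the n − 1 standard
deviation available as an option; ranking consumes SD(±Ct). The
BestKeeper index is the per-sample geometric mean over candidates, and
each gene's Pearson r against it is reported (undefined, reported as
missing, when the index is constant). Which dispersion an aggregator
website uses is not recoverable at two-decimal resolution; both give the
same rankings on the panels tested here.

## Comprehensive ranking

Each algorithm contributes a competition ranking (exact metric ties share
the minimum rank; the next rank is skipped). A gene's comprehensive score
is the geometric mean of its ranks; the final order sorts it ascending,
with ties broken by arithmetic mean rank and then input order. The
geometric mean is kept at full precision internally and rounded to two
decimals only for display. Dominance monotonicity (a gene at least as good
everywhere never aggregates worse) is property-tested.

## Quantification

RQ_s = 2^−[(Ct_tgt,s − Ct_ref,s) − (Ct_tgt,m − Ct_ref,m)] for milestone
sample m, so RQ_m = 1 exactly. Per-donor treated/control ratios are
RQ_t/RQ_c, identical to a direct within-donor 2^−ΔΔCt (asserted to
1e−12) and therefore independent of the milestone. Because the ΔCt inside
is a within-sample difference, per-sample equalizations never affect RQ.

Significance uses a two-sided one-sample t-test against 1 (two-sided is
the conservative default and the default of common GUI statistics
packages; sidedness is a documented choice, not a data-driven one),
optionally preceded by a two-sided single-outlier Grubbs screen
(G = max|x−x̄|/s; G_crit = ((n−1)/√n)·√(t²/(n−2+t²)), t the upper α/(2n)
t-quantile with n−2 df; at most one value is ever flagged, and the t-test
then runs on the reduced sample). The treated-vs-control report applies
the compound rule *mean fold ≥ 2 and p ≤ 0.05* by default.

## Synthetic panels

The generator draws Ct_{i,s} = baseline_i + offset_s + effect_i·[s
treated] + ε_{i,s}, with ε ~ N(0, noise_sd_i) — Gaussian on the Ct scale
(log-normal abundance), the error model all four algorithms implicitly
assume — plus a spike row spike_base + τ_s. Values beyond the threshold
are reported missing with probability ½ and floored at the limit
otherwise, exercising both censoring rules real exports produce. A seed
fully determines the output.

The default panel is 15 candidates + spike, 3 donors × {CTRL, SF},
baselines 12–26 cycles, sample-offset SD 0.5, spike-offset SD 0.3, with
designated roles:

| role | gene | noise SD | treatment effect |
|---|---|---|---|
| stable | miR-24-3p | 0.05 | 0 |
| unstable | miR-34a-5p | 1.5 | 0 |
| condition-shifted | miR-23a-3p | 0.10 | +1.2 cycles |
| responsive target | miR-193b-5p | 0.12 | −1 cycle (2-fold up) |
| near-limit (×3) | miR-22-5p, miR-29a-5p, miR-101-3p | 0.5 | 0 (baseline 27.5) |
| fillers (×8) | remaining panel | 0.30–0.80 | 0 |

The near-limit trio fails presence filtering, leaving 12 analyzable
candidates. The condition-shifted gene's +1.2-cycle effect makes it
competitive within each single condition but places it outside the top
five of the merged ranking while staying well clear of the unstable
gene's last place; filler SDs span the quality range a real panel shows.

What the generator does *not* emulate: correlated (co-regulated) genes,
donor-level random effects shared across conditions, preamplification
stochasticity and copy-number Poisson noise near the detection limit, and
efficiency differences between assays. Passing recovery tests therefore
demonstrate that the pipeline identifies stability structure under the
additive Gaussian model, not that any particular biological panel behaves
this way.

## Small-sample identifiability limits

Two honest limits of the 3 + 3 design are worth stating because the test
suite measures them:

* A gene's SD estimated from six samples has ~32% coefficient of
  variation (df = 5). The designated unstable gene's *realized* spread
  collapses below the noisiest filler in roughly a tenth of simulated
  panels, and the quietest filler overtakes the near-noiseless gene at a
  similar rate; the corresponding recovery rates over 100 seeded panels
  plateau around 85–90%, not higher, for any realistic filler
  configuration. Tightening all filler SDs into a narrow band raises
  those two rates a few points but destroys the ability of the
  comprehensive ranking to recover the *full* noise ordering (Spearman
  drops from ~0.81 to ~0.56), so the defaults keep the realistic spread.
* With a true effect of exactly 2-fold, the compound rule's "mean fold
  ≥ 2" clause sits on the decision boundary: its pass probability is ~½
  by construction (Jensen's inequality nudges the expected mean fold to
  ≈ 2.02). The misnormalization experiment therefore reports the SD
  inflation (median ≈ 10× with the unstable reference) as the robust
  readout, and the compound-rule pass rate as the knife-edge it truly is.

Problem sizes used by the test suite and the acceptance script — 100
simulated panels per recovery experiment, 100 random 12 × 6 matrices for
the ΔCt/geNorm identity, 50 random 5 × 8 matrices for the NormFinder
cross-check — are the package's standard verification sizes; they complete
in seconds.

## Numerical choices

* Pairwise-variation matrices are symmetrized explicitly and their
  diagonal zeroed, so V_jk = V_kj holds exactly, not just to rounding.
* NormFinder variance estimates are clamped at zero; clamps are logged at
  debug level, never raised.
* Ranking always happens on unrounded metrics; rounding is display-only.
* geNorm exclusion ties remove the gene occurring later in input order;
  aggregation ties fall back to arithmetic mean rank, then input order.
* Degenerate inputs fail loudly: zero-SD samples for the t-test, < 3
  genes for geNorm/NormFinder, non-positive Ct for BestKeeper's geometric
  mean, empty panels after filtering.
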