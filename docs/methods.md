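# Methods

This note documents the statistical model behind each pipeline stage, the
conventions adopted where several are in common use, what the synthetic
cohorts do and do not emulate, and the numerical choices that affect
results.

## Fold-change classification

Fold change at a DMR is the ratio of group-mean methylation fractions,
case over control. Records with a zero control mean or non-finite fold are
dropped (with a warning) before thresholding. Percentiles use linear
interpolation between order statistics — rank `h = (n−1)q/100 + 1` on the
sorted values — the default of mainstream numeric stacks. Class membership
is strict (`FC < P5`, `FC > P95`), so values tied with a threshold belong
to neither tail. With distinct values the tail size is exactly
`⌈0.05(n−1)⌉`: 42 at n=841, 1 at n=20. Classification requires at least
20 finite records; below that the 5% tails are degenerate and an error is
raised. Each DMR is a separate network node identified as
`gene@chrom:start`; multiple DMRs mapping to one gene symbol are not
collapsed, so tail counts equal node counts.

The orientation (case/control rather than control/case) makes genes
hypo-methylated in cases fall in the low tail, which matches how
hypo-/hyper-methylated loci are labelled at validation.

## Mutual-information estimation

Profiles are discretized per gene into `n_bins` equal-width bins spanning
that gene's own [min, max]; the default `n_bins = ⌈√n_samples⌉` (4 at 12
samples). Interior bin edges are right-closed — a value exactly on an edge
falls in the lower bin — and constant profiles occupy a single bin. MI is
the plug-in (maximum-likelihood) estimate from the joint frequency table,
in nats. This estimator returns exactly zero whenever the empirical joint
factorizes, which is what makes an `MI > 0` edge rule meaningful; a
tolerance of 1e-12 suppresses floating-point phantom edges. Self-pairs are
excluded; the matrix is symmetric with a zero diagonal.

With 12 continuous samples the empirical joint almost never factorizes
exactly, so synthetic networks are typically near-complete; how sparse a
real network is depends on the data and the coarseness of discretization.
The realized edge count, density and average MI are therefore surfaced as
manifest diagnostics rather than asserted. Whether MI should be estimated
across all samples or within one group is a genuine modelling choice; the
default uses all samples of the class matrix passed in, and callers can
restrict the matrix to one group.

Plug-in MI is biased upward at small n; for edge *ranking* within a fixed
n this bias is shared across pairs. k-NN/continuous MI estimators are out
of scope because they cannot return exact zeros.

## Topology conventions

Edges are unweighted for all distance-based statistics (diameters are
integers). Betweenness uses Brandes' algorithm with the undirected
unordered-pair convention, reported raw and normalized by
`(N−1)(N−2)/2`. Closeness is reported in two forms because the common
glossaries disagree: the raw sum of distances to reachable nodes
(farness) and the reciprocal of the mean distance (reachable count /
farness), the latter being the ranking default; for an isolated node both
are undefined. Degree heterogeneity is the coefficient of variation of
the degree distribution (population variance). The mean local clustering
coefficient counts nodes of degree < 2 as 0. Centralization is the
Freeman degree form scaled by `N/(N−2)`, exactly 1 for a star and 0 for
any regular graph. The shortest-path count is over *ordered* finite pairs
— the only convention under which a connected 42-node network yields
42·41 = 1722 — and the characteristic path length averages over the same
pairs. On disconnected graphs, diameter and path length are computed over
finite distances only and a connectivity flag is recorded.

## Candidate ranking

"Outstanding topological properties" is operationalized as the
lexicographic sort degree ↓, betweenness ↓, closeness ↓, node id ↑ — a
total order, hence deterministic across platforms and input orderings —
truncated to the top k (default 10). Degree leads because hub-ness is the
property of interest and the other centralities serve as tie-breakers.
The literature-screening step that narrows network candidates to a
validation panel is not computable; it enters as a user-supplied selected
list plus supplementary genes, each panel member tagged with its
provenance (network-LMG / network-HMG / supplementary).

## Phenotype association

Pearson r and Spearman rho (mid-ranks for ties) both use the two-sided
t-transform P value, `t = r√((n−2)/(1−r²))` on n−2 df. Each gene ×
phenotype pair is tested by both methods and an edge is emitted per
method that passes `P < α`; no combination rule is imposed. Filtering is
on raw P values by default, reflecting how such screens are commonly
reported at this scale; a Benjamini–Hochberg switch exists but is off by
default. Case-only variables (duration, CAS, TRAb) restrict the pair to
samples with observed values; pairs with fewer than three complete
observations or constant input are skipped with a warning.

## Validation statistics

Per locus: Welch t test (pooled available by flag, since group SDs are
explicitly unequal at the design locus); univariate logistic regression
of case status on percent methylation; and a multivariable logistic model
adding age and sex (F/M coded 0/1). Coefficient P values are two-sided
Wald. Fitting is Newton maximum likelihood (equivalent to iteratively
reweighted least squares), tolerance 1e-8, at most 100 iterations.
Perfect or quasi-separation — surfaced by statsmodels as a warning, a
singular information matrix, or a non-intercept coefficient exceeding 50
in magnitude — is raised as an explicit `SeparationError`; the intercept
is exempt because it is legitimately large with uncentered percent-scale
covariates. In `validate_panel`, a failing locus is reported with missing
P values and an error note rather than aborting the panel; with a very
strong injected effect a small fraction of replicates genuinely separate
and are counted as non-detections. Baseline sex comparison is the
Pearson chi-square without continuity correction — with Yates' correction
the 2×2 counts 23/25 vs 11/13 would not reproduce the reference P of
0.867 (they give it exactly as 0.8674 without).

The sample-size computation finds the smallest n per arm at which the
two-sided two-sample t test reaches the target power, with noncentrality
`δ/√(σ₁²/n₁ + σ₂²/n₂)` and `n₁+n₂−2` degrees of freedom, searched
incrementally from n=2. At the design point (δ=12.86, σ=3.30/10.76,
α=0.05, power 0.90) this gives n=10 (power 0.927 at 10, 0.896 at 9). A
normal-approximation formula would give ~9; the t-corrected search is
used because small-n designs are exactly where the correction matters.
The analytic form corresponds to the pooled statistic; the Monte-Carlo
power check (`simulate_power`) shows Welch gives slightly less power at
unequal variances (≈0.90 vs 0.92 at n=10), both consistent with a
90%-power design.

## Synthetic cohorts: what they emulate, and what not

**Discovery generator.** Per-site background methylation is Beta(2, 2)
(clipped to [0.02, 0.98] to keep logits finite); per-sample values are
inverse-logit of the site logit plus N(0, noise_sd²) noise, so every
value lies in [0, 1] by construction. Exactly `round(0.05·n)` sites get a
negative logit-scale case shift and the same number a positive one; shift
magnitudes are Gamma(4, eff/4) (mean `effect_log_fold` = 1.5, little mass
near zero so affected sites reliably populate the tails). Defaults
(noise_sd = 0.3, Beta(2, 2)) were chosen once as a realistic bimodal
methylation landscape with clearly separated but not degenerate tails.
The DMR-table P value is a Welch t test on per-sample fractions — any
monotone-in-effect P value suffices here because upstream DMR calling is
out of scope. An optional `missing_rate` knob produces incomplete
matrices; the default cohort is complete, since the original missingness
mechanism is not derivable.

Not emulated: read-level bisulfite data, CpG context, genomic structure
(positions are synthetic integers), and — deliberately — co-methylation
between affected sites, so the generator does not reproduce one class
having systematically higher network MI than the other. Consequently,
passing tests demonstrate correctness of the *procedure* (classification
counts, estimator identities, calibration), not that real LMG networks
are denser than HMG networks.

**Phenotype generator.** Group-specific normals matched to published
baseline moments (case age 46.0 ± 11.4 vs control 43.4 ± 5.5; male
fractions 23/48 and 11/24; height/weight/SBP/DBP likewise); BMI derived
from height and weight; duration Gamma with mean 9.7 months; CAS a
rounded normal (3.0 ± 0.8) clipped at 0; TRAb log-normal matched to
median 4.50 and IQR 1.69–9.64. Duration, CAS and TRAb are missing for
controls (whose TRAb sits below the 1.75 U/L detection limit).

**Validation generator.** Per-locus truncated normals on [0, 100]
percent; zero SD degenerates to the group mean exactly. The default
9-locus panel carries: one hypo locus at the power-design point
(Δ=−12.86, case SD 3.30, control SD 10.76 — which group has which SD is a
modelling choice; the smaller SD is assigned to cases), two hyper loci of
similar standardized effect, four moderate hyper effects, and two null
loci. All randomness descends from one integer seed via deterministic
sub-streams.

## Reproducibility and problem sizes

The pipeline manifest records config, realized thresholds, stage counts
and SHA-256 hashes of every TSV; identical config + seed give identical
hashes (floats are written at 10 significant digits). The test suite
exercises the estimator-vs-oracle equivalences on all non-isomorphic
graphs with ≤ 6 nodes plus 200 random ≤ 8-node graphs, MI on hundreds of
tiny label vectors against an exhaustive joint-table oracle, power at the
design point with 10⁴ Monte-Carlo replicates, detection with 200 seeded
validation-cohort replicates, and type-I calibration with 10³ null
replicates (t-test route) and 3·10² (adjusted-logistic route) — sizes
chosen so the binomial error on a 5% rate is a small fraction of the
rate while the whole suite stays interactive.

## Known limitations

- Plug-in MI with ⌈√n⌉ bins on a dozen samples yields near-complete
  networks; the observed sparsity of real co-methylation networks is not
  reproduced, only accommodated (any edge count is handled downstream).
- The logistic separation threshold (|slope| > 50) is a heuristic;
  extremely strong true effects on the percent scale can trip it, and
  those replicates are reported as errors rather than P values.
- The generator draws sites independently; long-range co-methylation,
  batch structure and cell-composition effects in blood are absent.
- Closeness of nodes in small disconnected components is computed within
  the component and can exceed that of more central nodes in the giant
  component; rankings on disconnected networks should use degree-led
  ordering (the default) for that reason.
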