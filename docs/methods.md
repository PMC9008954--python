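# Methods

This note documents the statistical model behind `diffregnet`, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## Data model

The input is a genes × samples matrix of log2-scale expression values with
a two-level condition label per sample (called A and B below; in a cancer
study, normal and tumor). Both conditions need at least three samples;
duplicate gene rows (several probes per gene) are collapsed by arithmetic
mean at load time, and missing values are rejected rather than imputed —
the correlation and regression machinery assumes complete data. The second
input is a candidate TF→target prior (directed pairs); it defines the
search space of the network inference and is the only place where
regulator identity enters.

## Differential co-expression

Pearson correlations are computed per unordered gene pair within each
condition. A pair *qualifies* when `max(|r_A|, |r_B|)` reaches the
`(1 − q_keep)` quantile of that magnitude over all pairs (default
`q_keep = 0.25`, i.e. the strongest quarter; ties at the threshold are
kept). Genes with zero variance in either condition are flagged and their
pairs can never qualify.

**DCp.** For gene i with qualified partners j,
`dC_i = sqrt(Σ_j (r_A,ij − r_B,ij)² / n_i)`. Significance comes from
permuting the condition labels (default 100 permutations, seeded) and
recomputing the statistic *on the same qualified pair set*; the per-gene
FDR is the pooled null exceedance count divided by the number of
permutations and by the observed exceedance count, clipped to [0, 1] and
made monotone in the statistic (the usual q-value construction). The
label permutation is implemented by permuting the label vector, which
makes the estimate exactly invariant under swapping the two conditions,
including for unbalanced designs.

**Calibration caveat.** Freezing the qualified pair set before permuting
is anticonservative when the qualified set is dominated by pairs that
qualified *by chance*: qualification selects extreme sample correlations,
and permutations cannot reproduce that selection. On data with genuine
co-expression structure (correlated modules — which is what expression
data look like, and what the generator produces), qualified pairs are
mostly structural, and the measured false-positive rate at FDR < 0.05 is
at or below nominal (0–5% on the multivariate-null fixtures in the test
suite). On large panels of completely unstructured noise the estimator
breaks down and can call everything significant; do not use the DCG list
as a standalone discovery on data with no co-expression structure. In the
pipeline the DCG step acts as a permissive pre-selection; specificity is
carried by the regulator prefilter and the stepwise selection that follow.

**Modified LFC link screen.** Per qualified pair,
`f = |ln((|r_A| + eps) / (|r_B| + eps))|` (default `eps = 0.001`) and
`m = max(|r_A|, |r_B|)`. Pairs whose correlations switch sign with both
magnitudes ≥ 0.25 are flagged `switched` directly. The remaining pairs are
split into `bins` equal-count bins by m (default 20); the 0.9 quantile
(`env_q`) of f in each bin defines an envelope point, a decreasing power
law `f̂(m) = a·m^b` is least-squares fitted to the usable envelope points
in log–log space, and a pair is flagged iff `f > f̂(m)`. When fewer than
two envelope points are usable (e.g. f is mostly exactly zero) the filter
degrades to a global `env_q` quantile threshold on f. Binning follows a
canonical `(m, f)` ordering, so the result is invariant to the input pair
order.

## Condition-specific GRNs

For each DCG target and each condition separately:

1. **Prefilter** — candidate regulators are the target's prior TFs with
   `|Pearson r| ≥ r_min` in that condition (default 0.25), ordered by |r|
   descending and truncated to `max_candidates` (default 10).
2. **Stepwise selection** — target and candidates are z-scored within the
   condition (sample SD, ddof 1), removing the need for an intercept and
   making coefficients comparable across conditions. Classical
   bidirectional stepwise regression: a candidate enters when its
   partial-F p-value is below `alpha_enter` (default 0.05; ties broken by
   prefilter order) and a selected term leaves when its removal p-value
   exceeds `alpha_remove` (default 0.10), up to `max_steps` (50)
   iterations. Rank-deficient additions are skipped with a log message; a
   perfect fit stops further entry. The final-model least-squares
   coefficients of the selected TFs are the regulation efficacies; exact
   zeros are never stored.

Because efficacies are standardized coefficients, they are dimensionless
and directly comparable between the two networks — the property the
differential-regulation statistics rely on. Standardized magnitudes
substantially above 1 can still occur under collinear regulators.

## Differential regulation

* **DR (per gene).** `DR_i = sqrt(Σ_{j=1}^{n} (X_ij − Y_ij)² / n)` where j
  ranges over the union of gene i's incident links in the two networks —
  distinct *directed* edges, incoming and outgoing, with links absent from
  one network contributing efficacy 0. (Reciprocal links, if both
  directions were ever fitted, count as two entries; the directed
  TF→target prior makes this a non-issue in practice.) Genes isolated in
  both networks have no defined DR and are excluded. The ranked table
  breaks ties lexicographically by gene ID and flags the top 1% (only
  among genes with DR > 0).
* **DRL (per link).** The absolute efficacy change `|X − Y|` over the
  union link set, ranked descending. The same envelope filter as the LFC
  screen (on efficacy magnitudes instead of correlations) marks detected
  links; ranking and detection are deliberately decoupled, and with fewer
  candidate links than bins the envelope is skipped and every link passes,
  with a logged notice.
* **TDR (per regulator).** The Jaccard distance between the TF's target
  sets in the two networks: 0 for identical sets, 1 for disjoint ones.

## Topology

Directed-network centralities admit several conventions; the package fixes
these: in-/out-degree on the directed graph, with the summary means
defined as links / #target-role nodes and links / #TF-role nodes (so the
mean–count identities hold exactly); unnormalized betweenness on the
directed graph; clustering coefficient on the undirected projection (the
TF→target graph is nearly bipartite, so directed triangles are rare);
closeness of a node as (#nodes reached) / (sum of directed shortest-path
distances), 0 when it reaches nothing. Per-metric comparisons use the
two-sided Wilcoxon rank-sum test: exact null when the combined sample is
≤ 20 without ties, otherwise the normal approximation with tie correction
and no continuity correction (so identical distributions give p = 1
exactly).

## Synthetic data generator

The generator emulates a two-group transcriptome study driven by linear
TF→target regulation:

* TF expressions are i.i.d. standard normal across samples (regulators are
  exogenous — they are not themselves regulated, matching the regression
  model's assumption and avoiding feedback identifiability questions).
* Each target is `Σ_k c_k · TF_k + N(0, noise_sd²)`; genes with no
  regulator are pure noise. Values are centered log-scale expression;
  correlation- and z-score-based inference is scale-free, so no baseline
  offset is added.
* Condition B rewires a fraction of condition A's links
  (`rewire_fraction`, default 0.3) by dropping, sign-flipping or adding
  links; all other coefficients are identical between conditions.
* The emitted prior is the union of both conditions' true links plus
  `decoy_prior_fraction` (default 0.5) random non-links, so prior
  contamination is part of the recovery problem.
* Ground truth records raw planted coefficients, their standardized
  counterparts (raw coefficient × SD(TF)/SD(target) on the generated
  data — the scale on which efficacies are estimated), the rewired link
  and gene sets, and the decoys.

Defaults: 300 genes of which 15 TFs, 8 targets per TF, 60 samples per
condition, `noise_sd = 0.5`, effect magnitudes uniform in ±[0.75, 2.0]
(log2 units per TF standard deviation — the strong regulation typical of
validated TF–target pairs), at most 2 regulators per target. The regulator
cap keeps the weakest marginal TF–target correlation above the prefilter
floor of 0.25, so planted links remain identifiable by design; real
networks with many weak combinatorial inputs are harder than this
benchmark. Other features of real data the generator does not emulate:
probe/batch effects, count noise, mean-expression shifts between
conditions (the synthetic study has essentially no differentially
*expressed* genes — it is a differential-*regulation* study), unbalanced
group sizes, and TF protein activity differing from TF mRNA level.
Passing the recovery tests therefore demonstrates correctness of the
machinery under its own model assumptions, not performance on microarray
data.

Problem sizes used in the test suite and the acceptance script (three to
five seeds of the 300-gene default study, 100 label permutations, 500
rank-sum replicates) were chosen so the full suite completes in well under
a minute while keeping Monte-Carlo error comfortably inside the asserted
margins.

## Evaluation harness

`evaluate_recovery` scores a ranked DRG or DRL table against the planted
truth: precision@k over the ranked list, and AUROC as the exact
probability that a random rewired item outranks a random non-rewired item
(ties count 0.5). When the full item universe is supplied, items missing
from the ranking are placed in a single tie below every ranked item — so
failing to rank a rewired gene costs AUROC rather than silently dropping
out of the evaluation.

## Numerical choices and degenerate inputs

* FDR monotonization takes, per item, the minimum raw FDR over items with
  smaller-or-equal statistic; tied statistics share one value.
* The SAM fudge constant `s0` defaults to the 5th percentile of the
  per-gene pooled standard errors — a deterministic stand-in for the full
  quantile-tuning procedure; `s + s0 = 0` with unequal group means raises
  an error asking for a positive `s0`.
* Permutation counts below 50 are rejected for the DCp FDR (the estimate
  is too coarse to be meaningful).
* Zero-variance genes: excluded from candidate lists, their pairs
  unqualified, their targets skipped (all logged).
* Network edge lists are written with `repr` floats, so write→read round
  trips are bit-exact.
* Every source of randomness flows through explicit integer seeds; the
  pipeline derives per-stage seeds from the single config seed, and two
  runs with the same config produce byte-identical outputs.

## Known limitations

* Stepwise selection inherits the classical caveats: with contaminated
  priors and α_enter = 0.05, roughly 5% of spurious candidates that
  survive the correlation prefilter will enter; exact support recovery is
  only guaranteed when the candidate set is clean (the test suite checks
  both regimes).
* The DCp permutation FDR is anticonservative on data without genuine
  co-expression structure (see the calibration caveat above).
* Efficacies are linear, within-condition, and mRNA-level; post-
  transcriptional regulation, saturation and feedback are out of scope.
* The LFC envelope's power-law fit needs a spread of magnitudes; with
  degenerate magnitude distributions it falls back to a global quantile
  threshold, which is coarser.
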