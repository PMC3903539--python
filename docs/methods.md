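# Methods

This note records the models, conventions and numerical choices behind
`fmcm`, including the points where the design was genuinely open and a
decision had to be made.

## Statistical model and procedure

**Differential expression.** The moderated statistic is
*d* = (x̄_case − x̄_control)/(*s* + *s₀*), with *s* the pooled gene-specific
standard error and *s₀* a fudge factor that stabilises *d* for low-variance
genes. *s₀* is chosen deterministically from the candidate percentiles
(0, 5, …, 95) of the *s* distribution as the value minimising the
coefficient of variation, across *s*-quantile windows (100 windows, fewer
when there are under 500 genes), of the windowed median absolute deviation
of *d*. Intensities are assumed log2-scale; fold change is reported on the
linear scale as 2^(mean difference), and "FC > 2" always means FC > 2 or
FC < 1/2, so both directions are selected symmetrically.

The FDR is a permutation estimate: *q*(g) = median over permutations of
\#{|d\*| ≥ |d(g)|} divided by \#{observed |d| ≥ |d(g)|}, clipped to [0, 1]
and monotonised by a running maximum down the |d|-ranked list. The
monotonisation guarantees that DEG sets are nested across thresholds, which
the module-shrinkage behaviour (and any fold-change sweep) relies on. When
the cohort is paired, permutations are within-subject label swaps (sign
flips); otherwise full label permutations. No π₀ correction is applied.
Default 1,000 permutations.

**Edge statistics.** Pearson *r* over the condition's samples; the edge
*p*-value defaults to the closed-form two-sided *t* transform on *n*−2
degrees of freedom. A seeded permutation *p* (≥1,000 sample shuffles) is
available as an opt-in dialect; on well-behaved data the two agree closely
(tested), so the closed form is the default for speed and determinism.
Zero-variance genes cannot be correlated and their pairs are skipped with a
log notice.

**Clustering coefficient.** *C* = 2·(edges among neighbours)/(*k*(*k*−1)),
and *C* = 0 when *k* < 2. The *k* < 2 case is undefined in the standard
formula; defining it as 0 keeps the trend-filter comparisons total.

**Conditional enrichment.** Terms are tested leaves-upward through the
annotation DAG. Before testing a term, genes annotated to any
already-significant descendant are removed from the term's (propagated)
gene set and from the universe, then the hypergeometric upper tail
P(X ≥ k) is computed. A parent is therefore only reported when it adds
signal beyond its significant children. The universe is the set of genes
present in the expression matrix that carry at least one annotation; the
significance level defaults to α = 0.01 with no multiplicity correction
beyond the conditioning.

**Trend filter.** The comparison uses non-strict inequalities with at
least one strict. With only two conditions and many *C* = 0 ties,
requiring strict increase on both metrics would empty most modules; ties
on one metric with a strict move on the other still count as a trend. A
gene absent from one condition graph scores (0, 0) there, which makes the
comparison total while presence in at least one graph is still required.

**Connectivity score.** For tag positions V(1..t) in an n-gene ranking:
a = max_j(j/t − V(j)/n), b = max_j(V(j)/n − (j−1)/t), ks = a if a > b else
−b; the a = b tie resolves to −b. Signed queries: s = ks_up − ks_down when
the two signs differ, else 0; single-list queries use s = ks_up or
s = −ks_down so that positive s always means the instance mimics the
query. Drug-level ES is the same KS statistic applied to the drug's
instance positions in the s-descending instance ordering, ties broken
lexicographically by instance id for determinism. Module queries are split
into up/down tag lists by DEG direction — the scoring convention requires
signed tags, and the DEG direction is the only direction the pipeline
carries.

**Randomization p.** The null draws uniform same-size instance sets and
computes their ES in the same ordering; p = (1 + \#{same-sign |ES\*| ≥
|ES|})/(1 + n_perm), add-one smoothed so p is never 0. Because a uniform
random t-subset of n positions does not depend on the observed ordering,
the null sample is cached per (t, n) and shared across drugs and queries —
an exact reformulation that makes 10,000-draw nulls essentially free.
Under the null, p is uniform on each sign's tail (≈(0, ½) per tail), which
the calibration test checks on the doubled scale.

**Classification.** Beneficial: ES < −0.5 **and** p < 0.005. Harmful:
ES > 0.3 with no p gate — the asymmetry is deliberate: a harmful call only
needs to veto a drug, not nominate it.

**Compounds.** "Minimum set of purely beneficial drugs covering all
functions" is implemented as **exact cover** — component beneficial-module
sets pairwise disjoint, union equal to the full module set — not merely
minimal set cover; overlapping covers would double-treat functions, and
every published degree-ratio partition sums exactly to the module count.
The per-component filter requires *every* beneficial link of a component
drug at or below −0.75 (configurable). Interchangeability classes merge
drugs whose beneficial coverage is identical and of size ≤ 2; a class may
hold a single drug (it then just names the coverage), while broader drugs
always stay individual named components. The drug *degree* counts all FDAM
links, beneficial and harmful alike. Enumeration is a depth-first exact
cover search branching on the first uncovered module; it is checked against
a powerset brute force up to 12 slots.

**Evaluation.** NB/NA are predicted beneficial/harmful counts, TP/FN the
known anti-tumor agents among them, TN = NA−FN, FP = NB−TP; accuracy =
(TP+TN)/(NB+NA), specificity = TN/(FP+TN); zero denominators yield
"undefined" (None), never 0. Reproducibility between two selected drug sets
is |A∩B|/√(|A|·|B|). The subsampling protocol repeats the procedure 10
times on random 20+20 subsamples (sampling subjects, both arms, when the
cohort is paired) and reports all 45 pairwise values. The module screen's
per-run selection is its set of (module, drug) non-neutral decisions,
compared module-wise and averaged; the whole-signature baseline is compared
per fold-change level and averaged — the harmful side of these sets is not
p-gated, consistent with the classification rule. Both procedures run on
the *same* subsample draws so the comparison is paired.

**Whole-signature baseline.** One signed query per fold-change threshold
(default grid 3.0–5.0 in 0.5 steps) using the full DEG lists; lists longer
than 1,000 genes per direction are truncated to the top-|d| 1,000,
mirroring the query-length limit of rank-library services.

## Synthetic scenario (the study conditions)

The default scenario emulates a paired 32-subject cohort on a 2,000-gene
array: eight 40-gene modules named by the eight disease functions, planted
|log2 FC| = 2 (linear FC = 4, comfortably above the FC > 2 selection
threshold at this cohort size), alternating up/down direction. Co-expression
comes from one shared latent factor per module per condition — SD 1.0 in
the condition matching the module's direction of dysregulation, 0.45 in the
other — over per-gene subject baselines (SD 0.3) and residual noise
(SD 0.55), giving within-module correlations of roughly 0.7 (dense arm)
vs 0.35 (sparse arm), i.e. mostly above and below the *p*₀ = 0.001 edge
threshold at n = 32. The factor is centred within each condition so the
planted fold change is exact. The interaction layer contains each
within-module pair with probability 0.2 plus Erdős–Rényi background at
0.002; the ontology is a three-level DAG whose leaves are the modules plus
four 50-gene decoy terms.

The library holds 200 drugs × 3 instances: 30 signature-reversing drugs,
30 mimics, 140 nulls. Rank profiles sort a planted score plus standard
Gumbel noise (noisy-sorting model: effect strength maps smoothly onto rank
displacement). Planted drugs carry full strength 4 on their target
module(s) — two reverse drugs are deliberately broad (three and two
targets) so exact covers within six components exist — plus a mild
whole-signature effect at strength 1 (¼ of full) on every module. The mild
global term reflects that one disease's module signatures are correlated:
a drug reversing one module mildly reverses the rest. Without it, the
3-instance drug-level KS null is wide enough that nearly every true
reversal drug would pick up a spurious harmful link (ES > 0.3 carries no p
gate) on some non-target module, and no purely beneficial drugs would
survive — a small-library artifact, not a property of the method.

What the generator does *not* model: batch effects, probe saturation,
annotation errors, inter-module gene overlap, and dose/cell-line structure
within a drug's instances. Passing tests therefore demonstrate the
machinery and its calibration, not robustness to array artifacts.

## Problem sizes used in the checks

The bundled worked example (46 drugs, 8 modules) runs in milliseconds.
Planted-recovery statistics average 5 scenario seeds; the reproducibility
comparison uses the 10-run/20+20 protocol (45 pairs) with 1,000 SAM
permutations per run and a shared 10,000-draw connectivity null; oracle
checks cover rankings up to n = 50 and slot sets up to 12. These sizes keep
a full reproduction run in the minutes range on a single CPU while leaving
every statistic well away from its decision boundary.

## Known limitations

* Thresholds (p₀, FDR, FC, ES cut-offs) are fixed, not data-adaptive; no
  multiplicity correction is applied across the many edge tests (a fixed
  p₀ plays that role) or across modules.
* The SAM variant here does not reproduce the original software's
  asymmetric delta-band cutoffs; q-values follow the permutation estimator
  above.
* The module term list is configuration, not inference: the pipeline
  reports enrichment for any term, but which terms become modules is the
  analyst's choice (default: the eight disease functions).
* Drug–drug interactions within a compound are outside scope; a compound
  is a coverage statement, not a dosing recommendation.
* With very few instances per drug, drug-level ES is coarse (|ES| ≥ 1/t
  granularity) and the harmful call (no p gate) is noisy; the purely
  beneficial filter inherits that noise.
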