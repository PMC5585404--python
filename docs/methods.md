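# Methods

## The analysis model

The package implements a comparative transcriptome-mining procedure for
direct cell-conversion (transdifferentiation) studies. The unit of input is
a *dataset*: one expression experiment contrasting origin cells (e.g.
fibroblasts) with the converted target cells, as a genes × samples matrix of
pre-normalized linear-scale intensities. A *conversion* (e.g. fibroblast →
endothelial cell) may be carried by one or several independently produced
datasets, and a *study* is a panel of conversions — the canonical layout is
five fibroblast-derived conversions carried by nine datasets (1, 1, 3, 1, 3).

The stages are:

1. **Per-dataset differential expression.** For each gene, the linear fold
   change is the ratio of target-group to origin-group mean intensity
   (group means floored at a pseudocount of 1e-6 × the global matrix median
   before division, so ratios are finite on sparse data). Significance comes
   from a two-sample t-test on log2 intensities; a gene is called *up*
   (*down*) when p < 0.05 and its log2 fold change is positive (negative),
   *none* otherwise. When either group has a single sample the test is
   undefined; such datasets fall back to a fold-change-only call at
   |FC| ≥ 1.5 (`single_sample_mode="fc_only"`), because published conversion
   panels contain 1-vs-1 experiments and still report DEGs for them. The
   strict alternative never calls untestable genes. No per-dataset
   multiple-testing correction is applied: robustness is delegated to the
   cross-dataset votes below, which is the design the raw p < 0.05 threshold
   belongs to.

2. **Within-conversion consensus.** Conversions with several datasets merge
   their calls by a vote: a gene is a conversion DEG when at least
   n − 1 of its n datasets agree on a direction and no dataset shows the
   opposite one (the 2-of-3 and 3-of-4 patterns). Single-dataset conversions
   pass their calls through. The merged fold change reported for a gene is
   the geometric mean of the per-dataset fold changes over the datasets that
   support the consensus direction — the geometric mean is the natural
   average of ratios and reduces to the single dataset's value for
   single-dataset conversions.

3. **Cross-conversion common signature.** Genes with the same direction in
   at least 8 of the study's 9 datasets form the common signature; a strict
   tier additionally requires every supporting dataset to reach |FC| ≥ 1.5.
   Whether an *opposite* call in the one dissenting dataset is tolerated is
   configurable; the pipeline default rejects it. With the tolerance on, a
   gene regulated one way in a single-dataset conversion and the opposite
   way everywhere else satisfies the 8-of-9 count and is indistinguishable
   from a genuinely common gene — exactly the pattern conversion-specific
   genes produce — so the no-opposite default keeps the common and specific
   signatures disjoint by construction.

4. **Conversion-specific signatures.** A gene is specific to a conversion
   when (a) it is a conversion DEG there, (b) at least `min_opposite` of the
   other conversions' datasets show the *opposite* direction, and (c) at
   most `max_identical = 2` show the identical one — the exception tolerance
   that absorbs occasional cross-reacting datasets. Uncalled (none) datasets
   count toward neither bound, and `min_opposite` defaults to
   n_other − 2 (7 of 9 others in the canonical layout). The two bounds are
   not additive: requiring 7 opposite among 8 others while tolerating up to
   2 identical is satisfiable (7 opposite + 1 identical), so feasibility
   only requires `min_opposite ≤ n_other`. The fold-change gate (1.5)
   applies to the target conversion's supporting datasets.

5. **Regulatory networks.** A TF→target database (gene sets derived from
   protein–DNA binding experiments, carried as GMT) is queried with each
   conversion's DEG list. Per TF, enrichment is the one-sided upper-tail
   hypergeometric probability P(X ≥ overlap) with population
   N = |database universe ∩ measured genes|, successes K = |regulon ∩
   universe| and draws n = |DEGs ∩ universe|. TFs with raw p < 0.05 that are
   themselves conversion DEGs with |FC| ≥ 1.5 are the DE-TFs (a
   Holm-adjusted column is emitted alongside for reference, but the gate
   uses the raw p, matching how binding-site databases are conventionally
   queried). The GRN has an edge from each DE-TF to each of its regulon
   members in the DEG list (self-loops only when the TF is itself a DEG);
   the core network keeps only DE-TF → DE-TF edges. Hubs are ranked by
   out-degree, descending, ties broken alphabetically and sharing the
   minimum rank.

6. **Term enrichment.** Ontology-style term sets are tested two-sidedly:
   p = min(1, 2·min(upper tail, lower tail)) — the doubling convention; a
   minimum-likelihood variant (sum of all outcome probabilities no larger
   than the observed one, ties included) is available as
   `method="minlike"` for sensitivity checks. P-values are corrected with
   the Holm (Bonferroni step-down) procedure across all terms of one
   database per query list, and terms with *adjusted* p < 0.05 are flagged —
   the correction is named, so the threshold is applied to the corrected
   value.

7. **Clustering.** Similarity between expression profiles is the uncentered
   correlation Σxy/(‖x‖‖y‖) (cosine; no mean-centering), so profiles
   differing by a positive scale factor are identical. Agglomeration is
   average linkage on d = 1 − similarity, implemented with Lance–Williams
   updates and a deterministic tie-break (smallest node-index pair), on both
   the gene and the array axes of the common-signature log2 fold-change
   matrix. Log2 fold changes, not raw intensities, are the default input
   because the object of interest is the up/down pattern across datasets.
   Outputs are TreeView-compatible CDT/GTR files.

## Choice of the two-sample test

The test statistic is configurable (`DEThresholds.test`). The default is
Student's equal-variance t: the two groups of a conversion dataset are
replicate arrays from the same platform and experiment, for which a shared
noise variance is the standard assumption, and under the simulation model
below the statistic is exactly t-distributed with n₁+n₂−2 df. Welch's
unequal-variance test is available, but at 2–3 replicates per group its
Satterthwaite df estimate is itself noisy (df ≈ 2–4 instead of 4), which
costs about six points of per-dataset power at the default effect size —
enough to visibly erode an 8-of-9 consensus. Neither choice affects the
fold-change computation.

## The synthetic-study generator

`convmine.simulate` produces studies with planted ground truth:

- **Baseline**: per dataset, each gene draws a log2 baseline mean from
  N(7, 2²) — typical log-intensity location and spread for normalized
  arrays. The baseline is shared by both groups, so it cancels from every
  contrast.
- **Noise**: i.i.d. Gaussian on the log2 scale per sample, s.d. 0.5
  (log-normal linear intensities) — a standard array noise model.
- **Common signature**: 20 up + 25 down genes shifted by ±2 log2 units in
  the target group of *every* conversion.
- **Specific signatures**: 15 genes per conversion, shifted by their sign in
  the home conversion and the *opposite* sign everywhere else, so the
  opposite-pattern branch of the specificity rule is exercised rather than
  trivially satisfied by absent signal.
- **Regulons**: one planted master TF per conversion whose regulon (80
  genes) draws 60% of its members from the conversion's planted
  differential genes, the rest from never-planted genes; the TF itself is
  planted differential (|log2 FC| = 2) in its home conversion so it passes
  the DE-TF gates. Decoy TFs have regulons drawn entirely from unplanted
  genes and no expression change.
- **Term database**: one term per planted signature (its genes plus five
  random padding genes) and uniformly drawn decoy terms.
- **Layout**: five conversions carried by (1, 1, 3, 1, 3) datasets — nine in
  total — with 3 replicates per group and 5 000 genes; runs in ~2 s.

Identical seeds give bit-identical studies. What the generator does *not*
emulate: platform-specific artifacts (probe saturation, background,
batch effects), correlated noise between genes, heteroscedasticity across
intensity, partial effect penetrance, and mixed-platform gene coverage.
Passing recovery tests therefore demonstrates the pipeline's statistical
logic under its own model assumptions, not performance on real array
panels, where per-dataset power is lower and gene universes are ragged.

Recovery on these studies behaves as designed: with zero noise every stage
reproduces the planted truth exactly; at the default noise the common
signature is recovered with F1 ≈ 0.94 in expectation (per-dataset call
power for planted genes is 0.948, and an 8-of-9 agreement demand is steep —
single realizations range roughly 0.89–0.98), specific signatures with
F1 ≈ 0.93–0.97, and every planted master TF ranks first among its
conversion's hubs.

## Numerical and degenerate-input conventions

- Zero-variance genes with equal group means produce NaN from the t-test
  and are mapped to p = 1 (no evidence); unequal means with zero variance
  give p = 0. This makes the noiseless limit exact rather than undefined.
- Genes with zero-norm profiles are rejected by the clustering metric
  (callers drop them with a warning).
- Votes where both directions qualify (possible only when
  min_same ≤ n/2) return none and are logged; the voting scheme does not
  contemplate ties.
- All writers sort their records and use fixed float formats, so identical
  config + seed yields byte-identical artifacts (checked via SHA-256 in the
  run manifest).
- Gene symbols are uppercased on ingest so mouse and human symbols (Gata4 /
  GATA4) unify for cross-species comparisons; duplicate symbols
  (multi-probe genes) are collapsed by row mean, with a logged warning — the
  collapse rule is a documented package choice.

## Known limitations

- The fold-change-only path for 1-vs-1 datasets has no error control; its
  calls are as noisy as single-replicate arrays are.
- The specificity rule's denominator is reported differently in different
  descriptions of such workflows (7 of 8 vs 7 of 9 other datasets);
  `min_opposite` is therefore explicit and configurable rather than
  hard-wired.
- TF enrichment inherits the regulon database's universe definition; with
  sparse databases the universe intersection can make p-values
  optimistic.
- Out-degree is the only centrality implemented — it is the stated hub
  criterion — and no betweenness/closeness alternatives are offered.
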