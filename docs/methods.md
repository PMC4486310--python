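# Methods

## The analysis model

`mirmint` implements a paired-platform integration analysis for a
two-condition (CD99-transfected vs parental osteosarcoma cells), three-time-point
(days 0/7/14 of osteoblast differentiation), two-replicate microarray design:
12 arrays per platform, already normalized and log2-transformed.  The pipeline
follows the standard flow of this family of studies:

1. **Probe filtering.**  Probes whose raw intensity (`2**log2`) is ≤ 100 in at
   least 75 % of samples are removed, then probes whose IQR of log2 signal is
   ≤ the median IQR.  All three boundaries are inclusive, exactly as such rules
   are conventionally stated.  The median of IQRs is computed over the probes
   that survive the intensity filter (the filters are applied in the order
   listed); computing it before the intensity filter would be an equally
   defensible convention, but one had to be fixed.  The quartile convention is
   linear interpolation between order statistics ("type 7"), fixed so tests can
   be exact.  miRNA matrices get the same intensity rule (threshold
   configurable, default 100); the IQR filter is off for miRNAs by default.

2. **Differential expression.**  One linear model per feature over the six
   (condition × day) cells, pooling the residual variance with
   `d_g = 12 − 6 = 6` degrees of freedom, rather than three separate 2-vs-2
   fits (which would leave only 2 df each).  Per-feature variances are shrunk
   by empirical Bayes: `(d0, s0²)` are moment-matched on `log s_g²` through the
   digamma/trigamma closed forms, with a Newton inversion of the trigamma
   function (tolerance 1e-8); the moderated statistic is
   `t = logFC / (s̃ √(1/n₁+1/n₂))` with `s̃² = (d0 s0² + d_g s_g²)/(d0+d_g)` on
   `d0 + d_g` df (capped at the pooled total).  The implementation is checked
   against Bioconductor limma (`lmFit`/`eBayes`) on a frozen 50-feature
   fixture to 1e-6.  Features with zero residual variance are flagged and
   receive the shrunken variance from the same formula.  BH adjustment is per
   day (per contrast).  Significance defaults: genes |logFC| ≥ 0.585
   (fold change 1.5) with adjusted p ≤ 0.05; miRs |logFC| ≥ 0.485 (fold change
   1.4) with **raw** p ≤ 0.01 — the miRNA rule in the source protocol omits
   the multiple-testing clause that the gene rule carries, so raw p is the
   default and `mir_use_adjusted` exposes the stricter reading.

3. **Target prediction.**  Per-database (miR, gene) tables are merged by
   union: a couple counts if listed in ≥ `min_databases` sources (default 1),
   with no score threshold.  Matching is case-insensitive with the `hsa-`
   prefix stripped; passenger-strand stars (`miR-425*`) are kept verbatim.
   miRs absent from every database yield zero couples and are reported as
   lacking prediction coverage, not treated as errors.  Predictions are at
   gene level; probe-level views expand through the probe→gene map, assuming
   one gene per probe.

4. **Correlation screen.**  For each day, Pearson r between every DE miR and
   every DE gene probe over that day's paired arrays.  The per-day DE sets
   are used (the per-day products of DE probes × DE miRs are what the count
   structure of such studies implies), and the screen is kept at probe level,
   so several significant correlations per gene may exist by design.
   Significance is the conjunction |r| ≥ 0.7 and asymptotic p ≤ 0.05
   (`t = r√(n−2)/√(1−r²)` on n−2 df), with **no** multiplicity correction —
   the high |r| cut is the type-I error control.  Both signs are kept.  With
   n = 4 arrays per day this conjunction effectively requires |r| ≳ 0.95;
   published tables in this genre report significant couples down to
   |r| ≈ 0.81, implying a larger effective n or a different p formula that is
   not recoverable from the printed record.  Both interpretations are exposed:
   `sample_scope` (per_day | all_samples) and `p_method` (t | fisher-z);
   defaults are per_day and t.  Constant vectors are skipped with a warning
   rather than propagating NaN.

5. **Integration.**  A couple is reported for a day when it is both
   significantly correlated and predicted.  Probe collapse keeps, per
   (miR, gene, day), the probe with the largest |r|; exact ties go to the
   lexicographically smallest probe ID (logged).  A couple's sign is the sign
   of the retained probe's r.  The total across days is a union (each couple
   counted once), mirroring how such studies total their tables.  The bundled
   reference couples table keeps a duplicated miR-34a/NTNG1 row exactly as
   printed — the collapse rule is per (couple, day), which is consistent with
   that duplication.

6. **Network.**  Per-day bipartite graphs (miR and gene nodes, one edge per
   couple).  Degree centralization is Freeman's
   `C = Σ(d_max − d_i)/((n−1)(n−2))` on the simple undirected graph, which is
   exactly 1 for a star and 0 for a regular graph, and is algebraically the
   same quantity NetworkAnalyzer-style tools report; centralization is
   computed per connected component.  Edge sign and multiplicity are ignored
   by topology metrics.  Exports: SIF and GraphML.

7. **Downstream.**  Over-representation is a plain one-sided hypergeometric
   test per gene set against the array-list universe with BH correction
   (significant at adjusted p ≤ 0.1).  This deliberately replaces the
   proprietary "modified Fisher" of commercial pathway suites, whose exact
   modification is unpublished — a documented semantic difference.
   Ordination is ordinary PCA on feature-centred log2 values with no batch
   correction; external reference profiles are simply extra sample columns.

## Synthetic data: what it emulates and what it does not

The generator plants the statistical structure the analysis assumes, on the
study's own scale: 12 arrays per platform; 2000 probes over 1500 genes (some
genes carry 2–3 probes); 150 miRs of which 12 carry a per-day condition
effect with magnitude drawn uniformly in [0.6, 1.5] log2 units (≥ 0.6 so both
sides of the miR threshold are exercised), 80 % up-regulated — the mostly-up
pattern typical of these transfection experiments.  Each DE miR regulates a
disjoint block of 5–50 target genes; every probe of a target gene is
`baseline + day effect + sign·β·(miR deviation) + N(0, σ)`, with β = 1.0 and
σ = 0.25 by default and the coupling sign chosen so that 80 % of planted DE
genes are down-regulated (`frac_down`).  Because the gene's condition effect
flows entirely through the miR term, β = 0 yields a true null for both DE and
correlation.  5 % of probes are planted at raw intensity ≤ 100 and 5 % near
constant, to exercise the filters; 10 % of miRs are lowly expressed.  Four
synthetic prediction databases each list a true couple with probability 0.7
and add false pairs at a rate of 0.001 of all possible (miR, gene) pairs.
The source study reports no effect-size or noise magnitudes for its arrays,
so these defaults are calibrated only to reproduce qualitative structure
(≈ 80 % down-regulation, detectable couples); they were chosen once as
plausible microarray scales and are not tuned.

One `numpy` Generator seeded from `SimulationConfig.seed` is consumed in a
fixed order (miR structure → miR expression → gene expression → databases),
so outputs are bit-identical for a given seed.  The truth ledger (planted DE
features, couples, namespaces) is written to separate files the pipeline
never reads.

Features of real arrays the simulation does **not** model: probe-level
hybridization physics, background and normalization artifacts, correlated
probe noise within a gene, miRNAs sharing targets, batch structure, and
condition effects on genes that bypass miRNAs.  Passing recovery tests
therefore show the pipeline correctly extracts the structure it is designed
for — not that the thresholds are optimal for any particular real dataset.
In particular, because all planted DE miRs share the condition contrast,
their expression profiles are mutually correlated and the correlation screen
alone cannot attribute a target to the right miR; it is the prediction
intersection that restores specificity, which is visible in the recovery
precision (≈ 0.95 at β = 1.5, σ = 0.1) versus the large fraction of
significant cross-miR correlations.

## Numerical choices

* Quartiles: linear interpolation ("type 7"); all filter boundaries inclusive.
* Trigamma inversion: Newton iteration from `0.5 + 1/y`, relative tolerance
  1e-8, with asymptotic shortcuts for extreme arguments; non-positive excess
  variance of `log s²` ⇒ `d0 = ∞` (complete shrinkage).
* BH: mergesort ordering (stable), cumulative minimum from the largest rank.
* Pearson r clipped to [−1, 1] after the dot-product formula; |r| = 1 maps to
  p = 0.
* Probe-collapse ties: |r| compared with a 1e-15 absolute tolerance, smallest
  probe ID wins.
* Degenerate inputs raise typed errors (`DegenerateInputError`,
  `PairingError`, …) rather than returning NaN.

## Scale of the shipped checks

The test suite and the acceptance script run the full pipeline on simulated
studies at the default scale (2000 probes × 12 samples) for 20 replicate
seeds for recovery statistics, and on reduced scenes (60–400 probes) for
Monte-Carlo sign and null checks with 100 replicates; these sizes give stable
averages while keeping a complete run in a few minutes on one CPU.

## Known limitations and non-reproduced quantities

* Data-dependent results of the motivating study — its 536 DE probes, 510
  significant correlations (7.3 %), and specific pathway p-values — depend on
  the original raw arrays (GEO-deposited CEL/feature-extraction files) and on
  proprietary pathway content, and are not desk-reproducible here.  The
  package reproduces the *reporting arithmetic* on curated printed tables and
  the full method on synthetic data; it does not attempt to regenerate those
  study-specific counts.
* The published subnetwork centralization value 0.552 requires the study's
  unpublished day-0 edge list; the centralization implementation is instead
  verified on closed-form cases (star = 1, regular = 0, path of 4 = 1/3) and
  by property tests over random bipartite graphs.
* In printed study tables of this genre the per-day "total" columns mix
  union-style and sum-style totals and can be internally inconsistent; the
  summary layer always counts unique features and labels the union total
  explicitly rather than targeting any printed total column.
* One transcription correction in the bundled reference miRNA table: a p-value
  printed without its decimal separator ("000841") is encoded as 0.00841.
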