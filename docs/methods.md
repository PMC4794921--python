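# Methods

This note documents the models and procedures implemented in `nfkbmap`,
the defaults and why they were chosen, what the synthetic data emulate,
and the package's known limitations.

## Coordinate and identity conventions

All intervals are 0-based half-open (BED dialect); GFF3 annotation input
(1-based inclusive) is converted on load. Strand affects only the TSS of a
gene (TSS = start on `+`, end − 1 on `-`); binding regions are strandless.
Region identity for set operations and sorting is `(chrom, start, end)`;
summit and score are carried as annotations and never enter equality.

## Occupancy unification

Unified regions are the single-linkage merge of the union of all four
per-subunit peak sets: two intervals belong to the same unified region when
they overlap by at least `min_overlap` bp (default 1), directly or through
a chain. This anchors the analysis on "bound by at least one subunit"
rather than privileging any single subunit's peak list. A subunit's
indicator is set when at least one of its peaks overlaps the unified
region, giving the 4-bit pattern code in the fixed order p50, p52, RelA,
RelB. The summit of a merged region is the summit of its highest-scoring
member peak (ties to the leftmost; midpoint when no member has a summit or
score) — a merged region inherits its best-supported anchor point rather
than an average that may fall between two sub-peaks.

Signal-profile clustering uses the concatenated per-subunit vectors over
summit ± 500 bp in 20-bp bins (50 bins per subunit), k-means with
k-means++ initialisation, 10 restarts, best SSE kept, fixed seed; k = 8 by
default. Cluster labels are canonicalised by decreasing cluster size so
that a fixed seed yields a stable labelling regardless of input row order
(regions are always in coordinate order).

## Region→gene assignment

* proximal: every gene whose TSS lies within ± `proximal_window`
  (default 5 kb) of the region summit; evidence `tss-window`; signed
  distance, negative upstream by strand. The boundary is inclusive
  (|d| ≤ window).
* distal: the region overlaps one anchor of a chromatin loop and a gene's
  TSS lies within `proximal_window` of the other anchor; evidence `loop`;
  capped at `max_distal` (default 250 kb). Pairs already inside the
  proximal window are never labelled distal (strict >), so the two strata
  partition the distance axis. When a DHS set is supplied, distal links
  additionally require the region to overlap a DHS site; proximal links
  stand on TSS distance alone, since promoter-proximal binding needs no
  open-chromatin corroboration beyond the peak itself.
* multi-gene links are retained (no nearest-gene-wins): downstream models
  aggregate per (gene, stratum), so duplication is harmless and avoids an
  arbitrary tie-break.

The 5 kb / 250 kb defaults are configurable; they bracket typical
promoter-proximal windows and intra-TAD enhancer distances in mammalian
genomes.

## Differential expression and target calling

The knockdown design has four groups (Group1/2: control and p50+RelA
knockdown; Group3/4: control and p52+RelB knockdown). Each experiment is
tested strictly within itself; controls are never pooled across
experiments. Per transcript cluster, a two-sample t-test (Welch's
unequal-variance form by default — the safer choice when knockdown alters
expression variance; the pooled form is available behind `equal_var`)
with Benjamini–Hochberg adjustment applied per experiment over all
clusters tested there. Rows with zero variance in both groups get P = 1
when the means agree (and P = 0 otherwise, a degenerate case that only
arises in constructed data).

Gene-level rule: regulated ⟺ at least one transcript cluster assigned to
the gene has q < α (default 0.05) **and** at least `min_diff` (default
10 %) expression difference. The 10 % is interpreted on the linear
intensity scale, i.e. |Δlog2| ≥ log2(1.1) ≈ 0.1375, since expression
"difference" reads most naturally on the measurement scale while the
matrix is log2; the threshold is configurable. Direction follows the sign
of control − knockdown: positive means expression falls upon subunit
depletion, i.e. the gene is activated by NF-κB.

Direct target: regulated in a pathway **and** bound in ≥1 assigned region
by the pathway's obligatory subunit (p50 for canonical, p52 for
non-canonical).

## Binding-pattern logistic regression

One joint model per contrast with an intercept and one indicator per
observed (pattern, stratum) pair (≤30 columns). Negatives for the
\*-vs-none contrasts are genes with ≥1 assigned region but no regulation
call — the model asks what distinguishes bound-and-regulated from
bound-only genes, not bound from unbound. Genes regulated only by the
other pathway are excluded from a \*-vs-none contrast (they are neither
clean positives nor clean negatives), and genes regulated by both pathways
are excluded from canonical-vs-noncanonical for the same reason. The
activated-vs-repressed contrast uses all regulated genes with an
unambiguous direction.

Estimates are maximum-likelihood log odds ratios with Wald 95 % CIs and
P values; significance at P < 0.01; bootstrap stability is the fraction of
B gene-resampled refits (default B = 1000) in which the coefficient stays
below P < 0.01, flagged stable at ≥90 %.

Perfect separation: a feature whose 2×2 table against the outcome has an
empty cell drives its MLE to ±∞. Such features are detected up front,
excluded from the fit, and reported with a missing estimate and status
`separated`; features never observed in the selected rows carry
`not_observed`. If the remaining fit still fails to converge or produces a
degenerate standard error (|coef| > 15 or SE > 30), the offending columns
are moved to the separated set and the model is refitted (at most once per
column). An optional L2-penalised fit (`ridge > 0`, estimates only) is
available when separation is pervasive. Within a bootstrap resample,
separated or absent features simply count as not significant there.

## Lymphoma panel concordance

Genes with mean log2 expression over **all** panel samples below the floor
(default 6.0, strict <) are removed; the mean is taken over all samples,
not per group, because the filter models probe-level detectability, not
biology. HL vs all-remaining samples is then tested with exactly the
gene-level rule above. Direct targets that are HL-differential are kept
when the directions agree (activated & up, or repressed & down in HL);
genes whose canonical and non-canonical direct calls disagree in direction
are excluded rather than guessed. The exported heat-map matrix is ordered
canonical-only → both → non-canonical-only, then by NF-κB direction.

## Synthetic data: what it emulates, and what it does not

The generator plants, at toy scale, the joint structure the pipeline
consumes:

* **Cistrome** — pattern counts are multinomial over a supplied frequency
  table; the default mirrors the qualitative structure of the HL setting:
  p50/p52-containing patterns dominate, 41 % of regions bind p50 or p52
  alone, the exclusive prototypic dimers (`1010`, `0101`) sit near 2 %
  each, and RelA-containing patterns are rare. Proximal regions are
  uniform within ±2 kb of their target TSS; distal regions uniform in
  10–100 kb with an emitted loop to the promoter and a DHS site covering
  every region. Regions are non-overlapping (≥1 kb gap) and kept >6 kb
  from every non-target TSS, so unification and assignment reproduce the
  planted structure exactly — by design, the ground truth is unambiguous.
* **Regulation** — per pathway, P(regulated) = expit(β₀ + β·x) on the
  gene's true (pattern, stratum) features; default β encode the headline
  structure (combined p50/p52 binding drives both transcriptomes;
  RelA-containing patterns act proximally; prototypic-dimer-only patterns
  carry no effect); 70 % of regulated genes are activated. Knockdown
  matrices shift the affected group by ± effect_log2 on a
  Normal(8, 1) per-cluster baseline with Normal(0, σ) noise — typical
  log2 microarray scale.
* **Panel** — planted concordant targets are shifted in HL in the matching
  direction; the remaining targets are planted *discordant* (strong
  opposite shift). A fraction of background genes sits below the
  expression floor; target baselines are kept above it.

The bundled end-to-end fixture (300 genes, 300 regions, effect 2.0 log2,
σ = 0.06, 8 replicates per siRNA arm) is sized so that planted calls are
recovered exactly: with these settings the probability that a null
transcript cluster passes both the BH threshold and the 10 % rule is
~10⁻⁶ per row, while planted effects are detected with essentially
certainty — an analytical consequence of the 10 % rule binding at
|t| ≈ 0.1375/SE ≈ 6.5 at this noise level. At literature-typical noise
(σ ≈ 0.25, 3 replicates) the same pipeline is calibrated but not exact:
BH at FDR 0.05 tolerates ≈ 5 % false discoveries by construction, which
the calibration study measures instead.

What the generator does **not** emulate: read-level noise, peak-calling
artefacts, correlated probe effects, batch structure, overlapping or
ambiguous regulatory domains, trans-chromosomal contacts, and
entity-specific expression signatures beyond the HL shift. Passing tests
therefore demonstrate the correctness and calibration of the pipeline's
inference, not robustness to upstream measurement pathologies.

## Parameter-recovery study

The core validation loop plants sparse β ∈ {0, ±1.5, ±2} over a reduced
pattern set, runs the real cistrome→assignment→design path on 2000 genes ×
3000 regions, and fits on the generator's true regulation labels. Over 50
replicates the per-feature mean estimate stays within 0.15 of truth and
the aggregate Wald-CI coverage within [0.90, 0.99]. Fitting on true labels
isolates the regression layer; routing the outcome through the DE caller
would attenuate coefficients by its (separately measured) error rate.
Bootstrap stability is summarised as a mean over replicates: within a
single dataset a null feature can legitimately show high stability when
the data contain a chance association, because the bootstrap resamples
that same data.

## Numerical choices and degenerate inputs

* BH is statsmodels' `fdr_bh`; the worked identity
  q = (0.04, 0.04, 0.04, 0.04) for p = (0.01, 0.02, 0.03, 0.04) is tested
  exactly.
* k-means uses scikit-learn with `n_init=10` and a fixed `random_state`;
  determinism and row-order invariance are tested.
* All randomness flows through `numpy.random.default_rng` seeds; the
  pipeline fans a single global seed out per stage by SHA-256 of the
  stage name (seeds < 2³¹). Run logs contain no timestamps and record
  input paths relative to the run directory, so reruns are byte-identical.
* Empty peak sets, all-zero indicator rows, single-class outcomes, groups
  with <2 samples, trans-chromosomal loops and out-of-range thresholds are
  rejected with specific errors; an all-filtered panel warns rather than
  fails.

## Limitations

* The logistic model treats (pattern, stratum) indicators as marginal
  features without interactions; it identifies association, not causation.
* Distal assignment depends entirely on supplied loops; without loop data
  distal regulation is invisible.
* The 10 %-difference rule and the expression floor are scale conventions
  inherited from microarray practice; RNA-seq inputs would need different
  defaults.
* Cross-cistrome comparison reports overlap fractions on unified regions;
  peak-level Venn counts can differ when several peaks of one subunit fall
  into one unified region.
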