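# Methods

This note documents the models and procedures `cellcube` implements, the
parameters that matter, the design choices made where the design was open,
and what the synthetic corpora do and do not establish.

## Data model and schema

A dataset is an AnnData: raw counts (non-negative integers) in the layer
named `raw` (falling back to `X`), per-cell metadata in `obs`, embeddings in
`obsm`. Eleven `obs` fields are required; eight are ontology CURIEs with a
configurable allowed prefix per field (organism→NCBITaxon, tissue→UBERON,
cell_type→CL, assay→EFO, disease→MONDO/PATO, sex→PATO,
self_reported_ethnicity→HANCESTRO, development_stage→HsapDv/MmusDv/UBERON);
`donor_id` is free text, `suspension_type` ∈ {cell, nucleus, na}, and
`is_primary_data` is a per-cell boolean. Validation is syntactic by default:
term *existence* is checked only when an ontology term set is supplied,
because pinning ontology releases is out of scope. Extra metadata columns
are reported at `info` severity — the schema is deliberately extensible.
`is_primary_data` may vary within a dataset; the corpus-level constraint is
only that a given cell identifier is primary at most once. Cross-dataset
cell identity uses an explicit `cell_id` column when present, otherwise
barcode + donor_id — a stand-in for curator bookkeeping.

## QC and normalization

Steps run per dataset, in order; each is independently switchable:

1. `dedup_primary` — keep `is_primary_data == True`.
2. `filter_low_coverage` — keep cells with ≥ `min_genes` (default 500) genes
   at raw count > 0. "Expressed" means a positive raw count: the filter
   precedes normalization, so no other definition is available. The boundary
   is inclusive — exactly 500 expressed genes is retained.
3. `filter_assay` — keep cells whose assay CURIE is on the allow-list of 12
   UMI-based/droplet assays (`src/cellcube/data/assay_allowlist.tsv`);
   full-length assays would need gene-length normalization and are excluded.
4. `normalize_cptt` — `v = ln(count/total · s + 1)` with scale factor
   `s = 10⁴` (CPTT) by default; `s = 10⁶` (CPM) is used by the batch-effect
   study. Before the log, per-cell CPTT values sum exactly to `s`.
5. `mask_low_expression` — values ≤ 3 become *missing*: removed from the
   sparse structure, never stored as zero, so non-zero means downstream are
   unaffected by masking artifacts. The threshold is interpreted on the
   normalized scale because masking follows normalization in the pipeline;
   the wording is ambiguous enough that a `scale="raw"` switch applies the
   same threshold to the aligned raw counts instead. Masking is idempotent.

`normalize_quantile` (per-cell rankit: non-zero ranks mapped to
Φ⁻¹((r − ½)/m), zeros untouched, average ranks for ties) exists solely for
normalization-comparison studies and is never masked.

## Expression cube and ontology roll-up

For each (tissue, cell type [, facet]) stratum and gene the cube stores the
mean over present values (`mean_nonzero`), the number of present values
(`n_expressing`) and the stratum's QC-passing cell count (`n_cells`, a
stratum property identical across its genes). Zeros and masked values never
enter the mean; the stratum denominator still counts non-expressing cells so
the fraction expressing is reproducible. Facet group-by is exact
stratification over observed value combinations, not re-weighting. Datasets
concatenate along the gene axis by id union: a gene unmeasured in a dataset
contributes neither values nor expressing counts for its cells (absence of
measurement ≠ measured zero). Building per dataset and merging sums/counts
is exactly equivalent to building once on the concatenated corpus, with one
caveat: a stratum's size is recoverable from a per-dataset cube only if that
stratum expressed at least one gene there.

Roll-up: the cell-type ontology is a DAG of `is_a` edges (child → parent).
The value reported for a term sums over cells labeled with that term or any
descendant. Because each cell carries exactly one label, attributing each
label's totals to the label's ancestor *set* counts every cell at most once
per ancestor even under multiple-parent diamonds — plain tree semantics
would double count. Ancestor means are recomputed from rolled sums of
non-zero values and rolled non-zero counts (exact), not by averaging
per-term means, which would weight terms rather than cells. Roll-up is
per tissue; tissues never mix. `prune_colinear` drops the more basal member
of every ancestor/descendant pair, leaving an antichain — used when
evaluating marker recall so a term and its ancestor are not both scored on
overlapping cell populations.

## Marker genes

Inputs are the masked normalized values; missing values are excluded from
group vectors, consistent with the cube's non-zero semantics. For target
type *t* and each other type *o* in the same tissue, per gene:

- Welch: `tstat = (m_t − m_o)/√(s_t²/n_t + s_o²/n_o)`, df by
  Welch–Satterthwaite; effect `d = (m_t − m_o)/√((s_t² + s_o²)/2)`.
- Student (validation arm): pooled variance, df `n_t + n_o − 2`, effect is
  Cohen's d with the pooled SD. The two coincide as variances equalize.

The effect size is the standardized mean difference rather than the t
statistic so that group sizes do not dominate the ranking (`effect_metric="t"`
switches). Zero-variance pairs with distinct means are guarded to a finite
sentinel (10⁶) instead of ±∞. Comparisons where either group has fewer than
`min_cells = 5` present values are skipped; a gene with no usable comparison
is excluded; a single-type tissue yields an empty table.

Per gene the comparison effects are aggregated as a bootstrapped 10th
percentile: `reps = 100` resamples with replacement of the effect list (the
resampling unit is the per-comparison effect, not cells), the 10th
percentile of each replicate by linear interpolation, averaged. The genes
with the top 25 aggregated effects are returned; ties break by gene id.
Bootstrap generators are derived per (tissue, target, gene) from the run
seed via a CRC-keyed SeedSequence, so results are deterministic and
invariant to cell and dataset order. Replicate count and resampling unit are
implementation choices (the procedure itself does not fix them); no
expression floor is applied before ranking.

## Validation statistics

**Marker recall.** Predicted top-k markers vs a reference set, over the
tissue's gene universe (the union of gene ids observed in the tissue).
`recall = overlap / |reference|`; the chance probability is the exact
hypergeometric upper tail `P[X ≥ overlap]`,
`X ~ Hypergeom(universe, |reference|, |predicted|)`. The chance model for
"sensitivity this high by chance" is a design choice — a uniform draw of the
predicted set from the universe — chosen as the standard overlap null.
The study prunes colinear reference types, uses the Student variant by
default (matching how such evaluations are typically run with off-the-shelf
differential-expression routines), and skips tissues or types absent from
the corpus.

**Batch effects.** Per cell type and named gene set (e.g. markers vs
housekeeping), the per-gene average expression at each covariate level
(dataset id or assay) — zeros excluded, no ≤3 mask, CPM scaling for the log
arm — feeds a one-way repeated-measures ANOVA with genes as subjects
(pingouin's implementation). Designs are unbalanced because not every gene
appears at every level; genes missing a level are dropped (complete case)
rather than imputed — mixed models are out of scope. When the between-level
sum of squares is exactly zero the test statistic is 0/0; (F, p) = (0, 1) by
convention since there is no covariate effect at all. In the balanced
two-level case F equals the squared paired t statistic (verified to 1e-9
relative).

## Streaming statistics

Chunked Welford in batched form: each chunk's mean and squared-deviation sum
combine into the running state by Chan's update; states merge associatively.
The state anchors a per-gene *shift* at the first chunk's means and
accumulates in shifted coordinates — subtracting a nearby constant is exact
in IEEE arithmetic, so running quantities live at the scale of the data's
spread rather than its mean. On data with mean 10⁸ and SD 10⁻², streamed
variances agree with an extended-precision two-pass oracle to ~10⁻¹⁰
relative regardless of chunk size (a plain float64 two-pass is itself only
~10⁻⁹ accurate there). Sample (n−1) variance is reported by default,
population variance by `ddof=0`; fewer than ddof+1 observations flag the
variance undefined. HVG ranking orders genes by the variance of their
normalized values (dispersion = variance/mean available) — the simplest
criterion computable in one pass — with deterministic tie-breaking by gene
order, and is invariant to chunk size.

## Synthetic corpora

`generate_corpus` emulates the corpus structure the pipeline assumes.
Counts are Gamma–Poisson: gene relative expression `r_g ~ Gamma(2, 1)`,
per-cell library size `LogNormal(ln 5000, 0.35)`, counts
`Poisson(L_i · w_tg / Σw)` — the standard droplet-data stand-in. Defaults:
3 datasets × 1 tissue × 5 labeled immune types × 80 cells (240 per type
corpus-wide) × 800 genes; 5 markers per type at 4-fold enrichment; 5% each
of planted non-primary, low-coverage (exactly 100 expressed genes) and
disallowed-assay cells, mutually disjoint so each QC stage removes exactly
its planted set; 10% of cells labeled at the parent ontology term to
exercise roll-up and colinear handling. Planted markers receive a fixed
well-expressed baseline (relative expression 4 vs a mean of 2): canonical
markers are robustly detected genes, and a marker buried below the ≤3 mask
would be unrecoverable by construction since masking truncates both groups
to their upper tails. Non-planted cells are floored at 520 expressed genes
(adding single counts to zero genes when library-size noise would dip a
cell below) so the low-coverage ground truth stays exact. Batch effect is a
per-dataset sequencing-depth factor `exp(b·z_d)` on library sizes: depth
shifts are exactly the batch component that count-per-total scaling cancels,
which is what makes the raw-vs-log ANOVA comparison directional. A per-gene
multiplicative dataset shift would instead form a gene×level interaction
that log-additivity removes from the ANOVA error term, reversing the
direction.

What passing tests show — and what they do not: the generator produces
independent Poisson counts given rates, one organism, no doublets, no
ambient RNA, no correlated gene programs, and marker effects that are clean
multiplicative folds. Recovery and calibration results on these corpora
demonstrate correctness of the machinery, not expected sensitivity on real
corpora, where reference noise, assay mixtures and rare types depress
recall substantially.

## Problem sizes and numerical choices

Tests and the acceptance script run on scaled-down corpora (20–80 cells per
type, 600–800 genes, bootstrap reps 25–100), chosen so the full suite
completes in well under a minute while leaving planted effects far above
noise. Tolerances: streaming vs two-pass 1e-9 relative (extended-precision
oracle); ANOVA/paired-t equivalence 1e-9 relative; hypergeometric tails
exact against enumeration for universes ≤ 15; type-I error within 2
Monte-Carlo SE of α = 0.05 over 400 null replicates. Ranking ties break
lexicographically; all stochastic steps derive from a single seed.

## Known limitations

- No doublet detection, ambient-RNA correction or gene-length normalization
  (the assay allow-list makes the latter unnecessary by construction).
- Marker derivation is a t-test screen traded for speed; it is not a
  substitute for count-based differential-expression models.
- The hypergeometric chance model ignores gene-gene correlation.
- Unbalanced RM-ANOVA uses complete-case deletion, which loses information
  relative to mixed models when many genes miss levels.
- OBO relations other than `is_a` (part_of, develops_from) and UBERON tissue
  roll-up are not modeled.
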