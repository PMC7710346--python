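# Methods

## Problem and model

`phenoconcord` implements a phenotype-informed meta-analysis of differential
gene expression across independent transcriptome studies of the same
condition — its motivating case being CHD8 haploinsufficiency
(Zahir–Friedman syndrome), where one patient blood transcriptome is compared
against public CHD8+/- cellular models (neural progenitors, neurons,
cerebral organoids). The pipeline consumes per-study DEG tables (not raw
counts) and per-phenotype candidate-gene ("phenotype seed gene", PSG) lists,
and asks four questions:

1. **Which genes are DEGs in each study, under one uniform rule?**
   A gene is a DEG when its Benjamini–Hochberg adjusted value satisfies
   `q < 0.05` (strict inequality; a record at exactly the threshold is
   excluded). With m p-values sorted ascending, the step-up rule gives
   `q_(i) = min_{j>=i} (m * p_(j) / j)`, clipped to 1. Ties in p receive
   identical q by construction. Upstream q-values are trusted by default —
   the public studies ship their own adjusted values — and recomputed from
   raw p only on an explicit flag. Called DEGs are additionally tiered by
   |log2 fold change| at inclusive cutoffs (default 1, 2, 3, i.e. 2-, 4- and
   8-fold); the cutoffs operate on the log2 scale. Records with infinite
   log2fc (one condition at zero expression) keep their direction and are
   counted, but are excluded from the tiers and reported separately; a
   log2fc of exactly 0 is flagged "flat" and belongs to neither the up nor
   the down split.

2. **How much does each study's DEG set overlap each phenotype list?**
   For every (dataset, phenotype) cell: `n_overlap = |DEG ∩ PSG|`,
   `pct_of_psg = 100 * n_overlap / |PSG|` and
   `pct_of_deg = 100 * n_overlap / |DEG|`. Percentages are stored at full
   precision; *display* rounding is decimal half-up to one decimal place
   (62/181 → 34.3), and per-dataset means are taken over the full-precision
   values, not the rounded ones. Per-dataset distinct union counts
   (`|DEG ∩ ∪PSG|`) are computed on sets, never by summing cells. No
   enrichment p-value is attached — the contract is the raw percentages.

3. **Which DEGs recur across phenotypes, and which are concordant across
   studies?** Recurrence is the number of seed lists containing a given DEG
   of the focal dataset (default report threshold: at least 9 of 12 lists; a
   flag, not a constant). Concordance assigns each gene in the union of DEG
   sets a membership bitmask over a fixed dataset order (LSB = first
   dataset) and decomposes the union into the 2^n − 1 non-empty Venn
   regions; region counts therefore sum exactly to the union size. Derived
   queries — the all-datasets core, at-least-k membership, leave-one-out
   intersections (the excluded study's membership is *ignored*, not required
   absent), and the PSG/non-PSG partition of a core — are all mask
   arithmetic. The region table is exponential in n, so builds are guarded
   to n ≤ 16.

4. **Which model's overlap profile most resembles the reference (patient)?**
   Datasets are compared on their per-phenotype `pct_of_psg` vectors. The
   default metric is the mean absolute difference (MAD); Spearman rank
   correlation is the alternative. No canonical metric exists for this
   comparison — the original analysis judged resemblance qualitatively — so
   the chosen metric is printed into every similarity output. MAD ranks
   ascending, Spearman descending; ties break alphabetically and are flagged.

## Gene identity

Matching across studies is by exact normalized symbol: uppercase, surrounding
whitespace stripped, nothing else. No alias or ortholog mapping is attempted;
cross-study symbol harmonization across annotation vintages is an open
problem deliberately left to a future pluggable hook, trading recall for
reproducibility. Duplicate rows for one symbol within a dataset collapse to
the row with the smallest q (ties: smallest p, then largest |log2fc|, then
first occurrence), and every collapse is logged.

## Synthetic-data generator

The generator stands in for data that cannot ship with the package: the
patient transcriptome is controlled-access and the public studies' full DEG
lists live in supplements. Each simulated study over a shared universe of
`n_genes` symbols (G000001…) is a two-group mixture:

* null genes (fraction `pi0`): p ~ Uniform(0,1), log2fc ~ Normal(0, 0.1·`lfc_scale`);
* alternative genes: p ~ Beta(`alt_beta_a`, 1) — a < 1 pushes p toward 0 and
  gives the closed form P(p ≤ t) = t^a that the tests exploit — and
  |log2fc| ~ folded Normal(0, `lfc_scale`) with random sign.

Alternatives decompose into a **core** planted in every study (its
fold-change sign drawn once and held consistent), a **shared** pool
(fraction 1 − `private_frac` of the non-core slots, same genes in every
study), and **private** alternatives drawn independently per study. q-values
are BH-adjusted within each study. Phenotype lists draw a fraction
`enrichment` of members from the first study's true alternatives and the
rest from its null pool, without replacement.

Defaults mirror the motivating study's conditions: 6 datasets and 12
phenotype lists over a 12,000-gene universe, `pi0 = 0.85`,
`alt_beta_a = 0.15`, a 2-gene core, `private_frac = 0.9` (hence poor
cross-study concordance), `lfc_scale = 1.2`, list sizes uniform on
180–1240 (the span of the published seed lists) and `enrichment = 0.27`
(the observed ~27% seed-list recovery). A single integer seed drives one
substream per dataset and per phenotype list (`SeedSequence([seed, stream,
index])`), so adding datasets never perturbs existing ones and identical
configs produce byte-identical files.

What the generator does **not** emulate: count-level noise, between-gene
correlation, batch effects, annotation-vintage symbol drift, or dependence
between studies. Passing tests therefore demonstrate the *set arithmetic and
error-rate behavior* of the pipeline, not robustness to those real-data
features.

## Packaged reference values

Five small tables of published summary numbers ship with the package
(`phenoconcord.reference`): the 23 extreme-fold-change patient DEGs, the 12
phenotype (overlap, seed-size) count pairs with the 5,388-DEG total, the six
per-study DEG counts, the 16 highly recurrent seed-gene DEGs, and the
six-study membership grid of the eight ≥5-of-6 concordant genes. They anchor
the test suite and the acceptance script: every printed percentage, average,
tier count, core intersection, leave-one-out gain and seed/non-seed
partition is recomputed through the pipeline from these inputs. The reported
724-gene DEG∪PSG union is documented but not asserted — it needs the full
seed lists, which are not redistributable here.

## Numerical and procedural choices

* Display rounding is decimal half-up (via `decimal.Decimal`), matching the
  printed tables; Python's banker's rounding is never used for display.
* BH uses a stable argsort; the step-up minimum is a reversed cumulative
  minimum, O(m log m).
* An even-length median is the mean of the two middle order statistics; the
  displayed mean DEG count rounds to the nearest integer (2157.33 → 2157).
* Degenerate inputs fail loudly and early: empty tables, empty seed lists
  (unless explicitly allowed, in which case the cell is marked
  not-applicable), missing q-values without the recompute flag, k outside
  [1, n], mismatched phenotype keys.
* Outputs are byte-stable (sorted keys, fixed float formats) and every run
  directory carries a manifest with SHA-256 hashes of all inputs and
  outputs plus a full config echo including defaults.

## Test problem sizes

Statistical suites run at sizes chosen to make their error bounds sharp while
keeping the default test run quick: 1,000 fuzz vectors (length ≤ 50) for the
BH oracle; 200 fuzzed set families (n ≤ 4, universe 50) for the Venn oracle;
500 complete-null studies of m = 1,000 for FDR control; 100 replicates of a
600-gene, 4-study design at `alt_beta_a = 1e-4` for ≥0.99 planted-core
recall; 40 replicates for enrichment recovery within two standard errors.

## Known limitations

The similarity metric is the package's own choice, not the field's; symbol
matching ignores aliases; overlap percentages carry no significance
calibration; and the concordance machinery assumes each study contributes a
single DEG set (no multi-contrast designs).
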