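# Methods

## Study design and data model

The package analyzes a two-condition microarray contrast: three liver
cell types — sinusoidal endothelial (E), hepatic stellate/Ito (I) and
Kupffer (K) — sampled under healthy control (C) and tumor-colonized
(T, the tumor microenvironment) conditions, with a small number of
biological replicates per (cell type, condition) group. Intensities are
treated as log2-scale and approximately Gaussian within a group; probe
redundancy is collapsed to the per-feature median before analysis, and
features with missing values are dropped (the selection rule below has
no missing-data contract). Tumor-cell comparison columns (TP, primary
tumor; TM, liver metastasis) may be carried in annotations but are
always excluded from the C-vs-T contrast.

Both expression layers (miRNA and mRNA) are quantile-normalized before
testing: every column's sorted values are replaced by the across-column
mean of sorted values, so all samples share one empirical distribution.
Tied values within a column receive the mean of the reference values at
their tied ranks; this makes the transform well defined and idempotent
on ties at the cost of exact cross-column multiset equality in the
(degenerate) tied case.

## Differential expression

The contrast pools all control samples of the selected cell types
against all TME samples — cell types are not modelled separately. This
mirrors a design where per-cell-type replication (2–3) is too small to
support interaction terms. A feature is selected when both

* |mean_T − mean_C| ≥ log2(θ), with θ = 4 on the linear scale
  (i.e. 2 log2 units), boundary equality selecting; and
* p < α = 0.001 from a two-sided two-sample location test on the log2
  values.

The default test is Welch's unequal-variance t-test: group sizes are
small and unbalanced, and pooling across cell types leaves
heterogeneous within-group variance, which Welch tolerates better than
the pooled-variance Student test. Student and Wilcoxon (Mann–Whitney)
variants are available via `DEMParams(test=...)` for sensitivity
analysis. Features with zero variance in both groups receive p = 1. No
multiple-testing correction enters the selection rule — the joint
fold-change condition already suppresses false positives far below
α × N, as the null simulations verify — but a Benjamini–Hochberg column
is reported alongside for information. For display, p-values that
underflow to 0 are floored at the smallest positive double before
taking −log10.

An alternative pooling mode (`group_means(..., within_cell_type_first=True)`)
averages replicates within each cell type before averaging across cell
types; the default pools samples directly. The two differ only when
replicate counts are unbalanced across cell types.

## Catalog curation

The geromiR catalog merges three review compilations into one table of
harmonized names with hallmark-of-aging annotations and source
provenance. Harmonization strips species prefixes and markup and
unifies stem capitalization (`miR-`/`let-`/`lin-`); it never merges
distinct printed tokens — `miR-34`, `miR-34a` and `miR-16-1` are three
entries, and apparent typos in the printed sources (`miR-2016a`,
`miR-E1108`, `miR-E1016`) are preserved verbatim, because the package's
reference counts (115 compiled, 75 on the platform, 26 downregulated)
are properties of the printed compilation. An explicit alias table
would be the place to merge family names with lettered members; the
packaged compilation needs none, so none ships.

The 15 hallmark categories form a closed vocabulary keyed by unique
internal codes; the single-letter labels used in figure legends are
display-only because the published letters collide (uppercase S is
reused, and a lowercase s/h/i family shadows the uppercase letters).
A 16th legend letter ("changes in gene regulation") appears in one
figure legend with no corresponding compilation row and is excluded
from the vocabulary.

Platform restriction is exact name intersection. The platform-restricted
compilation carries its own hallmark rows (which reshuffle a few
annotations relative to the full table, e.g. `miR-376b`), and the
package exposes both views: `reference_catalog()` (full annotations,
platform/downregulation flags) and `platform_catalog()`
(platform-table annotations).

## Over-representation statistics

All enrichment is the one-sided, upper-tail hypergeometric test
(`scipy.stats.hypergeom.sf(k − 1, N, K, n)`): over-representation only,
matching the directional question asked of the data.
Categories overlap — a miRNA annotated to several hallmarks counts once
per hallmark — and no exclusivity correction is applied.
Benjamini–Hochberg values across the 15 hallmarks are reported;
rankings use raw p with ties broken by descending overlap then name. A
permutation oracle (`permutation_null`, uniform subsets with add-one
smoothing) provides an independent Monte-Carlo check of the exact tail.

**The population matters.** For the hallmark ranking,
`hallmark_enrichment` defaults to the on-platform catalog itself as the
universe (N = 75), which asks "are the downregulated geromiRs biased
toward this hallmark *relative to other geromiRs*?". Passing
`population_size` — naturally, the number of distinct miRNAs tested on
the platform — instead asks the question relative to the whole array.
The two disagree: against the 75-geromiR universe, histone
modifications ranks first (k = 6 of K = 8, p = 0.018) but the tiny
two-member inflammaging category ranks second; against any
platform-scale universe (N ≳ 200) the top two are histone modifications
and DNA methylation, the published ordering, because ranking is then
dominated by overlap size. The pipeline therefore uses the number of
miRNAs tested (the DEM table's population size) as N for both the
geromiR-among-DEMs test and the hallmark ranking. As a calibration
note: the published intersection p-value of 2.746 × 10⁻⁶ for 26 hits
among 71 downregulated miRNAs with 75 catalog members corresponds to an
upper-tail hypergeometric universe of N ≈ 467
(`hypergeom.sf(25, 467, 75, 71)` = 2.77 × 10⁻⁶); the platform's true
distinct-miRNA count is not recorded here, so this is a consistency
observation, not an assertion.

## Target network and reverse-expression screen

The miRNA→gene interaction table is a local, versioned input
(MirTarBase-export-like columns `mirna`, `gene`, `evidence`); no web
service is queried. The packaged table is *synthetic* — constructed to
exercise the code with plausible validated-interaction rows — and real
analyses should substitute an actual export. No evidence-level
filtering is applied by default; the evidence column is carried through
for user-side filtering.

The network keeps exactly the interaction rows whose miRNA is in the
downregulated-geromiR set; bipartiteness is asserted on construction
and after GraphML re-import. The reverse-expression screen applies the
*same* θ/α selection rule to the gene matrix and returns the network
genes called up in the TME — loss of repression is the hypothesis, and
reusing the stated thresholds is the only defensible default (both are
independently configurable). Gene symbols match case-insensitively with
matrix capitalization preserved, since murine (`Cercam`) and human
(`CERCAM`) capitalization conventions mix freely in interaction
resources.

## Synthetic data generator

`simulate()` draws, in a fixed documented order from one seeded
generator: geromiR catalog membership, planted miRNA/gene sets,
hallmark assignments, per-feature baselines
(Normal(8, 2) log2 units), per-(feature, cell type) offsets
(Normal(0, 0.25) — enough heterogeneity to exercise pooled testing),
and i.i.d. Gaussian noise (sd 0.5 log2 units, a typical post-
normalization replicate scatter for arrays). Planted effects are ±3
log2 units, comfortably above the θ = 4 boundary of 2 log2 units, as
befits reference conditions for verifying recovery rather than probing
the detection limit. The default replicate design is the study's: three
per (cell type, condition) except two for endothelial controls and
Kupffer TME samples (8 vs 8 pooled). Planted upregulated miRNAs avoid
the catalog, emulating the finding that no geromiR was upregulated;
planted downregulated miRNAs include 10 catalog members, all annotated
to a designated hallmark (histone modifications by default) so the
hallmark ranking has a planted answer. Each planted up-gene is wired to
three planted-down geromiRs in the generated interaction table, the
synthetic counterpart of the *Cercam*/*Spsb4* finding.

The reference scenario uses 600 miRNAs and 2000 genes — array-like
proportions at a size where a hundred replicate simulations are cheap —
with a 75-member catalog (geromiR fraction 0.125, the platform
proportion). The generator emulates group structure, effect geometry
and catalog wiring; it does **not** emulate probe-level variation, dye
or spatial artifacts, intensity-dependent variance, correlated miRNA
families, or partial repression dose-response. Passing recovery tests
therefore demonstrate the pipeline's correctness under its own model
assumptions, not performance on raw array data.

One numerical property of the reference design is worth recording:
with 30 planted downregulated miRNAs of which 10 are catalog members,
complete recovery gives a geromiR over-representation of exactly
`hypergeom.sf(9, 600, 75, 30)` = 1.93 × 10⁻³ — the acceptance script's
`geromir_enrichment_p_median` reproduces this. The scenario's
enrichment signal is real but bounded: p below 10⁻³ would require a
*smaller* down-called list at the same overlap, so near-perfect recall
pins the p-value at the 1.9 × 10⁻³ floor.

## Conventions and degenerate inputs

* Empty DEM calls: precision 1 (no false positives), recall 0.
* Empty hit sets: every enrichment p = 1 exactly.
* Empty networks and empty catalogs are valid values, not errors.
* Ranking ties: −log10 p descending, then lexicographic feature id;
  enrichment: p ascending, then overlap descending, then name.
* `restrict_to_platform` never adds names; platform inputs are assumed
  pre-normalized.
* Reruns of `run_pipeline` with identical inputs, config and seed are
  byte-identical (no timestamps are written).

## Known limitations

* No empirical-Bayes variance moderation and no paired or per-cell-type
  interaction modelling; the caller is a thresholded two-group test by
  design.
* Raw-α selection: the reported BH column is informational, and
  selection claims inherit the raw-α convention of the thresholding
  approach.
* The GEO series-matrix reader handles the standard single-table layout
  with quoted fields and configurable title parsing; it is not a
  general GEO client.
* The packaged interaction table is synthetic; partner sets queried
  from it (e.g. for *Cercam* and *Spsb4*) describe the fixture, not a
  database snapshot.
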