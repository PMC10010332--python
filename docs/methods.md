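# Methods

This note documents the models and procedures implemented in
`lesionscope`, the assumptions behind them, the parameters that matter,
what the synthetic-data generators do and do not emulate, and the design
choices made where the design was genuinely open.

## Somatic-variant filtering

A candidate call carries per-strand tumor allele counts, germline
counts, a population-database flag and a coding consequence. The filter
rejects a call when **any** enabled criterion fires and records the full
set of failed criteria (no short-circuit), so per-criterion tallies are
reproducible regardless of evaluation order.

Thresholds are strict inequalities: reject when total tumor reads < 20,
tumor VAF < 0.05, or germline mutant reads > 2 — a call with exactly 20
reads, VAF exactly 0.05 or exactly 2 germline mutant reads is retained.
The strand criterion applies to ALT-supporting reads only (the mutation
being present on a single strand), not to total depth. The
population-database criterion consumes a precomputed boolean column; no
external database is queried, which keeps the module self-contained and
testable. The `mouse` preset disables the germline and
population-database criteria. Multi-allelic records must be pre-split
(e.g. `bcftools norm -m-`); the readers reject them.

A call with zero tumor depth has no defined VAF; `tumor_vaf` raises, and
the filter simply never evaluates the VAF criterion there (such a call
already fails the total-read criterion).

Upstream variant calling itself is out of scope: the module filters
whatever candidate set it is given, without assuming how multiple
callers' outputs were combined.

## Copy number: the log-R-ratio track

Four steps, each a separate function and composed by `lrr_pipeline`:

1. **Site selection.** SNP sites are kept when the matched normal is
   clearly homozygous (VAF ≤ 0.05 or ≥ 0.95) or clearly heterozygous
   (VAF in [0.4, 0.6]); ambiguous sites are excluded. Both interval
   boundaries are inclusive.
2. **GC adjustment.** Within each sample independently, sites are binned
   by GC fraction (1% bins) and each depth is multiplied by
   (global median depth / bin median depth). Median scaling was chosen
   over loess for robustness and determinism; it preserves the overall
   median up to binning granularity and leaves a GC-unbiased track
   unchanged. The GC fraction of a site is computed over a 101-bp window
   (50 bp of flank on each side of the position); the "100 bp flanking"
   convention is read as centred, and the window size is configurable.
   Bins whose median depth is zero yield adjusted depth 0; those sites
   are dropped at the next step with a logged count.
3. **Per-site LRR.** `LRR_i = log2((t_i/T)/(n_i/N))` with `t_i`, `n_i`
   the GC-adjusted tumor and normal depths and `T`, `N` their sums over
   all evaluated sites. The sum (library-size) normaliser is the
   default; a median normaliser is available (`normalizer="median"`).
   The statistic is invariant to rescaling either sample's depths by a
   constant, and sites with zero adjusted depth in either sample are
   dropped rather than producing infinities.
4. **Windowed median.** The representative LRR at site *i* is the median
   of per-site LRRs over sites within ±500 kb on the same chromosome
   (window closed on both ends; windows never span chromosomes). It is
   reported only where the window holds at least 10 sites — single-site
   medians are noise — and the median of an even count is the mean of
   the two central values.

Tumor purity and ploidy are **not** modelled. On a pure diploid tumor a
single-copy loss sits near `log2(1/2) = −1` and a single-copy gain near
`log2(3/2) ≈ +0.58`; because `T/N` renormalises to the genome-wide
average, planted-segment expectations in tests include the correction
`−log2(mean(CN)/2)`, which is ≈ 0.01 for the default segment
configuration. No segmentation, purity/ploidy inference or
allele-specific copy number is attempted.

## Neoantigen enumeration and overlap

For a substitution at protein position *p* in a protein of length *L*,
the candidate peptides are all 9-mers of the mutated sequence whose span
covers *p*: window starts `max(1, p−8)` through `min(p, L−8)`, i.e. 9
peptides at interior positions, down to 1 at the termini. Proteins
shorter than 9 residues yield no peptides (with a warning). Only
single-residue substitutions are supported; frameshift- and
fusion-derived peptides and lengths other than 9 are out of scope.

Binding prediction is consumed from a table of (peptide, allele, %Rank);
the binding model itself is external. The strong-binder threshold is
%Rank ≤ 0.5, **boundary inclusive** (the inclusive reading of the
conventional "≤ 0.5" strong-binder cut; configurable). Duplicate
(peptide, allele) pairs keep the minimal rank. Pairs missing from the
table are excluded from counts and listed in a coverage report rather
than silently dropped.

Neoantigen identity for overlap purposes is the (peptide, allele) pair —
distinct mutations can produce identical peptides — while a
mutation-keyed partition is emitted alongside for burden bookkeeping.
For tests and examples a deterministic hash-based pseudo-rank generator
stands in for real predictions; it is labelled synthetic and is not a
binding model.

## TCR clonotypes

**QC.** Cells with mitochondrial fraction above 10% or with fewer than
200 or more than 4,000 detected genes are removed; boundary values are
retained (the exclusions are strict, matching "above" / "less than" /
"more than").

**Resolution.** Clonotype identity is the TRB (V gene, J gene, CDR3
nucleotide) triple: β-less cells are dropped while α-less cells are
kept, so β defines identity and the top TRA is stored as annotation.
With several candidate β clonotypes (UMIs summed per candidate), the top
one by UMIs is taken unless the runner-up has **more than half** the top
count — exactly half resolves to the top — in which case the cell is
ambiguous. A tie for the top is ambiguous (the conservative extension of
the more-than-half rule). Every input cell lands in exactly one of
{qc_filtered, dropped_no_trb, ambiguous, resolved}.

**Diversity.** Pielou's evenness `J = H′/ln S` with `H′` the Shannon
entropy of clone frequencies and `S` the number of clones with positive
counts; zero counts are dropped first and `S ≥ 2` is required (ln 1 = 0).
`J` is scale-invariant and equals 1 exactly for a uniform repertoire.

**Dominance.** After merging clonotypes across two lesions, a clonotype
is A-dominant when its within-sample frequency in A is at least
`ratio_threshold` (default 2) times its frequency in B, B-dominant
symmetrically, otherwise equivalent. A clonotype absent from one sample
counts as dominated by the other side provided that side holds at least
`min_cells` (default 2) of its cells; clonotypes below `min_cells`
everywhere are excluded. The frequency-ratio quantification is a
parameter, not an assertion about how any particular study drew the
line; the classification is antisymmetric under exchanging the samples.

**Enrichment.** A clonotype is "exhausted" when more than half
(configurable) of its cells sit in the exhausted-CD8 cluster. The 2×2
table {A-dominant, B-dominant} × {exhausted, not} (equivalent clones
excluded) is tested with the in-house exact Fisher test; an empty margin
returns p = 1 with a warning.

**Cluster annotation.** A rule table maps marker combinations to the
nine canonical T-cell states (naive/activated/memory/exhausted CD8;
naive/regulatory/cytotoxic/follicular-helper/activated-memory CD4) plus
a generic T-cell fallback; the only exclusion marker is CD8A for
cytotoxic CD4 cells. A gene is "high" in a cluster when its mean exceeds
the across-cluster **mean** for that gene. The mean was chosen over the
median deliberately: CD4 is required by five of the nine states, and a
marker high in a majority of clusters sits *at* the median in its
weakest positive cluster, so a strict above-the-median rule can never
label that cluster; the mean has no such failure mode
(`dichotomize="median"` remains available). Rules are ordered most
specific first and the first match wins; clusters matching no rule are
`unassigned`. This rule-based annotator is an explicit, testable
surrogate for what is in practice a manual step. Expression
normalisation, integration, PCA/UMAP and graph clustering are out of
scope; the module consumes cluster assignments.

## Statistics

**Fisher exact test** (two-sided): with margins fixed, the p-value is
the sum of hypergeometric probabilities of all tables whose probability
is ≤ the observed table's. Computation is in log space via `gammaln`
(never overflows); exact ties are kept despite float rounding by
admitting tables within relative tolerance 1e−7 of the observed
probability. Against exact integer-arithmetic enumeration the
implementation agrees to ~1e−13 relative error over all 135,751 tables
with total ≤ 40.

**Kaplan–Meier**: the standard product-limit estimator; with no
censoring it equals the empirical survivor function exactly. The median
is the smallest event time with S(t) ≤ 0.5 (NaN if never reached).

**Log-rank test** (k groups): observed-minus-expected event counts over
pooled event times with the hypergeometric variance/covariance, chi-squared
with k−1 degrees of freedom via the pseudo-inverse of the covariance of
the first k−1 groups. Identical groups give statistic 0 and p = 1. Cox
proportional-hazards modelling is deliberately not included.

## Mixed-response classification and survival

Lesion trajectories are assessed within the first 183 days (six months,
inclusive). Per-lesion regression/progression thresholds are not part of
the three-group definition itself, so RECIST-style per-lesion thresholds
are adopted and exposed as parameters: a lesion is regressing if any
in-window scan is ≤ −30% from baseline, progressing if any scan is
≥ +20% or the lesion is newly detected after baseline. A lesion that
regresses and then progresses within the window counts toward **both**
flags — responses are dynamic, and a patient with such a lesion plus a
regressing one is a mixed responder.

Groups: nonmixed responder (every evaluable lesion regressing, no new
lesion), mixed responder (≥1 regressing **and** ≥1 progressing or new),
nonmixed nonresponder (≥1 progressing/new, none regressing). Patients
whose lesions are all stable fall outside this trichotomy; they receive
`stable_unclassified` and are excluded from group comparisons rather
than forced into a bin.

Tumor burden is the sum of measured lesion diameters at a scan. The
simplified RECIST category works on the burden sum only — CR at burden
0, PR at ≤ −30% from baseline, PD at ≥ +20% from the nadir or on a new
lesion, else SD — ignoring target-lesion selection, lymph-node short-axis
rules and confirmation scans; it is a surrogate for tabulation, not a
RECIST implementation. Reported percentages are rounded half-up to one
decimal, matching how such tables are printed.

## Synthetic-data generators

All generators draw from a single `numpy` generator seeded by
`SimConfig.seed`; a fixed seed reproduces every table exactly, and each
generator returns a truth table the test suite consumes (no test infers
ground truth from observables).

- **Paired-lesion mutations**: 60 trunk mutations present in both
  lesions (same allele, independently re-sampled read counts), 30/20
  private to each lesion, all constructed to pass every criterion with
  margin (depth ≥ 25, VAF 0.12–0.5, both strands, ≤ 1 germline read),
  plus 10 decoys per criterion per lesion engineered to fail exactly
  that criterion. Consequences are nonsynonymous with probability 0.75.
- **Depth tracks**: sites every 5 kb on two chromosomes (40 + 30 Mb,
  ~14,000 sites); normal depth Poisson with mean 100 × a GC effect
  (slope 1.5 per unit GC deviation from 0.45, floored at 0.1); tumor
  depth additionally scaled by CN/2 inside planted segments (defaults: a
  2-Mb CN = 1 deletion and a 3-Mb CN = 3 gain). Normal VAFs are binomial
  draws from true genotypes (hom-ref/het/hom-alt plus 10% noisy
  intermediate sites that selection should exclude).
- **TCR repertoires**: 200 clonotypes, clone frequencies a truncated
  power law (exponent 1.2), 8,000 cells per sample. Planted dominance
  classes (15% A-dominant, 65% equivalent, 20% B-dominant, ratio 4) are
  imposed so the frequency ratio holds **after** per-sample
  normalisation — applying the ratio before normalising lets the two
  samples' total masses diverge and silently re-labels planted classes;
  the construction pins the dominant-class mass (20% of a sample's own
  dominant side) and lets equivalent clones absorb the remainder.
  Exhausted flags are drawn at base probability 0.10 for non-A-dominant
  clones and at the odds implied by the target odds ratio (4) for
  A-dominant ones; cells of exhausted clonotypes sit in the exhausted
  cluster with probability 0.9 (0.05 otherwise). Ambiguous (5%), β-less
  (8%) and QC-fail (5%) cells are planted and recorded per cell.
  The 8,000-cells/200-clonotypes scale is a deliberate scale-down from
  the ~16,000 cells per lesion a real 5′ single-cell run yields: at much
  smaller scales typical clones hold only 2–4 cells and chance 2×
  frequency ratios among truly-equivalent clones swamp the enrichment
  signal, which is a property of the data size, not of the method.
- **Cohorts**: 503 patients over four cancer types with per-type group
  counts fixed exactly — melanoma 27/145, head-and-neck 14/86, NSCLC
  20/174, gastric 9/98 mixed responders (70/503 pooled, 13 of the 70
  flagged for local therapy) — so the printed-percentage arithmetic is
  checkable; trajectories implement the group templates with margins
  well beyond the ±thresholds (−50/−60% vs +35/+50%), and 30% of mixed
  responders gain a new lesion at day 90. PFS is exponential with group
  scales 500/250/120 days (responder/mixed/nonresponder), OS 2.2× longer
  and never before progression, both censored by independent exponential
  times (scale 1,500 days). Exponential survival keeps closed-form
  checks available.

What the generators do **not** emulate: read-level data, caller-specific
artefact spectra, subclonal VAF structure, purity/ploidy mixtures,
linkage between the mutation and TCR layers of one virtual patient, or
non-proportional hazards. Passing tests therefore demonstrate
correctness of the implemented procedures under controlled conditions,
not robustness to every artefact of real sequencing data.

## Numerical and degenerate-input conventions

- Median of an even count = mean of the two central values (unit-tested).
- Fisher tie tolerance 1e−7 relative, as above; p clipped to ≤ 1.
- Evenness requires ≥ 2 positive counts; zero tumor depth has no VAF;
  empty variant input yields an empty report, not an error; unsorted
  positions and overlapping CNV segments are validation errors.
- Dominance with both frequencies zero is excluded; an empty enrichment
  margin yields p = 1 with a warning.
- Problem sizes in tests and the acceptance script (14,000 depth sites,
  1,000 oracle calls, 16,000 cells, 503 patients, 135,751 Fisher tables)
  were chosen as the smallest scales at which each property is cleanly
  observable.

## Known limitations

- The LRR normaliser (sum of adjusted depths) is one conventional
  reading; pipelines differ here, which is why it is a config option.
- The dominance rule and the exhausted-clonotype definition are
  parameterised quantifications of qualitative descriptions; results at
  other thresholds follow from the same code paths but are not asserted.
- The simplified RECIST category is not RECIST 1.1.
- Cluster annotation assumes cluster-level marker means are informative;
  it does not model dropout or batch structure.
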