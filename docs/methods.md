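# Methods

This note documents the models behind `ylineage`, the defaults and why
they were chosen, the numerical and tie-breaking rules, what the
simulator does and does not emulate, and the package's known
limitations.

## The data-generating model (simdata)

The simulator emulates a targeted Y-chromosome capture cohort of three
groups — modern admixed (ModAdmix), ancient indigenous (AncNAM), modern
indigenous (ModNAM) — on an abstract haploid reference where the
ancestral base is fixed to `A` and coordinates are drawn without
replacement from a 7.45 Mb target span.

**Tree.** Branches are grown by iterative uniform-random attachment:
branch *b* picks its parent uniformly among branches `0..b-1`. This
Yule-like process produces both deep chains and wide polytomies, the
two regimes a Y-haplogroup tree builder must handle. Each branch
carries `max(1, Poisson(μ))` mutations. Samples attach to branches
uniformly — internal branches included, because real samples are
assigned to internal haplogroups, not only tips. The
`ensure_branch_coverage` flag pins one sample per branch first, making
"every branch observable" constructible for exact-recovery tests.

**Recurrence.** With probability `recurrence_rate` per site, the site
is placed a second time on a branch neither identical to nor on one
root-to-tip path with its home branch. Such a site is guaranteed to
produce a crossing (contradictory) carrier pattern once both placements
have carriers. Default 0.01, matching the ~1% recurrence rate reported
for capture-scale Y-SNP panels.

**Coverage and noise.** Each sample × site is covered with probability
`1 − missingness[group]`; covered sites draw a zero-truncated
negative-binomial depth (zero-truncation keeps the coverage process
governed *solely* by the missingness Bernoulli, so covered-site counts
are exactly binomial — a property the tests check at 3 sd). Reads
report the true allele flipped with `base_error_rate` to a uniformly
chosen other base; phred qualities are normal, rounded, clipped to
[2, 60].

**Defaults as study conditions.** 300 branches; 130/104/43 samples per
group (a 277-sample cohort); 11.3 mutations per branch (≈ 3400 SNPs on
300 branches); InDel fraction 0.064 (≈ 804 of 12 572 variants);
quality model N(35, 5); error rate 0.002. Per-group missingness is
derived from mean covered span relative to the best-covered group
(≈ 13.2 Mb treated as near-complete): AncNAM 1.19/13.16 → 0.91,
ModAdmix 9.94/13.16 → 0.25, ModNAM 0.02. The mapping from covered
base-pairs to per-site missingness is this package's modelling choice;
coverage in real data is strongly *regional* (a sample covers
contiguous intervals), whereas the simulator draws missingness
independently per site. Per-site independence is sufficient for the
coverage asymmetry the tree builder must survive, but it understates
the correlation structure of real dropout — passing tests demonstrate
robustness to the *amount* of missing data, not to its spatial
clustering.

**Capture-QC fixture.** `simulate_capture_meta` emulates a 59-sample
enrichment cohort: log-uniform DNA concentrations over 0.2–9.2 ng/µL
(library inputs skew low), on/off-target ratio with mean ≈ 1 rising
mildly with concentration, and a low-input regime (< 0.6 ng/µL) where
the ratio is depressed and far more variable — the signature the
window statistics are built to detect. It does not model batch
effects, probe GC bias, or duplication structure.

## Calling (basecall)

Strict thresholds: per-read quality ≥ 25, surviving depth ≥ 5, base
majority ≥ 95%, all boundaries inclusive ("minimum of five reads" reads
naturally as ≥ 5; the 19/20 = 95% boundary is pinned by test).
Majority is computed **after** quality filtering. A consequence worth
knowing: the calling rule is monotone in depth and majority (raising
either can only turn calls missing) but *not* in the quality floor —
raising it can discard low-quality contamination and rescue a
previously majority-failing column into a clean call. The suite pins
the monotone property where it holds and the counterexample where it
does not.

Discovery mode needs a single Q ≥ 25 non-reference read (haploid,
depth-one calling), so the discovered site set always contains every
strictly-called site. The ancestral allele defaults to the reference
allele with an explicit override table for known back-mutations; how
novel variants should be polarized is genuinely open (reference vs
outgroup), and the default is a decision, not an inference. A called
base matching neither configured allele is logged and treated as
missing: multi-allelic sites are out of scope. InDels are carried as
single-base-vs-multi-base allele pairs, tallied by the QC module, and
excluded from tree building.

Annotation resolves names by tier (database tree > publication > rs id
> gnomAD), first-listed source winning logged conflicts within a tier;
unmatched sites receive sequential novel identifiers in ascending
position order. Re-annotation of its own output is a no-op.

## Tree building (pairtree)

Relations are classified from the 2×2 derived/ancestral contingency
counts over jointly called samples (table in the README). A pair needs
≥ `min_informative` (default 2) jointly called samples: a single
overlapping sample cannot distinguish nesting from equivalence, and the
default stays low because over half of real cohort variants are
singletons. All-pairs counts are computed as four BLAS matrix products,
so study-scale matrices (hundreds of samples × thousands of sites)
classify in seconds.

Design choices, each pinned by oracle or recovery tests:

* **Contradiction removal** is greedy by descending contradiction
  count, ties by ascending site order — deterministic and near-optimal
  on the sparse contradiction graphs recurrence produces; no exhaustive
  vertex cover is attempted.
* **Equivalence clusters** are transitive closures of pairwise
  equivalence. A cluster is ambiguous and removed when two members hold
  conflicting definite relations to a third site, or when closure glued
  members that are themselves in a definite non-equivalent relation
  (possible only under missing data).
* **Hierarchy assembly** classifies *cluster* pairs on merged columns
  (derived if any member derived; ancestral if none derived and some
  member ancestral), transitively reduces the above/below DAG, and
  requires a unique immediate dominator; clusters with several
  admissible placements are dropped as ambiguous. Cluster-level
  contradictions (again a missing-data artefact) drop the
  smaller-carrier cluster. Polytomies are kept explicit; no binary
  resolution is invented.
* **Singleton tip placement:** a single-carrier cluster uninformative
  against every placed cluster is attached under the deepest placed
  cluster whose carriers contain its sample, flagged `tip_placed`,
  rather than discarded — sample-specific tip branches are real
  structure, not noise.
* Siblings order by descending carrier count, then site order; branch
  ids are assigned in preorder. The whole module is deterministic.

`audit_tree` re-checks every output ancestor/descendant link against
the raw counts (a descendant-carrier observed ancestral at the
ancestor SNP falsifies the link); the robustness suite requires a clean
audit under 30% missingness.

## Anchoring and nomenclature (refanchor)

The merged topology is the transitive reduction of the union of two
constraint sets: the reference's parent links, and the inferred tree's
parent links mapped through the SNP-name anchoring. An inferred
constraint between two anchored branches that contradicts reference
ancestry is dropped and reported — reference precedence. Where the
union leaves two ancestors of a common node unordered (a pass-through
database branch vs a novel cluster inserted from data), database
branches are ordered above novel ones, keeping novel clusters at
database depth; residual ties are ordered deterministically and
reported. "Most parsimonious" is thus operationalized as: no invented
nodes, minimal structure satisfying all non-contradicted pairwise
constraints. A cluster matching two reference branches on one ancestor
line merges into the deepest (SNPs the reference assigns to shallower
branches stay there); matches to incomparable branches leave the
cluster unanchored and reported. Anchoring is idempotent.

Novel branches are named in the Y Chromosome Consortium lineage style:
parent lineage label + alternating letter/digit ordinal + hyphenated
first defining SNP. Ordinals already used at that lineage level
*anywhere* in the tree are skipped, because database names are
historical: inserting a novel branch above `Q1b1a1a1-M848` must not
mint a second `Q1b1a1a1`.

## Assignment (hapassign)

A branch is supported for a sample when ≥ 1 defining SNP is derived
and the derived fraction of typed defining SNPs is ≥ `min_support`
(default 0.95, mirroring the strict-majority ethos of calling; the
underlying studies do not publish their exact per-sample QC rule). A
branch with typed defining SNPs all ancestral blocks descent; an
untyped branch is passable — missing is not contradiction. The sample
takes the deepest supported reachable branch; two supported branches of
equal maximal depth on diverging paths (only possible with conflicting
calls) fall back to their deepest supported common ancestor and flag
the sample. No supported branch at all → `failed_qc`.

Adding markers never reduces assignment depth or distinct-lineage
counts *when the calls are consistent* (noiseless complete data, the
pinned property). With noisy calls the guarantee genuinely fails: an
added marker can type a previously-untyped intermediate branch
all-ancestral and block descent. `resolution_report` therefore only
asserts monotonicity when told the panels are nested and consistent.

## QC statistics (qcstats)

Capture specificity is on-target / off-target sequenced bases (zero
off-target → undefined, reported). Windows are stride-1 sliding
windows of five samples over concentration-sorted metadata (ties by
sample id); "variation" is the sample standard deviation by default
(variance and coefficient of variation are options — the underlying
spread measure is not standardized in the capture literature). The
stability threshold is the mean concentration of the
maximum-variation window, ties resolved toward the lower
concentration. Pearson r and its two-sided p come from
`scipy.stats.pearsonr`; constant inputs are reported as undefined.
Integer percentages round half away from zero (54.92% → 55%), as do
fold changes (10.72 → 11). The seven-cell group partition classifies
each variant by the set of groups containing ≥ 1 derived carrier and
always sums to the variant total.

## Problem sizes

The acceptance suite runs, per seed: exact recovery on 30 branches ×
120 samples × ~3 mutations/branch (20 seeds), recurrent-site removal
(3 seeds), robustness audit on 20 branches × 60 samples at 30%
missingness (20 seeds), and the anchored end-to-end pipeline (2 seeds).
"Complete data" runs use a depth model of mean 30 with near-Poisson
dispersion so the chance of any column dipping below the strict
minimum depth is negligible. The acceptance script runs the full
study-scale defaults (300 branches, 277 samples, noisy) once — about
20 seconds on one CPU — plus three clean recovery runs and the QC
cohort.

## Limitations

* Evidence arrives as per-position pileups or a minimal haploid VCF;
  alignment, duplex-consensus building, deduplication and recalibration
  are upstream of this package.
* Calling is the threshold rule, not a genotype-likelihood model, and
  sites are strictly biallelic.
* The simulator's per-site-independent missingness and error do not
  reproduce regional dropout, reference bias, or ancient-DNA damage
  profiles (C→T deamination); results on real ancient data will be
  correspondingly harsher.
* No branch lengths, dates, or TMRCA estimation — the hierarchy is
  purely topological.
* Equivalence of the tree-building stage with any external sorting
  software is not claimed; its behaviour is pinned against the
  brute-force carrier-set oracle and truth-recovery tests defined here.
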