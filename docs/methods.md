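# Methods

## Scope and model

`dpgkit` analyses divergently-paired genes (DPGs): adjacent protein-coding
genes on opposite strands transcribed head-to-head whose transcription start
sites (TSSs) lie within 1 kb of each other, so that the inter-TSS interval
acts as a shared bidirectional promoter. The pipeline covers six analysis
stages — pair calling, cross-species conservation coding, tissue
co-expression, scaled regulatory-signal metaprofiles, population indel
pressure on the inter-TSS space, and lineage assignment of alignment gap
blocks — plus a synthetic-data generator that plants ground truth for every
stage. All tests and the acceptance script run on synthetic cohorts; no
external data are downloaded.

## Pair calling

A gene model keeps one canonical transcript, the longest by span, with ties
broken by the lexicographically smallest transcript ID for determinism. The
TSS is the canonical transcript's start (`+` strand) or end (`-` strand);
gene-bound TSSs are available via `tss_source="gene"`. Coordinates are
1-based inclusive throughout, matching GFF3; any half-open arithmetic is
internal.

The signed inter-TSS distance of a (minus-strand, plus-strand) gene pair is
d = TSS(+) − TSS(−); d < 0 means the 5′ regions overlap. Pairs are every
opposite-strand combination on one chromosome with |d| < 1000 (strict).
Divergence is defined purely by this distance window — no gene-body-overlap
exclusion is applied; unusual nested configurations within the window are
admitted and surfaced through the ambiguity log. Because a gene may fall
within 1 kb of several opposite-strand TSSs, a one-gene-one-pair resolution
is applied: candidates are ranked by |d|, ties by the smaller partner TSS
(implemented as the TSS sum, which compares partners symmetrically
whichever member is contested), then by gene IDs, and accepted greedily.
Displaced candidates are logged. The fast path (per-chromosome binary
search) is checked against an exhaustive double-loop oracle in the tests.

Spacing modes follow the distance sign and a configurable boundary
`t_distant` (default 500 bp): overlapping (d < 0), optimal (0 ≤ d ≤ 500),
distant (d > 500). The published mode definitions rest on where
active-promoter (H3K4me3) peaks fall rather than on a printed distance
rule, so a peak-based classifier is provided as an alternative mode: one
peak cluster between the TSSs → optimal, peaks only outside the interval →
overlapping, two separated clusters → distant. The distance rule is the
default because it is exactly reproducible.

## Conservation coding

Each pair is scored per comparison species from a many-to-many ortholog map
and the target species' own pair set: 2 when some ortholog combination of
the two members is itself a divergent pair in the target (only one
combination is required — the most favourable reading of "orthologs
maintaining the same orientation"); 1 when both members have orthologs but
no combination pairs (orientation or spacing lost — both causes fold into
code 1); 0 when exactly one member has an ortholog; −1 when neither does.
Orthologs absent from the target annotation are ignored. An `uncertain`
flag exists for annotation-quality exceptions and is only ever set from an
explicit list, never inferred.

Fully conserved pairs require code ≥ 2 in every species (`min_code=1` is
exposed); orientation-specific pairs have code exactly 1 in at least one
species. Species are clustered on their code rows with complete linkage and
Euclidean distance (the linkage method is the study convention; the metric
is our choice, as only the linkage is conventionally fixed), verified
against a naive O(n³) agglomeration oracle.

## Co-expression

Samples need RIN strictly above 6; tissues need strictly more than 20
surviving samples. Correlation is Spearman's rho on ln(TPM+1) across the
samples of each tissue, with average-rank ties; fold changes use raw-TPM
tissue medians — the two conventions intentionally differ, mirroring the
two separate definitions. The two-sided p-value uses the t approximation at
n ≥ 10 and exact permutation enumeration below (n ≤ 9), where the
approximation is unreliable.

Thresholds are all strict as specified: co-expressed in a tissue iff
rho > 0.8 and p < 0.05; generally co-expressed iff rho > 0.7 in more than
70% of tissues. The pair's level comes from its maximum defined rho over
tissues: high (> 0.9), medium (0.8–0.9 read as a closed interval, so
rho = 0.9 is medium), RLow (< 0.8). A pair with a constant gene in a tissue
gets an undefined rho there — excluded from the maximum, never coerced to
0. Note the per-tissue flag and the max-based level are distinct statistics:
a medium-level pair can have no co-expressed tissue when its p-values are
large (small n); the tests pin this non-implication.

## Signal metaprofiles

Inter-TSS intervals vary from −1 kb to +1 kb, so signals are rescaled onto
a common axis: the closed interval between the TSSs is integrated (signals
treated as piecewise-constant per base) into 1000 equal segments — exact
for any length ratio, so constant tracks are preserved to float precision —
oriented from the minus-gene TSS toward the plus-gene TSS, with 500 bp
flanks appended unscaled at 1 bp per position (flank handling is our
choice; default flank 500 bp). A zero-length interval (d = 0) replicates
its single-base value. Group metaprofiles are positionwise means over the
pairs of each co-expression level.

Peaks are local maxima above a prominence threshold defaulting to 10% of
the profile range (no published parameters exist); plateau maxima report
their leftmost index. GC content uses a 50 bp window sliding by 3 bp, with
N bases excluded from the denominator and all-N windows undefined.
Display-only transforms (methylation ×20, DNase ÷10) are never applied to
stored values. Promoter signal fold change is the larger over the smaller
mean signal in ±250 bp windows around the two TSSs, undefined when the
smaller is zero. Shared TFs are those with motif hits on both members'
regulatory regions; core TFs are the top k = 3 by mean Spearman rho against
the two members over tissues (co-expression with the pair members, not
among TFs — the open reading we adopted), ties by TF ID.

## Indel pressure

Indels are read from VCF with AF taken from the INFO field (global
alternate-allele frequency; the population field is not otherwise
specified). The AF is rounded to 6 decimals after parsing because the
reader holds it at float32 precision and the threshold must behave as the
printed text does. Filters are inclusive: AF ≥ 0.005 and length change
≥ 2 bp. An indel belongs to a pair when its (left-aligned) position lies in
the closed interval between the TSSs; abutting regions may both claim one
indel. Pairs are binned by inter-TSS distance into 40 half-open 50-bp bins
over (−1000, 1000); both raw totals and per-pair means are emitted since
the normalisation convention is not fixed. The per-bin deletion/insertion
ratio is only defined when insertions exceed 1; otherwise it is an explicit
undefined marker, never clamped.

## Gap-block lineage events

Three-way alignments (focal, sister, outgroup — e.g. human, chimpanzee,
macaque) are scanned for maximal runs of columns where the focal row is
gapped. Runs are maximal per joint gap pattern, so a pattern change splits
a run and every block carries one label: focal-lost (sister and outgroup
both carry sequence), sister-insertion (only the sister does), other
(anything else). N counts as sequence. The minimum event length defaults to
2 bp, mirroring the indel length filter, as no published value exists.

## Statistical contract

Proportion comparisons on 2×2 tables use Fisher's exact test up to a total
n of 40 and the chi-squared test above (strictly n > 40), two-sided. The
chi-squared branch applies the Yates continuity correction by default, with
an uncorrected option. Distribution comparisons use the two-sided
Mann–Whitney U test with average-rank ties. Significance bands are the
conventional 0.05 / 0.01 / 0.001 stars.

The type-I calibration simulates a true null (equal binomial proportions)
1000 times per branch and checks the rejection rate at α = 0.05 against
[0.03, 0.07]. The null designs were fixed by exact size computation (sum of
binomial-product probabilities over all table outcomes): the Fisher branch
uses groups of 14 and 25 at p = 0.5 (exact size 0.044) because balanced
small-group designs are inherently more conservative — Fisher's exact test
with 20/20 groups cannot reject more than ~2% of true nulls at any p, a
property of its discreteness, so a balanced design could never sit in the
band. The chi-squared branch uses 150 per group at p = 0.5 (exact size
0.043 with Yates).

## Synthetic cohorts: what they emulate and what they do not

The generator is a pure function of (spec, seed); each output type draws
from an independent seeded stream, so consuming one generator never
perturbs another. Study conditions planted by default:

- **Spacing**: a three-component truncated-normal mixture on integer
  support — overlapping N(−469, 150²) on [−999, −1], optimal N(95, 80²) on
  [0, 500], distant N(976, 20²) on [501, 999] — weighted 0.29/0.60/0.11
  after the relative abundances of the three modes. Pair units are spaced
  20 kb apart with same-strand, far-apart, convergent, and non-coding
  decoys covering each reason a gene must not pair.
- **Conservation**: per-species categorical class draw (defaults 0.5 / 0.2
  / 0.2 / 0.1 for codes 2/1/0/−1) realised structurally — code-2 orthologs
  are placed as an actual target pair, code-1 orthologs on one strand 5 kb
  apart, etc. — so the classifier is tested end to end, not against labels.
- **Expression**: Gaussian copula with log-normal TPM margins. Targets are
  Spearman values; the copula's Pearson parameter is set to
  r = 2·sin(πρ/6), the inverse of the bivariate-normal grade
  correlation, so planted rho is recovered without the systematic ≈1%
  distortion a naive r = ρ would carry. Default targets 0.95/0.85/0.30
  weighted 0.25/0.35/0.40, five tissues of 50 samples, plus RIN≈5 decoy
  samples and a 10-sample decoy tissue that the filters must remove.
- **Signal**: one Gaussian bump per pair at the inter-TSS midpoint
  (σ = L/8, floor 5 bp), amplitude 10/5/2 by co-expression level.
- **Indels**: Poisson counts per region (mean 3 passing, 1.5 failing;
  failing records violate exactly one filter, half on AF and half on
  length), insertion probability 0.65 in overlapping regions vs 0.35
  elsewhere, emulating the observed insertion bias of overlapping spacings.
- **Alignments**: a 1.5 kb ancestral sequence with 3 focal-lost, 3
  sister-insertion and 1 mixed-pattern event of 2–12 bp at distinct
  interior positions, so every planted block is maximal with a known span.

These fixtures are format-faithful (GFF3, TSV, bedGraph, VCF, aligned
FASTA) but deliberately idealised: genes never share TSS coordinates with
unrelated neighbours except in the stress catalogs, expression margins are
exactly log-normal, signal is noise-free, indels are independent of
sequence context, and alignments contain no substitutions. Passing tests
therefore demonstrate correctness of the computations and exact contract
behaviour at boundaries — not robustness to annotation errors, expression
batch effects, or alignment ambiguity in real data.

## Problem sizes and numerical choices

The analysis drivers and acceptance script use cohorts of 500 pairs
(≈1100 genes), 6 comparison species, 5 tissues × 50 samples, 200 copula
replicates per rho target, 100 random catalogs for the pairing oracle, 100
random alignments, and 1000 null replicates per test branch — sizes at
which every planted-truth check is exact and the whole run completes in
seconds on one CPU. Degenerate inputs are handled explicitly rather than
silently: empty catalogs, constant genes, zero-length intervals, flat
profiles, missing AFs, and empty housekeeping lists each produce a defined
marker, warning, or error as documented on the function.

## Known limitations

- The published overlapping/optimal/distant decision rule is not exactly
  recoverable; the distance rule with `t_distant=500` reproduces the
  qualitative classes but not necessarily the published group sizes.
- Code 1 conflates orientation loss with spacing loss; the two cannot be
  separated without a printed rule.
- The pipeline consumes ortholog tables and motif-hit tables; orthology
  inference and motif scanning are out of scope.
- `bigWig` input is optional (pyBigWig); bedGraph is the tested path.
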