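# Methods

`mengen` re-implements, as a tested library, the downstream statistical
analyses used in cohort genomics of high-grade meningioma: mutation burden
and spectrum, arm-level somatic copy-number alteration (SCNA) calling,
driver co-occurrence and binomial detection power, multi-sample
heterogeneity and recurrence phylogenetics, complex-rearrangement
decomposition with repair-mechanism classification, and neoantigen scoring.
Because the real tumor data of such studies are controlled-access, the
package ships a synthetic-cohort generator with a recorded truth table, and
every analysis stage is validated by recovering that truth.

## Models and procedures

### Mutation burden and spectrum (`burden`)

A mutation is *nonsynonymous* when its classification is one of {missense,
nonsense, splice_site, frameshift_indel, inframe_indel}; silent and
noncoding calls are excluded. The allelic-fraction filter discards records
with AF < 0.1 (the boundary is kept) and is applied to driver and
recurrence analyses only — burden counts default to unfiltered, because
low-AF passengers still contribute to mutational load; a flag exposes the
filtered variant. SNVs are collapsed to the six pyrimidine-reference
substitution classes (G>A counts as C>T, etc.); indels are excluded from
the spectrum. Samples with burden above Q3 + 3×IQR are flagged as
hypermutators but never removed. Group comparisons use Student's t or the
Wilcoxon rank-sum (Mann–Whitney U), both two-sided, via `scipy.stats`.

### Percent genome disrupted and arm events (`scna`)

Percent genome disrupted = 100 × (covered autosomal length on segments with
|log2 ratio| ≥ 0.2) / (total covered autosomal length). Sex chromosomes are
excluded because cohorts mix sexes. An arm is called gained (lost) when at
least 80% of its covered length lies at log2 ≥ +0.2 (≤ −0.2). The 0.2/0.8
thresholds are conventional arm-call values, exposed as parameters. Arm
coordinates derive from the hg19 cytoband table and ship with the package;
cohort incidence excludes angiomatous samples from the denominator by
default, since their gain-dominated profiles are outliers. A one-copy loss
at purity ρ appears at log2(1 − ρ/2) ≈ −0.74 for ρ = 0.9, so these
thresholds give essentially error-free arm calls at the purities the
generator emulates (≥ 0.8); at low purity (≲ 0.45) a single-copy event
falls below 0.2 and would be missed — ploidy correction is out of scope.

### Driver association and detection power (`assoc`)

Driver flags (NF2 mutation, chromosome-22q loss, canonical non-NF2 driver —
TRAF7/KLF4/AKT1/SMO by default, extensible to the other published genes)
are derived from AF-filtered mutations and arm calls. Pairwise association
uses Fisher's exact test (two-sided, by summation of hypergeometric
probabilities no larger than the observed table's); perfectly nested flags
give an infinite sample odds ratio, reported as missing with direction
co-occurring. Benjamini–Hochberg q-values are reported alongside raw p.

The detection-power model treats the number of mutated patients in a
cohort of n as Binomial(n, p) and asks for the rate p at which
P(X ≥ k) equals a target power. The tail is continuous and strictly
increasing in p, so bisection (to |Δpower| < 1e−10) finds the unique root.
The whole-percent figure reported is the smallest integer percent whose
power meets the target — the natural reading of "power to detect genes
mutated in at least X% of patients". With the package defaults n = 115 and
k = 15, the 95% and 50% targets land at 19% and 13%.

### Heterogeneity and recurrence phylogenetics (`hetphylo`)

Events are identified by (chrom, pos, ref, alt), gene-independent. Within a
patient with k ≥ 2 samples, an event is ubiquitous (present in all k),
shared (2..k−1), or private (exactly 1); single-sample patients are flagged
unanalyzable. Pairwise overlap is Jaccard |A∩B|/|A∪B| by default — the
symmetric, bounded choice — with a per-sample-denominator variant (mean of
|A∩B|/|A| and |A∩B|/|B|) exposed, since published "percent shared" figures
are ambiguous between the two. The discovery curve averages, over all
size-m sample subsets, the fraction of the patient-wide event union
recovered; it is monotone and ends at 1.

Detection power for an event in a sample is P(≥ 3 alt reads) under
Binomial(depth, expected clonal AF), with expected AF =
ρ·m / (ρ·c + 2(1−ρ)) for purity ρ, local copy number c (default 2) and
multiplicity m (default 1); the ≥3-read threshold is a standard calling
heuristic. Site depths are used when available, else the sample's mean
coverage. Trees use only events powered (≥ 0.95) in *every* sample of the
patient: distances are 1 − Jaccard, neighbor joining (scikit-bio) with
negative branch lengths clamped to 0, rooted by an all-absent germline
outgroup; sample ids are sorted before the distance matrix is built, making
output invariant to input order.

Topology classification asks whether successive resections look like
progressive dominance of one invasive lineage (linear) or outgrowth of
geographically distinct lineages (branched). For each chronologically
consecutive pair (i, i+1), the pair scores when resection i+1 is among the
nearest *later* samples of i in patristic distance; the adjacency score is
the fraction of consecutive pairs scoring, and the call is linear when the
score ≥ 0.5. A strict mutual-nearest-neighbor rule was rejected during
design: on a perfect ladder (each resection adding private mutations to the
last) an interior sample is always closer to its later neighbor than the
earlier one, so mutual nearest neighborship cannot reach a perfect score on
exactly the series that should be called linear; the directional rule
scores a perfect ladder 1.0 and alternating-lineage cherries below 0.5.

### Rearrangements (`sv`)

Junctions of one sample are linked when any breakend of one lies within 10
kb of any breakend of another on the same chromosome; connected components
(networkx) are events, and components with ≥ 4 members are complex
(chromothripsis/chromoplexy-like). The linkage window is a package choice —
assembly-based SV callers do not expose one — and a sensitivity table of
complex fraction versus window is emitted as a diagnostic. Clustering is
per-sample only.

Mechanism classification follows the conventional microhomology/insertion
decision table: templated insertion ≥ 10 bp → MMBIR; else microhomology
≥ 3 bp → MMEJ; else (homology ≤ 2 bp, insertion < 10 bp) → NHEJ. Repeat
overlap flags are ingested and retained but no repeat-mediated (NAHR) class
is assigned. Thresholds are parameters.

### Neoantigens (`neo`)

For each protein-altering mutation, candidate peptides of lengths 8–11
(MHC class I) and 15 (class II) containing an altered residue are
enumerated; frameshifts contribute every window with at least one novel
residue, with no wild-type counterpart. Binding prediction itself is out of
scope: per-predictor affinities (nM) arrive as data. The composite affinity
is the median across predictors; the neoepitope ratio is mutant composite /
wild-type composite (scale-invariant; forced to 1 when the peptides are
identical). Per mutation only the best epitope (minimum mutant composite
across alleles and lengths; ties by lower ratio, then lexicographic
peptide) is considered, and the mutation is neoantigenic when that
composite ≤ 500 nM, the conventional weak-binder cutoff (a parameter).

Clonality uses a closed-form cancer-cell-fraction estimate,
ccf = AF · (ρ·c + 2(1−ρ)) / (ρ·m), capped at 1 (the raw value is
retained), with clonal defined as ccf ≥ 0.9. This replaces full
purity/ploidy modeling and is accurate to a median absolute error well
under 0.1 at 100× depth and purity ≥ 0.8. The expression filter ranks genes
by cross-sample mean, removes the lowest ⌊0.25·G⌋ (ties broken by gene
name), and reports the fraction of neoantigen-bearing genes retained.

## The synthetic generator (`simdata`)

Each patient receives a clone tree under an infinite-sites assumption (no
back-mutation; single-copy multiplicity): a trunk clone plus subclones in
either a single chain (linear) or two sibling chains (branched). Resection
r is dominated by the r-th clone along the chain (linear) or alternates
between branches (branched); a sample's mutations and arm events are the
union along its dominant clone's ancestry, so arm events — placed mostly on
the trunk — are far more conserved across recurrences than mutations,
reproducing the stability asymmetry the analyses measure. Allele counts are
drawn Binomial(depth, expected AF) at Poisson depth; a record enters the
sample's table when it reaches 3 alt reads, so absent clones yield absent
records and present clones are detected essentially always at the default
100× coverage and purity 0.8–1.0.

Defaults are anchored to the magnitudes the analyses target: nonsynonymous
burden Poisson with grade means {I: 8, II: 23, III: 23}; spectrum dominated
by C>T (weight 0.55); 22q-loss marginal rate 0.56, multiplied by 1.5 in
NF2-mutant patients (and 0.5 otherwise) so NF2 mutation and monosomy 22
co-occur while the marginal is preserved at a 50% NF2 rate; canonical
non-NF2 drivers anti-correlated with NF2 (40% vs 5%); mechanism mixture
MMEJ 0.45 / NHEJ 0.45 / MMBIR 0.10; a complex event in 40% of samples with
4 + Poisson(8) junctions chained within the linkage window across ~4
chromosomes, isolated junctions kept ≥ 10 Mb apart; two thirds of
nonsynonymous mutations neoantigenic, with a higher binder rate on the
trunk (0.70 vs 0.60) so neoantigenic mutations skew clonal. Affinity tables
are lognormal with per-predictor scatter rescaled so each pair's median
hits its target; expression is lognormal.

What the generator does *not* emulate — and hence what passing tests do not
establish about real tumors: trinucleotide (96-class) signatures, focal
SCNAs and ploidy shifts, intra-sample subclonal admixture (off by default;
a knob exists), sequence-context-real peptides, germline contamination, or
caller-specific artifact modes. Recovery tests certify the bookkeeping and
the statistics, not the upstream callers.

## Numerical choices and degenerate inputs

Bisection tolerance 1e−10 on the power scale; Fisher tie comparison uses
the standard relative slack; BH q-values via the step-up recursion.
Zero-margin 2×2 tables return p = 1 with a missing odds ratio. Empty
spectra, empty composition groups, and zero-mutation neoantigen fractions
report NaN rather than 0. NJ tie-breaking is made deterministic by sorting
sample ids; negative NJ branch lengths are clamped to 0. BEDPE is 0-based
half-open and converted to 1-based inclusive at the boundary; all internal
coordinates are 1-based inclusive; chromosome names are normalized by
stripping `chr`.

## Problem sizes

Validation runs use cohorts of 200 single-sample patients (arm-event and
mechanism recovery), 200 four-sample patients at 30 mutations per clone
(topology recovery), 2,000 draws at 100× depth (CCF error), and ≥ 1,000
mutations (neoantigen fraction), with fixed seeds throughout.

## Known limitations

Arm calls are not ploidy-corrected; whole-genome doubling would defeat the
log2 thresholds. The power filter applies a whole-sample expected AF unless
site depths are supplied. The topology classifier assumes each resection is
dominated by a single clone; heavily admixed samples blur the
linear/branched distinction. Cohort-level figures from controlled-access
data (e.g. observed shared-fraction means) depend on upstream callers and
are design anchors for the generator, not quantities this package claims to
reproduce.
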