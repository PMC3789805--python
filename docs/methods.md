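# Methods

This note documents the models and procedures behind each stage, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## The analysis model

Two diploid genome groups, A and D, diverged from a common ancestor; an
allopolyploid later formed from one A-like and one D-like progenitor, so
its nucleus carries both genomes as subgenomes A_T and D_T. All analyses
are performed in the coordinate frame of a single D-like reference
sequence. The central object is the **homoeo-SNP index**: the catalog of
reference positions where the two genome groups carry fixed, diagnostic
alleles. Everything downstream — subgenome read categorization, conversion
detection, pseudo-genome construction — consumes this index.

Internally every coordinate is 0-based half-open; 1-based conventions
exist only at the SAM/VCF/GFF3 boundaries. Bases are uint8 codes
(A=0, C=1, G=2, T=3), and all per-base work (pileups, genotype calling,
read voting, run detection) is vectorized over whole chromosomes.

## Genotype calling and the index

A site is callable at depth ≥ 10 (`min_depth`); with the two most frequent
bases *major*/*minor*, the call is heterozygous when minor/depth ≥ 0.40
(`min_maf`, inclusive — "a minimum of 40%" includes 40%), otherwise
homozygous for the major base. Count ties break by the fixed base order
A<C<G<T, the only deterministic convention that is also order-free.
Exact-boundary arithmetic relies on correctly-rounded division: 4/10 and
6/15 both compare equal to 0.40.

The index rule: a position enters the index when **every accession with
coverage there is homozygous**, all covered A accessions agree on one
base, all covered D accessions agree on another, and the bases differ. At
least one covered accession per group is required; "with coverage" means
"has a non-nocall genotype", so a group that is entirely below the depth
floor cannot satisfy unanimity and the site is skipped. A heterozygous
call anywhere vetoes the site; third alleles are excluded by construction
(unanimity on two differing bases leaves no room for one).

No mapping- or base-quality filtering is applied after alignment
(`min_mapq` exists but defaults to 0) and duplicates are kept; both are
configurable where a stricter protocol is wanted.

## Read categorization

Each aligned read votes once per index site covered by an M/=/X-aligned
base: the A allele votes A, the D allele votes D, any other base (error or
third allele) abstains. The majority decides. A read overlapping no index
site is `uncat_no_snp`; a tie — including the all-abstain case — is
`uncat_conflict`. Ties are surfaced rather than broken, and votes are
unweighted: plain counts keep the rule transparent, and base-quality
weighting adds nothing for the constant-quality simulated reads this
package validates against. The truth-based error rate is
(reads assigned to the other group) / (reads assigned at all).

## Structural variation

**Deletions** are coverage gaps: maximal runs where the library-size-
normalized test depth is < 3 at every base (strict, per "near-zero
(<3-times)"), of length ≥ 1000 bp, where the control track holds ≥ 20
(inclusive) at the run's first and last base and at ≥ 1 interior base at
least 200 bp from both ends. "Both ends" are the endpoints of the
zero-coverage run itself, evaluated on the control — the control has
coverage there while the test does not, which is the only reading under
which the check is informative. Normalization precedes thresholding, so
fractional depths are compared.

**Duplications** use a deliberately simplified control-vs-test Poisson
peak caller: fixed 200-bp windows; per window, the local rate is the
maximum of the genome-wide control rate and the control rate in 1-kbp and
10-kbp windows centered on it (the "dynamic" background); coverage sums
are converted to read-equivalent counts (divided by the read length)
before the upper-tail Poisson p-value is taken, because per-base coverage
sums are overdispersed by a factor of the read length; windows with
p < 1e-5 and fold ≥ 1.5 merge into peaks. There is no fragment-size model
building — read-shifting is meaningless for WGS — and no FDR correction,
mirroring peak-caller practice; the threshold is configurable. A planted
tandem duplication appears as a fold ≈ 2 peak.

**Conserved regions** are the base-level intersection over all required
accessions minus the union over excluded accessions, re-segmented and
length-filtered; the implementation is an event sweep, validated in tests
against per-base bit vectors. **Gene overlap** reports genes whose length
is covered ≥ 50% (inclusive) by the interval union, flagging genes spanned
end-to-end by one single interval as completely deleted.

## Conversion detection

**Method 1 (site-wise).** At an index site (a, d), both subgenome
genotypes homozygous for *a* is an A_T-biased conversion signal (the D_T
copy carries the A allele), both homozygous for *d* a D_T-biased one. The
direction requires *both* subgenomes homogenized, matching what a
conversion physically does; the reciprocal single-swap pattern is flagged
`double_swap` (a categorization artifact, not a direction) and any third
allele `novel_allele`. The signal is inherently confounded: a
lineage-specific (autapomorphic) substitution onto the other genome's
allele produces the identical pattern with no conversion at all. The test
suite asserts this confound as a positive control on conversion-free
simulations.

**Method 2 (region-wise).** Within the presence mask (bases where every
diploid accession of both groups has depth ≥ 1 — conversion is only
defined where both progenitor genomes exist), the subgenome coverage
tracks of the categorized tetraploid reads are scanned with coverage-gap
semantics at relaxed thresholds: a maximal run where the "deleted"
subgenome is < 4 at every base, trimmed to the span delimited by the
"duplicated" subgenome's first and last base ≥ 15, with one further
interior point ≥ 15 at least 200 bp from both ends, and trimmed length
≥ 1 kbp. Two deliberate departures from a per-base high-side rule:

- categorized coverage legitimately dips wherever a read span contains no
  diagnostic site (an index-sparse stretch leaves reads uncategorizable),
  so demanding ≥ 15 at every base fragments genuine tracts;
- categorized coverage decays across a tract boundary, because
  boundary-spanning reads vote with whichever side contributes more of
  their span; trimming the run to the high-side-delimited span keeps the
  endpoint test out of this transition zone.

The cross-tabulation reports, per region, how many diploid index sites it
contains and how many of those still segregate between the tetraploid
subgenomes — zero inside a genuine conversion, which homogenizes the
copies.

## Molecular evolution

Pseudo-genomes substitute one genome's diagnostic alleles into the
reference; by construction they are gapless, so per-gene alignments are
trivial codon-wise pairings. dN/dS is **Nei–Gojobori (1986)** with equal
pathway weighting: per-codon synonymous site counts are the fraction of
one-step changes preserving the amino acid (changes to a stop codon count
as nonsynonymous, so S + N = 3 per counted codon); observed differences
per codon pair are averaged over all minimal mutational pathways,
excluding pathways through stop intermediates (if every pathway passes
through a stop, the full enumeration is averaged with a warning); the
Jukes–Cantor transform d = −(3/4)·ln(1 − (4/3)p) corrects both
proportions. The method was chosen because the counting approach is the
standard baseline where no estimator is named; users comparing against
codon-model ML estimates should expect the usual NG86 downward bias at
high divergence. Conventions: the terminal stop codon is trimmed; codon
pairs containing an internal stop or an ambiguous base are skipped;
proportions ≥ 0.75 are reported `saturated`; "sufficient polymorphism"
for an omega is ≥ 1 observed difference and dS > 0, else
`insufficient_polymorphism`. Standard nuclear code only.

Stop-codon screens report every in-frame stop strictly before the final
codon with its position fraction, flagging those in the final 10% of
codons (conventionally ignored as likely annotation artifacts), plus
disrupted start codons (first amino acid differs from the reference's),
altered stops (reference stop lost) and reference genes lacking an
annotated stop.

## Distances, trees, attribution

The distance between two taxa is the mean score over co-called, unmasked
sites: identical genotypes 0; homozygous for different bases 1; differing
genotypes that share an allele 0.5 (switchable to strict 0/1 — the 0.5
convention acknowledges that a heterozygote half-matches either
homozygote). The tetraploid subgenomes enter as two separate taxa.
Neighbor-joining is the standard Saitou–Nei agglomeration on the Q
criterion; ties break deterministically on sorted taxon names (for
internal nodes, the smallest descendant leaf); negative branch lengths are
clamped to zero with the deficit moved to the sibling edge, as the
classical implementations do. Branch attribution is computed against a
*supplied* clade structure, not the inferred tree: a site counts for clade
C when all C members are called and homozygous for one shared allele and
every other called taxon is homozygous for a single different allele;
heterozygous or clade-splitting patterns are unassigned. Heterozygosity
summaries use each taxon's observable (called, unmasked) sites as the
denominator within each partition (genome/genic/nongenic) — sites inside
group-conserved duplications are masked first, since collapsed paralogs
masquerade as heterozygotes.

## The synthetic-data generator

The generator emulates the study conditions and is not a tuning dial. Its
defaults *are* those conditions: fixed inter-genome differences at
1 per 32.3 bases, 40× coverage of 100-bp single-end reads, 1% base error
(constant Phred-35 qualities — trimming is out of scope), two accessions
per diploid group at desk scale, and a tetraploid sequenced at the same
total coverage split evenly between subgenomes. Where no number is stated
anywhere, values were fixed once at what is realistic for this system and
not revisited:

| parameter | default | rationale |
|---|---|---|
| `allele_snp_rate_A` / `_D` | 0.004 / 0.0005 | qualitative A ≫ D diversity contrast |
| `het_rate_A` / `_D` | 0.005 / 0.0002 | same contrast, ~25× ratio |
| `deletion_count`, lengths | 8, 1.5–4 kbp | ≥ 1 kbp rule exercised with margin |
| `duplication_count`, lengths | 4, 2–5 kbp | ≥ 2 kbp for confident fold-2 peaks |
| `conversion_tract_count`, lengths | 6, 1.2–3 kbp | ≥ 1 kbp rule exercised with margin |
| `conversion_direction_bias` | 0.8 toward D_T | the direction skew of region-based detection |
| `tetraploid_autapomorphy_rate` | 0.005 per subgenome | reproduces a ~24% polyploid-only share of homoeo-SNPs |

Design points that matter for interpretation:

- **Substitution-only accession genomes** plus interval-level
  deletions/tandem duplications: read-to-reference coordinate maps stay
  gapless, so truth alignments are exact `<len>M` records and reads
  crossing a planted breakpoint are emitted unmapped. There are no small
  indels, by design.
- **Duplications are sampled twice**: the physical genome repeats the
  duplicated interval, which is exactly what a coverage peak caller sees.
- **Autapomorphies may hit index positions** — that is the mechanism that
  makes the site-wise conversion signal ambiguous, and it is required for
  the confound positive control.
- **Conversion tracts are placed only where both progenitors are present**
  (outside planted deletions/duplications), and overwrite one subgenome's
  current sequence (including its autapomorphies) with the other's.
- **One RNG stream per accession**, keyed by (seed, accession index):
  adding accessions never perturbs existing ones; a single seed fixes
  every output byte-for-byte. Planted site classes are drawn as a binomial
  count followed by sampling without replacement, which realises
  "resample on collision" exactly.

What the generator does **not** emulate — and therefore what green tests
do *not* demonstrate about real data: repeat content and mapping
ambiguity (reads are placed at their true positions; there is no
mis-mapping), indels and alignment gaps, base-quality error profiles,
GC or library bias, paired-end structure (no stage in scope uses
pairing), or population structure within a genome group beyond
independent per-accession variation. In particular the ~0.05%
categorization error measured in simulation is far below the ~2% scale
seen with real mapped reads, because real error is dominated by mapping
ambiguity that is absent here; the simulation establishes the bound, not
the value.

## Problem sizes

The shipped test suite runs on a 200-kbp two-chromosome cohort (session
fixture) plus one 1-Mbp cohort for the headline categorization bound;
`scripts/acceptance.py` uses the 1-Mbp scale. These sizes give thousands
of index sites and several planted events per class while keeping a full
run to tens of seconds on one CPU; all detectors are vectorized, so they
scale linearly to full genomes.

## Known limitations

- The duplication caller can split one planted duplication into adjacent
  peaks when a window straddles its boundary; recovery properties are
  therefore asserted as coverage of the planted interval, not 1:1 region
  identity.
- Method-2 conversion regions shrink by up to a read length at each
  boundary (the categorization transition zone); breakpoint accuracy is
  read-length-limited throughout.
- NG86 with equal pathway weighting underestimates rates at high
  divergence; the `saturated` status marks where the correction fails
  outright.
- The pipeline's file-based route holds one depth array per chromosome
  per accession in memory; it is designed for chromosome-scale arrays,
  not for streaming constant-memory operation.
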