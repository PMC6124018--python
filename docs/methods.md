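# Methods

This note documents the models behind each analysis, the simulator that the
validation suite runs them against, the numerical choices that were genuinely
open, and what the passing tests do and do not show about real data.

## The synthetic hybrid cross

The simulator generates everything in a single shared **ancestral coordinate
frame**: one random ancestral chromosome (default 1 Mb), against which all
variants are recorded.

* **Species divergence.** Variant sites are drawn i.i.d. uniform at rate
  `interspecies_divergence` (default 0.01/bp); at each site one species
  (chosen 50/50) deviates from the ancestor. The default is a free parameter
  of the generator, chosen as a realistic congeneric-species distance that
  leaves ~8 diagnostic SNPs per 1-kb gene; no sequence-level estimate for the
  motivating cherry cross is available to pin it.
* **Within-species heterozygosity.** Each parent's two haplotypes differ at
  rate `intraspecies_heterozygosity` (default 0.002/bp): haplotype *a* is the
  species consensus, haplotype *b* carries the parent-private variants.
* **InDels.** A fraction of variant sites (default 0.15, matching the
  InDel share of typical resequencing variomes) become 1–10 bp insertions or
  deletions (uniform length, 50/50 direction). Divergence, heterozygosity and
  InDel positions are drawn jointly without replacement, so per-category
  counts are exactly binomial and no two variants overlap; InDel promotion is
  restricted to sites with >10 bp to the next variant so footprints never
  collide (this thins the realized InDel fraction by a few percent — the
  substitution rates, which the statistics depend on, are unaffected).
* **Offspring.** An F1 carries one randomly chosen haplotype from each
  parent. A BC1 carries one recombined F1 gamete (crossovers ~
  Poisson(`bc_recomb_rate`), breakpoints uniform) plus one haplotype of the
  maternal recurrent parent.
* **Reads.** Single-end reads (default 150 bp) with uniform start positions
  and 50/50 strands at per-haplotype fold coverage `coverage`; substitution
  errors i.i.d. at `error_rate` (default 0.005). A read-origin sidecar (true
  haplotype, start, strand per read) substitutes for alignment on the
  synthetic path; per-haplotype InDel offset maps translate between
  haplotype and ancestral coordinates exactly outside InDel footprints.
* **Determinism.** All randomness derives from one seed through named
  sub-streams (one per stage, read sets keyed by genome label), so identical
  configurations reproduce byte-identical output files.

What the generator deliberately does **not** model: recombination hotspots,
structural variants beyond 10 bp, quality-score-dependent errors, paired
ends, repeats (the ancestor is i.i.d. random sequence), and shared
within-species polymorphism between the two parents. Passing tests therefore
demonstrate correctness of the *inference machinery* under the stated
statistical model, not robustness to repeat-rich genomes or aligner
artifacts.

## K-mer spectrum and genome size

Canonical k-mers (lexicographic minimum of a window and its reverse
complement, default k = 17, 2-bit packed) are counted exactly; multiplicities
above 10,000 fall into an overflow bin that contributes volume but never
peaks. Peak fitting smooths the histogram with a 3-bin moving average (the
minimal smoother; the method behind published spectra is never stated),
takes the **error trough** as the end of the initial descent, and collects
local maxima beyond it. The homozygous peak c_hom is the greater-multiplicity
member of the two tallest candidates; the heterozygous peak c_het is the
candidate nearest c_hom/2 within [0.35, 0.65]·c_hom (theory puts it at 0.5;
the window absorbs sampling noise) and at least 1% of the tallest
candidate's height — without the height floor, count jitter at mid
multiplicities in homozygous spectra occasionally fakes a "het" maximum.

Genome sizes divide a volume by a peak depth. With V = total k-mer instances
minus the error volume (instances below the trough):

* haploid `G₁ = V / c_hom`;
* maximum diploid `G₂ = V / c_het` when a het peak exists, else `G₂ = G₁`.

Dividing the *same* volume by each peak depth is the operative definition
here; it is self-consistent (read errors depress both V and the fitted
c_hom, so the ratio stays calibrated) and gives `G₂/G₁ = c_hom/c_het ≈ 2`
for a deeply heterozygous F1. An additive alternative
(`G₁ + het_volume/c_het`) was considered and rejected: it counts only the
k-mers that actually differ between haplotypes and lands at ~1.3× for a 1%
diverged F1, which is not the two-haplotype total a "maximum diploid size"
denotes. `basis="read_length"` instead divides total read bases by the peak
depth converted to base coverage via R/(R−k+1); the two bases agree within
2% on clean data and are both exposed because which volume a published
figure used is rarely stated.

## Phase classification

Evidence per gene: breadth of the gene covered by each parent's reads
(`cov_m`, `cov_p`) and counts of diagnostic-SNP sites supporting each parent
(`support_m`, `support_p`), where a site supports a parent when at least
`min_depth = 2` of that parent's reads observe the assembly allele. Support
is counted at the **site level** by default (one vote per passing site,
robust to depth imbalance between the parental read sets); the read-level
alternative, summing the supporting reads themselves, is available via
`--support-unit reads`. The decision ladder:

1. no coverage by either parent → `NO_DATA`;
2. one parent covers ≥ `min_breadth = 0.5` of the gene and the other none →
   `UNIQUE_*` (the breadth floor keeps single stray reads from triggering
   unique calls);
3. one parent supports ≥ `fold = 2.0` times as many sites, with at least
   `min_support = 1` site → `PHASED_*` (a twofold tie at 0:0 with
   min_support 0 is `COMMON`);
4. otherwise `COMMON`.

`NO_DATA` genes are reported separately and excluded from percentage
denominators. The classifier is a pure function; the test suite checks it
against an exhaustive enumeration of all small evidence vectors and a
parent-swap symmetry law.

The synthetic path emulates a haplotype-fused assembly: each gene's
reference is a randomly chosen child haplotype, and truth is the donor of
that haplotype. The no-divergence **control uses genuinely identical
parents** (divergence and heterozygosity both zero). With parent-private
heterozygosity left on, the twofold rule correctly phases genes by
individual alleles — real classifier behaviour, but not the "identical
parents" null whose expected outcome is ~100% common.

## Variome

Genotypes come from multi-sample VCF GT fields (cyvcf2; `./.` missing).
Summaries per sample: heterozygous/homozygous SNP sites, InDel sites, and
Ti/Tv counted per non-reference allele copy at biallelic SNPs (multiallelic
sites stay in the totals, leave Ti/Tv). Note the simulator mutates uniformly
over the three alternative bases, so its expected Ti/Tv is 0.5, the
no-bias null — the Ti/Tv machinery is validated by exact hand counts, not by
reproducing a biological transition bias.

The distance between two samples sums `2 − |multiset intersection|` of their
genotypes over jointly-called sites (pairwise-complete deletion, the PLINK
`--genome` convention; `normalize` divides by the per-pair site count).
InDels are included; `snps_only` restricts. Classical MDS double-centres the
squared distances and eigendecomposes; axis signs are fixed by making each
axis's first nonzero loading positive so plots reproduce across runs and
BLAS backends. The tree is standard Saitou–Nei neighbor-joining with
lexicographic tie-breaking on the joined clusters' smallest leaf names and
negative branch lengths clamped to zero (excess moved to the sister branch);
NJ was chosen as the distance-based estimator because fitting a likelihood
tree to a distance matrix is not a well-defined construct. Both MDS and NJ
are cross-checked against scikit-bio in the test suite.

## S-locus

The clustered unit is a *haplotype*: the S-RNase + SFB pair carried by one
locus copy (the two genes are completely linked; a pair concordant at one
gene only is logged as a putative recombinant). Pairwise identity uses
global alignment with free end gaps (match +1, mismatch −1, gap −2), identity
= matches over alignment columns excluding terminal gaps — alleles of one
class may differ modestly in length. Two haplotypes join a class when both
genes reach the identity threshold (default 0.99, configurable and recorded
in output headers; the class count on real data is threshold-dependent
because no published numeric criterion exists). Labels S1..Sn order by class
size, then first appearance. GSI supplies three testable laws: every
accession heterozygous (homozygous pairs are flagged, not dropped), trio
transmission with pollen rejection (the paternal donation must be absent
from the seed parent), and cross compatibility graded by how many pollen
classes the seed parent lacks (0/1/2 → incompatible / semi / fully) —
semi-compatibility is kept distinct because inter-specific crosses being
only half-blocked is exactly what lets hybrid swarms form. The sharing
network has an edge iff two accessions' class sets intersect.

The simulated allele pool derives each class from a common base gene at 10%
divergence (between-class identity ~0.82) and gives each allele at most one
private substitution (within-class divergence ≤ 0.33%), so the 0.99
threshold separates classes with margin by construction.

## Problem sizes and tolerances

The validation suite runs at desk scale, chosen to keep the full run in a
few minutes while leaving comfortable statistical margins: 1 Mb genomes for
genome sizing (50×) and phasing (500 genes, 30× per parent), 150–200 kb for
property and backcross tests (20 replicate seeds), 12 accessions / 8 classes
for the S-locus population. Genome-size recovery is asserted within 5%
(observed ~1%), phasing recovery at ≥90% of diagnostic-SNP genes (observed
~99.6%), MDS fidelity at 1e−6 relative, NJ additive recovery and the
distance/classifier oracles exactly. Quantities that depend on the free
divergence parameter (e.g. the het/hom peak height ratio) are asserted
directionally, not numerically.

## Known limitations

* Real-data phasing enters via per-parent VCFs or pileup TSVs; the package
  does not align reads or call variants, and breadth must be supplied (or
  falls back to a site-presence proxy) when no coverage table is given.
* Peak fitting assumes a unimodal-per-component spectrum; heavy repeat
  content or contamination (multi-peak spectra) will confuse the top-2
  candidate rule.
* The diploid size is an upper bound ("maximum diploid size"): regions
  identical between haplotypes are counted once per haplotype only through
  the het-peak division, not measured directly.
* NJ trees carry no support values; bootstrap is out of scope.
* Ti/Tv on simulated panels reflects the uniform mutation model (0.5), not
  a biological transition bias.
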