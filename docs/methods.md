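# Methods

This note documents the models, conventions and numerical choices behind
`strmps`, in the package's own terms: what each stage assumes, which knobs
matter, what the synthetic cohorts do and do not emulate, and where the
design was genuinely open.

## Locus model and coordinates

All coordinates are GRCh38, 1-based, inclusive at both ends, matching the
convention of published sequence-based allele names
(`84,160,226–84,160,277`). Sequences are stored on the plus strand; any
reverse-complementing belongs upstream of this package. A locus config
carries the repeat-region interval, motif length (2–6 nt), the analysed
flanking intervals, calling thresholds, and a *reference structure
template*: an ordered list of slots, each either a variable motif run
(absorbs a maximal run when aligning), a fixed literal interruption
(lowercase slots are excluded from repeat-unit counting), or a
variable-length `N` gap block. Reference structures and CE anchors are
config data, not code; the shipped `data/loci.json` covers 21 loci spanning
autosomal, X and Y chromosome classes, simple and compound repeats, gap
blocks and known flanking-variant sites.

Casing (counted vs uncounted) is config-driven per reference slot, because
the display convention shows but does not define the rule; full-motif-length
uppercase segments count toward the repeat-unit total, lowercase and
partial-length segments do not. One display convention is worth noting:
a template-fixed singleton slot stays separate from an adjacent run of the
same motif (e.g. `[CAGA]4 CAGA` when the allele's final reference slot is
substituted), so "maximal runs" applies to encoder-discovered runs, not to
template-pinned singletons.

## Bracket encoding

Encoding an observed repeat-region sequence is an exact dynamic programme
over (sequence position, template slot). Variable slots try maximal runs
first and backtrack; fixed slots match literally or accept a same-length
substitution; slots may be skipped; unclaimed stretches fall to a run
scanner that emits maximal runs of any configured motif (earliest run wins,
ties broken by reference order) and splits leftovers into motif-length
pieces. Alignments are scored lexicographically by (template-claimed
nucleotides, exactly matched fixed slots, substituted slots); ties keep the
first alignment in a fixed exploration order, so encoding is deterministic.
`expand ∘ bracket_encode` is the identity on any input (gaps as N-runs) by
construction, and is asserted on every call.

## CE designation

The CE (capillary-electrophoresis-equivalent) allele number is derived from
*fragment length* relative to a per-locus anchor, never from counting
repeat units, because flanking InDels and interruptions decouple the two.
With ΔL the analysed-fragment length difference to the reference allele,

    whole   = anchor.whole + floor((ΔL + anchor.partial) / motif_len)
    partial = (ΔL + anchor.partial) mod motif_len

Flanking insertions/deletions contribute to ΔL; variants whose coordinates
fall *inside* the repeat region contribute zero, because their length
effect is already visible in the repeat structure itself (e.g. a 6-nt
deletion that shortens an uncalled gap block from N42 to N36). Loci whose
conventional allele numbers are offset from their structure (the
D19S433-type case) carry the offset entirely in their config anchor, which
may itself be a microvariant (e.g. `13.2`). Insertion positions are
left-aligned to the 5'-most equivalent coordinate with a `.1` sub-index;
the true position within a homopolymer/repeat context is genuinely
ambiguous, and left-alignment makes naming deterministic.

## Variant classification and novelty

An allele's repeat pattern "differs from the reference" when its encoding
needed any foreign or substituted segment, or skipped a fixed interruption
— i.e. by more than run counts of the reference motifs. Pure run-count and
gap-length changes are not repeat variation. Classification is then a
2×2 partition on (repeat differs, has flanking variants):
REFERENCE / RRVO / FRVO / RRFR. Variants located inside the repeat region
count as repeat variation and are excluded from flanking-variant frequency
tallies ("not counted"). Novelty is exact canonical-string membership in a
catalog — reproducible, and what a database lookup does; the shipped
catalog is a synthetic stand-in (each locus's reference allele) for a local
database snapshot.

In the gain decomposition (sequence-based over length-based allele counts),
distinct sequence alleles are grouped by CE designation; each group
contributes its size minus one, attributed to the variant classes of the
non-reference members. Distinct CE designations are treated as distinct
length-based alleles.

## Genotype calling

AT (analytical, default 1.5 %) and IT (interpretation, default 4.5 %) are
interpreted as fractions of total reads at one sample×locus, matching the
relative-threshold convention of MPS STR software; an absolute profile
(AT = 2 reads, heterozygote ratio 0.40) is available for pipelines that use
fixed-read thresholds. Which base the original percentage thresholds use is
not documented by the instrument software; the relative reading is the
field's common usage. Among callable alleles the second is retained iff its
reads reach the locus balance threshold (0.60 default; 0.10 for loci with
known extreme imbalance). Heterozygotes with ACR < 0.5 are flagged
`imbalance_suspect`; a locus whose heterozygote ACRs are *all* below 0.5
gets a discard recommendation. Y and male-X loci call at most one allele.
No stutter filter is applied: stutter in the simulator defaults below AT,
so thresholding removes it, as in the real analysis workflow.

## Frequencies and forensic parameters

Counting-method frequencies keep exact integer counts and denominators
(2N autosomal; 2F+M for X, females contributing two alleles and males one;
M for Y). Output files round to 4 decimals; full precision is kept
internally. Hexp and GD are the same unbiased estimator
n(1−Σp²)/(n−1) under two names (n = chromosomes); HD uses N = sampled
individuals. The text definition of n as "number of alleles" is
incompatible with the worked values this estimator must reproduce, so the
chromosome/individual reading is used. RMP uses expected HWE genotype
frequencies from sample allele frequencies (2a₂² − a₄); an
observed-genotype-frequency variant sits behind a flag, since third-party
programs differ here. PIC = 1 − a₂ − (a₂² − a₄). The four exclusion
closed forms (README) were derived from the standard exclusion logic —
duo: the alleged father shares no allele with the child; trio: his alleles
all fall outside the child's possible paternal-allele set given the mother
— and are required to match exhaustive enumeration oracles to 1e−12 in the
test suite.

## HWE and LD testing

The HWE test is the exact conditional test: the probability of a genotype
table given its allele counts (Levene distribution), with the p-value the
total probability of tables no more probable than the observed one. Tables
are fully enumerated when the off-diagonal state space is small (≤10⁶
states by a product bound); otherwise a seeded Monte-Carlo permutation of
the 2N-allele vector (default 10⁵ shuffles, vectorised and chunked) uses
the same ordering statistic, with the add-one estimator
p = (1+hits)/(B+1). Monomorphic loci return p = 1 with a notice.

The LD test permutes one locus's genotypes across individuals and uses the
chi-square of the two-locus genotype contingency table as statistic. The
composite statistic used by the standard population-genetics software is
not published; this permutation statistic is a documented stand-in with
exact type-I control by construction. Calibration is verified empirically:
over 600 null cohorts of 100 individuals, both tests reject at α = 0.05
within (0.03, 0.07). Sparse contingency tables make the permutation p
conservative through ties, so calibration checks use biallelic/triallelic
loci at cohort-scale N. Bonferroni (α/k) is the only multiple-testing
correction, with k the locus count for HWE and L(L−1)/2 for LD pairs.

## Panel combination

CMP multiplies per-locus RMPs in natural-log space (values reach 10⁻⁷⁰
scale); CPE accumulates log1p(−PE). TDP prints as `1−(CMP)` (U+2212 minus)
whenever 1−CMP is floating-point-indistinguishable from 1, and combined
values render in scientific notation with 4 significant digits. X loci are
excluded from panels by default; an option swaps in their MEC values.

## Synthetic cohorts

The generator emulates the *statistical* structure the analysis assumes:
HWE-distributed autosomal genotypes over planted allele pools, sex-aware X
ploidy, male-only Y alleles (per-locus independent draws; multi-locus
haplotypes are derived, not planted), negative-binomial total coverage
(mean 600 reads, dispersion 20 — amplicon-scale overdispersion), Beta
heterozygote balance, binomial read splitting, single-step stutter (one
full repeat shorter, rate 1 % of allele reads — below AT by design) and
background noise reads (rate 0.2 %). The default cohort is 54 females and
53 males, the study-scale sample size. Balance defaults to Beta(50, 10)
(mean ACR ≈ 0.83, matching per-locus averages of 0.70–0.96); the severe
regime Beta(10, 30) (mean 0.25, concentrated) reproduces the
all-ACRs-below-0.5 phenomenon. The "noiseless balanced" regime used for
exact-recovery checks turns off stutter/noise/imbalance and concentrates
balance near 1 (Beta(300, 3)) so that no true allele can cross a calling
threshold — under the default balance model a heterozygote occasionally
lands within read-sampling noise of the 0.60 threshold, which is a genuine
property of threshold calling, not an error.

Pool construction plants labels *by construction*, independently of the
classifier: reference-pattern alleles at stepped run counts, an RRVO allele
(point mutation inside the longest run), an FRVO allele (flanking
substitution), and an RRFR allele (both). Not emulated: PCR error beyond
single-step stutter, related individuals, locus dropout correlated across
loci, sequencing error within reads, and real allele-frequency spectra —
so passing recovery tests demonstrates the pipeline's correctness under its
own assumptions, not population realism.

Frequency-recovery checks use an exact binomial central interval per locus:
each allele's count is compared with Binomial(n, p) quantiles at level
0.01/k per allele (Bonferroni within the locus), giving ≥99 % joint
per-locus coverage regardless of allele count.

## Problem sizes and numerical choices

The analysis drivers run the 107×21 cohort end to end; the recovery check
uses 250 replicated loci; permutation-test calibration uses 600 replicates
at 999 permutations; HWE/LD in the analysis drivers default to 5,000
permutations. Exact enumeration bounds, threshold tie-breaks (alleles sort
by read count, then name), and the add-one permutation estimator are fixed
as described above. All stochastic components take explicit seeds; a fixed
seed reproduces outputs byte-identically.

## Known limitations

* Nomenclature requires a configured reference template per locus; motifs
  absent from every config are segmented as foreign chunks, and loci
  without configs cannot be named.
* The LD statistic is genotypic association, not gametic-phase
  disequilibrium; with unphased diploid data the latter is not identifiable
  without an EM step, which is out of scope.
* The demo catalog is synthetic; novelty flags against it demonstrate the
  mechanism, not real discovery.
* Combined-panel values for X loci mix exclusion conventions (MEC vs PE)
  and are therefore reported separately by default.
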