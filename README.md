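# strmps

Sequence-based STR allele nomenclature, genotype QC and forensic population
statistics for massively parallel sequencing (MPS) data.

Forensic laboratories moving from capillary electrophoresis (CE) to MPS gain
access to the full sequence of each short tandem repeat (STR) allele: alleles
of identical length frequently differ in their repeat-region structure or in
flanking-region SNPs/InDels, and those differences carry real discrimination
power. This package implements the desk-side half of such a study for
population geneticists and forensic scientists: it turns per-sample allele
observations (STRait-Razor-style sequence + read-count tables) into

* **bracketed sequence-based allele names** with CE designations, e.g.
  `D7S820 [CE10.1]-Chr7-GRCh38 84,160,226–84,160,277 [TATC]10 84,160,204-A;
  84,160,204.1A` — run-length bracketed repeat structures, lowercase
  uncounted interruptions, `N<len>` gap blocks, and flanking variants
  annotated by GRCh38 coordinate;
* **QC'd genotypes** via relative analytical/interpretation thresholds
  (AT = 1.5 %, IT = 4.5 % of locus reads) and per-locus intralocus balance
  thresholds, with allele coverage ratios (ACR = min/max reads) and
  discard recommendations for severely imbalanced loci;
* **variant classes** (REFERENCE / RRVO / FRVO / RRFR — repeat-region-only,
  flanking-region-only, or both) and novelty flags against a local catalog;
* **population and forensic statistics** — counting-method frequencies with
  ploidy-aware denominators (2N autosomal, 2F+M for X, M for Y), unbiased
  gene/haplotype diversity, effective allele number, Hobs/Hexp, PIC, RMP,
  DP, paternity powers of exclusion (duo/trio), X-chromosomal mean exclusion
  chances, exact/permutation HWE tests and genotypic LD permutation tests
  with Bonferroni correction, and log-domain panel combination
  (CMP / TDP / CPE);
* a **synthetic cohort generator** with full truth records, so the entire
  pipeline is testable at desk scale without access to protected casework
  data.

## The statistics at the core

With allele frequencies $p_i$ estimated by counting over $n$ sampled
chromosomes (haplotypes):

$$\mathrm{GD} = \mathrm{HD} = \frac{n\,(1 - \sum_i p_i^2)}{n - 1},
\qquad A_e = \frac{1}{\sum_i p_i^2}$$

The CE designation of an allele is *length*-anchored, never unit-count
anchored: if the analysed fragment is $\Delta L$ nucleotides longer than the
reference allele (flanking InDels included), the allele number is the
reference anchor shifted by $\lfloor \Delta L / m \rfloor$ whole repeats with
the remainder as the microvariant part ($m$ = motif length). That is why a
`[TATC]10` allele with a 1-nt flanking insertion is named CE 10.1 even though
it carries exactly 10 repeats.

Exclusion probabilities are closed forms in the power sums
$a_k = \sum_i p_i^k$ (validated against exhaustive genotype-enumeration
oracles in the test suite):

$$\mathrm{PE}_{\mathrm{duo}} = 1 - 4a_2 + 4a_3 - 3a_4 + 2a_2^2, \qquad
\mathrm{PE}_{\mathrm{trio}} = 1 - 2a_2 + a_3 + 3a_2a_3 - 3a_5 - 2a_2^2 + 2a_4$$

$$\mathrm{MEC}_{\mathrm{duo}} = 1 - 2a_2 + a_3, \qquad
\mathrm{MEC}_{\mathrm{trio}} = 1 - a_2 - a_2^2 + a_4$$

Panel-level parameters are products accumulated in log space:
$\mathrm{CMP} = \prod_\ell \mathrm{RMP}_\ell$,
$\mathrm{TDP} = 1 - \mathrm{CMP}$ (printed `1−(CMP)` when the complement is
indistinguishable from 1), and
$\mathrm{CPE} = 1 - \prod_\ell (1 - \mathrm{PE}_\ell)$.

## Worked example

The analysis is organised as numbered drivers over the library
(`analysis/01_simulate_cohort.py` … `analysis/08_concordance.py`), writing
tables to `results/`. Running them in order simulates a cohort of 107
individuals (54 female, 53 male) at the 21 shipped loci and pushes it
through every stage:

```text
$ python analysis/01_simulate_cohort.py --seed 1
Simulated 107 individuals at 21 loci (6119 allele observations) with seed 1.
Severe-imbalance regime planted at: D22S1045.

$ python analysis/02_call_genotypes.py
Called 1869 sample-locus genotypes (951 heterozygous).
Discard recommended for D22S1045: all ACRs < 0.5 (range 0.1215–0.4036).

$ python analysis/03_name_alleles.py
Named 6119 allele observations (166 distinct sequence-based alleles).
Golden set: 39/39 published names reproduced byte-identically.

$ python analysis/06_forensic_parameters.py
Parameters for 20 loci (excluded after QC: ['D22S1045']).
HWE: 0/9 loci significant after Bonferroni (alpha' = 0.05/9).
LD: 0/36 pairs significant after Bonferroni (alpha' = 0.05/36).

$ python analysis/07_combine_panels.py
autosomal (9 loci): CMP = 1.779E−9, TDP = 1−(1.779E−9), CPE_duo = 0.9751335037, ...
```

Reading the output: every heterozygote ACR at the planted severe-imbalance
locus fell below 0.5, so it is dropped from the statistics (exactly how a
real severely imbalanced locus is handled); the naming engine reproduced all
39 published allele-name strings from their raw sequences; the HWE-simulated
cohort shows no departures from equilibrium or linkage after Bonferroni
correction; and the nine clean autosomal loci alone already give a
random-match probability of about 1.8 × 10⁻⁹.

The same stages are exposed as a CLI (`strmps simulate|call|name|classify|
freqs|params|combine|concordance|all`) for use on external observation
tables.

## Layout

```
src/strmps/          library: locus_model, nomenclature, variants,
                     genotyping, popgen, panels, simulate, io, cli
src/strmps/data/     locus configs (JSON), published-name fixture (TSV),
                     synthetic demo catalog (TSV)
analysis/            numbered narrative drivers writing results/
tests/               pytest suite incl. enumeration oracles
docs/methods.md      models, assumptions, numerical choices, limitations
```
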