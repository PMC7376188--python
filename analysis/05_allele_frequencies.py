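#!/usr/bin/env python
"""Counting-method allele frequencies with ploidy-aware denominators
(2N autosomal, 2F+M for X, M for Y), flanking-variant carrier frequencies
(repeat-region variants excluded), and the Y-haplotype spectrum with its
haplotype diversity.

Writes results/allele_frequencies.csv, results/flank_variant_frequencies.csv
and results/y_haplotypes.csv.
"""

from pathlib import Path

import pandas as pd

from strmps.genotyping import call_genotype
from strmps.io import read_observations
from strmps.locus_model import load_builtin_loci
from strmps.nomenclature import format_isfg
from strmps.popgen import (
    HaplotypeTable,
    allele_frequencies,
    flank_variant_frequencies,
    haplotype_diversity,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    configs = load_builtin_loci()
    grouped = read_observations(RESULTS / "observations.tsv", configs)
    sexes = {sample: obs[0].sex for (sample, _), obs in grouped.items()}
    calls_by_locus: dict[str, list] = {}
    for (_, locus), obs in grouped.items():
        calls_by_locus.setdefault(locus, []).append(
            call_genotype(obs, configs[locus]))

    freq_frames, flank_frames = [], []
    for locus in sorted(calls_by_locus):
        cfg = configs[locus]
        table = allele_frequencies(calls_by_locus[locus], cfg, sexes)
        frame = table.to_frame()
        frame["allele"] = [format_isfg(a, cfg) for a, _ in table.counts]
        freq_frames.append(frame)
        flank_frames.append(
            flank_variant_frequencies(calls_by_locus[locus], cfg, sexes))
    pd.concat(freq_frames, ignore_index=True).to_csv(
        RESULTS / "allele_frequencies.csv", index=False, encoding="utf-8")
    flanks = pd.concat(flank_frames, ignore_index=True)
    flanks.to_csv(RESULTS / "flank_variant_frequencies.csv", index=False,
                  encoding="utf-8")

    # Y haplotypes: one multi-locus string per male
    y_loci = sorted(l for l, c in configs.items() if c.chrom_class == "Y")
    per_male: dict[str, list[str]] = {}
    for locus in y_loci:
        for call in calls_by_locus.get(locus, []):
            if call.called and call.alleles:
                ce = format_isfg(call.alleles[0], configs[locus])
                per_male.setdefault(call.sample, []).append(f"{locus}={ce}")
    haplotypes = ["|".join(parts) for parts in per_male.values()
                  if len(parts) == len(y_loci)]
    counts: dict[str, int] = {}
    for hap in haplotypes:
        counts[hap] = counts.get(hap, 0) + 1
    table = HaplotypeTable.from_counts(counts)
    hd = haplotype_diversity(table)
    pd.DataFrame({"haplotype": [h for h, _ in table.counts],
                  "count": [c for _, c in table.counts]}).to_csv(
        RESULTS / "y_haplotypes.csv", index=False, encoding="utf-8")

    print(f"Frequencies for {len(freq_frames)} loci "
          f"({len(flanks)} flanking variants tallied).")
    print(f"Y haplotypes: {table.n_distinct} distinct among {table.n} males; "
          f"HD = {hd:.4f}, singleton fraction "
          f"{table.singleton_fraction:.2f}.")
    print(f"Wrote allele_frequencies.csv, flank_variant_frequencies.csv, "
          f"y_haplotypes.csv under {RESULTS}.")


if __name__ == "__main__":
    main()
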