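#!/usr/bin/env python
"""Per-locus forensic parameters (Hobs, Hexp, PIC, RMP, DP, PE, MEC, GD, Ae)
plus Hardy-Weinberg and pairwise linkage-disequilibrium permutation tests
with Bonferroni-corrected thresholds.

The D22S1045 locus is excluded from the statistics, following its
discard recommendation from the ACR summary.

Writes results/locus_parameters.csv, results/hwe_tests.csv and
results/ld_tests.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from strmps.genotyping import call_genotype
from strmps.io import read_observations
from strmps.locus_model import load_builtin_loci
from strmps.popgen import (
    allele_frequencies,
    bonferroni,
    hwe_test,
    ld_test,
    locus_parameters,
    pair_count,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1, n_perm: int = 5000) -> None:
    configs = load_builtin_loci()
    grouped = read_observations(RESULTS / "observations.tsv", configs)
    sexes = {sample: obs[0].sex for (sample, _), obs in grouped.items()}
    calls_by_locus: dict[str, list] = {}
    for (_, locus), obs in grouped.items():
        calls_by_locus.setdefault(locus, []).append(
            call_genotype(obs, configs[locus]))

    discarded = set(pd.read_csv(RESULTS / "acr_summary.csv")
                    .query("discard_recommended")["locus"])

    rows = []
    diploid: dict[str, list] = {}
    for locus in sorted(calls_by_locus):
        if locus in discarded:
            continue
        cfg = configs[locus]
        table = allele_frequencies(calls_by_locus[locus], cfg, sexes)
        par = locus_parameters(table, calls_by_locus[locus],
                               x_locus=cfg.chrom_class == "X")
        rows.append(vars(par))
        if cfg.chrom_class == "autosomal":
            diploid[locus] = [
                (c.alleles[0], c.alleles[-1])
                for c in calls_by_locus[locus]
                if c.called and 1 <= len(c.alleles) <= 2]
    pd.DataFrame(rows).to_csv(RESULTS / "locus_parameters.csv", index=False,
                              encoding="utf-8")

    alpha_hwe = bonferroni(0.05, len(diploid))
    hwe_rows = [{"locus": locus,
                 "p": hwe_test(genos, seed=seed, n_perm=n_perm),
                 "bonferroni_alpha": alpha_hwe}
                for locus, genos in sorted(diploid.items())]
    for row in hwe_rows:
        row["significant"] = row["p"] < row["bonferroni_alpha"]
    pd.DataFrame(hwe_rows).to_csv(RESULTS / "hwe_tests.csv", index=False)

    loci = sorted(diploid)
    alpha_ld = bonferroni(0.05, pair_count(len(loci)))
    ld_rows = []
    for i, locus_a in enumerate(loci):
        for locus_b in loci[i + 1:]:
            p = ld_test(diploid[locus_a], diploid[locus_b], seed=seed,
                        n_perm=n_perm)
            ld_rows.append({"locus_a": locus_a, "locus_b": locus_b, "p": p,
                            "bonferroni_alpha": alpha_ld,
                            "significant": p < alpha_ld})
    pd.DataFrame(ld_rows).to_csv(RESULTS / "ld_tests.csv", index=False)

    n_sig_hwe = sum(r["significant"] for r in hwe_rows)
    n_sig_ld = sum(r["significant"] for r in ld_rows)
    print(f"Parameters for {len(rows)} loci "
          f"(excluded after QC: {sorted(discarded) or 'none'}).")
    print(f"HWE: {n_sig_hwe}/{len(hwe_rows)} loci significant after "
          f"Bonferroni (alpha' = 0.05/{len(diploid)}).")
    print(f"LD: {n_sig_ld}/{len(ld_rows)} pairs significant after "
          f"Bonferroni (alpha' = 0.05/{pair_count(len(loci))}).")
    print(f"Wrote locus_parameters.csv, hwe_tests.csv, ld_tests.csv "
          f"under {RESULTS}.")


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-perm", dest="n_perm", type=int, default=5000)
    main(**vars(parser.parse_args()))
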