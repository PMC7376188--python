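#!/usr/bin/env python
"""Classify every distinct called allele against its locus reference
(REFERENCE / RRVO / FRVO / RRFR), flag novel alleles against the local
catalog, and decompose the sequence-based allele gain over length-based
alleles per locus.

Writes results/allele_classes.tsv and results/allele_gain.csv.
"""

from pathlib import Path

import pandas as pd

from strmps.locus_model import load_builtin_loci
from strmps.nomenclature import parse_isfg
from strmps.variants import (
    builtin_demo_catalog,
    classify_variant,
    flag_novel,
    summarize_allele_gain,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    configs = load_builtin_loci()
    catalog = builtin_demo_catalog()
    genotypes = pd.read_csv(RESULTS / "genotypes.tsv", sep="\t",
                            keep_default_na=False)

    alleles_by_locus: dict[str, list] = {}
    rows = []
    seen = set()
    for record in genotypes.itertuples(index=False):
        for column in ("allele_1", "allele_2"):
            name = getattr(record, column)
            if not name or (record.locus, name) in seen:
                continue
            seen.add((record.locus, name))
            cfg = configs[record.locus]
            allele = parse_isfg(name, cfg)
            alleles_by_locus.setdefault(record.locus, []).append(allele)
            rows.append({
                "locus": record.locus,
                "isfg_name": name,
                "variant_class": classify_variant(allele, cfg).value,
                "novel": flag_novel(allele, catalog, cfg),
            })
    classes = pd.DataFrame(rows)
    classes.to_csv(RESULTS / "allele_classes.tsv", sep="\t", index=False,
                   encoding="utf-8")

    gain = summarize_allele_gain(alleles_by_locus, configs)
    gain.to_csv(RESULTS / "allele_gain.csv", index=False, encoding="utf-8")

    total = gain[gain["locus"] == "TOTAL"].iloc[0]
    by_class = classes["variant_class"].value_counts().to_dict()
    print(f"Classified {len(classes)} distinct alleles: {by_class}.")
    print(f"Novel against the local catalog: {int(classes['novel'].sum())}.")
    print(f"Allele gain (SB over LB): {int(total['sb_alleles'])} SB vs "
          f"{int(total['lb_alleles'])} LB alleles "
          f"(+{int(total['gain_rrvo'])} RRVO, +{int(total['gain_frvo'])} FRVO, "
          f"+{int(total['gain_rrfr'])} RRFR).")
    print(f"Wrote {RESULTS / 'allele_classes.tsv'} and "
          f"{RESULTS / 'allele_gain.csv'}.")


if __name__ == "__main__":
    main()
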