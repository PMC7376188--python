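#!/usr/bin/env python
"""Combine per-locus parameters into panel-level cumulative match
probability (CMP), total discrimination power (TDP, printed in the 1−(CMP)
convention) and combined powers of exclusion for duos and trios, for the
autosomal panel and for the autosomal+X panel (X loci contribute their mean
exclusion chances).

Writes results/combined_panels.csv.
"""

from pathlib import Path

import pandas as pd

from strmps.locus_model import load_builtin_loci
from strmps.panels import combine
from strmps.popgen import ForensicParams

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    configs = load_builtin_loci()
    table = pd.read_csv(RESULTS / "locus_parameters.csv")
    params = {}
    for record in table.to_dict("records"):
        clean = {k: (None if pd.isna(v) else v) for k, v in record.items()}
        clean["locus"] = record["locus"]
        clean["n_chromosomes"] = int(record["n_chromosomes"])
        params[clean["locus"]] = ForensicParams(**clean)

    autosomal = sorted(l for l in params
                       if configs[l].chrom_class == "autosomal")
    with_x = autosomal + sorted(l for l in params
                                if configs[l].chrom_class == "X")
    panels = [
        ("autosomal", combine(params, autosomal)),
        ("autosomal+X", combine(params, with_x, use_mec_for_x=True)),
    ]
    rows = []
    for label, summary in panels:
        rendered = summary.render()
        rows.append({"panel": label, "n_loci": len(summary.loci),
                     "cmp_value": summary.cmp, **rendered})
    out = pd.DataFrame(rows)
    out.to_csv(RESULTS / "combined_panels.csv", index=False, encoding="utf-8")

    for row in rows:
        print(f"{row['panel']} ({row['n_loci']} loci): CMP = {row['CMP']}, "
              f"TDP = {row['TDP']}, CPE_duo = {row['CPE_duo']}, "
              f"CPE_trio = {row['CPE_trio']}")
    print(f"Wrote {RESULTS / 'combined_panels.csv'}.")


if __name__ == "__main__":
    main()
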