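"""Readers and writers for the pipeline's TSV/CSV/JSON surfaces.

Observations travel as TSV (``sample, sex, locus, sequence, flank_variants,
reads``), genotype calls as TSV, statistics as CSV, configs and simulation
specs as JSON.  Everything is UTF-8 (allele names contain en-dashes).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .genotyping import GenotypeCall, ReadObservation, lb_projection
from .locus_model import FlankVariant, LocusConfig
from .nomenclature import SequenceAllele, bracket_encode, ce_designation, format_isfg

OBS_COLUMNS = ["sample", "sex", "locus", "sequence", "flank_variants", "reads"]


def _parse_flanks(text: str) -> tuple[FlankVariant, ...]:
    text = (text or "").strip()
    if not text:
        return ()
    return tuple(FlankVariant.parse(tok) for tok in text.split("; "))


def observations_from_frame(df: pd.DataFrame,
                            configs: Mapping[str, LocusConfig]
                            ) -> dict[tuple[str, str], list[ReadObservation]]:
    """Group an observation table into per-sample×locus observation lists,
    encoding each sequence into a :class:`SequenceAllele`."""
    cache: dict[tuple[str, str, str], SequenceAllele] = {}
    grouped: dict[tuple[str, str], list[ReadObservation]] = {}
    for row in df.itertuples(index=False):
        locus = row.locus
        config = configs[locus]
        flanks = "" if pd.isna(row.flank_variants) else str(row.flank_variants)
        key = (locus, row.sequence, flanks)
        allele = cache.get(key)
        if allele is None:
            allele = SequenceAllele(locus, bracket_encode(row.sequence, config),
                                    _parse_flanks(flanks))
            cache[key] = allele
        obs = ReadObservation(row.sample, row.sex, locus, allele,
                              int(row.reads))
        grouped.setdefault((row.sample, locus), []).append(obs)
    return grouped


def read_observations(path: str | Path,
                      configs: Mapping[str, LocusConfig]
                      ) -> dict[tuple[str, str], list[ReadObservation]]:
    df = pd.read_csv(path, sep="\t", dtype={"flank_variants": str},
                     keep_default_na=False)
    return observations_from_frame(df, configs)


def write_observations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def calls_to_frame(calls: list[GenotypeCall],
                   configs: Mapping[str, LocusConfig]) -> pd.DataFrame:
    """Genotype table with allele names, CE designations, ACR and flags."""
    rows = []
    for call in calls:
        config = configs[call.locus]
        names = [format_isfg(a, config) if hasattr(a, "structure") else str(a)
                 for a in call.alleles]
        ces = [str(ce_designation(a, config)) if hasattr(a, "structure")
               else "" for a in call.alleles]
        lb = lb_projection(call, config)
        rows.append({
            "sample": call.sample,
            "locus": call.locus,
            "allele_1": names[0] if names else "",
            "allele_2": names[1] if len(names) > 1 else "",
            "ce_1": ces[0] if ces else "",
            "ce_2": ces[1] if len(ces) > 1 else "",
            "lb": "/".join(lb) if len(lb) > 1 else (f"{lb[0]}/{lb[0]}"
                                                    if lb else ""),
            "acr": "" if call.acr is None else round(call.acr, 4),
            "flags": ",".join(sorted(call.flags)),
        })
    return pd.DataFrame(rows, columns=["sample", "locus", "allele_1",
                                       "allele_2", "ce_1", "ce_2", "lb",
                                       "acr", "flags"])
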