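"""Variant classification against the locus reference, and novelty flags.

Each sequence-based allele is placed in exactly one of four classes relative
to its locus reference:

* ``REFERENCE`` — repeat pattern conforms to the reference template and no
  flanking-region variants;
* ``RRVO`` — repeat-region variation only (interruptions, motif
  substitutions or extra segment types beyond pure run-count differences);
* ``FRVO`` — flanking-region variation only;
* ``RRFR`` — both.

Variants whose coordinates fall inside the repeat region (e.g. a deletion
already reflected in a shorter N-gap) count as repeat-region variation, not
flanking variation, and are excluded from flank-variant frequency tallies.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .locus_model import LocusConfig
from .nomenclature import (
    NomenclatureError,
    SequenceAllele,
    bracket_encode,
    format_isfg,
)

__all__ = [
    "VariantClass",
    "AlleleCatalog",
    "classify_variant",
    "flag_novel",
    "summarize_allele_gain",
]


class VariantClass(str, Enum):
    REFERENCE = "REFERENCE"
    RRVO = "RRVO"
    FRVO = "FRVO"
    RRFR = "RRFR"


def _repeat_pattern_differs(allele: SequenceAllele, config: LocusConfig) -> bool:
    """True when the repeat region differs from the reference by more than
    run counts of the reference motifs (gap lengths are treated like run
    counts)."""
    structure = bracket_encode(allele.structure.expand(), config)
    if any(seg.origin in ("subst", "foreign") for seg in structure.segments):
        return True
    # a skipped reference interruption also breaks the pattern
    n_fixed_matched = sum(1 for seg in structure.segments
                          if seg.origin == "fixed")
    n_fixed_slots = sum(1 for t in config.reference_structure
                        if not t.variable and not t.gap)
    return n_fixed_matched != n_fixed_slots


def classify_variant(allele: SequenceAllele, config: LocusConfig
                     ) -> VariantClass:
    """Classify one allele as REFERENCE / RRVO / FRVO / RRFR."""
    if allele.locus != config.name:
        raise NomenclatureError(
            f"allele locus {allele.locus!r} != config locus {config.name!r}")
    in_repeat = [v for v in allele.flank_variants if config.in_repeat_region(v)]
    flank = [v for v in allele.flank_variants if not config.in_repeat_region(v)]
    repeat_differs = bool(in_repeat) or _repeat_pattern_differs(allele, config)
    if repeat_differs and flank:
        return VariantClass.RRFR
    if repeat_differs:
        return VariantClass.RRVO
    if flank:
        return VariantClass.FRVO
    return VariantClass.REFERENCE


# ---------------------------------------------------------------------------
# Known-allele catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlleleCatalog:
    """Exact-string catalog of previously reported sequence-based alleles."""

    entries: frozenset[tuple[str, str]] = frozenset()
    source_tag: str = ""

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]],
                   source_tag: str = "") -> "AlleleCatalog":
        pairs = list(pairs)
        unique = frozenset(pairs)
        if len(unique) != len(pairs):
            raise ValueError("duplicate catalog entries")
        return cls(unique, source_tag)

    @classmethod
    def from_tsv(cls, path: str | Path, source_tag: str | None = None
                 ) -> "AlleleCatalog":
        """Read a TSV with columns ``locus``, ``isfg_name``."""
        path = Path(path)
        with path.open(encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            pairs = [(row["locus"], row["isfg_name"]) for row in reader]
        return cls.from_pairs(pairs, source_tag if source_tag is not None
                              else path.name)

    def __contains__(self, item: tuple[str, str]) -> bool:
        return item in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def flag_novel(allele: SequenceAllele, catalog: AlleleCatalog,
               config: LocusConfig) -> bool:
    """True iff the allele's canonical name is absent from the catalog."""
    return (allele.locus, format_isfg(allele, config)) not in catalog


def builtin_demo_catalog() -> AlleleCatalog:
    """Synthetic stand-in catalog (the reference-pattern allele of each
    shipped locus); a real deployment would load a local database snapshot."""
    path = Path(__file__).parent / "data" / "demo_catalog_synthetic.tsv"
    return AlleleCatalog.from_tsv(path, source_tag="synthetic demo catalog")


# ---------------------------------------------------------------------------
# Length-based vs sequence-based allele gain
# ---------------------------------------------------------------------------

def summarize_allele_gain(
        sb_alleles: Mapping[str, Iterable[SequenceAllele]],
        configs: Mapping[str, LocusConfig]) -> pd.DataFrame:
    """Per-locus decomposition of the sequence-based allele gain.

    For each locus, distinct sequence-based alleles are grouped by their CE
    designation (= the length-based allele).  Each CE group contributes its
    size minus one to the gain; gained alleles are attributed to their
    variant class (reference-pattern alleles sort first within a group, so a
    plain allele never counts as its own gain).  Returns a DataFrame with a
    totals row.
    """
    from .nomenclature import ce_designation

    rows = []
    order = [VariantClass.REFERENCE, VariantClass.FRVO, VariantClass.RRVO,
             VariantClass.RRFR]
    for locus, alleles in sb_alleles.items():
        config = configs[locus]
        distinct = {}
        for allele in alleles:
            distinct[format_isfg(allele, config)] = allele
        groups: dict[str, list[SequenceAllele]] = {}
        for allele in distinct.values():
            groups.setdefault(str(ce_designation(allele, config)), []).append(allele)
        gain = {cls: 0 for cls in (VariantClass.RRVO, VariantClass.FRVO,
                                   VariantClass.RRFR)}
        for ce, members in groups.items():
            classed = sorted(((classify_variant(a, config), a) for a in members),
                             key=lambda t: order.index(t[0]))
            for cls, _ in classed[1:]:
                if cls is VariantClass.REFERENCE:
                    # two reference-pattern alleles with equal CE cannot occur
                    # (same pattern + same length = same allele); guard anyway
                    continue
                gain[cls] += 1
        rows.append({
            "locus": locus,
            "lb_alleles": len(groups),
            "sb_alleles": len(distinct),
            "gain_rrvo": gain[VariantClass.RRVO],
            "gain_frvo": gain[VariantClass.FRVO],
            "gain_rrfr": gain[VariantClass.RRFR],
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        total = df.drop(columns="locus").sum()
        total["locus"] = "TOTAL"
        df = pd.concat([df, total.to_frame().T], ignore_index=True)
        df = df[["locus", "lb_alleles", "sb_alleles",
                 "gain_rrvo", "gain_frvo", "gain_rrfr"]]
    return df
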