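"""Threshold-based genotype calling, allele coverage ratios, concordance.

Calling follows the relative-threshold convention of MPS STR analysis
software: the analytical threshold (AT, default 1.5%) and interpretation
threshold (IT, default 4.5%) are fractions of the total reads at one
sample×locus.  Reads below AT are discarded, alleles between AT and IT are
flagged ``below_interpretation``, and among callable alleles a second allele
is retained only when its reads reach ``balance_threshold`` (default 0.60;
0.10 for known-imbalanced loci) of the top allele.  An absolute-reads
profile (AT = 2 reads, heterozygote threshold 0.40) is available as an
alternative.

The allele coverage ratio (ACR) of a heterozygote is the lower read count
divided by the higher; heterozygotes with ACR < 0.5 are flagged
``imbalance_suspect``, and a locus whose heterozygote ACRs are *all* below
0.5 is recommended for discard (the D22S1045-type phenomenon).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .locus_model import CeDesignation, LocusConfig

__all__ = [
    "ReadObservation",
    "GenotypeCall",
    "ThresholdProfile",
    "call_genotype",
    "acr_summary",
    "lb_projection",
    "concordance_report",
    "IMBALANCE_ACR",
]

IMBALANCE_ACR = 0.5  # heterozygotes below this ratio are suspect


@dataclass(frozen=True)
class ReadObservation:
    """Read support for one candidate allele of one sample at one locus."""

    sample: str
    sex: str  # "female" | "male"
    locus: str
    allele: object  # SequenceAllele, or any hashable allele key
    reads: int

    def __post_init__(self) -> None:
        if self.reads < 0:
            raise ValueError("reads must be non-negative")
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")


@dataclass(frozen=True)
class ThresholdProfile:
    """Calling thresholds; ``mode='fraction'`` uses fractions of total locus
    reads (instrument-software convention), ``mode='absolute'`` uses a fixed
    read count with a heterozygote ratio threshold."""

    mode: str = "fraction"
    at_reads: int = 2
    het_ratio: float = 0.40


@dataclass(frozen=True)
class GenotypeCall:
    sample: str
    locus: str
    alleles: tuple = ()
    reads: tuple[int, ...] = ()
    acr: Optional[float] = None
    flags: frozenset[str] = frozenset()

    @property
    def is_het(self) -> bool:
        return len(self.alleles) == 2

    @property
    def called(self) -> bool:
        return bool(self.alleles) and "locus_discarded" not in self.flags


def _expected_ploidy(chrom_class: str, sex: str) -> int:
    if chrom_class == "Y" or (chrom_class == "X" and sex == "male"):
        return 1
    return 2


def call_genotype(observations: Sequence[ReadObservation],
                  config: LocusConfig,
                  profile: ThresholdProfile | None = None) -> GenotypeCall:
    """Call the genotype for one sample×locus from per-allele read counts."""
    if not observations:
        raise ValueError("no observations")
    sample = observations[0].sample
    sex = observations[0].sex
    if any(o.sample != sample or o.locus != config.name for o in observations):
        raise ValueError("observations span multiple samples or the wrong locus")

    profile = profile or ThresholdProfile()
    total = sum(o.reads for o in observations)
    if total == 0:
        return GenotypeCall(sample, config.name, flags=frozenset({"no_call"}))

    if profile.mode == "fraction":
        at = config.analytical_threshold_pct * total
        it = config.interpretation_threshold_pct * total
        balance = config.balance_threshold
    elif profile.mode == "absolute":
        at = it = profile.at_reads
        balance = profile.het_ratio
    else:
        raise ValueError(f"unknown threshold profile mode {profile.mode!r}")

    flags: set[str] = set()
    surviving = sorted((o for o in observations if o.reads >= at),
                       key=lambda o: (-o.reads, repr(o.allele)))
    callable_ = [o for o in surviving if o.reads >= it]
    if any(o.reads < it for o in surviving):
        flags.add("below_interpretation")
    if not callable_:
        return GenotypeCall(sample, config.name,
                            flags=frozenset(flags | {"no_call"}))

    top = callable_[0]
    ploidy = _expected_ploidy(config.chrom_class, sex)
    balanced = [o for o in callable_[1:] if o.reads / top.reads >= balance]

    if ploidy == 1:
        if balanced:
            flags.add("excess_alleles")
        return GenotypeCall(sample, config.name, (top.allele,), (top.reads,),
                            flags=frozenset(flags))

    if len(balanced) >= 2:
        flags.add("excess_alleles")
    if balanced:
        second = balanced[0]
        acr = second.reads / top.reads
        if acr < IMBALANCE_ACR:
            flags.add("imbalance_suspect")
        return GenotypeCall(sample, config.name,
                            (top.allele, second.allele),
                            (top.reads, second.reads), acr=acr,
                            flags=frozenset(flags))
    return GenotypeCall(sample, config.name, (top.allele,), (top.reads,),
                        flags=frozenset(flags))


# ---------------------------------------------------------------------------
# ACR summaries
# ---------------------------------------------------------------------------

def acr_summary(calls: Iterable[GenotypeCall]) -> pd.DataFrame:
    """Per-locus ACR distribution over heterozygous calls.

    Loci with no heterozygotes are omitted (listed in the ``notices``
    attribute of the returned frame).  A locus whose ACRs are all below
    0.5 gets ``discard_recommended=True``.
    """
    by_locus: dict[str, list[float]] = {}
    loci_seen: set[str] = set()
    for call in calls:
        loci_seen.add(call.locus)
        if call.is_het and call.acr is not None:
            by_locus.setdefault(call.locus, []).append(call.acr)
    rows = []
    for locus in sorted(by_locus):
        acrs = np.asarray(by_locus[locus])
        rows.append({
            "locus": locus,
            "n_het": len(acrs),
            "mean_acr": float(acrs.mean()),
            "min_acr": float(acrs.min()),
            "max_acr": float(acrs.max()),
            "discard_recommended": bool((acrs < IMBALANCE_ACR).all()),
        })
    df = pd.DataFrame(rows, columns=["locus", "n_het", "mean_acr", "min_acr",
                                     "max_acr", "discard_recommended"])
    df.attrs["notices"] = sorted(loci_seen - set(by_locus))
    return df


# ---------------------------------------------------------------------------
# Length-based projection and concordance
# ---------------------------------------------------------------------------

def lb_projection(call: GenotypeCall, config: LocusConfig) -> tuple[str, ...]:
    """Project a sequence-based call onto length-based (CE) designations.

    Distinct sequence alleles with equal CE merge, so a sequence-based
    heterozygote may become a length-based homozygote (one designation).
    """
    from .nomenclature import ce_designation

    ces = []
    for allele in call.alleles:
        if isinstance(allele, CeDesignation):
            ces.append(str(allele))
        elif hasattr(allele, "structure"):
            ces.append(str(ce_designation(allele, config)))
        else:
            ces.append(str(allele))
    unique = sorted(set(ces), key=lambda c: (float(c), c))
    return tuple(unique)


def concordance_report(set_a: pd.DataFrame, set_b: pd.DataFrame,
                       shared_loci: Sequence[str]
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Compare two genotype tables on their length-based projections.

    Both tables need columns ``sample``, ``locus``, ``lb`` (the projected
    genotype as a string, e.g. ``"10/12"``).  Returns ``(per_locus,
    discordances, unmatched)``: per-locus concordant/discordant counts,
    itemized discordant calls, and samples present in only one table.
    """
    a = set_a[set_a["locus"].isin(shared_loci)]
    b = set_b[set_b["locus"].isin(shared_loci)]
    merged = a.merge(b, on=["sample", "locus"], how="outer",
                     suffixes=("_a", "_b"), indicator=True)
    unmatched = merged[merged["_merge"] != "both"][
        ["sample", "locus", "_merge"]].copy()
    both = merged[merged["_merge"] == "both"]
    agree = both["lb_a"] == both["lb_b"]
    per_locus = (
        pd.DataFrame({"locus": both["locus"], "concordant": agree})
        .groupby("locus", sort=True)
        .agg(n=("concordant", "size"), concordant=("concordant", "sum"))
        .reset_index())
    per_locus["discordant"] = per_locus["n"] - per_locus["concordant"]
    per_locus["concordance"] = per_locus["concordant"] / per_locus["n"]
    discordances = both[~agree][["sample", "locus", "lb_a", "lb_b"]].copy()
    return per_locus, discordances.reset_index(drop=True), unmatched
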