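"""Synthetic MPS cohorts with full truth records.

The generator emulates the structure of a forensic MPS population study:
a cohort of unrelated individuals (default 54 females + 53 males), per-locus
allele pools containing repeat-region and flanking-region variants at planted
frequencies, HWE-distributed autosomal genotypes, sex-aware X ploidy,
male-only Y alleles, negative-binomial amplicon coverage, Beta-distributed
heterozygote balance (with an optional severe-imbalance regime reproducing
the D22S1045 phenomenon), single-step stutter and low-rate noise reads.

Every random draw flows from the spec's mandatory seed through one
`numpy.random.Generator`, and loci/samples are visited in fixed order, so a
fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .genotyping import GenotypeCall, acr_summary, call_genotype
from .locus_model import LocusConfig, load_builtin_loci
from .nomenclature import SequenceAllele, ce_designation, format_isfg, parse_isfg
from .variants import classify_variant

__all__ = [
    "PoolAllele",
    "LocusSimSpec",
    "SimulationSpec",
    "TruthRecord",
    "simulate_cohort",
    "recovery_suite",
    "default_spec",
    "replicate_config",
]


class PoolAllele(BaseModel):
    """One allele of a locus pool: canonical name, planted frequency, and
    the variant class it was constructed to belong to."""

    model_config = {"frozen": True}

    name: str
    frequency: float = Field(gt=0, le=1)
    label: str = "REFERENCE"


class LocusSimSpec(BaseModel):
    model_config = {"frozen": True}

    locus: str
    alleles: tuple[PoolAllele, ...]

    @model_validator(mode="after")
    def _check(self) -> "LocusSimSpec":
        if not self.alleles:
            raise ValueError(f"{self.locus}: empty allele pool")
        total = sum(a.frequency for a in self.alleles)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"{self.locus}: pool frequencies sum to {total}, not 1")
        return self


class SimulationSpec(BaseModel):
    """Study-design parameters of one synthetic cohort."""

    model_config = {"frozen": True}

    loci: tuple[LocusSimSpec, ...]
    n_female: int = 54
    n_male: int = 53
    mean_reads: float = 600.0
    dispersion: float = 20.0
    balance_alpha: float = 50.0
    balance_beta: float = 10.0
    severe_imbalance_loci: tuple[str, ...] = ()
    severe_alpha: float = 10.0
    severe_beta: float = 30.0
    stutter_rate: float = Field(default=0.01, ge=0, le=1)
    noise_rate: float = Field(default=0.002, ge=0, le=1)
    seed: int

    @model_validator(mode="after")
    def _check(self) -> "SimulationSpec":
        if self.n_female + self.n_male < 1:
            raise ValueError("cohort must contain at least one individual")
        return self


@dataclass
class TruthRecord:
    """Planted truth emitted alongside the observations."""

    genotypes: dict[tuple[str, str], tuple[str, ...]]      # (sample, locus) -> names
    lb_genotypes: dict[tuple[str, str], tuple[str, ...]]   # (sample, locus) -> CEs
    frequencies: dict[str, dict[str, float]]               # locus -> name -> p
    labels: dict[tuple[str, str], str]                     # (locus, name) -> class
    sexes: dict[str, str]


def _stutter_allele(allele: SequenceAllele, config: LocusConfig
                    ) -> Optional[SequenceAllele]:
    """One full repeat shorter: decrement the longest counted run."""
    segments = list(allele.structure.segments)
    best_idx, best_count = -1, 1
    for i, seg in enumerate(segments):
        if seg.counted and not seg.gap and seg.count > best_count:
            best_idx, best_count = i, seg.count
    if best_idx < 0:
        return None
    segments[best_idx] = replace(segments[best_idx],
                                 count=segments[best_idx].count - 1)
    from .locus_model import RepeatStructure
    return SequenceAllele(allele.locus, RepeatStructure(tuple(segments)),
                          allele.flank_variants)


def _obs_key(allele: SequenceAllele) -> tuple[str, str]:
    flanks = "; ".join(v.render() for v in allele.flank_variants)
    return allele.structure.expand(), flanks


def simulate_cohort(spec: SimulationSpec,
                    configs: Mapping[str, LocusConfig] | None = None
                    ) -> tuple[pd.DataFrame, TruthRecord]:
    """Draw one cohort; returns (observation table, truth record).

    The observation table has columns ``sample, sex, locus, sequence,
    flank_variants, reads`` and round-trips unchanged through
    :func:`strmps.io.read_observations`.
    """
    configs = configs or load_builtin_loci()
    rng = np.random.default_rng(spec.seed)

    samples = ([(f"F{i + 1:03d}", "female") for i in range(spec.n_female)]
               + [(f"M{i + 1:03d}", "male") for i in range(spec.n_male)])
    truth = TruthRecord({}, {}, {}, {}, dict(samples))
    rows: list[dict] = []

    for locus_spec in spec.loci:
        config = configs[locus_spec.locus]
        pool = [parse_isfg(a.name, config) for a in locus_spec.alleles]
        freqs = np.array([a.frequency for a in locus_spec.alleles])
        freqs = freqs / freqs.sum()
        truth.frequencies[config.name] = {
            a.name: float(f) for a, f in zip(locus_spec.alleles, freqs)}
        for a in locus_spec.alleles:
            truth.labels[(config.name, a.name)] = a.label
        severe = config.name in spec.severe_imbalance_loci
        b_alpha = spec.severe_alpha if severe else spec.balance_alpha
        b_beta = spec.severe_beta if severe else spec.balance_beta

        for sample, sex in samples:
            if config.chrom_class == "Y":
                ploidy = 1 if sex == "male" else 0
            elif config.chrom_class == "X" and sex == "male":
                ploidy = 1
            else:
                ploidy = 2
            if ploidy == 0:
                continue
            idx = rng.choice(len(pool), size=ploidy, p=freqs)
            alleles = [pool[i] for i in idx]
            names = tuple(sorted(format_isfg(a, config) for a in alleles))
            truth.genotypes[(sample, config.name)] = names
            truth.lb_genotypes[(sample, config.name)] = tuple(sorted(
                {str(ce_designation(a, config)) for a in alleles},
                key=lambda c: (float(c), c)))

            total = int(rng.negative_binomial(
                spec.dispersion,
                spec.dispersion / (spec.dispersion + spec.mean_reads)))
            reads: dict[tuple[str, str], int] = {}
            distinct = {_obs_key(a): a for a in alleles}
            if len(distinct) == 2:
                acr = float(rng.beta(b_alpha, b_beta))
                minor_frac = acr / (1.0 + acr)
                keys = list(distinct)
                minor = int(rng.integers(2))
                n_minor = int(rng.binomial(total, minor_frac))
                reads[keys[minor]] = n_minor
                reads[keys[1 - minor]] = total - n_minor
            else:
                reads[next(iter(distinct))] = total

            # single-step stutter
            if spec.stutter_rate > 0:
                for key, allele in list(distinct.items()):
                    n = reads.get(key, 0)
                    if n == 0:
                        continue
                    s = int(rng.binomial(n, spec.stutter_rate))
                    if s == 0:
                        continue
                    st = _stutter_allele(allele, config)
                    if st is None:
                        continue
                    skey = _obs_key(st)
                    reads[skey] = reads.get(skey, 0) + s
            # background noise onto a pool allele outside the genotype
            if spec.noise_rate > 0:
                others = [a for a in pool if _obs_key(a) not in distinct]
                if others:
                    n = int(rng.binomial(total, spec.noise_rate))
                    if n > 0:
                        tgt = others[int(rng.integers(len(others)))]
                        key = _obs_key(tgt)
                        reads[key] = reads.get(key, 0) + n

            for (sequence, flanks), n in sorted(reads.items()):
                if n == 0:
                    continue
                rows.append({"sample": sample, "sex": sex,
                             "locus": config.name, "sequence": sequence,
                             "flank_variants": flanks, "reads": n})

    observations = pd.DataFrame(
        rows, columns=["sample", "sex", "locus", "sequence",
                       "flank_variants", "reads"])
    return observations, truth


# ---------------------------------------------------------------------------
# Default study design
# ---------------------------------------------------------------------------

def replicate_config(config: LocusConfig, new_name: str) -> LocusConfig:
    """A copy of a locus under a new name (for many-locus simulations)."""
    return config.model_copy(update={"name": new_name})


def _mutate_run(allele: SequenceAllele, config: LocusConfig
                ) -> Optional[SequenceAllele]:
    """Plant a repeat-region variant: point-mutate one base inside the
    longest run, creating an interruption (an RRVO-by-construction allele)."""
    from .nomenclature import allele_from_sequence

    seq = allele.structure.expand()
    if "N" in seq:
        return None
    mid = len(seq) // 2
    base = seq[mid]
    swap = {"A": "G", "C": "T", "G": "A", "T": "C"}[base]
    mutated = seq[:mid] + swap + seq[mid + 1:]
    return allele_from_sequence(allele.locus, mutated, config,
                                allele.flank_variants)


def _flank_sub(config: LocusConfig) -> Optional["FlankVariant"]:
    from .locus_model import FlankVariant

    rng_def = config.flank_ranges.get("upstream") or next(
        iter(config.flank_ranges.values()), None)
    if rng_def is None:
        return None
    return FlankVariant("substitution", rng_def.end, alt="A")


def default_spec(configs: Mapping[str, LocusConfig] | None = None,
                 seed: int = 1,
                 loci: Sequence[str] | None = None,
                 stutter_rate: float = 0.01,
                 noise_rate: float = 0.002,
                 severe_imbalance_loci: tuple[str, ...] = ("D22S1045",),
                 balance_alpha: float = 50.0,
                 balance_beta: float = 10.0,
                 ) -> SimulationSpec:
    """A cohort design mirroring the shipped locus set.

    Each locus gets a pool of reference-pattern alleles at stepped run
    counts (frequencies 0.4/0.3/0.2/0.1 collapsed to the available
    alleles), one planted repeat-region variant and, where a flank range is
    configured, one planted flanking variant.
    """
    configs = configs or load_builtin_loci()
    chosen = list(loci) if loci is not None else list(configs)
    locus_specs = []
    for name in chosen:
        config = configs[name]
        ref = config.reference_repeat_structure()
        # stepped run counts on the longest variable slot
        var_idx = max(
            (i for i, t in enumerate(config.reference_structure) if t.variable),
            key=lambda i: config.reference_structure[i].count,
            default=None)
        base_alleles: list[SequenceAllele] = []
        for delta in (0, 1, -1):
            segments = list(ref.segments)
            if var_idx is None and delta != 0:
                continue
            if var_idx is not None:
                tmpl = config.reference_structure[var_idx]
                new_count = tmpl.count + delta
                if new_count < 2:
                    continue
                # template order is preserved segment-for-segment
                seg_positions = [i for i, s in enumerate(ref.segments)]
                segments[var_idx] = replace(ref.segments[var_idx],
                                            count=new_count)
            from .locus_model import RepeatStructure
            base_alleles.append(SequenceAllele(
                name, RepeatStructure(tuple(segments))))
        pool: list[tuple[SequenceAllele, str]] = [
            (a, "REFERENCE") for a in base_alleles]
        rr = _mutate_run(base_alleles[0], config)
        if rr is not None:
            pool.append((rr, "RRVO"))
        fv = _flank_sub(config)
        if fv is not None:
            pool.append((SequenceAllele(name, base_alleles[0].structure,
                                        (fv,)), "FRVO"))
        if rr is not None and fv is not None:
            pool.append((SequenceAllele(name, rr.structure, (fv,)), "RRFR"))
        weights = {1: [1.0], 2: [0.6, 0.4], 3: [0.5, 0.3, 0.2],
                   4: [0.4, 0.3, 0.2, 0.1], 5: [0.35, 0.25, 0.2, 0.15, 0.05],
                   6: [0.3, 0.25, 0.15, 0.15, 0.1, 0.05]}
        w = weights[len(pool)]
        alleles = tuple(
            PoolAllele(name=format_isfg(a, config), frequency=f, label=label)
            for (a, label), f in zip(pool, w))
        locus_specs.append(LocusSimSpec(locus=name, alleles=alleles))
    return SimulationSpec(loci=tuple(locus_specs), seed=seed,
                          stutter_rate=stutter_rate, noise_rate=noise_rate,
                          severe_imbalance_loci=severe_imbalance_loci,
                          balance_alpha=balance_alpha,
                          balance_beta=balance_beta)


def noiseless_spec(configs: Mapping[str, LocusConfig] | None = None,
                   seed: int = 1,
                   loci: Sequence[str] | None = None) -> SimulationSpec:
    """The no-error-source regime: no stutter, no noise, no imbalanced
    locus, and heterozygote balance concentrated near 1 so that no true
    allele can cross the calling thresholds."""
    return default_spec(configs, seed=seed, loci=loci, stutter_rate=0.0,
                        noise_rate=0.0, severe_imbalance_loci=(),
                        balance_alpha=300.0, balance_beta=3.0)


# ---------------------------------------------------------------------------
# End-to-end recovery
# ---------------------------------------------------------------------------

def recovery_suite(spec: SimulationSpec,
                   configs: Mapping[str, LocusConfig] | None = None,
                   ci_level: float = 0.99) -> dict:
    """Simulate, call, name, classify and estimate frequencies; compare
    everything against the truth record.

    Frequency recovery uses an exact binomial central interval at locus
    level: each allele's count is checked against Binomial(n, p) quantiles
    at level ``1 - (1 - ci_level)/k`` so the joint per-locus coverage is at
    least ``ci_level``.
    """
    from scipy.stats import binom

    from .io import observations_from_frame
    from .popgen import allele_frequencies

    configs = configs or load_builtin_loci()
    obs_df, truth = simulate_cohort(spec, configs)
    grouped = observations_from_frame(obs_df, configs)

    calls: dict[str, list[GenotypeCall]] = {}
    n_correct = n_total = 0
    for (sample, locus), observations in grouped.items():
        config = configs[locus]
        call = call_genotype(observations, config)
        calls.setdefault(locus, []).append(call)
        called_names = tuple(sorted(
            format_isfg(a, config) for a in call.alleles))
        want = truth.genotypes[(sample, locus)]
        want_set = tuple(sorted(set(want)))
        n_total += 1
        if called_names == want_set:
            n_correct += 1

    # planted variant-class labels vs classifier output
    class_ok = True
    for locus_spec in spec.loci:
        config = configs[locus_spec.locus]
        for pa in locus_spec.alleles:
            allele = parse_isfg(pa.name, config)
            if classify_variant(allele, config).value != pa.label:
                class_ok = False

    # frequency recovery
    sexes = truth.sexes
    loci_ok = 0
    n_loci = 0
    for locus_spec in spec.loci:
        config = configs[locus_spec.locus]
        table = allele_frequencies(calls[locus_spec.locus], config, sexes)
        by_name = {format_isfg(a, config): c
                   for (a, c) in table.counts}
        n = table.denominator
        planted = truth.frequencies[config.name]
        k = len(planted)
        tail = (1 - ci_level) / (2 * k)
        ok = True
        for name, p in planted.items():
            count = by_name.get(name, 0)
            lo = binom.ppf(tail, n, p)
            hi = binom.ppf(1 - tail, n, p)
            if not (lo <= count <= hi):
                ok = False
        loci_ok += ok
        n_loci += 1

    acr = acr_summary(c for lst in calls.values() for c in lst)
    return {
        "genotype_accuracy": n_correct / n_total if n_total else float("nan"),
        "n_sample_loci": n_total,
        "class_labels_recovered": class_ok,
        "freq_loci_within_bounds": loci_ok / n_loci if n_loci else float("nan"),
        "n_loci": n_loci,
        "acr_summary": acr,
        "discard_recommended": sorted(
            acr.loc[acr["discard_recommended"], "locus"]) if len(acr) else [],
    }
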