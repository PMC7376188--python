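"""Allele frequencies, diversity and forensic parameters, HWE and LD tests.

Frequencies use the counting method with ploidy-aware denominators: 2N
chromosomes for autosomal loci, 2F+M for X loci (both female alleles plus
the single male allele), M for Y loci.

Diversity statistics use the unbiased heterozygosity-style estimator

    GD = n (1 - sum p_i^2) / (n - 1),

with n the number of sampled chromosomes (for haplotype diversity, the
number of sampled individuals).  The effective number of alleles is the
reciprocal of expected homozygosity, Ae = 1 / sum p_i^2.

Exclusion probabilities are closed forms in the power sums a_k = sum p_i^k
(child-only duos and mother-child trios for autosomal loci; father-daughter
duos and father-mother-daughter trios for X loci); each is validated against
an exhaustive genotype-enumeration oracle in the test suite:

    PE_duo   = 1 - 4 a2 + 4 a3 - 3 a4 + 2 a2^2
    PE_trio  = 1 - 2 a2 + a3 + 3 a2 a3 - 3 a5 - 2 a2^2 + 2 a4
    MEC_duo  = 1 - 2 a2 + a3
    MEC_trio = 1 - a2 - a2^2 + a4

The HWE test is the exact conditional test (Levene distribution; full table
enumeration when the state space is small, otherwise a seeded Monte-Carlo
permutation of the allele vector).  The LD test permutes one locus's
genotypes and uses a genotypic contingency chi-square statistic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotyping import GenotypeCall, _expected_ploidy
from .locus_model import LocusConfig

__all__ = [
    "FrequencyTable",
    "HaplotypeTable",
    "ForensicParams",
    "allele_frequencies",
    "flank_variant_frequencies",
    "genetic_diversity",
    "haplotype_diversity",
    "effective_alleles",
    "pic",
    "rmp",
    "pe_duo",
    "pe_trio",
    "mec_x",
    "locus_parameters",
    "hwe_test",
    "ld_test",
    "pair_count",
    "bonferroni",
]


# ---------------------------------------------------------------------------
# Frequency containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrequencyTable:
    """Counting-method allele frequencies with their exact denominator."""

    locus: str
    counts: tuple[tuple[Hashable, int], ...]
    denominator: int

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ValueError("denominator must be positive")
        if sum(c for _, c in self.counts) != self.denominator:
            raise ValueError("counts must sum to the denominator")

    @classmethod
    def from_counts(cls, locus: str, counts: Mapping[Hashable, int]
                    ) -> "FrequencyTable":
        items = tuple(sorted(counts.items(), key=lambda kv: (-kv[1], repr(kv[0]))))
        return cls(locus, items, sum(counts.values()))

    @property
    def p(self) -> np.ndarray:
        return np.array([c for _, c in self.counts], dtype=float) / self.denominator

    def frequency(self, allele: Hashable) -> float:
        for a, c in self.counts:
            if a == allele:
                return c / self.denominator
        return 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "locus": self.locus,
            "allele": [repr(a) if not isinstance(a, str) else a
                       for a, _ in self.counts],
            "count": [c for _, c in self.counts],
            "denominator": self.denominator,
            "frequency": [round(c / self.denominator, 4) for _, c in self.counts],
        })


@dataclass(frozen=True)
class HaplotypeTable:
    """Multi-locus haplotype counts over N sampled individuals."""

    counts: tuple[tuple[Hashable, int], ...]
    n: int

    @classmethod
    def from_counts(cls, counts: Mapping[Hashable, int]) -> "HaplotypeTable":
        items = tuple(sorted(counts.items(), key=lambda kv: (-kv[1], repr(kv[0]))))
        return cls(items, sum(counts.values()))

    @property
    def p(self) -> np.ndarray:
        return np.array([c for _, c in self.counts], dtype=float) / self.n

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    @property
    def singleton_fraction(self) -> float:
        singletons = sum(1 for _, c in self.counts if c == 1)
        return singletons / self.n_distinct


def allele_frequencies(calls: Iterable[GenotypeCall], config: LocusConfig,
                       sexes: Mapping[str, str] | None = None
                       ) -> FrequencyTable:
    """Counting-method frequencies for one locus over a cohort of calls.

    X loci count both female alleles and the single male allele; Y loci
    count males only.  Samples with missing sex at a sex-linked locus are
    excluded with a warning.
    """
    sexes = sexes or {}
    counts: dict[Hashable, int] = {}
    denominator = 0
    for call in calls:
        if call.locus != config.name:
            raise ValueError(f"call at {call.locus} passed to {config.name}")
        if not call.called:
            continue
        sex = sexes.get(call.sample)
        if config.chrom_class != "autosomal" and sex not in ("female", "male"):
            warnings.warn(
                f"{config.name}: sample {call.sample} has no sex; excluded")
            continue
        if config.chrom_class == "Y" and sex != "male":
            continue
        ploidy = (_expected_ploidy(config.chrom_class, sex)
                  if config.chrom_class != "autosomal" else 2)
        if len(call.alleles) > ploidy:
            continue
        if call.is_het:
            for allele in call.alleles:
                counts[allele] = counts.get(allele, 0) + 1
        else:
            counts[call.alleles[0]] = counts.get(call.alleles[0], 0) + ploidy
        denominator += ploidy
    if denominator == 0:
        raise ValueError(f"{config.name}: no countable calls")
    return FrequencyTable.from_counts(config.name, counts)


def flank_variant_frequencies(calls: Iterable[GenotypeCall],
                              config: LocusConfig,
                              sexes: Mapping[str, str] | None = None
                              ) -> pd.DataFrame:
    """Per-variant carrier-chromosome frequencies over the locus denominator.

    Variants located inside the repeat region are excluded ("not counted"),
    mirroring how such records are reported alongside flanking variants.
    """
    table = allele_frequencies(calls, config, sexes)
    rows = []
    for allele, count in table.counts:
        if not hasattr(allele, "flank_variants"):
            continue
        for var in allele.flank_variants:
            if config.in_repeat_region(var):
                continue
            rows.append({"variant": var, "count": count})
    if not rows:
        return pd.DataFrame(columns=["locus", "variant", "kind", "count",
                                     "denominator", "frequency"])
    df = (pd.DataFrame(rows).groupby("variant", sort=False)["count"].sum()
          .reset_index())
    df["locus"] = config.name
    df["kind"] = df["variant"].map(lambda v: v.kind)
    df["denominator"] = table.denominator
    df["frequency"] = (df["count"] / table.denominator).round(4)
    df["variant"] = df["variant"].map(lambda v: v.render())
    return df[["locus", "variant", "kind", "count", "denominator", "frequency"]]


# ---------------------------------------------------------------------------
# Diversity statistics
# ---------------------------------------------------------------------------

def _as_p(freqs) -> np.ndarray:
    if isinstance(freqs, FrequencyTable):
        return freqs.p
    if isinstance(freqs, HaplotypeTable):
        return freqs.p
    p = np.asarray(freqs, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("need a 1-D, non-empty frequency vector")
    if not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
        raise ValueError(f"frequencies sum to {p.sum()}, not 1")
    return p


def genetic_diversity(freqs, n: int | None = None) -> float:
    """Unbiased gene diversity GD = n (1 - sum p^2) / (n - 1)."""
    if n is None:
        if not isinstance(freqs, FrequencyTable):
            raise ValueError("n required unless a FrequencyTable is given")
        n = freqs.denominator
    if n < 2:
        raise ValueError("gene diversity undefined for n < 2")
    p = _as_p(freqs)
    return float(n * (1.0 - np.sum(p * p)) / (n - 1))


def haplotype_diversity(haps: HaplotypeTable) -> float:
    """HD = N (1 - sum p_j^2) / (N - 1) over N sampled haplotypes."""
    if haps.n < 2:
        raise ValueError("haplotype diversity undefined for N < 2")
    return genetic_diversity(haps.p, haps.n)


def effective_alleles(freqs) -> float:
    """Ae = 1 / sum p_i^2 (reciprocal of expected homozygosity)."""
    p = _as_p(freqs)
    return float(1.0 / np.sum(p * p))


# ---------------------------------------------------------------------------
# Forensic parameters
# ---------------------------------------------------------------------------

def _power_sums(p: np.ndarray, upto: int = 5) -> dict[int, float]:
    return {k: float(np.sum(p ** k)) for k in range(2, upto + 1)}


def pic(freqs) -> float:
    """Polymorphism information content."""
    p = _as_p(freqs)
    a2 = float(np.sum(p * p))
    a4 = float(np.sum(p ** 4))
    return 1.0 - a2 - (a2 * a2 - a4)


def rmp(freqs) -> float:
    """Random match probability under HWE genotype frequencies."""
    p = _as_p(freqs)
    a2 = float(np.sum(p * p))
    a4 = float(np.sum(p ** 4))
    return 2.0 * a2 * a2 - a4


def rmp_observed(genotypes: Sequence[tuple]) -> float:
    """RMP from observed genotype frequencies (alternative estimator)."""
    counts: dict[tuple, int] = {}
    for g in genotypes:
        key = tuple(sorted(map(repr, g)))
        counts[key] = counts.get(key, 0) + 1
    n = sum(counts.values())
    return float(sum((c / n) ** 2 for c in counts.values()))


def pe_duo(freqs) -> float:
    """Power of exclusion, child-only (no mother) paternity duos."""
    a = _power_sums(_as_p(freqs))
    return 1 - 4 * a[2] + 4 * a[3] - 3 * a[4] + 2 * a[2] ** 2


def pe_trio(freqs) -> float:
    """Power of exclusion, mother-child-alleged-father trios."""
    a = _power_sums(_as_p(freqs))
    return (1 - 2 * a[2] + a[3] + 3 * a[2] * a[3] - 3 * a[5]
            - 2 * a[2] ** 2 + 2 * a[4])


def mec_x(freqs) -> tuple[float, float]:
    """X-chromosomal mean exclusion chance (father/daughter duo;
    father/mother/daughter trio)."""
    a = _power_sums(_as_p(freqs))
    duo = 1 - 2 * a[2] + a[3]
    trio = 1 - a[2] - a[2] ** 2 + a[4]
    return duo, trio


@dataclass(frozen=True)
class ForensicParams:
    """Per-locus forensic efficiency parameters."""

    locus: str
    n_chromosomes: int
    hobs: Optional[float] = None
    hexp: Optional[float] = None
    pic: Optional[float] = None
    rmp: Optional[float] = None
    dp: Optional[float] = None
    pe_duo: Optional[float] = None
    pe_trio: Optional[float] = None
    mec_duo: Optional[float] = None
    mec_trio: Optional[float] = None
    gd: Optional[float] = None
    ae: Optional[float] = None


def locus_parameters(freqs: FrequencyTable,
                     genotypes: Sequence[GenotypeCall] | None = None,
                     x_locus: bool = False,
                     use_observed_rmp: bool = False) -> ForensicParams:
    """All diploid-locus parameters from a frequency table and cohort calls.

    ``hobs`` is the observed heterozygote fraction among the provided calls;
    ``hexp`` equals the unbiased gene diversity with n = counted
    chromosomes.  With ``x_locus=True`` the X-chromosomal exclusion chances
    are reported as well.
    """
    called = [c for c in (genotypes or []) if c.called]
    if genotypes is not None and not called:
        raise ValueError(f"{freqs.locus}: empty genotype set")
    hobs = (sum(1 for c in called if c.is_het) / len(called)
            if called else None)
    hexp = genetic_diversity(freqs)
    the_rmp = (rmp_observed([c.alleles for c in called])
               if use_observed_rmp else rmp(freqs))
    duo, trio = mec_x(freqs) if x_locus else (None, None)
    return ForensicParams(
        locus=freqs.locus,
        n_chromosomes=freqs.denominator,
        hobs=hobs,
        hexp=hexp,
        pic=pic(freqs),
        rmp=the_rmp,
        dp=1.0 - the_rmp,
        pe_duo=pe_duo(freqs),
        pe_trio=pe_trio(freqs),
        mec_duo=duo,
        mec_trio=trio,
        gd=hexp,
        ae=effective_alleles(freqs),
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium
# ---------------------------------------------------------------------------

def _encode_genotypes(genotypes: Sequence[tuple]) -> tuple[np.ndarray, int]:
    alleles = sorted({a for g in genotypes for a in g}, key=repr)
    index = {a: i for i, a in enumerate(alleles)}
    arr = np.array([[index[g[0]], index[g[1]]] for g in genotypes], dtype=np.int64)
    return arr, len(alleles)


def _log_table_prob(genotype_counts: np.ndarray, allele_counts: np.ndarray,
                    n: int) -> float:
    """Levene conditional log-probability of a genotype count table."""
    k = len(allele_counts)
    het = sum(genotype_counts[i, j] for i in range(k) for j in range(i + 1, k))
    logp = (gammaln(n + 1) + het * math.log(2)
            + float(np.sum(gammaln(allele_counts + 1)))
            - gammaln(2 * n + 1))
    for i in range(k):
        for j in range(i, k):
            logp -= gammaln(genotype_counts[i, j] + 1)
    return float(logp)


def _enumerate_hwe(allele_counts: np.ndarray, log_obs: float) -> float:
    """Exact conditional p-value by DFS over heterozygote count tables."""
    k = len(allele_counts)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    total = 0.0
    p_value = 0.0
    n = int(allele_counts.sum()) // 2
    het = np.zeros((k, k), dtype=np.int64)
    remaining = allele_counts.astype(np.int64).copy()

    def rec(idx: int) -> None:
        nonlocal total, p_value
        if idx == len(pairs):
            if np.any(remaining % 2):
                return
            table = het.copy()
            for i in range(k):
                table[i, i] = remaining[i] // 2
            logp = _log_table_prob(table, allele_counts, n)
            prob = math.exp(logp)
            total += prob
            if logp <= log_obs + 1e-9:
                p_value += prob
            return
        i, j = pairs[idx]
        limit = min(remaining[i], remaining[j])
        for h in range(limit + 1):
            het[i, j] = h
            remaining[i] -= h
            remaining[j] -= h
            rec(idx + 1)
            remaining[i] += h
            remaining[j] += h
        het[i, j] = 0

    rec(0)
    # `total` sums to 1 up to float error; normalize defensively
    return min(1.0, p_value / total)


def _enum_state_estimate(allele_counts: np.ndarray) -> float:
    k = len(allele_counts)
    est = 1.0
    for i in range(k):
        for j in range(i + 1, k):
            est *= min(allele_counts[i], allele_counts[j]) + 1
            if est > 1e12:
                return est
    return est


def hwe_test(genotypes: Sequence[tuple], seed: int | None = None,
             n_perm: int = 100_000, max_enum_states: int = 1_000_000
             ) -> float:
    """Exact conditional HWE test for one diploid locus.

    ``genotypes`` are unordered allele pairs.  Full enumeration of the
    conditional distribution is used when the table state space is small;
    otherwise a seeded Monte-Carlo permutation of the allele vector with
    the conditional probability as the ordering statistic.  Monomorphic
    loci return p = 1.
    """
    if len(genotypes) < 2:
        raise ValueError("need at least two genotypes")
    arr, k = _encode_genotypes(genotypes)
    if k == 1:
        warnings.warn("monomorphic locus: HWE test is trivial (p = 1)")
        return 1.0
    n = arr.shape[0]
    allele_counts = np.bincount(arr.ravel(), minlength=k)
    obs_table = np.zeros((k, k), dtype=np.int64)
    lo = np.minimum(arr[:, 0], arr[:, 1])
    hi = np.maximum(arr[:, 0], arr[:, 1])
    np.add.at(obs_table, (lo, hi), 1)
    log_obs = _log_table_prob(obs_table, allele_counts, n)

    if _enum_state_estimate(allele_counts) <= max_enum_states:
        return _enumerate_hwe(allele_counts, log_obs)

    rng = np.random.default_rng(seed)
    pool = arr.ravel()
    log2 = math.log(2)
    const = (gammaln(n + 1) + float(np.sum(gammaln(allele_counts + 1)))
             - gammaln(2 * n + 1))
    hits = 0
    done = 0
    chunk = max(1, min(n_perm, 20_000_000 // max(1, n * k)))
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perms = np.tile(pool, (b, 1))
        perms = rng.permuted(perms, axis=1)
        a1 = perms[:, 0::2]
        a2 = perms[:, 1::2]
        lo_b = np.minimum(a1, a2)
        hi_b = np.maximum(a1, a2)
        gid = lo_b * k + hi_b
        flat = (np.arange(b)[:, None] * (k * k) + gid).ravel()
        tables = np.bincount(flat, minlength=b * k * k).reshape(b, k * k)
        het_mask = (np.arange(k)[:, None] != np.arange(k)[None, :]).ravel()
        hets = tables[:, het_mask].sum(axis=1)
        logp = const + hets * log2 - gammaln(tables + 1).sum(axis=1)
        hits += int(np.sum(logp <= log_obs + 1e-9))
        done += b
    return (1 + hits) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def _genotype_codes(genotypes: Sequence[tuple]) -> np.ndarray:
    keys = {}
    codes = []
    for g in genotypes:
        key = tuple(sorted(map(repr, g)))
        codes.append(keys.setdefault(key, len(keys)))
    return np.asarray(codes, dtype=np.int64)


def ld_test(genotypes_a: Sequence[tuple], genotypes_b: Sequence[tuple],
            seed: int | None = None, n_perm: int = 100_000) -> float:
    """Permutation test of genotypic association between two loci.

    The statistic is the chi-square of the two-locus genotype contingency
    table; the null is generated by permuting individuals at the second
    locus.  Both loci must be typed in the same individuals, in order.
    """
    if len(genotypes_a) != len(genotypes_b):
        raise ValueError("genotype lists differ in length")
    n = len(genotypes_a)
    if n < 2:
        raise ValueError("need at least two individuals")
    ca = _genotype_codes(genotypes_a)
    cb = _genotype_codes(genotypes_b)
    na, nb = ca.max() + 1, cb.max() + 1
    margin_a = np.bincount(ca, minlength=na).astype(float)
    margin_b = np.bincount(cb, minlength=nb).astype(float)
    expected = np.outer(margin_a, margin_b).ravel() / n
    live = expected > 0

    def chi2_rows(b_codes: np.ndarray) -> np.ndarray:
        # b_codes: (B, n) permuted codes for locus b
        B = b_codes.shape[0]
        joint = ca[None, :] * nb + b_codes
        flat = (np.arange(B)[:, None] * (na * nb) + joint).ravel()
        obs = np.bincount(flat, minlength=B * na * nb).reshape(B, na * nb)
        diff = obs[:, live] - expected[live]
        return np.sum(diff * diff / expected[live], axis=1)

    stat_obs = float(chi2_rows(cb[None, :])[0])
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    chunk = max(1, min(n_perm, 20_000_000 // max(1, n)))
    while done < n_perm:
        b = min(chunk, n_perm - done)
        keys = rng.random((b, n))
        order = np.argsort(keys, axis=1)
        permuted = cb[order]
        stats = chi2_rows(permuted)
        hits += int(np.sum(stats >= stat_obs - 1e-12))
        done += b
    return (1 + hits) / (n_perm + 1)


def pair_count(n_loci: int) -> int:
    """Number of distinct locus pairs, L(L-1)/2."""
    return n_loci * (n_loci - 1) // 2


def bonferroni(alpha: float, k: int) -> float:
    """Bonferroni-corrected per-test significance level alpha/k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return alpha / k
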