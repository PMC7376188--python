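"""Independent brute-force oracles used by the test suite.

These enumerate genotype configurations explicitly (mother x true father x
child x random man) with Mendelian compatibility logic, deliberately
avoiding the closed-form power-sum expressions they are used to validate.
"""

from __future__ import annotations

import numpy as np


def enum_pe_duo(p) -> float:
    """Child-only paternity exclusion: random man shares no child allele."""
    p = np.asarray(p, dtype=float)
    k = len(p)
    total = 0.0
    for i in range(k):
        for j in range(k):
            child_prob = p[i] * p[j]
            excluded = sum(p[a] * p[b]
                           for a in range(k) for b in range(k)
                           if a not in (i, j) and b not in (i, j))
            total += child_prob * excluded
    return total


def _paternal_allele_set(mother: tuple[int, int],
                         child: tuple[int, int]) -> set[int]:
    pa = set()
    for idx in range(2):
        allele, other = child[idx], child[1 - idx]
        if other in mother:
            pa.add(allele)
    return pa


def enum_pe_trio(p) -> float:
    """Mother-known paternity exclusion via full genotype enumeration."""
    p = np.asarray(p, dtype=float)
    k = len(p)
    total = 0.0
    for mi in range(k):
        for mj in range(k):
            p_mother = p[mi] * p[mj]
            for maternal in (mi, mj):
                for paternal in range(k):
                    p_child = 0.5 * p[paternal]
                    pa = _paternal_allele_set((mi, mj), (maternal, paternal))
                    q = sum(p[a] for a in pa)
                    # random man excluded iff neither of his alleles is in PA
                    total += p_mother * p_child * (1.0 - q) ** 2
    return total


def enum_mec_duo(p) -> float:
    """X-chromosomal father/daughter exclusion (father hemizygous)."""
    p = np.asarray(p, dtype=float)
    k = len(p)
    total = 0.0
    for i in range(k):
        for j in range(k):
            p_daughter = p[i] * p[j]
            q = p[i] + (p[j] if j != i else 0.0)
            total += p_daughter * (1.0 - q)
    return total


def enum_mec_trio(p) -> float:
    """X-chromosomal father/mother/daughter exclusion."""
    p = np.asarray(p, dtype=float)
    k = len(p)
    total = 0.0
    for mi in range(k):
        for mj in range(k):
            p_mother = p[mi] * p[mj]
            for maternal in (mi, mj):
                for paternal in range(k):
                    p_daughter = 0.5 * p[paternal]
                    pa = _paternal_allele_set((mi, mj), (maternal, paternal))
                    q = sum(p[a] for a in pa)
                    total += p_mother * p_daughter * (1.0 - q)
    return total
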