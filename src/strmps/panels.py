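"""Panel-level combination of per-locus forensic parameters.

The cumulative match probability of a marker panel is the product of the
per-locus random match probabilities; products reaching the 1e-70 scale are
accumulated in log space.  The combined power of exclusion is
1 - prod(1 - PE_l), accumulated through log1p of the complements.  Total
discrimination power TDP = 1 - CMP is printed in the ``1−(x)`` convention
when the complement is floating-point-indistinguishable from 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .popgen import ForensicParams

__all__ = ["PanelSummary", "combine", "format_scientific", "format_complement"]

MINUS = "−"  # U+2212, as printed in combined-parameter tables


def format_scientific(value: float, sig: int = 4) -> str:
    """``3.218E−34``-style scientific notation with 4 significant digits."""
    if value == 0:
        return "0"
    s = f"{value:.{sig - 1}E}"
    mantissa, exponent = s.split("E")
    exp = int(exponent)
    return f"{mantissa}E{MINUS}{abs(exp)}" if exp < 0 else f"{mantissa}E{exp}"


def format_complement(log1m: float, sig: int = 4) -> str:
    """Render 1 - x given log(x)... i.e. ``1−(3.218E−34)`` when x underflows
    the printable precision of 1 - x, else the plain decimal."""
    x = math.exp(log1m)
    if 1.0 - x < 1.0 and x > 1e-4:
        return f"{1.0 - x:.{sig + 4}g}"
    return f"1{MINUS}({format_scientific(x, sig)})"


@dataclass(frozen=True)
class PanelSummary:
    """Combined parameters of a marker subset, stored in log domain."""

    loci: tuple[str, ...]
    log_cmp: float            # natural log of the cumulative match probability
    log1m_cpe_duo: float      # log(1 - CPE_duo)
    log1m_cpe_trio: float     # log(1 - CPE_trio)

    @property
    def cmp(self) -> float:
        return math.exp(self.log_cmp)

    @property
    def tdp(self) -> float:
        return 1.0 - self.cmp

    @property
    def cpe_duo(self) -> float:
        return -math.expm1(self.log1m_cpe_duo)

    @property
    def cpe_trio(self) -> float:
        return -math.expm1(self.log1m_cpe_trio)

    def render(self) -> dict[str, str]:
        """Display strings in combined-parameter table conventions."""
        return {
            "CMP": format_scientific(self.cmp),
            "TDP": format_complement(self.log_cmp),
            "CPE_duo": f"{self.cpe_duo:.10g}" if self.cpe_duo < 1 - 1e-12
                        else format_complement(self.log1m_cpe_duo),
            "CPE_trio": f"{self.cpe_trio:.10g}" if self.cpe_trio < 1 - 1e-12
                         else format_complement(self.log1m_cpe_trio),
        }


def combine(params: Mapping[str, ForensicParams] | Iterable[ForensicParams],
            subset: Sequence[str] | None = None,
            use_mec_for_x: bool = False) -> PanelSummary:
    """Combine per-locus parameters over a marker subset.

    ``CMP = prod RMP_l`` and ``CPE = 1 - prod(1 - PE_l)``; X-chromosomal
    loci are excluded unless explicitly requested (``use_mec_for_x`` swaps
    in MEC_duo/MEC_trio for loci that carry them).
    """
    if not isinstance(params, Mapping):
        params = {p.locus: p for p in params}
    loci = list(subset) if subset is not None else list(params)
    missing = [l for l in loci if l not in params]
    if missing:
        raise KeyError(f"missing parameters for loci: {', '.join(missing)}")
    log_cmp = 0.0
    log1m_duo = 0.0
    log1m_trio = 0.0
    used: list[str] = []
    for locus in loci:
        par = params[locus]
        is_x = par.mec_duo is not None
        if is_x and not use_mec_for_x:
            continue
        if par.rmp is None:
            raise ValueError(f"locus {locus} lacks RMP")
        duo = par.mec_duo if (is_x and use_mec_for_x) else par.pe_duo
        trio = par.mec_trio if (is_x and use_mec_for_x) else par.pe_trio
        if duo is None or trio is None:
            raise ValueError(f"locus {locus} lacks exclusion parameters")
        log_cmp += math.log(par.rmp)
        log1m_duo += math.log1p(-duo)
        log1m_trio += math.log1p(-trio)
        used.append(locus)
    if not used:
        raise ValueError("no loci left to combine")
    return PanelSummary(tuple(used), log_cmp, log1m_duo, log1m_trio)
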