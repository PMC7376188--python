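"""Static locus descriptions for sequence-based STR analysis.

A locus is described by its GRCh38 repeat-region interval (1-based, both ends
inclusive, matching the convention used in published sequence-based allele
names such as ``84,160,226–84,160,277``), the repeat motif length, a reference
repeat structure expressed as an ordered segment template, the CE designation
anchored to that reference structure, the analysed flanking intervals, and the
genotype-calling thresholds.

The reference structure doubles as the alignment template for bracketed
ISFG-style encoding: *variable* segments absorb maximal runs of their motif,
*fixed* segments are literal interruptions (lowercase segments are excluded
from repeat-unit counting), and *gap* segments stand for uncalled stretches
rendered ``N<len>``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, Field, model_validator

EN_DASH = "–"

_NUC_RE = re.compile(r"^[ACGTN]+$")


# ---------------------------------------------------------------------------
# Repeat structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """One maximal block of a bracketed repeat structure.

    ``unit`` is stored uppercase; ``lower`` marks segments rendered lowercase
    (display convention for interruptions that do not count toward the repeat
    unit total). ``gap`` segments represent uncalled stretches: ``unit`` is
    ``"N"`` and ``count`` is the gap length in nucleotides. ``origin`` records
    how the encoder placed the segment (template match, substitution of a
    fixed slot, or foreign material) and does not take part in equality.
    """

    unit: str
    count: int = 1
    counted: bool = True
    lower: bool = False
    gap: bool = False
    origin: str = field(default="template", compare=False)

    def __post_init__(self) -> None:
        if self.gap:
            if self.unit != "N" or self.count < 1:
                raise ValueError("gap segments must have unit 'N' and count >= 1")
        else:
            if not _NUC_RE.match(self.unit):
                raise ValueError(f"invalid segment unit {self.unit!r}")
            if self.count < 1:
                raise ValueError("segment count must be >= 1")

    @property
    def length(self) -> int:
        return self.count if self.gap else len(self.unit) * self.count

    def expand(self) -> str:
        return "N" * self.count if self.gap else self.unit * self.count

    def render(self) -> str:
        if self.gap:
            return f"N{self.count}"
        if self.lower:
            return self.unit.lower()
        if self.count >= 2:
            return f"[{self.unit}]{self.count}"
        return self.unit


@dataclass(frozen=True)
class RepeatStructure:
    """Ordered segments of one repeat-region allele."""

    segments: tuple[Segment, ...] = ()

    @property
    def length(self) -> int:
        return sum(s.length for s in self.segments)

    def unit_count(self) -> int:
        """Total counted repeat units (lowercase / partial / gap segments: 0)."""
        return sum(s.count for s in self.segments if s.counted and not s.gap)

    def expand(self) -> str:
        return "".join(s.expand() for s in self.segments)

    def render(self) -> str:
        return " ".join(s.render() for s in self.segments)


def expand(structure: RepeatStructure) -> str:
    """Expand a repeat structure to its nucleotide string (gaps as N-runs)."""
    return structure.expand()


# ---------------------------------------------------------------------------
# CE designation
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class CeDesignation:
    """Length-derived allele number: whole repeats plus leftover nucleotides."""

    whole: int
    partial: int = 0

    def __post_init__(self) -> None:
        if self.whole < 0 or self.partial < 0:
            raise ValueError("CE designation components must be non-negative")

    def __str__(self) -> str:
        return f"{self.whole}.{self.partial}" if self.partial else str(self.whole)

    @classmethod
    def parse(cls, text: str) -> "CeDesignation":
        text = text.strip()
        if "." in text:
            whole, partial = text.split(".", 1)
            return cls(int(whole), int(partial))
        return cls(int(text))


# ---------------------------------------------------------------------------
# Flanking-region variants
# ---------------------------------------------------------------------------

def _fmt_coord(pos: int) -> str:
    return f"{pos:,}"


_COORD = r"\d{1,3}(?:,\d{3})*|\d+"
_SUB_RE = re.compile(rf"^({_COORD})-([ACGT]+)$")
_INS_RE = re.compile(rf"^({_COORD})\.(\d+)([ACGT]+)$")
_DEL_RE = re.compile(rf"^({_COORD})[{EN_DASH}-]({_COORD})$")


@dataclass(frozen=True, order=True)
class FlankVariant:
    """A substitution, insertion or deletion in the analysed fragment.

    ``position`` is the GRCh38 coordinate; insertions additionally carry a
    ``sub_index`` (``204.1`` = first base inserted after coordinate 204, with
    the insertion left-aligned to its 5'-most equivalent position). Deletions
    carry their full coordinate ``span``.
    """

    kind: Literal["substitution", "insertion", "deletion"]
    position: int
    alt: str = ""
    sub_index: int = 0
    span: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.kind == "substitution":
            if not self.alt or self.sub_index:
                raise ValueError("substitution needs alt and no sub_index")
        elif self.kind == "insertion":
            if not self.alt or self.sub_index < 1:
                raise ValueError("insertion needs alt and sub_index >= 1")
        elif self.kind == "deletion":
            span = self.span or (self.position, self.position)
            if span[0] > span[1]:
                raise ValueError("deletion span reversed")
            object.__setattr__(self, "span", span)
        else:  # pragma: no cover - guarded by Literal
            raise ValueError(f"unknown variant kind {self.kind!r}")

    @property
    def length_effect(self) -> int:
        """Signed change in analysed-fragment length caused by this variant."""
        if self.kind == "insertion":
            return len(self.alt)
        if self.kind == "deletion":
            assert self.span is not None
            return -(self.span[1] - self.span[0] + 1)
        return 0

    def render(self) -> str:
        if self.kind == "substitution":
            return f"{_fmt_coord(self.position)}-{self.alt}"
        if self.kind == "insertion":
            return f"{_fmt_coord(self.position)}.{self.sub_index}{self.alt}"
        assert self.span is not None
        return f"{_fmt_coord(self.span[0])}{EN_DASH}{_fmt_coord(self.span[1])} DEL"

    @classmethod
    def parse(cls, text: str, strict: bool = False) -> "FlankVariant":
        """Parse one annotation token (``pos-ALT``, ``pos.1ALT``, ``a–b DEL``).

        Tolerant mode (default) accepts an ASCII hyphen in deletion spans.
        """
        text = text.strip()
        if text.endswith(" DEL"):
            m = _DEL_RE.match(text[:-4].strip())
            if not m:
                raise ValueError(f"malformed deletion annotation {text!r}")
            if strict and EN_DASH not in text:
                raise ValueError(f"deletion span must use en-dash: {text!r}")
            start = int(m.group(1).replace(",", ""))
            end = int(m.group(2).replace(",", ""))
            return cls("deletion", start, span=(start, end))
        m = _INS_RE.match(text)
        if m:
            return cls("insertion", int(m.group(1).replace(",", "")),
                       alt=m.group(3), sub_index=int(m.group(2)))
        m = _SUB_RE.match(text)
        if m:
            return cls("substitution", int(m.group(1).replace(",", "")),
                       alt=m.group(2))
        raise ValueError(f"malformed flank annotation {text!r}")


# ---------------------------------------------------------------------------
# Locus configuration (pydantic-validated, JSON-backed)
# ---------------------------------------------------------------------------

class Interval(BaseModel):
    """1-based, both-ends-inclusive GRCh38 interval."""

    model_config = {"frozen": True}

    start: int
    end: int

    @model_validator(mode="after")
    def _check(self) -> "Interval":
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")
        return self

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start <= other.end and other.start <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class TemplateSegment(BaseModel):
    """One slot of a reference repeat-structure template.

    JSON uses display casing: lowercase ``unit`` marks an uncounted
    interruption. ``variable`` slots absorb a maximal run of their motif when
    aligning an observed sequence; fixed slots match literally. ``gap`` slots
    (``unit`` omitted) are N-stretches whose length may vary between alleles;
    ``count`` gives the reference length.
    """

    model_config = {"frozen": True}

    unit: str = ""
    count: int = 1
    variable: bool = False
    gap: bool = False

    @model_validator(mode="after")
    def _check(self) -> "TemplateSegment":
        if self.gap:
            if self.unit:
                raise ValueError("gap template segments take no unit")
        else:
            if not _NUC_RE.match(self.unit.upper()):
                raise ValueError(f"invalid template unit {self.unit!r}")
            if self.unit != self.unit.upper() and self.variable:
                raise ValueError("variable segments must be uppercase motifs")
        if self.count < 1:
            raise ValueError("template count must be >= 1")
        return self

    @property
    def lower(self) -> bool:
        return bool(self.unit) and self.unit == self.unit.lower()

    @property
    def unit_upper(self) -> str:
        return self.unit.upper()

    def to_segment(self, motif_len: int) -> Segment:
        if self.gap:
            return Segment("N", self.count, counted=False, gap=True)
        counted = (not self.lower) and len(self.unit) == motif_len
        return Segment(self.unit_upper, self.count, counted=counted,
                       lower=self.lower)


class LocusConfig(BaseModel):
    """Everything the pipeline needs to know about one locus."""

    model_config = {"frozen": True}

    name: str
    chrom_class: Literal["autosomal", "X", "Y"]
    chrom_label: str
    repeat_region: Interval
    motif_len: int = Field(ge=2, le=6)
    reference_structure: tuple[TemplateSegment, ...]
    reference_ce: str
    flank_ranges: dict[str, Interval] = Field(default_factory=dict)
    balance_threshold: float = 0.60
    analytical_threshold_pct: float = 0.015
    interpretation_threshold_pct: float = 0.045

    @model_validator(mode="after")
    def _check(self) -> "LocusConfig":
        if not (0.0 <= self.analytical_threshold_pct
                <= self.interpretation_threshold_pct <= 1.0):
            raise ValueError(
                f"locus {self.name}: need 0 <= AT <= IT <= 1, got "
                f"AT={self.analytical_threshold_pct} IT={self.interpretation_threshold_pct}")
        if not (0.0 < self.balance_threshold <= 1.0):
            raise ValueError(
                f"locus {self.name}: balance_threshold must be in (0, 1]")
        for label, rng in self.flank_ranges.items():
            if rng.overlaps(self.repeat_region):
                raise ValueError(
                    f"locus {self.name}: flank range {label!r} overlaps repeat region")
        for seg in self.reference_structure:
            if not seg.gap and not seg.lower and len(seg.unit) == self.motif_len:
                if (len(seg.unit) * seg.count) % self.motif_len:
                    raise ValueError(
                        f"locus {self.name}: counted segment {seg.unit!r} "
                        f"not a whole number of motifs")
        CeDesignation.parse(self.reference_ce)  # must parse
        return self

    # -- derived views -----------------------------------------------------

    @property
    def ce_anchor(self) -> CeDesignation:
        return CeDesignation.parse(self.reference_ce)

    def reference_repeat_structure(self) -> RepeatStructure:
        return RepeatStructure(tuple(
            seg.to_segment(self.motif_len) for seg in self.reference_structure))

    @property
    def reference_length(self) -> int:
        return self.reference_repeat_structure().length

    def in_repeat_region(self, variant: FlankVariant) -> bool:
        if variant.kind == "deletion" and variant.span is not None:
            return variant.span[0] in self.repeat_region
        return variant.position in self.repeat_region

    def in_flank_range(self, variant: FlankVariant) -> bool:
        pos = variant.position
        return any(pos in rng for rng in self.flank_ranges.values())

    def motif_priority(self) -> list[str]:
        """Motifs usable for run detection, in reference order."""
        seen: list[str] = []
        for seg in self.reference_structure:
            u = seg.unit_upper
            if not seg.gap and len(u) == self.motif_len and u not in seen:
                seen.append(u)
        return seen


class ConfigError(ValueError):
    """Raised for malformed or inconsistent locus configuration files."""


def load_locus_config(path: str | Path) -> list[LocusConfig]:
    """Load a JSON locus configuration file.

    The file holds a top-level list of locus objects (coordinates 1-based
    inclusive). Duplicate locus names are rejected.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(raw, list):
        raise ConfigError(f"{path}: expected a top-level list of loci")
    configs: list[LocusConfig] = []
    seen: set[str] = set()
    for item in raw:
        try:
            cfg = LocusConfig.model_validate(item)
        except Exception as exc:
            name = item.get("name", "<unnamed>") if isinstance(item, dict) else "<bad entry>"
            raise ConfigError(f"{path}: locus {name}: {exc}") from exc
        if cfg.name in seen:
            raise ConfigError(f"{path}: duplicate locus name {cfg.name!r}")
        seen.add(cfg.name)
        configs.append(cfg)
    return configs


def dump_locus_config(configs: list[LocusConfig], path: str | Path) -> None:
    """Serialize configs back to JSON (inverse of :func:`load_locus_config`)."""
    payload = [json.loads(cfg.model_dump_json()) for cfg in configs]
    Path(path).write_text(
        json.dumps(payload, indent=1, ensure_ascii=False) + "\n", encoding="utf-8")


def builtin_config_path() -> Path:
    """Path of the locus configuration shipped with the package."""
    return Path(__file__).parent / "data" / "loci.json"


def load_builtin_loci() -> dict[str, LocusConfig]:
    return {cfg.name: cfg for cfg in load_locus_config(builtin_config_path())}
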