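"""Bracketed sequence-based allele names and CE designations.

Observed repeat-region sequences are encoded into maximal-run bracketed
structures by aligning them against the locus reference template
(:class:`~strmps.locus_model.TemplateSegment` list).  The aligner is a small
exact dynamic programme over (sequence position, template slot):

* variable slots absorb a maximal contiguous run of their motif (with
  backtracking, so a literal interruption expected downstream is not eaten);
* fixed slots match literally, or accept a same-length substitution;
* slots may be skipped, and sequence stretches not claimed by the template are
  re-segmented by a run scanner over the configured motifs.

Scores are compared lexicographically: template-claimed nucleotides first
(substituted fixed slots count as claimed), then exactly matched fixed slots,
then substituted slots.  Ties keep the first alignment in a fixed exploration
order (maximal run counts first), which makes the encoding deterministic.

The CE (capillary-electrophoresis equivalent) designation is *length*
anchored, never unit-count anchored: the reference structure carries a CE
anchor, and an allele's CE is the anchor shifted by the analysed-fragment
length difference in motif-length steps, with the remainder as the
microvariant part.  Flanking insertions/deletions shift the fragment length;
variants located inside the repeat region do not (their effect is already
visible in the repeat structure itself).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .locus_model import (
    EN_DASH,
    CeDesignation,
    FlankVariant,
    LocusConfig,
    RepeatStructure,
    Segment,
    TemplateSegment,
)

__all__ = [
    "SequenceAllele",
    "bracket_encode",
    "repeat_unit_count",
    "ce_designation",
    "format_isfg",
    "parse_isfg",
    "allele_from_sequence",
    "NomenclatureError",
    "ParseError",
]


class NomenclatureError(ValueError):
    pass


class ParseError(NomenclatureError):
    def __init__(self, message: str, offset: int = -1):
        super().__init__(message if offset < 0 else f"{message} (at offset {offset})")
        self.offset = offset


# ---------------------------------------------------------------------------
# Template alignment
# ---------------------------------------------------------------------------

_NUC_RE = re.compile(r"^[ACGTN]+$")


def _run_length(seq: str, pos: int, unit: str) -> int:
    n, L = 0, len(unit)
    while seq.startswith(unit, pos + n * L):
        n += 1
    return n


def _align_template(seq: str, template: tuple[TemplateSegment, ...],
                    motif_len: int) -> list[Segment]:
    """Best segmentation of ``seq`` against the reference template.

    Scores are ``(claimed nucleotides, exact fixed slots, substituted
    slots)`` compared lexicographically.  Returns segments covering
    unclaimed stretches as ``origin='foreign'`` placeholders of unit
    length 1; these are merged and re-segmented by the caller.
    """
    memo: dict[tuple[int, int], tuple[tuple[int, int, int], list]] = {}

    def best(pos: int, idx: int) -> tuple[tuple[int, int, int], list]:
        key = (pos, idx)
        if key in memo:
            return memo[key]
        if pos == len(seq) and idx == len(template):
            result = ((0, 0, 0), [])
            memo[key] = result
            return result
        candidates: list[tuple[tuple[int, int, int], list]] = []

        if idx < len(template):
            slot = template[idx]
            if slot.gap:
                run = _run_length(seq, pos, "N")
                if run >= 1:
                    sc, tail = best(pos + run, idx + 1)
                    seg = Segment("N", run, counted=False, gap=True)
                    candidates.append(((sc[0] + run, sc[1], sc[2]),
                                       [seg] + tail))
            elif slot.variable:
                unit = slot.unit_upper
                max_run = _run_length(seq, pos, unit)
                for k in range(max_run, 0, -1):
                    sc, tail = best(pos + k * len(unit), idx + 1)
                    seg = Segment(unit, k,
                                  counted=len(unit) == motif_len, lower=False)
                    candidates.append(((sc[0] + k * len(unit), sc[1], sc[2]),
                                       [seg] + tail))
            else:
                unit = slot.unit_upper
                width = len(unit) * slot.count
                chunk = seq[pos:pos + width]
                if chunk == unit * slot.count:
                    sc, tail = best(pos + width, idx + 1)
                    counted = (not slot.lower) and len(unit) == motif_len
                    seg = Segment(unit, slot.count, counted=counted,
                                  lower=slot.lower, origin="fixed")
                    candidates.append(((sc[0] + width, sc[1] + 1, sc[2]),
                                       [seg] + tail))
                elif len(chunk) == width and "N" not in chunk:
                    # same-length substitution of a fixed slot
                    sc, tail = best(pos + width, idx + 1)
                    counted = (not slot.lower) and len(chunk) == motif_len
                    seg = Segment(chunk, 1, counted=counted, lower=slot.lower,
                                  origin="subst")
                    candidates.append(((sc[0] + width, sc[1], sc[2] + 1),
                                       [seg] + tail))
            # skip the slot entirely
            sc, tail = best(pos, idx + 1)
            candidates.append((sc, tail))

        if pos < len(seq):
            # leave one nucleotide to the foreign scanner
            sc, tail = best(pos + 1, idx)
            marker = Segment("N" if seq[pos] == "N" else seq[pos], 1,
                             counted=False, gap=seq[pos] == "N",
                             origin="foreign")
            candidates.append((sc, [marker] + tail))

        result = max(candidates, key=lambda c: c[0])
        memo[key] = result
        return result

    _, segments = best(0, 0)
    return segments


def _scan_foreign(chunk: str, motifs: list[str], motif_len: int) -> list[Segment]:
    """Segment template-unclaimed sequence into runs and leftover blocks."""
    out: list[Segment] = []
    pos = 0
    while pos < len(chunk):
        if chunk[pos] == "N":
            run = _run_length(chunk, pos, "N")
            out.append(Segment("N", run, counted=False, gap=True,
                               origin="foreign"))
            pos += run
            continue
        # earliest offset at which a configured motif run (or N-gap) starts
        best_off, best_unit, best_run = None, None, 0
        for off in range(len(chunk) - pos):
            if chunk[pos + off] == "N":
                best_off, best_unit, best_run = off, None, 0
                break
            for unit in motifs:
                run = _run_length(chunk, pos + off, unit)
                if run > best_run:
                    best_unit, best_run = unit, run
            if best_run >= 1:
                best_off = off
                break
        if best_off is None:
            best_off = len(chunk) - pos
        # leftover before the run: emit in motif-length pieces
        lead = chunk[pos:pos + best_off]
        while lead:
            piece, lead = lead[:motif_len], lead[motif_len:]
            out.append(Segment(piece, 1, counted=len(piece) == motif_len,
                               origin="foreign"))
        pos += best_off
        if best_unit is not None and best_run >= 1:
            out.append(Segment(best_unit, best_run,
                               counted=len(best_unit) == motif_len,
                               origin="foreign"))
            pos += best_run * len(best_unit)
    return out


def _merge_adjacent(segments: list[Segment]) -> list[Segment]:
    """Merge adjacent same-unit run segments when neither is a template slot.

    Template-fixed slots stay distinct (e.g. ``[CAGA]4 CAGA`` where the final
    slot is a substituted reference singleton).
    """
    out: list[Segment] = []
    for seg in segments:
        if (out and not seg.gap and not out[-1].gap
                and seg.origin == "foreign" and out[-1].origin == "foreign"
                and seg.unit == out[-1].unit and seg.counted == out[-1].counted
                and seg.lower == out[-1].lower):
            out[-1] = replace(out[-1], count=out[-1].count + seg.count)
        else:
            out.append(seg)
    return out


def bracket_encode(sequence: str, config: LocusConfig) -> RepeatStructure:
    """Encode a repeat-region sequence into a bracketed structure.

    ``sequence`` is the repeat-region portion of the analysed fragment
    (flanks already split off), A/C/G/T/N only.
    """
    sequence = sequence.upper()
    if not sequence:
        raise NomenclatureError("empty sequence")
    if not _NUC_RE.match(sequence):
        bad = re.search(r"[^ACGTN]", sequence)
        raise NomenclatureError(
            f"non-nucleotide character {sequence[bad.start()]!r} "
            f"at position {bad.start()}")
    if len(sequence) < config.motif_len:
        raise NomenclatureError(
            f"sequence shorter than one {config.motif_len}-nt motif")

    aligned = _align_template(sequence, tuple(config.reference_structure),
                              config.motif_len)
    motifs = config.motif_priority()

    # replace stretches of single-nucleotide foreign markers with scanner output
    out: list[Segment] = []
    buffer = ""
    for seg in aligned:
        if seg.origin == "foreign" and seg.count == 1 and seg.length == 1:
            buffer += seg.expand()
            continue
        if buffer:
            out.extend(_scan_foreign(buffer, motifs, config.motif_len))
            buffer = ""
        out.append(seg)
    if buffer:
        out.extend(_scan_foreign(buffer, motifs, config.motif_len))

    structure = RepeatStructure(tuple(_merge_adjacent(out)))
    assert structure.expand() == sequence, "encoder must preserve the sequence"
    return structure


def repeat_unit_count(structure: RepeatStructure) -> int:
    """Counted repeat units; lowercase and gap segments contribute zero."""
    return structure.unit_count()


# ---------------------------------------------------------------------------
# Sequence alleles and CE designation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceAllele:
    """One observed allele: repeat structure plus flanking-region variants."""

    locus: str
    structure: RepeatStructure
    flank_variants: tuple[FlankVariant, ...] = ()

    def __post_init__(self) -> None:
        # canonical order: genomic position, then insertion sub-index
        ordered = tuple(sorted(
            self.flank_variants,
            key=lambda v: (v.position, v.sub_index, v.kind, v.alt)))
        object.__setattr__(self, "flank_variants", ordered)

    def sorted_variants(self) -> tuple[FlankVariant, ...]:
        return self.flank_variants


def ce_designation(allele: SequenceAllele, config: LocusConfig) -> CeDesignation:
    """Length-anchored CE designation of an allele.

    ΔL is the analysed-fragment length difference to the reference allele;
    flanking insertions and deletions shift it, repeat-region variants do not
    (their length change is already part of the repeat structure).
    """
    if allele.locus != config.name:
        raise NomenclatureError(
            f"allele locus {allele.locus!r} != config locus {config.name!r}")
    delta = allele.structure.length - config.reference_length
    for var in allele.flank_variants:
        if not config.in_repeat_region(var):
            delta += var.length_effect
    anchor = config.ce_anchor
    total = delta + anchor.partial
    whole = anchor.whole + total // config.motif_len
    partial = total % config.motif_len
    if whole < 0:
        raise NomenclatureError(
            f"{config.name}: allele shorter than representable "
            f"(ΔL={delta} nt from CE {anchor})")
    return CeDesignation(whole, partial)


def allele_from_sequence(locus: str, sequence: str, config: LocusConfig,
                         flank_variants: tuple[FlankVariant, ...] = ()
                         ) -> SequenceAllele:
    """Convenience: encode a raw repeat-region sequence into an allele."""
    return SequenceAllele(locus, bracket_encode(sequence, config),
                          tuple(flank_variants))


# ---------------------------------------------------------------------------
# Canonical ISFG-style name strings
# ---------------------------------------------------------------------------

def _fmt_coord(pos: int) -> str:
    return f"{pos:,}"


def format_isfg(allele: SequenceAllele, config: LocusConfig) -> str:
    """Canonical name, e.g.
    ``D7S820 [CE10.1]-Chr7-GRCh38 84,160,226–84,160,277 [TATC]10
    84,160,204-A; 84,160,204.1A``."""
    ce = ce_designation(allele, config)
    region = config.repeat_region
    parts = [
        allele.locus,
        f"[CE{ce}]-Chr{config.chrom_label}-GRCh38",
        f"{_fmt_coord(region.start)}{EN_DASH}{_fmt_coord(region.end)}",
        allele.structure.render(),
    ]
    variants = allele.sorted_variants()
    if variants:
        parts.append("; ".join(v.render() for v in variants))
    return " ".join(parts)


_HEADER_RE = re.compile(
    rf"^\[CE(\d+(?:\.\d+)?)\]-Chr(\w+)-GRCh38$")
_REGION_RE = re.compile(
    rf"^(\d{{1,3}}(?:,\d{{3}})*|\d+)([{EN_DASH}-])(\d{{1,3}}(?:,\d{{3}})*|\d+)$")
_RUN_RE = re.compile(r"^\[([ACGT]+)\](\d+)$")
_GAP_RE = re.compile(r"^N(\d+)$")
_ANNOT_START_RE = re.compile(r"^\d")


def parse_isfg(name: str, config: LocusConfig, strict: bool = False
               ) -> SequenceAllele:
    """Parse a canonical allele name back into a :class:`SequenceAllele`.

    ``format_isfg`` on the result reproduces the input byte-identically.
    Strict mode insists on the en-dash in coordinate ranges; tolerant mode
    (default) also accepts an ASCII hyphen.
    """
    tokens = name.split(" ")
    if len(tokens) < 4:
        raise ParseError(f"too few fields in {name!r}", 0)
    locus = tokens[0]
    if locus != config.name:
        raise ParseError(
            f"name is for locus {locus!r}, config is {config.name!r}", 0)
    offset = len(tokens[0]) + 1
    m = _HEADER_RE.match(tokens[1])
    if not m:
        raise ParseError(f"malformed CE/chromosome field {tokens[1]!r}", offset)
    stated_ce = CeDesignation.parse(m.group(1))
    offset += len(tokens[1]) + 1
    m = _REGION_RE.match(tokens[2])
    if not m:
        raise ParseError(f"malformed coordinate range {tokens[2]!r}", offset)
    if strict and m.group(2) != EN_DASH:
        raise ParseError("coordinate range must use en-dash", offset)
    start = int(m.group(1).replace(",", ""))
    end = int(m.group(3).replace(",", ""))
    if (start, end) != (config.repeat_region.start, config.repeat_region.end):
        raise ParseError(
            f"coordinate range {start}-{end} does not match configured "
            f"repeat region", offset)
    offset += len(tokens[2]) + 1

    segments: list[Segment] = []
    variants: list[FlankVariant] = []
    i = 3
    while i < len(tokens):
        tok = tokens[i]
        tok_offset = offset
        offset += len(tok) + 1
        if not tok:
            raise ParseError("empty token (double space?)", tok_offset)
        if _ANNOT_START_RE.match(tok):
            # flank annotation; deletions span two tokens ("<range> DEL")
            annot = tok
            if i + 1 < len(tokens) and tokens[i + 1].rstrip(";") == "DEL":
                annot = f"{tok} {tokens[i + 1]}"
                offset += len(tokens[i + 1]) + 1
                i += 1
            trailing = annot.endswith(";")
            annot = annot.rstrip(";")
            try:
                variants.append(FlankVariant.parse(annot, strict=strict))
            except ValueError as exc:
                raise ParseError(str(exc), tok_offset) from None
            if trailing and i + 1 >= len(tokens):
                raise ParseError("dangling ';' after last annotation", tok_offset)
            i += 1
            continue
        if segments and variants:
            raise ParseError("structure segment after flank annotations",
                             tok_offset)
        m = _RUN_RE.match(tok)
        if m:
            unit, count = m.group(1), int(m.group(2))
            if count < 2:
                raise ParseError(f"bracketed run with count {count}", tok_offset)
            segments.append(Segment(unit, count,
                                    counted=len(unit) == config.motif_len))
            i += 1
            continue
        m = _GAP_RE.match(tok)
        if m:
            segments.append(Segment("N", int(m.group(1)), counted=False,
                                    gap=True))
            i += 1
            continue
        if re.match(r"^[acgt]+$", tok):
            segments.append(Segment(tok.upper(), 1, counted=False, lower=True))
            i += 1
            continue
        if re.match(r"^[ACGT]+$", tok):
            segments.append(Segment(tok, 1,
                                    counted=len(tok) == config.motif_len))
            i += 1
            continue
        raise ParseError(f"unrecognized token {tok!r}", tok_offset)

    if not segments:
        raise ParseError("no structure segments found", 0)
    allele = SequenceAllele(locus, RepeatStructure(tuple(segments)),
                            tuple(variants))
    computed = ce_designation(allele, config)
    if computed != stated_ce:
        raise ParseError(
            f"stated CE {stated_ce} inconsistent with computed {computed}", 0)
    return allele
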