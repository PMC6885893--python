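"""Transcript exon models and variant-to-exon assignment.

Exon coordinates are held 0-based half-open in genomic order (the refFlat /
BED convention); the single conversion to the 1-based inclusive junction
coordinates used by the count files happens here, when junction keys are
built.  For an internal exon N three junctions matter:

* ``junction_prev`` — exon N−1 → N (inclusion, "count B"),
* ``junction_next`` — exon N → N+1 (inclusion, "count C"),
* ``junction_skip`` — exon N−1 → N+1 (the exon-skipping gap, "count A").

Only variants in internal exons of autosomes, excluding splice-site calls,
are analyzable: the exon-exclusion-rate statistic needs both flanking
inclusion junctions, and sex-chromosome read counts are not comparable
between male and female samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .io import AUTOSOMES, JunctionKey, ParseError, SomaticVariant, normalize_chrom

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TranscriptModel:
    gene_symbol: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, genomic order

    def __post_init__(self):
        prev_end = -1
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"transcript {self.transcript_id}: empty exon [{start},{end})")
            if start < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons unsorted or overlapping at {start}"
                )
            prev_end = end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def junction(self, upstream_index: int, downstream_index: int) -> JunctionKey:
        """1-based junction key spanning from exon ``upstream_index`` to ``downstream_index``."""
        donor = self.exons[upstream_index][1]  # half-open end == 1-based last base
        acceptor = self.exons[downstream_index][0] + 1
        return JunctionKey(self.chrom, donor, acceptor, self.strand)


@dataclass(frozen=True)
class ExonAssignment:
    """A variant placed on one exon of one transcript."""

    variant: SomaticVariant
    transcript: TranscriptModel
    exon_index: int
    is_internal: bool
    exon_length: int
    junction_prev: JunctionKey | None
    junction_next: JunctionKey | None
    junction_skip: JunctionKey | None


def _parse_refflat_row(fields, path, lineno) -> TranscriptModel:
    if len(fields) < 11:
        raise ParseError(path, lineno, f"refFlat row has {len(fields)} fields, expected 11")
    gene, tx, chrom, strand = fields[0], fields[1], fields[2], fields[3]
    exon_count = int(fields[8])
    starts = [int(x) for x in fields[9].rstrip(",").split(",") if x]
    ends = [int(x) for x in fields[10].rstrip(",").split(",") if x]
    if len(starts) != exon_count or len(ends) != exon_count:
        raise ParseError(path, lineno, f"transcript {tx}: exonCount {exon_count} does not match lists")
    return TranscriptModel(gene, tx, normalize_chrom(chrom), strand, tuple(zip(starts, ends)))


def _parse_bed12_row(fields, path, lineno) -> TranscriptModel:
    if len(fields) < 12:
        raise ParseError(path, lineno, f"BED12 row has {len(fields)} fields, expected 12")
    chrom, start, name, strand = fields[0], int(fields[1]), fields[3], fields[5]
    block_count = int(fields[9])
    sizes = [int(x) for x in fields[10].rstrip(",").split(",") if x]
    offsets = [int(x) for x in fields[11].rstrip(",").split(",") if x]
    if len(sizes) != block_count or len(offsets) != block_count:
        raise ParseError(path, lineno, f"transcript {name}: blockCount {block_count} mismatch")
    exons = tuple((start + off, start + off + size) for off, size in zip(offsets, sizes))
    return TranscriptModel(name, name, normalize_chrom(chrom), strand, exons)


def read_gene_model(path, fmt: str = "auto") -> list[TranscriptModel]:
    """Read a refFlat (11-column) or BED12 gene model into transcript records."""
    path = Path(path)
    models: list[TranscriptModel] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            row_fmt = fmt
            if fmt == "auto":
                # BED12 has an integer in column 2 (chromStart); refFlat has
                # the chromosome name there.
                row_fmt = "bed12" if len(fields) >= 12 and fields[1].isdigit() else "refflat"
            try:
                if row_fmt == "refflat":
                    models.append(_parse_refflat_row(fields, path, lineno))
                elif row_fmt == "bed12":
                    models.append(_parse_bed12_row(fields, path, lineno))
                else:
                    raise ParseError(path, lineno, f"unknown gene model format {fmt!r}")
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return models


def build_junction_index(models) -> dict[JunctionKey, list[tuple[TranscriptModel, int]]]:
    """Map every adjacent-exon junction to its (transcript, upstream exon index) pairs.

    Junctions shared between transcripts accumulate entries under one key.
    """
    index: dict[JunctionKey, list[tuple[TranscriptModel, int]]] = {}
    for model in models:
        for i in range(model.n_exons - 1):
            index.setdefault(model.junction(i, i + 1), []).append((model, i))
    return index


def _make_assignment(variant: SomaticVariant, model: TranscriptModel, exon_index: int) -> ExonAssignment:
    start, end = model.exons[exon_index]
    is_internal = 0 < exon_index < model.n_exons - 1
    return ExonAssignment(
        variant=variant,
        transcript=model,
        exon_index=exon_index,
        is_internal=is_internal,
        exon_length=end - start,
        junction_prev=model.junction(exon_index - 1, exon_index) if exon_index > 0 else None,
        junction_next=(
            model.junction(exon_index, exon_index + 1)
            if exon_index < model.n_exons - 1
            else None
        ),
        junction_skip=(
            model.junction(exon_index - 1, exon_index + 1) if is_internal else None
        ),
    )


class VariantAssigner:
    """Index of transcript models supporting repeated variant-to-exon lookups.

    When a position falls in exons of several transcripts the transcript
    with the most exons wins, ties broken by lexicographic transcript id —
    a deterministic stand-in for an expression-aware choice.
    """

    def __init__(self, models):
        self._by_chrom: dict[str, list[TranscriptModel]] = {}
        for m in models:
            self._by_chrom.setdefault(m.chrom, []).append(m)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda m: (m.exons[0][0], m.transcript_id))

    def assign_all(self, variant: SomaticVariant) -> list[ExonAssignment]:
        """All (transcript, exon) assignments containing the variant start."""
        pos0 = variant.start_pos - 1  # 0-based
        out = []
        for model in self._by_chrom.get(variant.chrom, ()):
            if pos0 < model.exons[0][0] or pos0 >= model.exons[-1][1]:
                continue
            for i, (start, end) in enumerate(model.exons):
                if start <= pos0 < end:
                    out.append(_make_assignment(variant, model, i))
                    break
        return out

    def assign(self, variant: SomaticVariant) -> ExonAssignment | None:
        candidates = self.assign_all(variant)
        if not candidates:
            return None
        candidates.sort(key=lambda a: (-a.transcript.n_exons, a.transcript.transcript_id))
        return candidates[0]


def assign_variant_to_exon(variant: SomaticVariant, models) -> ExonAssignment | None:
    """One-shot wrapper around :class:`VariantAssigner` for a single variant."""
    return VariantAssigner(models).assign(variant)


def is_analyzable(assignment: ExonAssignment | None, variant: SomaticVariant) -> bool:
    """Whether the EER statistic is defined and comparable for this variant.

    Requires an autosomal locus (sex-chromosome read depths are confounded
    by sample sex), a non-splice-site classification (intronic splice-site
    calls regulate splicing trivially), an internal exon (both flanking
    inclusion junctions must exist), and a variant fully contained in the
    exon.
    """
    if assignment is None:
        return False
    if variant.chrom not in AUTOSOMES:
        return False
    if variant.variant_classification == "Splice_Site":
        return False
    if not assignment.is_internal:
        return False
    exon_start, exon_end = assignment.transcript.exons[assignment.exon_index]
    if variant.end_pos > exon_end:  # 1-based inclusive end vs half-open exon end
        logger.warning(
            "variant %s:%d-%d spans beyond exon %d of %s; dropped",
            variant.chrom, variant.start_pos, variant.end_pos,
            assignment.exon_index, assignment.transcript.transcript_id,
        )
        return False
    return True


def normalized_exon_position(variant: SomaticVariant, assignment: ExonAssignment) -> float:
    """Distance from the exon's 5' end, as a fraction of exon length.

    Strand-aware: 0 is the 5' end of the exon in transcript orientation,
    1 the 3' end.
    """
    start, end = assignment.transcript.exons[assignment.exon_index]
    length = end - start
    if assignment.transcript.strand == "-":
        return (end - variant.start_pos) / length
    return (variant.start_pos - (start + 1)) / length


def exon_in_frame(assignment: ExonAssignment) -> bool:
    """Whether skipping this exon preserves the reading frame (length % 3 == 0)."""
    return assignment.exon_length % 3 == 0
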