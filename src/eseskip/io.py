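"""Readers and writers for the file dialects the pipeline touches.

Three per-sample input dialects are supported, mirroring the TCGA Legacy
Archive layouts: splice-junction quantification tables (junction string +
raw read count), MAF-style somatic variant tables, and RSEM normalized
gene-expression tables.  A small manifest TSV ties sample ids to file paths
and projects, because none of the per-sample files carry a sample id
internally.

Coordinate conventions: all file coordinates are 1-based inclusive on
ingestion.  A junction key stores the 1-based last base of the upstream
(donor) exon and the 1-based first base of the downstream (acceptor) exon.
Chromosome names are normalized to the ``chr``-prefixed form at parse time
so junction files, MAFs and gene models compare on a single naming scheme.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

AUTOSOMES = frozenset(f"chr{i}" for i in range(1, 23))

#: MAF v2.4 controlled vocabulary for Variant_Classification.
MAF_CLASSIFICATIONS = frozenset(
    {
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Silent",
        "Splice_Site",
        "Translation_Start_Site",
        "Nonstop_Mutation",
        "3'UTR",
        "3'Flank",
        "5'UTR",
        "5'Flank",
        "IGR",
        "Intron",
        "RNA",
        "Targeted_Region",
    }
)


class ParseError(ValueError):
    """Malformed record in an input file; carries path and line number."""

    def __init__(self, path, line_number: int | None, message: str):
        self.path = str(path)
        self.line_number = line_number
        where = f"{path}" if line_number is None else f"{path}:{line_number}"
        super().__init__(f"{where}: {message}")


def normalize_chrom(name: str) -> str:
    """Return ``name`` in the ``chr``-prefixed convention (``X`` -> ``chrX``)."""
    name = name.strip()
    if name.lower().startswith("chr"):
        return "chr" + name[3:]
    return "chr" + name


@dataclass(frozen=True)
class JunctionKey:
    """A paired genomic coordinate: the gap an exon-exon junction read spans.

    ``donor_pos`` is the 1-based last base of the upstream exon,
    ``acceptor_pos`` the 1-based first base of the downstream exon.  Strand
    is carried for provenance but excluded from identity, so junctions from
    strand-less dialects still match the gene model.
    """

    chrom: str
    donor_pos: int
    acceptor_pos: int
    strand: str = field(default="?", compare=False)

    def __post_init__(self):
        if self.donor_pos >= self.acceptor_pos:
            raise ValueError(
                f"junction donor_pos {self.donor_pos} must precede "
                f"acceptor_pos {self.acceptor_pos} on the forward axis"
            )


@dataclass
class SampleJunctionProfile:
    """One sample's junction -> read-count map with normalization state."""

    sample_id: str
    project_id: str
    counts: dict[JunctionKey, int]
    total_count: int = 0
    normalized: dict[JunctionKey, float] = field(default_factory=dict)

    def recompute_total(self) -> int:
        self.total_count = int(sum(self.counts.values()))
        return self.total_count


@dataclass(frozen=True)
class SomaticVariant:
    """One somatic variant call parsed from a MAF row."""

    sample_id: str
    gene_symbol: str
    chrom: str
    start_pos: int
    end_pos: int
    ref_allele: str
    alt_allele: str
    variant_classification: str
    variant_type: str = "SNP"
    classification_is_standard: bool = True

    def __post_init__(self):
        if self.start_pos > self.end_pos:
            raise ValueError(
                f"variant start {self.start_pos} > end {self.end_pos}"
            )


@dataclass
class GeneExpressionTable:
    """Per-sample normalized gene expression (RSEM-style)."""

    sample_id: str
    project_id: str
    values: dict[str, float]


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    project_id: str
    junction_path: str
    maf_path: str
    rsem_path: str


def _parse_junction_string(text: str, dialect: str):
    """Parse a junction column value into (chrom, donor, acceptor, strand).

    ``legacy``: ``chrom:pos:strand,chrom:pos:strand`` (first member = donor
    side).  ``range``: ``chrom:start-end`` fallback for strand-less
    fixtures.  ``auto`` accepts either.
    """
    text = text.strip()
    if dialect in ("legacy", "auto") and "," in text:
        left, right = text.split(",", 1)
        lparts, rparts = left.split(":"), right.split(":")
        if len(lparts) != 3 or len(rparts) != 3:
            raise ValueError(f"junction string {text!r} is not chrom:pos:strand,chrom:pos:strand")
        lchrom, rchrom = normalize_chrom(lparts[0]), normalize_chrom(rparts[0])
        if lchrom != rchrom:
            raise ValueError(f"junction {text!r} spans two chromosomes")
        if lparts[2] != rparts[2]:
            raise ValueError(f"junction {text!r} mixes strands")
        return lchrom, int(lparts[1]), int(rparts[1]), lparts[2]
    if dialect in ("range", "auto") and "-" in text.rsplit(":", 1)[-1]:
        chrom, span = text.rsplit(":", 1)
        start, end = span.split("-", 1)
        return normalize_chrom(chrom), int(start), int(end), "?"
    raise ValueError(f"unrecognized junction string {text!r} for dialect {dialect!r}")


def read_junction_quantification(
    path, sample_id: str, project_id: str, dialect: str = "auto"
) -> SampleJunctionProfile:
    """Parse a junction_quantification.txt-style table into a profile.

    The header row is required.  Every data row becomes one
    (JunctionKey, raw count) entry; duplicate junctions are an error since
    their counts would be ambiguous.  ``normalized`` is left empty — the
    EER stage populates it.
    """
    path = Path(path)
    counts: dict[JunctionKey, int] = {}
    with path.open() as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(path, 1, "missing header row")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields_ = line.rstrip("\n").split("\t")
            if len(fields_) < 2:
                raise ParseError(path, lineno, f"expected 2 columns, got {len(fields_)}")
            try:
                chrom, donor, acceptor, strand = _parse_junction_string(fields_[0], dialect)
                count = int(fields_[1])
                if donor >= acceptor:
                    raise ValueError(
                        f"donor position {donor} is not before acceptor {acceptor}"
                    )
                if count < 0:
                    raise ValueError(f"negative read count {count}")
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            key = JunctionKey(chrom, donor, acceptor, strand)
            if key in counts:
                raise ParseError(path, lineno, f"duplicate junction {fields_[0]!r}")
            counts[key] = count
    profile = SampleJunctionProfile(sample_id=sample_id, project_id=project_id, counts=counts)
    profile.recompute_total()
    return profile


_MAF_REQUIRED = (
    "hugo_symbol",
    "chromosome",
    "start_position",
    "reference_allele",
    "tumor_seq_allele2",
    "variant_classification",
    "variant_type",
    "tumor_sample_barcode",
)


def read_maf(path) -> list[SomaticVariant]:
    """Parse a MAF-style TSV into SomaticVariant records.

    Column headers are matched case-insensitively; comment lines (leading
    ``#``) are skipped.  The reader does not filter — splice-site rows and
    all classifications come through and are handled downstream.
    """
    path = Path(path)
    variants: list[SomaticVariant] = []
    with path.open() as fh:
        header = None
        header_line = 0
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            if header is None:
                header = [h.strip().lower() for h in line.rstrip("\n").split("\t")]
                header_line = lineno
                missing = [c for c in _MAF_REQUIRED if c not in header]
                if missing:
                    raise ParseError(path, header_line, f"missing MAF columns: {', '.join(missing)}")
                col = {name: header.index(name) for name in header}
                continue
            fields_ = line.rstrip("\n").split("\t")
            if len(fields_) < len(header):
                raise ParseError(
                    path, lineno, f"truncated row: {len(fields_)} fields, header has {len(header)}"
                )
            def get(name, default=""):
                idx = col.get(name)
                return fields_[idx] if idx is not None else default

            try:
                start = int(get("start_position"))
                end = int(get("end_position", "")) if "end_position" in col else start
                classification = get("variant_classification")
                variants.append(
                    SomaticVariant(
                        sample_id=get("tumor_sample_barcode"),
                        gene_symbol=get("hugo_symbol"),
                        chrom=normalize_chrom(get("chromosome")),
                        start_pos=start,
                        end_pos=end,
                        ref_allele=get("reference_allele"),
                        alt_allele=get("tumor_seq_allele2"),
                        variant_classification=classification,
                        variant_type=get("variant_type"),
                        classification_is_standard=classification in MAF_CLASSIFICATIONS,
                    )
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    if header is None:
        raise ParseError(path, None, "no header row found")
    for v in variants:
        if not v.classification_is_standard:
            logger.warning(
                "non-standard Variant_Classification %r kept verbatim (%s:%d)",
                v.variant_classification, v.chrom, v.start_pos,
            )
    return variants


def read_rsem_genes(path, sample_id: str, project_id: str) -> GeneExpressionTable:
    """Parse an rsem.genes.normalized.results-style TSV (gene_id, normalized_count)."""
    path = Path(path)
    values: dict[str, float] = {}
    with path.open() as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(path, 1, "missing header row")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields_ = line.rstrip("\n").split("\t")
            if len(fields_) < 2:
                raise ParseError(path, lineno, f"expected 2 columns, got {len(fields_)}")
            gene_id = fields_[0]
            try:
                value = float(fields_[1])
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            if gene_id in values:
                raise ParseError(path, lineno, f"duplicate gene id {gene_id!r}")
            if value < 0:
                raise ParseError(path, lineno, f"negative normalized count {value}")
            values[gene_id] = value
    return GeneExpressionTable(sample_id=sample_id, project_id=project_id, values=values)


def read_manifest(path) -> list[ManifestEntry]:
    """Parse the cohort manifest (sample_id, project_id, junction/MAF/RSEM paths).

    Relative paths are resolved against the manifest's own directory.
    """
    path = Path(path)
    entries: list[ManifestEntry] = []
    root = path.parent
    with path.open() as fh:
        header = [h.strip().lower() for h in fh.readline().rstrip("\n").split("\t")]
        required = ["sample_id", "project_id", "junction_path", "maf_membership", "rsem_path"]
        missing = [c for c in required if c not in header]
        if missing:
            raise ParseError(path, 1, f"missing manifest columns: {', '.join(missing)}")
        col = {name: header.index(name) for name in header}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields_ = line.rstrip("\n").split("\t")
            if len(fields_) < len(header):
                raise ParseError(path, lineno, "truncated manifest row")

            def resolve(p):
                p = p.strip()
                return str(root / p) if p and not Path(p).is_absolute() else p

            entries.append(
                ManifestEntry(
                    sample_id=fields_[col["sample_id"]],
                    project_id=fields_[col["project_id"]],
                    junction_path=resolve(fields_[col["junction_path"]]),
                    maf_path=resolve(fields_[col["maf_membership"]]),
                    rsem_path=resolve(fields_[col["rsem_path"]]),
                )
            )
    seen = set()
    for e in entries:
        if e.sample_id in seen:
            raise ParseError(path, None, f"duplicate sample_id {e.sample_id!r} in manifest")
        seen.add(e.sample_id)
    return entries


def _format_value(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "True" if value else "False"
    if isinstance(value, float):
        return repr(value)  # shortest round-trip, >= 6 significant digits
    return str(value)


def write_results_table(records: Sequence, path, columns: Sequence[str] | None = None) -> None:
    """Write homogeneous result records (dicts or dataclasses) as a TSV.

    Column order is the field order of the first record unless ``columns``
    is given; an empty record list still produces a header-only file when
    columns are supplied, or an empty file otherwise.  Floats are written
    with full round-trip precision; missing optional fields become empty
    strings.
    """
    rows: list[Mapping] = []
    for rec in records:
        if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
            rows.append(dataclasses.asdict(rec))
        elif isinstance(rec, Mapping):
            rows.append(rec)
        else:
            raise TypeError(f"unsupported record type {type(rec)!r}")
    if columns is None:
        if rows:
            columns = list(rows[0].keys())
        else:
            columns = []
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_format_value(row.get(c)) for c in columns) + "\n")


def _parse_cell(text: str):
    if text == "":
        return None
    if text == "True":
        return True
    if text == "False":
        return False
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text


def read_results_table(path) -> list[dict]:
    """Inverse of :func:`write_results_table` with typed cells.

    Cells are parsed as int, float, bool or string in that order; empty
    cells become None.  Round-trips are exact for the numeric result
    schemas this package writes.
    """
    path = Path(path)
    rows: list[dict] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header == [""]:
            return rows
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            rows.append({h: _parse_cell(c) for h, c in zip(header, cells)})
    return rows


def iter_profiles(entries: Iterable[ManifestEntry], dialect: str = "auto"):
    """Yield (entry, profile) for every manifest entry with a junction file."""
    for entry in entries:
        yield entry, read_junction_quantification(
            entry.junction_path, entry.sample_id, entry.project_id, dialect=dialect
        )
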