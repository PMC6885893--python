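"""Discovery pipeline: candidates → control cohorts → KDE validation → calls.

The workflow per project:

1. normalize every sample's junction profile to counts per million;
2. assign each somatic variant to a transcript exon and keep the
   analyzable ones (autosome, internal exon, not a splice-site call);
3. compute the exon exclusion rate from the carrier's A/B/C counts and
   apply the permissive candidate window;
4. for each candidate, collect control samples — same project, usable
   profile, no somatic variant of any classification inside the exon —
   fit a KDE to their normalized skip-junction counts, and call the
   variant ESE-disrupting when the carrier's count A lands in the upper
   tail (p < alpha).

Controls and KDE distributions never cross project boundaries; library
size and splicing background differ too much between cancer types for
skip-count distributions to pool.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

from . import eer as eer_mod
from .eer import EerRecord, make_eer_record, normalize_profile
from .gene_model import (
    ExonAssignment,
    TranscriptModel,
    VariantAssigner,
    is_analyzable,
    read_gene_model,
)
from .io import (
    GeneExpressionTable,
    SampleJunctionProfile,
    SomaticVariant,
    read_manifest,
    read_maf,
    read_junction_quantification,
    read_rsem_genes,
    write_results_table,
)
from .kde import fit_kde, upper_tail_probability

logger = logging.getLogger(__name__)

MIN_CONTROLS_DEFAULT = 20


@dataclass
class CohortData:
    """Everything detection needs, resident in memory.

    ``profiles`` are normalized at load time; samples with a zero junction
    total are excluded (with a warning) and never act as carriers or
    controls.  ``variants`` keeps raw MAF rows deduplicated on
    (sample, chrom, position).
    """

    profiles: dict[str, SampleJunctionProfile]
    sample_project: dict[str, str]
    variants: list[SomaticVariant]
    models: list[TranscriptModel]
    assigner: VariantAssigner
    expression: dict[str, GeneExpressionTable] = field(default_factory=dict)
    n_variants_raw: int = 0
    cohort_id: str = ""
    _pos_index: dict = field(default=None, repr=False)

    @property
    def projects(self) -> list[str]:
        return sorted(set(self.sample_project.values()))

    def samples_in_project(self, project_id: str) -> list[str]:
        return sorted(
            s for s, p in self.sample_project.items() if p == project_id and s in self.profiles
        )

    def variant_position_index(self):
        """Per (project, chrom): sorted positions with their sample ids."""
        if self._pos_index is None:
            idx: dict[tuple[str, str], tuple[list[int], list[str]]] = {}
            buckets: dict[tuple[str, str], list[tuple[int, str]]] = {}
            for v in self.variants:
                project = self.sample_project.get(v.sample_id)
                if project is None:
                    continue
                buckets.setdefault((project, v.chrom), []).append((v.start_pos, v.sample_id))
            for key, pairs in buckets.items():
                pairs.sort()
                idx[key] = ([p for p, _ in pairs], [s for _, s in pairs])
            self._pos_index = idx
        return self._pos_index

    def carriers_in_interval(self, project_id: str, chrom: str, start_1b: int, end_1b: int):
        """Sample ids with any variant whose start lies in [start_1b, end_1b]."""
        idx = self.variant_position_index()
        entry = idx.get((project_id, chrom))
        if entry is None:
            return set()
        positions, samples = entry
        lo = bisect.bisect_left(positions, start_1b)
        hi = bisect.bisect_right(positions, end_1b)
        return set(samples[lo:hi])


def _dedupe_variants(variants) -> list[SomaticVariant]:
    seen = set()
    out = []
    for v in variants:
        key = (v.sample_id, v.chrom, v.start_pos)
        if key in seen:
            continue
        seen.add(key)
        out.append(v)
    return out


def load_cohort(
    manifest_path,
    gene_model_path,
    load_expression: bool = True,
    dialect: str = "auto",
    projects=None,
) -> CohortData:
    """Read manifest, gene model, junction profiles, MAFs and RSEM tables.

    Junction profiles are normalized here; zero-total samples are dropped
    with a warning.  MAF files shared between manifest rows are read once;
    only variants whose Tumor_Sample_Barcode appears in the manifest are
    kept.
    """
    entries = read_manifest(manifest_path)
    if projects:
        wanted = set(projects)
        entries = [e for e in entries if e.project_id in wanted]
    models = read_gene_model(gene_model_path)
    profiles: dict[str, SampleJunctionProfile] = {}
    sample_project: dict[str, str] = {}
    expression: dict[str, GeneExpressionTable] = {}
    maf_cache: dict[str, list[SomaticVariant]] = {}
    for entry in entries:
        sample_project[entry.sample_id] = entry.project_id
        profile = read_junction_quantification(
            entry.junction_path, entry.sample_id, entry.project_id, dialect=dialect
        )
        try:
            profiles[entry.sample_id] = normalize_profile(profile)
        except ValueError:
            logger.warning("sample %s excluded: zero junction total", entry.sample_id)
        if entry.maf_path and entry.maf_path not in maf_cache:
            maf_cache[entry.maf_path] = read_maf(entry.maf_path)
        if load_expression and entry.rsem_path:
            expression[entry.sample_id] = read_rsem_genes(
                entry.rsem_path, entry.sample_id, entry.project_id
            )
    known_samples = set(sample_project)
    raw = [v for maf in maf_cache.values() for v in maf if v.sample_id in known_samples]
    variants = _dedupe_variants(raw)
    return CohortData(
        profiles=profiles,
        sample_project=sample_project,
        variants=variants,
        models=models,
        assigner=VariantAssigner(models),
        expression=expression,
        n_variants_raw=len(raw),
        cohort_id=str(manifest_path),
    )


@dataclass
class ValidationResult:
    """KDE validation outcome for one candidate ESE-disrupting variant."""

    eer_record: EerRecord
    project_id: str
    control_sample_ids: tuple[str, ...]
    n_controls: int
    upper_tail_p: float | None  # None = unvalidatable (too few controls)
    is_ese_disrupting: bool


def find_controls(assignment: ExonAssignment, cohort: CohortData, project_id: str) -> list[str]:
    """Samples in the project with a usable profile and no variant in the exon.

    "No variant" means no somatic variant of any classification whose start
    position falls inside the exon's genomic interval — carriers of any
    lesion in the exon could skip it for reasons other than background.
    """
    start0, end0 = assignment.transcript.exons[assignment.exon_index]
    carriers = cohort.carriers_in_interval(
        project_id, assignment.transcript.chrom, start0 + 1, end0
    )
    return [s for s in cohort.samples_in_project(project_id) if s not in carriers]


def validate_candidate(
    eer_record: EerRecord,
    cohort: CohortData,
    alpha: float = 0.05,
    min_controls: int = MIN_CONTROLS_DEFAULT,
    renormalize: bool = True,
) -> ValidationResult:
    """Fit the control KDE for the skip junction and test the carrier's count A.

    The tail probability is renormalized to the non-negative support by
    default: skip-count control sets routinely contain an atom at zero, and
    without renormalization the kernel mass leaking below zero (half of
    each zero-valued kernel) puts a hard floor under every upper-tail p —
    a carrier arbitrarily far above all controls could then never reach
    p < alpha.  Pass ``renormalize=False`` for the raw truncated integral.
    """
    if not eer_record.is_candidate:
        raise ValueError("validate_candidate expects a candidate EER record")
    variant = eer_record.variant
    project_id = cohort.sample_project[variant.sample_id]
    controls = find_controls(eer_record.assignment, cohort, project_id)
    skip_key = eer_record.assignment.junction_skip
    if len(controls) < min_controls:
        return ValidationResult(
            eer_record, project_id, tuple(controls), len(controls), None, False
        )
    values = [cohort.profiles[s].normalized.get(skip_key, 0.0) for s in controls]
    kde = fit_kde(values)
    p = upper_tail_probability(kde, eer_record.count_a, renormalize=renormalize)
    return ValidationResult(
        eer_record, project_id, tuple(controls), len(controls), p, p < alpha
    )


@dataclass
class DetectionSummary:
    """Fig-1-style funnel counts plus per-project call totals."""

    n_variants_raw: int
    n_variants_unique: int
    n_assigned: int
    n_analyzable: int
    n_candidates: int
    n_validatable: int
    n_called: int
    per_project: list[dict]


@dataclass
class DetectionOutput:
    results: list[ValidationResult]
    summary: DetectionSummary
    cohort_id: str = ""

    @property
    def calls(self) -> list[ValidationResult]:
        return [r for r in self.results if r.is_ese_disrupting]

    def called_keys(self) -> set:
        return {
            (r.eer_record.variant.sample_id, r.eer_record.variant.chrom,
             r.eer_record.variant.start_pos)
            for r in self.calls
        }


def run_detection(
    cohort: CohortData,
    alpha: float = 0.05,
    eer_min: float = eer_mod.EER_MIN_DEFAULT,
    eer_max: float = eer_mod.EER_MAX_DEFAULT,
    min_controls: int = MIN_CONTROLS_DEFAULT,
    projects=None,
    renormalize: bool = True,
) -> DetectionOutput:
    """Run the full pipeline over every analyzable variant in the cohort.

    Returns one ValidationResult per analyzable variant (non-candidates
    carry no p-value), sorted deterministically, plus funnel counts.
    """
    wanted = set(projects) if projects else None
    n_assigned = n_analyzable = n_candidates = n_validatable = 0
    results: list[ValidationResult] = []
    per_project_counts: dict[str, dict] = {}
    variants = sorted(
        _dedupe_variants(cohort.variants),
        key=lambda v: (cohort.sample_project.get(v.sample_id, ""), v.sample_id, v.chrom,
                       v.start_pos),
    )
    for variant in variants:
        project_id = cohort.sample_project.get(variant.sample_id)
        if project_id is None or (wanted and project_id not in wanted):
            continue
        stats = per_project_counts.setdefault(
            project_id, {"n_variants": 0, "n_analyzable": 0, "n_called": 0}
        )
        stats["n_variants"] += 1
        if variant.sample_id not in cohort.profiles:
            continue
        assignment = cohort.assigner.assign(variant)
        if assignment is None:
            continue
        n_assigned += 1
        if not is_analyzable(assignment, variant):
            continue
        n_analyzable += 1
        stats["n_analyzable"] += 1
        record = make_eer_record(
            cohort.profiles[variant.sample_id], assignment, eer_min, eer_max
        )
        if not record.is_candidate:
            results.append(
                ValidationResult(record, project_id, (), 0, None, False)
            )
            continue
        n_candidates += 1
        vr = validate_candidate(
            record, cohort, alpha=alpha, min_controls=min_controls, renormalize=renormalize
        )
        if vr.upper_tail_p is not None:
            n_validatable += 1
        if vr.is_ese_disrupting:
            stats["n_called"] += 1
        results.append(vr)
    per_project = []
    for project_id in sorted(per_project_counts):
        stats = per_project_counts[project_id]
        n_v, n_a, n_c = stats["n_variants"], stats["n_analyzable"], stats["n_called"]
        per_project.append(
            {
                "project_id": project_id,
                "n_samples": len(cohort.samples_in_project(project_id)),
                "n_variants": n_v,
                "n_analyzable": n_a,
                "n_called": n_c,
                "pct_called_of_variants": 100.0 * n_c / n_v if n_v else 0.0,
                "pct_called_of_analyzable": 100.0 * n_c / n_a if n_a else 0.0,
            }
        )
    n_called = sum(p["n_called"] for p in per_project)
    summary = DetectionSummary(
        n_variants_raw=cohort.n_variants_raw,
        n_variants_unique=len(variants),
        n_assigned=n_assigned,
        n_analyzable=n_analyzable,
        n_candidates=n_candidates,
        n_validatable=n_validatable,
        n_called=n_called,
        per_project=per_project,
    )
    logger.info(
        "detection funnel: %d raw -> %d unique -> %d assigned -> %d analyzable -> "
        "%d candidates -> %d validatable -> %d called",
        summary.n_variants_raw, summary.n_variants_unique, n_assigned, n_analyzable,
        n_candidates, n_validatable, n_called,
    )
    return DetectionOutput(results=results, summary=summary, cohort_id=cohort.cohort_id)


CALLS_COLUMNS = [
    "sample_id", "project_id", "gene_symbol", "transcript_id", "chrom", "start_pos",
    "end_pos", "ref_allele", "alt_allele", "variant_classification", "exon_index",
    "count_a", "count_b", "count_c", "eer_minus", "eer_plus", "is_candidate",
    "n_controls", "upper_tail_p", "is_ese_disrupting",
]


def result_rows(output: DetectionOutput) -> list[dict]:
    rows = []
    for r in output.results:
        v = r.eer_record.variant
        rows.append(
            {
                "sample_id": v.sample_id,
                "project_id": r.project_id,
                "gene_symbol": v.gene_symbol,
                "transcript_id": r.eer_record.assignment.transcript.transcript_id,
                "chrom": v.chrom,
                "start_pos": v.start_pos,
                "end_pos": v.end_pos,
                "ref_allele": v.ref_allele,
                "alt_allele": v.alt_allele,
                "variant_classification": v.variant_classification,
                "exon_index": r.eer_record.assignment.exon_index,
                "count_a": r.eer_record.count_a,
                "count_b": r.eer_record.count_b,
                "count_c": r.eer_record.count_c,
                "eer_minus": r.eer_record.eer_minus,
                "eer_plus": r.eer_record.eer_plus,
                "is_candidate": r.eer_record.is_candidate,
                "n_controls": r.n_controls,
                "upper_tail_p": r.upper_tail_p,
                "is_ese_disrupting": r.is_ese_disrupting,
            }
        )
    return rows


def write_calls_table(output: DetectionOutput, path) -> None:
    """Write the per-variant results TSV (candidates and calls flagged)."""
    write_results_table(result_rows(output), path, columns=CALLS_COLUMNS)
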