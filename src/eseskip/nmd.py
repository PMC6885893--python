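"""Nonsense-mediated decay (NMD) escape analysis for nonsense variants.

A premature termination codon normally triggers NMD, degrading the
transcript and lowering the gene's expression in that sample.  When the
nonsense variant also disrupts an exonic splicing enhancer, the exon
containing the premature stop is skipped, the stop codon disappears from
the mature transcript, and the transcript escapes surveillance.

Nonsense variants are cross-classified on two axes:

* **ESE status** — whether the variant is in the detection call set
  (i.e. was identified as ESE-disrupting);
* **frame** — whether skipping the exon would preserve the reading frame
  (exon length divisible by 3).  For non-ESE variants the skip never
  happens, but the same exon-length rule fills the four-way table.

The expression consequence is scored as a KDE lower-tail probability: the
carrier's normalized expression against the distribution of the same gene
in same-project samples carrying no nonsense variant in that gene.  Values
near 0 mean the carrier expresses the gene far below controls (NMD
degradation); values above 0.5 mean equal or higher expression (escape,
with skipped transcripts accumulating).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import median

from .detection import CohortData
from .gene_model import ExonAssignment, exon_in_frame
from .io import SomaticVariant, write_results_table
from .kde import fit_kde, lower_tail_probability

logger = logging.getLogger(__name__)

GROUP_OOF_NON_ESE = "out-of-frame/non-ESE"
GROUP_IF_NON_ESE = "in-frame/non-ESE"
GROUP_OOF_ESE = "out-of-frame/ESE"
GROUP_IF_ESE = "in-frame/ESE"
GROUPS = (GROUP_OOF_NON_ESE, GROUP_IF_NON_ESE, GROUP_OOF_ESE, GROUP_IF_ESE)

MIN_EXPRESSION_CONTROLS_DEFAULT = 20


@dataclass
class NonsenseRecord:
    variant: SomaticVariant
    gene_id: str
    in_ese: bool
    in_frame: bool
    group: str
    lower_tail_p: float | None  # None = unvalidatable (too few controls)


def classify_nonsense(
    variant: SomaticVariant, assignment: ExonAssignment, call_set: set
) -> str:
    """Assign one of the four ESE × frame groups to a nonsense variant."""
    if variant.variant_classification != "Nonsense_Mutation":
        raise ValueError("classify_nonsense requires a Nonsense_Mutation variant")
    in_ese = (variant.sample_id, variant.chrom, variant.start_pos) in call_set
    in_frame = exon_in_frame(assignment)
    if in_ese:
        return GROUP_IF_ESE if in_frame else GROUP_OOF_ESE
    return GROUP_IF_NON_ESE if in_frame else GROUP_OOF_NON_ESE


def _nonsense_carriers_by_gene(cohort: CohortData) -> dict[tuple[str, str], set[str]]:
    """(project, gene) -> samples carrying a nonsense variant in that gene."""
    carriers: dict[tuple[str, str], set[str]] = {}
    for v in cohort.variants:
        if v.variant_classification != "Nonsense_Mutation":
            continue
        project = cohort.sample_project.get(v.sample_id)
        if project is None:
            continue
        carriers.setdefault((project, v.gene_symbol), set()).add(v.sample_id)
    return carriers


def expression_lower_tail(
    variant: SomaticVariant,
    cohort: CohortData,
    carriers_by_gene: dict | None = None,
    min_controls: int = MIN_EXPRESSION_CONTROLS_DEFAULT,
) -> float | None:
    """Lower-tail probability of the carrier's expression vs nonsense-free controls.

    Controls are expression values of the variant's gene across samples of
    the same project that carry no nonsense variant in that gene.  Returns
    None when fewer than ``min_controls`` controls have expression data.
    """
    if carriers_by_gene is None:
        carriers_by_gene = _nonsense_carriers_by_gene(cohort)
    project = cohort.sample_project.get(variant.sample_id)
    carrier_table = cohort.expression.get(variant.sample_id)
    if project is None or carrier_table is None:
        return None
    gene = variant.gene_symbol
    if gene not in carrier_table.values:
        return None
    excluded = carriers_by_gene.get((project, gene), set())
    controls = [
        table.values[gene]
        for sample, table in sorted(cohort.expression.items())
        if cohort.sample_project.get(sample) == project
        and sample not in excluded
        and gene in table.values
    ]
    if len(controls) < min_controls:
        return None
    kde = fit_kde(controls)
    return lower_tail_probability(kde, carrier_table.values[gene])


def run_nmd_analysis(
    cohort: CohortData,
    call_set: set,
    min_controls: int = MIN_EXPRESSION_CONTROLS_DEFAULT,
) -> list[NonsenseRecord]:
    """Classify every assignable nonsense variant and score its expression tail."""
    carriers_by_gene = _nonsense_carriers_by_gene(cohort)
    records: list[NonsenseRecord] = []
    variants = sorted(
        (v for v in cohort.variants if v.variant_classification == "Nonsense_Mutation"),
        key=lambda v: (v.sample_id, v.chrom, v.start_pos),
    )
    for variant in variants:
        assignment = cohort.assigner.assign(variant)
        if assignment is None:
            continue
        group = classify_nonsense(variant, assignment, call_set)
        p = expression_lower_tail(variant, cohort, carriers_by_gene, min_controls)
        records.append(
            NonsenseRecord(
                variant=variant,
                gene_id=variant.gene_symbol,
                in_ese=group in (GROUP_OOF_ESE, GROUP_IF_ESE),
                in_frame=group in (GROUP_IF_NON_ESE, GROUP_IF_ESE),
                group=group,
                lower_tail_p=p,
            )
        )
    return records


def summarize_nmd(records) -> dict[str, dict]:
    """Per-group counts and median lower-tail probability.

    Groups with no validatable record are absent from the summary rather
    than reported as zero.
    """
    summary: dict[str, dict] = {}
    for group in GROUPS:
        members = [r for r in records if r.group == group]
        scored = [r.lower_tail_p for r in members if r.lower_tail_p is not None]
        if not members:
            continue
        summary[group] = {
            "n": len(members),
            "n_scored": len(scored),
            "median_lower_tail_p": median(scored) if scored else None,
        }
    return summary


def write_nmd_tables(records, out_records_path, out_summary_path) -> None:
    rows = [
        {
            "sample_id": r.variant.sample_id,
            "gene_id": r.gene_id,
            "chrom": r.variant.chrom,
            "start_pos": r.variant.start_pos,
            "in_ese": r.in_ese,
            "in_frame": r.in_frame,
            "group": r.group,
            "lower_tail_p": r.lower_tail_p,
        }
        for r in records
    ]
    write_results_table(
        rows,
        out_records_path,
        columns=["sample_id", "gene_id", "chrom", "start_pos", "in_ese", "in_frame",
                 "group", "lower_tail_p"],
    )
    summary = summarize_nmd(records)
    summary_rows = [
        {"group": g, **summary[g]} for g in GROUPS if g in summary
    ]
    write_results_table(
        summary_rows, out_summary_path,
        columns=["group", "n", "n_scored", "median_lower_tail_p"],
    )
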