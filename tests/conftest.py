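"""Shared builders for in-memory cohorts and toy gene models."""

from __future__ import annotations

import pytest

from eseskip.detection import CohortData
from eseskip.eer import normalize_profile
from eseskip.gene_model import TranscriptModel, VariantAssigner
from eseskip.io import (
    GeneExpressionTable,
    JunctionKey,
    SampleJunctionProfile,
    SomaticVariant,
)

THREE_EXONS = ((100, 200), (300, 400), (500, 600))


def make_transcript(
    gene="GENE1", tx="TX1", chrom="chr1", strand="+", exons=THREE_EXONS
) -> TranscriptModel:
    return TranscriptModel(gene, tx, chrom, strand, tuple(exons))


def make_variant(
    sample="S0",
    gene="GENE1",
    chrom="chr1",
    pos=350,
    classification="Missense_Mutation",
    ref="G",
    alt="A",
) -> SomaticVariant:
    return SomaticVariant(
        sample_id=sample,
        gene_symbol=gene,
        chrom=chrom,
        start_pos=pos,
        end_pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        variant_classification=classification,
    )


def build_cohort(
    models,
    sample_counts: dict[str, dict[JunctionKey, int]],
    variants,
    project="P1",
    expression: dict[str, dict[str, float]] | None = None,
) -> CohortData:
    """Assemble a normalized in-memory cohort from raw junction counts."""
    profiles = {}
    for sample, counts in sample_counts.items():
        profile = SampleJunctionProfile(sample, project, dict(counts))
        profile.recompute_total()
        profiles[sample] = normalize_profile(profile)
    expr = {}
    if expression:
        expr = {
            sample: GeneExpressionTable(sample, project, dict(values))
            for sample, values in expression.items()
        }
    return CohortData(
        profiles=profiles,
        sample_project={s: project for s in sample_counts},
        variants=list(variants),
        models=list(models),
        assigner=VariantAssigner(models),
        expression=expr,
        n_variants_raw=len(variants),
        cohort_id="in-memory",
    )


@pytest.fixture
def transcript():
    return make_transcript()
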