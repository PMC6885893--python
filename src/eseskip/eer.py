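"""The exon exclusion rate (EER) statistic and candidate filter.

For a variant in internal exon N, three junction read counts are taken
from the carrier sample after within-sample normalization:

* A — the skip junction, exon N−1 → N+1 (transcripts excluding exon N),
* B — the inclusion junction, exon N−1 → N,
* C — the inclusion junction, exon N → N+1.

EER(N−1) = A/B and EER(N+1) = A/C measure how many transcripts skip the
exon relative to those including it.  A heterozygous, fully clonal variant
in a pure tumor that abolishes exon inclusion on one allele gives EER ≈ 1;
tumor purity below 100% pulls the true value below 1.  The candidate
filter therefore keeps variants with both EER values in a deliberately
permissive window (0.5–2.0, inclusive), leaving error control to the
downstream KDE validation.

EER is a ratio of same-sample counts, so it is invariant to the
normalization scale; the counts-per-million scale matters only for the
cross-sample KDE step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .gene_model import ExonAssignment
from .io import SampleJunctionProfile, SomaticVariant

logger = logging.getLogger(__name__)

NORMALIZATION_SCALE = 1e6  # counts per million

EER_MIN_DEFAULT = 0.5
EER_MAX_DEFAULT = 2.0


@dataclass
class EerRecord:
    """Normalized A/B/C counts and both EER values for one variant-exon pair."""

    variant: SomaticVariant
    assignment: ExonAssignment
    count_a: float
    count_b: float
    count_c: float
    eer_minus: float | None  # EER(N−1) = A/B
    eer_plus: float | None  # EER(N+1) = A/C
    is_candidate: bool


def normalize_profile(profile: SampleJunctionProfile) -> SampleJunctionProfile:
    """Populate counts-per-million values: count / total aligned reads × 1e6.

    Raises on a zero total; the cohort loader catches this and excludes the
    sample as unusable.
    """
    if profile.total_count <= 0:
        raise ValueError(
            f"sample {profile.sample_id}: total junction count is 0, profile unusable"
        )
    scale = NORMALIZATION_SCALE / profile.total_count
    profile.normalized = {key: count * scale for key, count in profile.counts.items()}
    return profile


def extract_abc(profile: SampleJunctionProfile, assignment: ExonAssignment):
    """Normalized (A, B, C) for an internal-exon assignment.

    Junctions absent from the sample's file are zero counts — the legacy
    files enumerate a fixed junction universe, so absence means no reads.
    """
    if not assignment.is_internal:
        raise ValueError("extract_abc requires an internal exon (both flanking junctions)")
    if not profile.normalized:
        raise ValueError(f"sample {profile.sample_id}: profile not normalized")
    norm = profile.normalized
    return (
        norm.get(assignment.junction_skip, 0.0),
        norm.get(assignment.junction_prev, 0.0),
        norm.get(assignment.junction_next, 0.0),
    )


def compute_eer(count_a: float, count_b: float, count_c: float):
    """(EER(N−1), EER(N+1)) = (A/B, A/C); None where the denominator is 0."""
    eer_minus = count_a / count_b if count_b > 0 else None
    eer_plus = count_a / count_c if count_c > 0 else None
    return eer_minus, eer_plus


def is_candidate(
    eer_minus: float | None,
    eer_plus: float | None,
    eer_min: float = EER_MIN_DEFAULT,
    eer_max: float = EER_MAX_DEFAULT,
) -> bool:
    """True iff both EER values are defined and inside [eer_min, eer_max].

    Undefined values (zero-coverage flanking junction) never qualify.
    """
    if eer_minus is None or eer_plus is None:
        return False
    return eer_min <= eer_minus <= eer_max and eer_min <= eer_plus <= eer_max


def make_eer_record(
    profile: SampleJunctionProfile,
    assignment: ExonAssignment,
    eer_min: float = EER_MIN_DEFAULT,
    eer_max: float = EER_MAX_DEFAULT,
) -> EerRecord:
    """Assemble the full EER record for one variant-exon pair in one sample."""
    a, b, c = extract_abc(profile, assignment)
    eer_minus, eer_plus = compute_eer(a, b, c)
    return EerRecord(
        variant=assignment.variant,
        assignment=assignment,
        count_a=a,
        count_b=b,
        count_c=c,
        eer_minus=eer_minus,
        eer_plus=eer_plus,
        is_candidate=is_candidate(eer_minus, eer_plus, eer_min, eer_max),
    )
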