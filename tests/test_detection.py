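"""Detection orchestration: controls, validation, calls, determinism."""

import pytest

from eseskip.detection import (
    find_controls,
    result_rows,
    run_detection,
    validate_candidate,
    write_calls_table,
)
from eseskip.eer import make_eer_record
from eseskip.io import JunctionKey

from conftest import build_cohort, make_transcript, make_variant

SKIP = JunctionKey("chr1", 200, 501)
PREV = JunctionKey("chr1", 200, 301)
NEXT = JunctionKey("chr1", 400, 501)


def ten_sample_cohort(carrier_skip=80, extra_variants=(), n=10):
    """One gene, one carrier (S0) with a planted skip signal, n-1 controls."""
    model = make_transcript()
    counts = {}
    for i in range(n):
        sample = f"S{i}"
        counts[sample] = {PREV: 100, NEXT: 100, SKIP: carrier_skip if i == 0 else 0}
    variants = [make_variant(sample="S0", pos=350)] + list(extra_variants)
    return build_cohort([model], counts, variants)


class TestFindControls:
    def test_all_other_samples_are_controls(self):
        cohort = ten_sample_cohort()
        a = cohort.assigner.assign(cohort.variants[0])
        assert len(find_controls(a, cohort, "P1")) == 9

    def test_any_variant_in_exon_excludes_sample(self):
        other = make_variant(sample="S3", pos=399, classification="Splice_Site")
        cohort = ten_sample_cohort(extra_variants=[other])
        a = cohort.assigner.assign(cohort.variants[0])
        controls = find_controls(a, cohort, "P1")
        assert len(controls) == 8 and "S3" not in controls

    def test_variant_outside_exon_does_not_exclude(self):
        other = make_variant(sample="S3", pos=150)  # first exon, not exon 1
        cohort = ten_sample_cohort(extra_variants=[other])
        a = cohort.assigner.assign(cohort.variants[0])
        assert len(find_controls(a, cohort, "P1")) == 9

    def test_everyone_a_carrier_gives_no_controls(self):
        extras = [make_variant(sample=f"S{i}", pos=310 + i) for i in range(1, 10)]
        cohort = ten_sample_cohort(extra_variants=extras)
        a = cohort.assigner.assign(cohort.variants[0])
        assert find_controls(a, cohort, "P1") == []


class TestValidate:
    def test_strong_signal_called(self):
        cohort = ten_sample_cohort()
        a = cohort.assigner.assign(cohort.variants[0])
        record = make_eer_record(cohort.profiles["S0"], a)
        assert record.is_candidate
        vr = validate_candidate(record, cohort, min_controls=5)
        assert vr.upper_tail_p == pytest.approx(0.0, abs=1e-6)
        assert vr.is_ese_disrupting

    def test_too_few_controls_unvalidatable(self):
        cohort = ten_sample_cohort(n=6)
        a = cohort.assigner.assign(cohort.variants[0])
        record = make_eer_record(cohort.profiles["S0"], a)
        vr = validate_candidate(record, cohort, min_controls=20)
        assert vr.upper_tail_p is None and not vr.is_ese_disrupting

    def test_carrier_at_control_level_not_called(self):
        # controls all carry the same background skip as the carrier
        model = make_transcript()
        counts = {
            f"S{i}": {PREV: 100, NEXT: 100, SKIP: 80} for i in range(30)
        }
        cohort = build_cohort([model], counts, [make_variant(sample="S0", pos=350)])
        a = cohort.assigner.assign(cohort.variants[0])
        record = make_eer_record(cohort.profiles["S0"], a)
        vr = validate_candidate(record, cohort, min_controls=5)
        assert vr.upper_tail_p > 0.3
        assert not vr.is_ese_disrupting

    def test_non_candidate_rejected(self):
        cohort = ten_sample_cohort(carrier_skip=1)  # EER 0.01, outside window
        a = cohort.assigner.assign(cohort.variants[0])
        record = make_eer_record(cohort.profiles["S0"], a)
        with pytest.raises(ValueError):
            validate_candidate(record, cohort)


class TestRunDetection:
    def test_planted_positive_called_with_all_predicates(self):
        cohort = ten_sample_cohort()
        out = run_detection(cohort, min_controls=5)
        assert out.summary.n_called == 1
        call = out.calls[0]
        v = call.eer_record.variant
        assert v.chrom in {f"chr{i}" for i in range(1, 23)}
        assert v.variant_classification != "Splice_Site"
        assert call.eer_record.assignment.is_internal
        assert call.eer_record.is_candidate
        assert call.upper_tail_p < 0.05

    def test_sex_chromosome_variant_absent_from_results(self):
        model_x = make_transcript(gene="GX", tx="TXX", chrom="chrX")
        model_1 = make_transcript()
        counts = {
            f"S{i}": {PREV: 100, NEXT: 100, SKIP: 80 if i == 0 else 0} for i in range(10)
        }
        variants = [
            make_variant(sample="S0", pos=350),
            make_variant(sample="S0", gene="GX", chrom="chrX", pos=350),
        ]
        cohort = build_cohort([model_1, model_x], counts, variants)
        out = run_detection(cohort, min_controls=5)
        assert all(r.eer_record.variant.chrom != "chrX" for r in out.results)

    def test_duplicate_position_collapsed(self):
        dup = make_variant(sample="S0", pos=350, classification="Silent")
        cohort = ten_sample_cohort(extra_variants=[dup])
        out = run_detection(cohort, min_controls=5)
        assert out.summary.n_variants_unique == 1

    def test_alpha_monotonicity(self):
        cohort = ten_sample_cohort()
        loose = run_detection(cohort, alpha=0.05, min_controls=5).called_keys()
        strict = run_detection(cohort, alpha=0.001, min_controls=5).called_keys()
        assert strict <= loose

    def test_eer_window_monotonicity(self):
        cohort = ten_sample_cohort(carrier_skip=45)  # EER 0.45, below default window
        narrow = run_detection(cohort, min_controls=5)
        wide = run_detection(cohort, eer_min=0.25, min_controls=5)
        assert narrow.summary.n_candidates <= wide.summary.n_candidates

    def test_byte_identical_reruns(self, tmp_path):
        cohort = ten_sample_cohort()
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_calls_table(run_detection(cohort, min_controls=5), p1)
        write_calls_table(run_detection(cohort, min_controls=5), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_result_rows_expose_predicates(self):
        cohort = ten_sample_cohort()
        rows = result_rows(run_detection(cohort, min_controls=5))
        assert rows[0]["is_ese_disrupting"] is True
        assert rows[0]["eer_minus"] == pytest.approx(0.8)
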