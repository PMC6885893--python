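"""Hypergeometric enrichment, PWM scanning, variant summaries."""

import math

import numpy as np
import pytest

from eseskip.enrichment import (
    EnrichmentInput,
    Pwm,
    enrich_gene_sets,
    hypergeometric_pvalue,
    motif_disruption,
    read_gene_sets,
    read_pwm_config,
    scan_pwm,
    summarize_variants,
)


def enumeration_pvalue(N, K, n, k):
    """Exhaustive upper-tail P(X >= k) from binomial coefficients."""
    denom = math.comb(N, n)
    total = sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(n, K) + 1)
    )
    return total / denom


class TestHypergeometric:
    def test_small_worked_example(self):
        # N=10, K=5, n=4, k=4: only C(5,4)C(5,0) of C(10,4) draws qualify
        p = hypergeometric_pvalue(EnrichmentInput(10, 5, 4, 4))
        assert p == pytest.approx(5 / 210, rel=1e-12)

    def test_k_zero_gives_one(self):
        assert hypergeometric_pvalue(EnrichmentInput(50, 10, 5, 0)) == pytest.approx(1.0)

    def test_matches_enumeration_small_populations(self):
        for N in range(2, 9):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, n + K - N), min(n, K) + 1):
                        expected = enumeration_pvalue(N, K, n, k)
                        got = hypergeometric_pvalue(EnrichmentInput(N, K, n, k))
                        assert got == pytest.approx(expected, abs=1e-12), (N, K, n, k)

    def test_monotone_decreasing_in_k(self):
        ps = [
            hypergeometric_pvalue(EnrichmentInput(100, 40, 20, k)) for k in range(0, 21)
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_oncogenic_signature_sized_inputs(self):
        # 243 of 416 variant-bearing genes inside a 4551-gene signature set
        # drawn from an 8079-gene universe; exact upper tail, frozen from
        # scipy's hypergeometric survival function
        p = hypergeometric_pvalue(EnrichmentInput(8079, 4551, 416, 243))
        assert p == pytest.approx(0.2038878264, abs=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            EnrichmentInput(10, 11, 4, 2)
        with pytest.raises(ValueError):
            EnrichmentInput(10, 5, 4, 5)

    def test_enrich_gene_sets_table(self, tmp_path):
        sets_file = tmp_path / "sets.tsv"
        sets_file.write_text("setA\tG1\nsetA\tG2\nsetB\tG3\n")
        sets = read_gene_sets(sets_file)
        rows = enrich_gene_sets({"G1", "G2"}, {"G1", "G2", "G3", "G4"}, sets)
        by_id = {r["set_id"]: r for r in rows}
        assert by_id["setA"]["overlap"] == 2
        # P(both draws in the 2-gene set | 2 draws from 4) = 1/6
        assert by_id["setA"]["p_value"] == pytest.approx(1 / 6, rel=1e-9)


TOY = Pwm("toy", {"A": (1.0, 0.0), "C": (-1.0, 0.0), "G": (0.0, 1.0), "T": (0.0, -1.0)}, 1.5)


class TestScanPwm:
    def test_single_hit_with_score(self):
        assert scan_pwm("AG", TOY) == [(0, 2.0)]

    def test_no_hit(self):
        assert scan_pwm("CC", TOY) == []

    def test_ambiguous_base_window_skipped(self):
        hits = scan_pwm("ANGAG", TOY)
        assert hits == [(3, 2.0)]

    def test_score_additivity_against_naive_loop(self):
        rng = np.random.default_rng(0)
        matrix = {b: tuple(rng.normal(size=6)) for b in "ACGT"}
        pwm = Pwm("rand", matrix, threshold=-1e9)
        seq = "".join(rng.choice(list("ACGT"), 40))
        hits = dict(scan_pwm(seq, pwm))
        for offset in range(len(seq) - 5):
            naive = 0.0
            for i in range(6):
                naive += matrix[seq[offset + i]][i]
            assert hits[offset] == pytest.approx(naive)


class TestDisruption:
    def test_ref_hit_lost_in_alt_is_disrupted(self):
        #            variant at offset 1: AG -> AC kills the only hit
        status = motif_disruption("AG", "AC", 1, [TOY])
        assert status == {"toy": "disrupted"}

    def test_no_ref_hit_is_absent(self):
        assert motif_disruption("CC", "CG", 1, [TOY]) == {"toy": "absent"}

    def test_alt_only_hit_is_created(self):
        assert motif_disruption("AC", "AG", 1, [TOY]) == {"toy": "created"}

    def test_identical_windows_never_disrupted(self):
        for seq in ("AG", "CC", "TTAG"):
            status = motif_disruption(seq, seq, 1, [TOY])
            assert status["toy"] in ("retained", "absent")

    def test_or_group_union(self):
        # two matrices for one protein: a hit in either counts
        m1 = Pwm("p-a", {"A": (5.0,), "C": (0.0,), "G": (0.0,), "T": (0.0,)}, 4.0, "P")
        m2 = Pwm("p-b", {"A": (0.0,), "C": (5.0,), "G": (0.0,), "T": (0.0,)}, 4.0, "P")
        assert motif_disruption("A", "C", 0, [m1, m2]) == {"P": "retained"}
        assert motif_disruption("A", "G", 0, [m1, m2]) == {"P": "disrupted"}

    def test_window_shorter_than_pwm_skipped(self):
        long_pwm = Pwm("long", {b: (0.0,) * 10 for b in "ACGT"}, 0.0)
        assert motif_disruption("AG", "AC", 1, [long_pwm]) == {}

    def test_yaml_round_trip(self, tmp_path):
        cfg = tmp_path / "pwms.yaml"
        cfg.write_text(
            "- name: toy\n  threshold: 1.5\n  matrix:\n"
            "    A: [1.0, 0.0]\n    C: [-1.0, 0.0]\n    G: [0.0, 1.0]\n    T: [0.0, -1.0]\n"
        )
        pwms = read_pwm_config(cfg)
        assert pwms[0].length == 2 and scan_pwm("AG", pwms[0]) == [(0, 2.0)]


class TestSummaries:
    def test_all_silent_calls(self):
        calls = [
            {"gene_symbol": "G1", "variant_classification": "Silent",
             "normalized_position": 0.5}
        ] * 3
        summary = summarize_variants(calls, calls)
        assert summary["type_counts"] == {"Silent": 3}

    def test_empty_calls(self):
        summary = summarize_variants([], [])
        assert summary["type_counts"] == {}
        assert sum(summary["position_histogram"]) == 0

    def test_uniform_positions_fill_all_bins(self):
        calls = [
            {"gene_symbol": "G", "variant_classification": "Silent",
             "normalized_position": p}
            for p in np.linspace(0.001, 0.999, 400)
        ]
        summary = summarize_variants(calls, calls)
        assert len(summary["position_histogram"]) == 20
        assert min(summary["position_histogram"]) >= 10  # roughly flat

    def test_gene_groups_by_call_count(self):
        calls = [
            {"gene_symbol": g, "variant_classification": "Missense_Mutation",
             "normalized_position": 0.2}
            for g in ["G1", "G1", "G2"]
        ]
        everything = calls + [
            {"gene_symbol": g, "variant_classification": "Silent",
             "normalized_position": None}
            for g in ["G1", "G2", "G3", "G3"]
        ]
        groups = summarize_variants(calls, everything)["gene_groups"]
        assert groups[">=2"] == [3]  # G1: 3 total variants
        assert groups["1"] == [2]  # G2
        assert groups["0"] == [2]  # G3
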