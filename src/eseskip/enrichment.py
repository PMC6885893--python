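"""Gene-set enrichment, variant summaries, and PWM motif-disruption calls.

Enrichment uses the exact hypergeometric upper tail: drawing ``n`` genes
(those carrying ESE-disrupting variants) from a universe of ``N``
analyzable genes of which ``K`` belong to the set, the p-value is
P(X >= k) for the ``k`` observed members.  Gene sets are flat membership
lists (set_id <TAB> gene), serving GO terms and oncogenic signatures
alike.

Motif scanning is a generic position-weight-matrix scorer: per-position
base scores summed over a window, hit when the score reaches the matrix's
threshold.  Matrices, thresholds and OR-groups (several matrices for one
SR protein, a hit in either counting as a motif) are user-supplied — the
classical SELEX-derived SRSF1/2/5/6 matrices are a licensed external
resource, not shipped here.  Disruption status for a variant compares
reference and alternate windows centered on the variant: a protein's motif
is *disrupted* when a reference hit overlapping the variant base has no
overlapping hit left in the alternate sequence.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class EnrichmentInput:
    population_size: int  # N
    population_successes: int  # K
    draws: int  # n
    observed_successes: int  # k

    def __post_init__(self):
        N, K, n, k = (
            self.population_size,
            self.population_successes,
            self.draws,
            self.observed_successes,
        )
        if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
            raise ValueError(
                f"invalid hypergeometric input N={N}, K={K}, n={n}, k={k}"
            )


def hypergeometric_pvalue(inp: EnrichmentInput) -> float:
    """Exact upper-tail P(X >= k) under Hypergeometric(N, K, n)."""
    return float(
        hypergeom.sf(
            inp.observed_successes - 1,
            inp.population_size,
            inp.population_successes,
            inp.draws,
        )
    )


def read_gene_sets(path) -> dict[str, set[str]]:
    """Read a long-format gene-set file: set_id <TAB> gene per row."""
    sets: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"gene-set row needs 2 columns: {line!r}")
            sets.setdefault(parts[0], set()).add(parts[1])
    return sets


def enrich_gene_sets(hit_genes, universe_genes, gene_sets) -> list[dict]:
    """Hypergeometric enrichment of each set among ``hit_genes`` vs the universe."""
    universe = set(universe_genes)
    hits = set(hit_genes) & universe
    rows = []
    for set_id in sorted(gene_sets):
        members = gene_sets[set_id] & universe
        k = len(hits & members)
        inp = EnrichmentInput(len(universe), len(members), len(hits), k)
        rows.append(
            {
                "set_id": set_id,
                "population_size": len(universe),
                "set_size": len(members),
                "n_hits": len(hits),
                "overlap": k,
                "p_value": hypergeometric_pvalue(inp),
            }
        )
    return rows


@dataclass(frozen=True)
class Pwm:
    """A position weight matrix with a hit threshold.

    ``matrix`` maps each base to a length-L tuple of scores.  Matrices
    sharing an ``or_group`` belong to one protein; a hit from any of them
    counts as that protein's motif.
    """

    name: str
    matrix: dict[str, tuple[float, ...]]
    threshold: float
    or_group: str | None = None

    def __post_init__(self):
        lengths = {len(v) for v in self.matrix.values()}
        if set(self.matrix) != set(BASES) or len(lengths) != 1 or 0 in lengths:
            raise ValueError(f"PWM {self.name}: need equal-length rows for A/C/G/T")
        for row in self.matrix.values():
            if not all(np.isfinite(row)):
                raise ValueError(f"PWM {self.name}: non-finite score")

    @property
    def length(self) -> int:
        return len(self.matrix["A"])

    @property
    def group(self) -> str:
        return self.or_group or self.name


def read_pwm_config(path) -> list[Pwm]:
    """Read PWMs from a YAML file: a list of {name, threshold, or_group, matrix}."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh)
    pwms = []
    for entry in raw:
        pwms.append(
            Pwm(
                name=entry["name"],
                matrix={b: tuple(float(x) for x in entry["matrix"][b]) for b in BASES},
                threshold=float(entry["threshold"]),
                or_group=entry.get("or_group"),
            )
        )
    return pwms


def scan_pwm(sequence: str, pwm: Pwm) -> list[tuple[int, float]]:
    """All (offset, score) hits with score >= threshold.

    Windows containing a base outside A/C/G/T (e.g. N) are skipped with a
    log message.
    """
    sequence = sequence.upper()
    L = pwm.length
    hits = []
    for offset in range(len(sequence) - L + 1):
        window = sequence[offset : offset + L]
        try:
            score = sum(pwm.matrix[base][i] for i, base in enumerate(window))
        except KeyError:
            logger.debug("window %r skipped: ambiguous base", window)
            continue
        if score >= pwm.threshold:
            hits.append((offset, score))
    return hits


def _group_hit_overlapping(sequence: str, pwms, position: int) -> bool:
    """Whether any hit from any matrix in the group covers ``position``."""
    for pwm in pwms:
        for offset, _ in scan_pwm(sequence, pwm):
            if offset <= position < offset + pwm.length:
                return True
    return False


def motif_disruption(
    ref_window: str, alt_window: str, variant_offset: int, pwms
) -> dict[str, str]:
    """Per-protein motif status at the variant: absent/retained/disrupted/created.

    ``ref_window``/``alt_window`` are reference and alternate sequences
    with the variant base at ``variant_offset`` (minus-strand genes should
    be passed reverse-complemented).  Windows shorter than 2L−1 cannot
    score every placement overlapping the variant; such PWMs are skipped.
    """
    by_group: dict[str, list[Pwm]] = {}
    for pwm in pwms:
        if len(ref_window) < pwm.length or len(alt_window) < pwm.length:
            logger.warning("window too short for PWM %s (L=%d); skipped", pwm.name, pwm.length)
            continue
        by_group.setdefault(pwm.group, []).append(pwm)
    status: dict[str, str] = {}
    for group in sorted(by_group):
        members = by_group[group]
        ref_hit = _group_hit_overlapping(ref_window, members, variant_offset)
        alt_hit = _group_hit_overlapping(alt_window, members, variant_offset)
        if ref_hit and alt_hit:
            status[group] = "retained"
        elif ref_hit:
            status[group] = "disrupted"
        elif alt_hit:
            status[group] = "created"
        else:
            status[group] = "absent"
    return status


POSITION_BINS = 20


def summarize_variants(call_rows, all_rows) -> dict:
    """Fig-5-style summaries of the detection output.

    ``call_rows``/``all_rows`` are results-table rows (dicts) with at least
    gene_symbol, variant_classification, is_ese_disrupting and, for calls,
    a ``normalized_position`` value in [0, 1] when available.

    Returns variant-classification counts for the calls, a 20-bin
    left-closed histogram of normalized exon positions, and the per-gene
    grouping {0, 1, >=2 ESE-disrupting variants} with each gene's total
    somatic variant count.
    """
    type_counts = Counter(r["variant_classification"] for r in call_rows)
    positions = [
        r["normalized_position"]
        for r in call_rows
        if r.get("normalized_position") is not None
    ]
    hist, edges = np.histogram(positions, bins=POSITION_BINS, range=(0.0, 1.0))
    calls_per_gene = Counter(r["gene_symbol"] for r in call_rows)
    totals_per_gene = Counter(r["gene_symbol"] for r in all_rows)
    gene_groups: dict[str, list[int]] = {">=2": [], "1": [], "0": []}
    for gene, total in sorted(totals_per_gene.items()):
        n_calls = calls_per_gene.get(gene, 0)
        key = ">=2" if n_calls >= 2 else ("1" if n_calls == 1 else "0")
        gene_groups[key].append(total)
    return {
        "type_counts": dict(sorted(type_counts.items())),
        "position_histogram": hist.tolist(),
        "position_bin_edges": edges.tolist(),
        "gene_groups": gene_groups,
    }
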