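"""Sample-label permutation test for the detection pipeline's false positives.

The pairing between a sample's somatic variants and its RNA-seq junction
profile is shuffled uniformly at random — within each project, never
across — and the whole detection pipeline is re-run on each shuffled
pairing.  Variants and profiles themselves are untouched; only the link
between them moves, so the permuted runs preserve the cohort's marginal
structure (variant burden per project, junction depth distributions) while
destroying the carrier-specific skip signal.  The distribution of call
counts over permutations estimates how many calls the exact pairing would
produce by chance.

Fixed points are allowed: the null is a true uniform shuffle, not a
derangement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .detection import CohortData, DetectionOutput, run_detection

logger = logging.getLogger(__name__)


def permute_pairing(
    cohort: CohortData,
    rng: np.random.Generator | None = None,
    mapping: dict[str, str] | None = None,
) -> CohortData:
    """Return a cohort whose variant sample labels are shuffled within project.

    ``mapping`` overrides the random draw (e.g. the identity, for checking
    that an unshuffled permutation reproduces the exact run).
    """
    if mapping is None:
        if rng is None:
            raise ValueError("permute_pairing needs an rng or an explicit mapping")
        mapping = {}
        for project in cohort.projects:
            samples = cohort.samples_in_project(project)
            perm = rng.permutation(len(samples))
            mapping.update({samples[i]: samples[perm[i]] for i in range(len(samples))})
    new_variants = [
        replace(v, sample_id=mapping[v.sample_id])
        for v in cohort.variants
        if v.sample_id in mapping
    ]
    return CohortData(
        profiles=cohort.profiles,
        sample_project=cohort.sample_project,
        variants=new_variants,
        models=cohort.models,
        assigner=cohort.assigner,
        expression=cohort.expression,
        n_variants_raw=cohort.n_variants_raw,
        cohort_id=cohort.cohort_id,
    )


@dataclass
class PermutationResult:
    n_iterations: int
    per_iteration_calls: list[int]
    mean_calls: float
    median_calls: float
    exact_calls: int
    fp_ratio: float | None  # mean permuted calls / exact calls
    seed: int

    def rows(self) -> list[dict]:
        out = [
            {"iteration": i, "n_calls": c}
            for i, c in enumerate(self.per_iteration_calls, start=1)
        ]
        return out


def run_permutation_test(
    cohort: CohortData,
    n_iterations: int = 1000,
    seed: int = 0,
    exact_output: DetectionOutput | None = None,
    **detection_kwargs,
) -> PermutationResult:
    """Estimate the false-positive call count by repeated label shuffling.

    ``detection_kwargs`` (alpha, eer window, min_controls) are forwarded to
    every detection run so the permuted runs test exactly the pipeline that
    produced the exact calls.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    for project in cohort.projects:
        if len(cohort.samples_in_project(project)) < 2:
            raise ValueError(f"project {project} has fewer than 2 usable samples")
    if exact_output is None:
        exact_output = run_detection(cohort, **detection_kwargs)
    exact_calls = len(exact_output.calls)
    rng = np.random.default_rng(seed)
    per_iteration: list[int] = []
    for it in range(n_iterations):
        permuted = permute_pairing(cohort, rng)
        out = run_detection(permuted, **detection_kwargs)
        per_iteration.append(len(out.calls))
        if (it + 1) % 100 == 0:
            logger.info("permutation %d/%d: mean calls so far %.3f",
                        it + 1, n_iterations, float(np.mean(per_iteration)))
    mean_calls = float(np.mean(per_iteration))
    median_calls = float(np.median(per_iteration))
    return PermutationResult(
        n_iterations=n_iterations,
        per_iteration_calls=per_iteration,
        mean_calls=mean_calls,
        median_calls=median_calls,
        exact_calls=exact_calls,
        fp_ratio=mean_calls / exact_calls if exact_calls else None,
        seed=seed,
    )
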