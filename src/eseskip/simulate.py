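"""Synthetic tumor-cohort generator for end-to-end pipeline testing.

The generator writes a complete cohort in the same file dialects the real
pipeline ingests — per-sample junction quantification tables, one shared
MAF, per-sample RSEM expression tables, a refFlat gene model and a
manifest — plus a ground-truth table, so recall and false-positive rates
are measurable without any controlled-access data.

Statistical world:

* Per (sample, gene) sequencing depth is gamma-distributed with shape
  ``negbin_dispersion`` and mean ``mean_junction_depth``; per-junction
  inclusion counts are Poisson around that depth, so marginally each
  inclusion count is negative-binomial while junctions of one gene stay
  correlated, as read counts along a single transcript are.
* Background exon skipping: every internal exon's skip junction draws
  Poisson(baseline_skip_rate × depth) reads in every sample.
* A planted ESE-disrupting variant adds skip reads targeting
  EER ≈ planted_eer_target × tumor_purity against the carrier's own
  realized flanking counts B and C (the heterozygous-clonal expectation
  ψ ≈ 1, diluted by purity ρ).
* Expression is log-normal with a gene-level and a sample-level variance
  component.  Samples carrying a nonsense variant that is *not*
  ESE-disrupting have that gene multiplied by ``nmd_effect`` (NMD
  degradation); carriers of ESE-disrupting nonsense variants are
  multiplied by ``nmd_escape_mult`` (escape with accumulation of the
  exon-skipped transcript).
* Decoy variants with realistic classification mixes are sprinkled over
  internal exons with no count effect, to measure false positives.

No nucleotide sequence is simulated; motif scanning is exercised
separately with toy matrices.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

# internal-exon length pools; first all divisible by 3, second none
_INFRAME_LENGTHS = (90, 120, 150, 180)
_OUTFRAME_LENGTHS = (100, 130, 160, 190)
_FLANK_EXON_LENGTH = 200
_INTRON_LENGTH = 300
_GENE_SPACING = 50_000
_MAF_HEADER = (
    "Hugo_Symbol\tChromosome\tStart_Position\tEnd_Position\tReference_Allele\t"
    "Tumor_Seq_Allele2\tVariant_Classification\tVariant_Type\tTumor_Sample_Barcode"
)


@dataclass
class SimConfig:
    """Parameters of the stated synthetic world (all rates per sample)."""

    n_samples: int = 200
    n_genes: int = 100
    exons_per_gene: int = 5
    mean_junction_depth: float = 200.0
    negbin_dispersion: float = 10.0
    baseline_skip_rate: float = 0.005
    n_planted_ese: int = 40
    planted_eer_target: float = 0.8
    tumor_purity: float = 0.9
    n_decoys: int = 400
    n_nonsense_nonese: int = 0
    n_nonsense_ese: int = 0
    nmd_effect: float = 0.4
    nmd_escape_mult: float = 1.25
    expression_mean_log: float = 7.0
    expression_gene_sdlog: float = 0.75
    expression_sample_sdlog: float = 0.3
    project_id: str = "SYNTH"
    seed: int = 0

    def __post_init__(self):
        if self.exons_per_gene < 3:
            raise ValueError("exons_per_gene must be >= 3 so internal exons exist")
        if not (0 < self.tumor_purity <= 1):
            raise ValueError("tumor_purity must be in (0, 1]")
        if not (0 <= self.planted_eer_target):
            raise ValueError("planted_eer_target must be non-negative")
        if not (0 < self.nmd_effect <= 1):
            raise ValueError("nmd_effect must be in (0, 1]")
        if self.baseline_skip_rate < 0:
            raise ValueError("baseline_skip_rate must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass(frozen=True)
class PlantedVariant:
    sample_id: str
    gene_index: int
    exon_index: int  # genomic-order index within the transcript
    chrom: str
    pos: int
    ref: str
    alt: str
    classification: str
    category: str  # ese | nonsense_ese | nonsense_nonese | decoy
    in_frame: bool


@dataclass
class CohortTruth:
    """Ground-truth labels for a simulated cohort."""

    cohort_id: str
    config: SimConfig
    sample_ids: tuple[str, ...]
    variants: list[PlantedVariant]

    @property
    def planted_ese(self) -> set:
        """Keys of variants with a planted skip effect (incl. ESE nonsense)."""
        return {
            (v.sample_id, v.chrom, v.pos)
            for v in self.variants
            if v.category in ("ese", "nonsense_ese")
        }

    @property
    def planted_nonsense(self) -> dict:
        return {
            (v.sample_id, v.chrom, v.pos): (v.category == "nonsense_ese", v.in_frame)
            for v in self.variants
            if v.classification == "Nonsense_Mutation"
        }

    @property
    def non_planted(self) -> set:
        return {
            (v.sample_id, v.chrom, v.pos)
            for v in self.variants
            if v.category in ("decoy", "nonsense_nonese")
        }


@dataclass
class SimPaths:
    out_dir: Path
    manifest_path: Path
    gene_model_path: Path
    maf_path: Path
    truth_path: Path


@dataclass(frozen=True)
class _Gene:
    index: int
    symbol: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open


def draw_junction_depths(rng: np.random.Generator, n: int, mean: float, dispersion: float):
    """Gamma-Poisson (negative binomial) junction depth draws."""
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion, size=n)
    return rng.poisson(lam)


def _build_genes(config: SimConfig, rng: np.random.Generator) -> list[_Gene]:
    genes = []
    cursors: dict[str, int] = {}
    for g in range(config.n_genes):
        chrom = f"chr{(g % 22) + 1}"
        strand = "+" if g % 2 == 0 else "-"
        start = cursors.get(chrom, 10_000)
        exons = []
        pos = start
        for e in range(config.exons_per_gene):
            if e == 0 or e == config.exons_per_gene - 1:
                length = _FLANK_EXON_LENGTH
            else:
                pool = _INFRAME_LENGTHS if (g + e) % 2 == 0 else _OUTFRAME_LENGTHS
                length = int(rng.choice(pool))
            exons.append((pos, pos + length))
            pos += length + _INTRON_LENGTH
        cursors[chrom] = pos + _GENE_SPACING
        genes.append(
            _Gene(g, f"G{g:04d}", f"TX{g:04d}", chrom, strand, tuple(exons))
        )
    return genes


def _plan_variants(config: SimConfig, genes, sample_ids, rng) -> list[PlantedVariant]:
    """Choose (sample, gene, exon, position) for every planted variant.

    Each variant takes a fresh (sample, gene) pair so NMD expression
    effects never collide within a gene of one sample.  Frame classes
    alternate within each nonsense category so the four-way NMD table gets
    balanced groups.
    """
    internal: list[tuple[int, int, bool]] = []  # (gene_idx, exon_idx, in_frame)
    for gene in genes:
        for e in range(1, config.exons_per_gene - 1):
            start, end = gene.exons[e]
            internal.append((gene.index, e, (end - start) % 3 == 0))
    in_frame_slots = [s for s in internal if s[2]]
    out_frame_slots = [s for s in internal if not s[2]]
    if not in_frame_slots or not out_frame_slots:
        raise ValueError("gene model lacks one exon frame class; increase n_genes")

    total = (
        config.n_planted_ese + config.n_nonsense_ese + config.n_nonsense_nonese + config.n_decoys
    )
    if total > config.n_samples * config.n_genes:
        raise ValueError(
            f"{total} variants requested but only {config.n_samples * config.n_genes} "
            "(sample, gene) pairs available"
        )

    used_pairs: set[tuple[str, int]] = set()
    variants: list[PlantedVariant] = []

    def draw_slot(frame: bool | None):
        if frame is None:
            pool = internal
        else:
            pool = in_frame_slots if frame else out_frame_slots
        for _ in range(10_000):
            gene_idx, exon_idx, in_frame = pool[int(rng.integers(len(pool)))]
            sample = sample_ids[int(rng.integers(len(sample_ids)))]
            if (sample, gene_idx) not in used_pairs:
                used_pairs.add((sample, gene_idx))
                return sample, gene_idx, exon_idx, in_frame
        raise ValueError("could not place all requested variants; cohort too small")

    def place(n, category, classifications, alternate_frame):
        for i in range(n):
            frame = (i % 2 == 0) if alternate_frame else None
            sample, gene_idx, exon_idx, in_frame = draw_slot(frame)
            gene = genes[gene_idx]
            start, end = gene.exons[exon_idx]
            pos = int(rng.integers(start + 1, end + 1))  # 1-based inside exon
            ref, alt = rng.choice(("A", "C", "G", "T"), size=2, replace=False)
            variants.append(
                PlantedVariant(
                    sample_id=sample,
                    gene_index=gene_idx,
                    exon_index=exon_idx,
                    chrom=gene.chrom,
                    pos=pos,
                    ref=str(ref),
                    alt=str(alt),
                    classification=classifications[i % len(classifications)],
                    category=category,
                    in_frame=in_frame,
                )
            )

    place(config.n_planted_ese, "ese", ("Missense_Mutation", "Silent"), False)
    place(config.n_nonsense_ese, "nonsense_ese", ("Nonsense_Mutation",), True)
    place(config.n_nonsense_nonese, "nonsense_nonese", ("Nonsense_Mutation",), True)
    place(
        config.n_decoys,
        "decoy",
        ("Missense_Mutation", "Silent", "Missense_Mutation", "Nonsense_Mutation"),
        False,
    )
    return variants


def _junction_rows(gene: _Gene):
    """(label, donor, acceptor) for inclusion then skip junctions of one gene."""
    rows = []
    E = len(gene.exons)
    for i in range(E - 1):
        rows.append(("incl", i, gene.exons[i][1], gene.exons[i + 1][0] + 1))
    for i in range(1, E - 1):
        rows.append(("skip", i, gene.exons[i - 1][1], gene.exons[i + 1][0] + 1))
    return rows


def simulate_cohort(config: SimConfig, out_dir) -> tuple[SimPaths, CohortTruth]:
    """Generate the cohort on disk; returns paths and ground truth.

    Identical configs (same seed) produce byte-identical files.
    """
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    (out_dir / "junctions").mkdir(parents=True, exist_ok=True)
    (out_dir / "rsem").mkdir(exist_ok=True)

    genes = _build_genes(config, rng)
    sample_ids = tuple(f"S{i:04d}" for i in range(config.n_samples))
    variants = _plan_variants(config, genes, sample_ids, rng)

    S, G, E = config.n_samples, config.n_genes, config.exons_per_gene
    depth = rng.gamma(
        shape=config.negbin_dispersion,
        scale=config.mean_junction_depth / config.negbin_dispersion,
        size=(S, G),
    )
    incl = rng.poisson(depth[:, :, None], size=(S, G, E - 1))
    skip = rng.poisson(config.baseline_skip_rate * depth[:, :, None], size=(S, G, E - 2))

    sample_index = {s: i for i, s in enumerate(sample_ids)}
    target = config.planted_eer_target * config.tumor_purity
    for v in variants:
        if v.category not in ("ese", "nonsense_ese"):
            continue
        s, g, e = sample_index[v.sample_id], v.gene_index, v.exon_index
        b = incl[s, g, e - 1]
        c = incl[s, g, e]
        skip[s, g, e - 1] += int(round(target * (b + c) / 2.0))

    # expression: gene baseline × sample lognormal noise, NMD multipliers after
    gene_base = np.exp(
        config.expression_mean_log
        + config.expression_gene_sdlog * rng.standard_normal(G)
    )
    expr = gene_base[None, :] * np.exp(
        config.expression_sample_sdlog * rng.standard_normal((S, G))
    )
    for v in variants:
        if v.classification != "Nonsense_Mutation":
            continue
        s, g = sample_index[v.sample_id], v.gene_index
        if v.category == "nonsense_ese":
            expr[s, g] *= config.nmd_escape_mult
        else:
            expr[s, g] *= config.nmd_effect

    # ---- write gene model -------------------------------------------------
    gene_model_path = out_dir / "gene_model.refFlat"
    with gene_model_path.open("w") as fh:
        for gene in genes:
            starts = ",".join(str(s) for s, _ in gene.exons) + ","
            ends = ",".join(str(e) for _, e in gene.exons) + ","
            tx_start, tx_end = gene.exons[0][0], gene.exons[-1][1]
            fh.write(
                f"{gene.symbol}\t{gene.transcript_id}\t{gene.chrom}\t{gene.strand}\t"
                f"{tx_start}\t{tx_end}\t{tx_start}\t{tx_end}\t{len(gene.exons)}\t"
                f"{starts}\t{ends}\n"
            )

    # ---- write per-sample junction and expression tables ------------------
    junction_rows = [(g.index, g.chrom, g.strand, _junction_rows(g)) for g in genes]
    for s, sample in enumerate(sample_ids):
        jpath = out_dir / "junctions" / f"{sample}.junction_quantification.txt"
        with jpath.open("w") as fh:
            fh.write("junction\traw_counts\n")
            for g, chrom, strand, rows in junction_rows:
                for kind, idx, donor, acceptor in rows:
                    count = incl[s, g, idx] if kind == "incl" else skip[s, g, idx - 1]
                    fh.write(
                        f"{chrom}:{donor}:{strand},{chrom}:{acceptor}:{strand}\t{count}\n"
                    )
        rpath = out_dir / "rsem" / f"{sample}.rsem.genes.normalized.results.txt"
        with rpath.open("w") as fh:
            fh.write("gene_id\tnormalized_count\n")
            for gene in genes:
                fh.write(f"{gene.symbol}\t{expr[s, gene.index]:.4f}\n")

    # ---- write MAF --------------------------------------------------------
    maf_path = out_dir / "somatic.maf"
    with maf_path.open("w") as fh:
        fh.write("#version 2.4 (synthetic cohort)\n")
        fh.write(_MAF_HEADER + "\n")
        for v in sorted(variants, key=lambda v: (v.sample_id, v.chrom, v.pos)):
            gene = genes[v.gene_index]
            fh.write(
                f"{gene.symbol}\t{v.chrom}\t{v.pos}\t{v.pos}\t{v.ref}\t{v.alt}\t"
                f"{v.classification}\tSNP\t{v.sample_id}\n"
            )

    # ---- manifest and truth ------------------------------------------------
    manifest_path = out_dir / "manifest.tsv"
    with manifest_path.open("w") as fh:
        fh.write("sample_id\tproject_id\tjunction_path\tmaf_membership\trsem_path\n")
        for sample in sample_ids:
            fh.write(
                f"{sample}\t{config.project_id}\t"
                f"junctions/{sample}.junction_quantification.txt\tsomatic.maf\t"
                f"rsem/{sample}.rsem.genes.normalized.results.txt\n"
            )

    truth_path = out_dir / "truth.tsv"
    with truth_path.open("w") as fh:
        fh.write("sample_id\tgene_symbol\tchrom\tpos\tclassification\tcategory\t"
                 "exon_index\tin_frame\n")
        for v in sorted(variants, key=lambda v: (v.sample_id, v.chrom, v.pos)):
            fh.write(
                f"{v.sample_id}\t{genes[v.gene_index].symbol}\t{v.chrom}\t{v.pos}\t"
                f"{v.classification}\t{v.category}\t{v.exon_index}\t{v.in_frame}\n"
            )

    truth = CohortTruth(
        cohort_id=f"synth-seed{config.seed}",
        config=config,
        sample_ids=sample_ids,
        variants=variants,
    )
    paths = SimPaths(
        out_dir=out_dir,
        manifest_path=manifest_path,
        gene_model_path=gene_model_path,
        maf_path=maf_path,
        truth_path=truth_path,
    )
    logger.info(
        "simulated cohort: %d samples, %d genes, %d variants (%d with skip effect)",
        S, G, len(variants), len(truth.planted_ese),
    )
    return paths, truth


def evaluate_against_truth(output, truth: CohortTruth) -> dict:
    """Recall and false-positive accounting of a detection run vs the truth.

    ``output`` is a DetectionOutput from the same cohort; a call on a
    sample the truth does not know is a cohort mismatch and raises.
    """
    called = output.called_keys()
    known = set(truth.sample_ids)
    stray = {k for k in called if k[0] not in known}
    if stray:
        raise ValueError(f"calls reference samples not in this cohort: {sorted(stray)[:3]}")
    planted = truth.planted_ese
    non_planted = truth.non_planted
    tp = called & planted
    fp = called - planted
    rows = []
    for v in sorted(truth.variants, key=lambda v: (v.sample_id, v.chrom, v.pos)):
        key = (v.sample_id, v.chrom, v.pos)
        rows.append(
            {
                "sample_id": v.sample_id,
                "chrom": v.chrom,
                "pos": v.pos,
                "category": v.category,
                "planted_effect": key in planted,
                "called": key in called,
            }
        )
    return {
        "n_planted": len(planted),
        "n_called": len(called),
        "n_true_positive": len(tp),
        "n_false_positive": len(fp),
        "recall": len(tp) / len(planted) if planted else None,
        "false_positive_fraction": len(fp) / len(non_planted) if non_planted else None,
        "per_variant": rows,
    }


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)
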