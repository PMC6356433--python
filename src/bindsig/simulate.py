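"""Synthetic inputs for the whole pipeline, with planted ground truth.

The generators emulate the statistical structure of the study's real
inputs — two TFs' clustered ChIP-seq peak tracks with controlled co-binding
near TSSs, curated gene sets with a planted overlap against the dual-bound
gene list, a log-scale expression matrix, and a proportional-hazards cohort
with independent exponential censoring — so every downstream stage has a
known truth to recover.

Each generator draws from its own RNG stream derived from the master seed
by a fixed offset, so adding a call to one generator never perturbs
another's output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .genome import GeneModel, Peak
from .genesets import GeneSet

# fixed per-generator RNG stream offsets
_STREAM_ANNOTATION = 0
_STREAM_PEAKS = 1
_STREAM_GENESETS = 2
_STREAM_COHORT = 3


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Planted parameters for the synthetic study.

    Defaults describe a desk-scale cohort: 300 genes on one 6 Mb
    chromosome, 200 peaks per TF of which 70% are genic, 30% co-binding,
    17 candidate gene sets (two planted), 300 patients, and a high-vs-low
    hazard ratio of 3 under exponential survival with independent
    exponential censoring.
    """

    n_genes: int = 300
    chrom_length: int = 6_000_000
    chrom_name: str = "chrS"
    n_peaks_per_tf: int = 200
    co_binding_fraction: float = 0.3
    genic_peak_fraction: float = 0.7
    peak_width: int = 200
    tss_placement_sd: float = 300.0
    n_gene_sets: int = 17
    gene_set_size: int = 60
    planted_set_overlap: float = 0.4
    universe_size: int = 300
    n_samples: int = 300
    expression_log_mean: float = 8.0
    expression_log_sd: float = 1.0
    high_group_shift_sd: float = 1.0
    hazard_ratio_high_vs_low: float = 3.0
    baseline_hazard: float = 5e-4      # deaths per day in the low group
    censoring_rate: float = 2.5e-4     # independent censoring, per day
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "chrom_length", "n_peaks_per_tf", "n_gene_sets",
                     "gene_set_size", "universe_size", "n_samples", "peak_width"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("co_binding_fraction", "genic_peak_fraction",
                     "planted_set_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.hazard_ratio_high_vs_low <= 0:
            raise ConfigurationError("hazard_ratio_high_vs_low must be > 0")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be > 0")
        if self.censoring_rate < 0:
            raise ConfigurationError("censoring_rate must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([stream, self.seed])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


_MIN_GENE_SPACING = 12_000
_GENE_LENGTH_RANGE = (2_000, 8_000)


def generate_gene_annotation(
    config: SimulationConfig,
) -> tuple[list[GeneModel], dict[str, str]]:
    """Place non-overlapping genes (>= 12 kb apart) on one chromosome and
    draw a uniform-composition genome sequence.
    """
    rng = config.rng(_STREAM_ANNOTATION)
    n = config.n_genes
    lengths = rng.integers(*_GENE_LENGTH_RANGE, size=n)
    required = int(lengths.sum()) + (n + 1) * _MIN_GENE_SPACING
    if required > config.chrom_length:
        raise ConfigurationError(
            f"chrom_length {config.chrom_length} cannot hold {n} genes with "
            f">= {_MIN_GENE_SPACING} bp spacing (needs >= {required} bp)"
        )
    # distribute the spare length over the n+1 inter-gene gaps
    spare = config.chrom_length - required
    extra = rng.multinomial(spare, np.full(n + 1, 1.0 / (n + 1)))
    gaps = _MIN_GENE_SPACING + extra
    strands = rng.choice(["+", "-"], size=n)
    if n >= 2:  # guarantee both strands are represented
        strands[0], strands[1] = "+", "-"
    genes: list[GeneModel] = []
    pos = 0
    width = len(str(n))
    for i in range(n):
        pos += int(gaps[i])
        start = pos
        end = start + int(lengths[i])
        genes.append(GeneModel(f"G{i + 1:0{width}d}", config.chrom_name,
                               start, end, str(strands[i])))
        pos = end
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = base_bytes[rng.integers(0, 4, size=config.chrom_length)].tobytes().decode()
    return genes, {config.chrom_name: seq}


def _draw_peak_at(center: int, width: int, chrom_length: int) -> Peak | None:
    start = max(0, center - width // 2)
    end = min(chrom_length, start + width)
    if end <= start:
        return None
    return Peak("", start, end)  # chrom filled by caller


def generate_peak_tracks(
    config: SimulationConfig, genes: Sequence[GeneModel]
) -> tuple[list[Peak], list[Peak], list[str]]:
    """Two TFs' peak tracks with a planted co-binding structure.

    A fraction `co_binding_fraction` of the genic peak budget targets
    shared (dual-bound) genes with one peak per TF drawn
    Normal(TSS, tss_placement_sd); the remaining genic peaks go to
    TF-private genes; non-genic peaks land in inter-gene gaps more than
    5 kb from any gene body. Returns (track1, track2, truth dual gene ids).
    """
    rng = config.rng(_STREAM_PEAKS)
    chrom = genes[0].chrom
    n_genic = round(config.genic_peak_fraction * config.n_peaks_per_tf)
    n_dual = round(config.co_binding_fraction * n_genic)
    n_single = n_genic - n_dual
    need = n_dual + 2 * n_single
    if need > len(genes):
        raise ConfigurationError(
            f"peak budget needs {need} distinct target genes but only "
            f"{len(genes)} genes exist; reduce n_peaks_per_tf or raise n_genes"
        )
    picked = rng.choice(len(genes), size=need, replace=False)
    dual_idx = picked[:n_dual]
    single1_idx = picked[n_dual:n_dual + n_single]
    single2_idx = picked[n_dual + n_single:]

    def tss_peak(gene: GeneModel) -> Peak:
        center = int(round(rng.normal(gene.tss, config.tss_placement_sd)))
        center = int(np.clip(center, config.peak_width // 2,
                             config.chrom_length - config.peak_width // 2))
        p = _draw_peak_at(center, config.peak_width, config.chrom_length)
        assert p is not None
        return Peak(chrom, p.start, p.end)

    track1 = [tss_peak(genes[i]) for i in dual_idx]
    track2 = [tss_peak(genes[i]) for i in dual_idx]
    track1 += [tss_peak(genes[i]) for i in single1_idx]
    track2 += [tss_peak(genes[i]) for i in single2_idx]

    n_intergenic = config.n_peaks_per_tf - n_genic
    if n_intergenic > 0:
        sorted_genes = sorted(genes, key=lambda g: g.start)
        half = config.peak_width // 2
        margin = 5001 + half  # strictly > 5 kb from any gene edge
        slots: list[tuple[int, int]] = []
        bounds = [0] + [g.end for g in sorted_genes]
        uppers = [g.start for g in sorted_genes] + [config.chrom_length]
        for lo, hi in zip(bounds, uppers):
            if hi - margin > lo + margin:
                slots.append((lo + margin, hi - margin))
        if not slots:
            raise ConfigurationError(
                "no inter-gene gap can hold an intergenic peak > 5 kb from "
                "every gene; increase chrom_length or gene spacing"
            )
        for tf_track in (track1, track2):
            for _ in range(n_intergenic):
                lo, hi = slots[rng.integers(len(slots))]
                center = int(rng.integers(lo, hi))
                tf_track.append(Peak(chrom, center - half, center - half + config.peak_width))

    truth = sorted(genes[i].gene_id for i in dual_idx)
    return track1, track2, truth


def generate_gene_sets(
    config: SimulationConfig,
    truth_dual_genes: Sequence[str],
    universe: Sequence[str],
) -> tuple[list[GeneSet], list[str]]:
    """Candidate gene sets: two planted (drawing `planted_set_overlap` of
    members from the truth dual-bound list) plus uniform null sets.

    Returns (sets, planted set names).
    """
    rng = config.rng(_STREAM_GENESETS)
    universe = list(dict.fromkeys(universe))
    truth = [g for g in truth_dual_genes if g in set(universe)]
    size = min(config.gene_set_size, len(universe))
    n_planted = min(2, config.n_gene_sets)
    sets: list[GeneSet] = []
    planted_names: list[str] = []
    non_truth = [g for g in universe if g not in set(truth)]
    width = len(str(config.n_gene_sets))
    for i in range(config.n_gene_sets):
        name = f"SET{i + 1:0{width}d}"
        if i < n_planted and truth:
            k_truth = min(round(config.planted_set_overlap * size), len(truth))
            members = list(rng.choice(truth, size=k_truth, replace=False))
            pool = [g for g in universe if g not in set(members)]
            members += list(rng.choice(pool, size=min(size - k_truth, len(pool)),
                                       replace=False))
            name = f"PLANTED{i + 1}"
            planted_names.append(name)
            desc = "planted: enriched for dual-bound genes"
        else:
            members = list(rng.choice(universe, size=size, replace=False))
            desc = "null: uniform draw from the universe"
        sets.append(GeneSet(name, desc, frozenset(members)))
    return sets, planted_names


def generate_expression_survival(
    config: SimulationConfig, signature_genes: Sequence[str],
    all_genes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Log-scale expression matrix plus a survival/clinical table.

    A randomly chosen half of samples (the intended "high" group) receives a
    latent upward shift of `high_group_shift_sd` expression SDs on the
    signature genes. Death times are exponential with hazard
    baseline_hazard * hazard_ratio^{is_high}; censoring is independent
    exponential (rate 0 = no censoring). Clinical covariates depend on the
    latent group so GLM recovery is testable: the high group skews toward
    higher grade, ER negativity, chemotherapy, younger age and more
    positive lymph nodes.

    Returns (expression genes x samples, clinical table, high-group sample ids).
    """
    rng = config.rng(_STREAM_COHORT)
    sig = list(dict.fromkeys(signature_genes))
    if not sig:
        raise ConfigurationError("signature_genes must be non-empty")
    genes = list(dict.fromkeys(all_genes)) if all_genes is not None else list(sig)
    for g in sig:
        if g not in set(genes):
            genes.append(g)
    n_s = config.n_samples
    samples = [f"S{i + 1:04d}" for i in range(n_s)]
    expr = rng.normal(config.expression_log_mean, config.expression_log_sd,
                      size=(len(genes), n_s))
    expression = pd.DataFrame(expr, index=genes, columns=samples)

    n_high = n_s // 2
    high_idx = rng.choice(n_s, size=n_high, replace=False)
    is_high = np.zeros(n_s, dtype=bool)
    is_high[high_idx] = True
    shift = config.high_group_shift_sd * config.expression_log_sd
    expression.loc[sig, np.array(samples)[is_high]] += shift

    hazard = config.baseline_hazard * np.where(
        is_high, config.hazard_ratio_high_vs_low, 1.0)
    death = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        censor = rng.exponential(1.0 / config.censoring_rate, size=n_s)
    else:
        censor = np.full(n_s, np.inf)
    time = np.minimum(death, censor)
    event = (death <= censor).astype(int)

    grade_p_high = np.array([0.10, 0.30, 0.60])
    grade_p_low = np.array([0.30, 0.50, 0.20])
    grade = np.where(
        is_high,
        rng.choice([1, 2, 3], size=n_s, p=grade_p_high),
        rng.choice([1, 2, 3], size=n_s, p=grade_p_low),
    )
    er = (rng.random(n_s) < np.where(is_high, 0.45, 0.70)).astype(int)
    chemo = (rng.random(n_s) < np.where(is_high, 0.60, 0.30)).astype(int)
    age = rng.normal(np.where(is_high, 58.0, 63.0), 12.0)
    nodes = rng.poisson(np.where(is_high, 3.0, 1.0))

    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "time": time,
            "event": event,
            "grade": grade,
            "er": er,
            "chemotherapy": chemo,
            "age_at_diagnosis": np.round(age, 1),
            "lymph_nodes_positive": nodes,
        }
    ).set_index("sample_id")
    high_samples = [s for s, h in zip(samples, is_high) if h]
    return expression, clinical, high_samples


def simulate_all(config: SimulationConfig, outdir: str | Path) -> dict:
    """Run every generator, write all pipeline inputs to `outdir`, and
    return (and write) a truth sidecar with the planted parameters and sets.
    """
    from .genome import write_bed, write_fasta, write_gene_table
    from .genesets import write_gmt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, genome = generate_gene_annotation(config)
    track1, track2, truth_dual = generate_peak_tracks(config, genes)
    universe = [g.gene_id for g in genes]
    sets, planted_names = generate_gene_sets(config, truth_dual, universe)
    # the planted signature construction: dual genes appearing in either planted set
    planted_members: set[str] = set()
    for s in sets:
        if s.name in planted_names:
            planted_members |= set(s.members) & set(truth_dual)
    signature_genes = sorted(planted_members) or truth_dual
    expression, clinical, high_samples = generate_expression_survival(
        config, signature_genes, all_genes=universe)

    write_gene_table(genes, outdir / "genes.bed")
    write_fasta(genome, outdir / "genome.fa")
    write_bed(track1, outdir / "peaks_tf1.bed")
    write_bed(track2, outdir / "peaks_tf2.bed")
    write_gmt(sets, outdir / "gene_sets.gmt")
    expression.to_csv(outdir / "expression.tsv", sep="\t", index_label="gene_id")
    clinical.to_csv(outdir / "clinical.tsv", sep="\t")

    truth = {
        "config": asdict(config),
        "dual_bound_genes": truth_dual,
        "planted_set_names": planted_names,
        "planted_signature_genes": signature_genes,
        "high_group_samples": high_samples,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth
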