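"""Pipeline orchestration: dual-binding -> enrichment -> signature -> survival.

`run_pipeline` sequences the stages over file inputs, writes every stage's
tables, and records a JSON manifest with the tool version, a config hash,
input checksums and the headline numbers, so a run is fully reproducible
from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .genome import read_bed, read_gene_table, read_fasta
from .genesets import (
    build_signature,
    fisher_enrichment,
    rank_and_select,
    read_gmt,
    write_enrichment_table,
)
from .motifs import extract_promoter_window, rank_tfs, read_jaspar_pfm, write_tba_report
from .peaks import (
    assign_peaks,
    dual_bound_genes,
    tss_proximity_fraction,
    write_assignments,
)
from .plots import plot_glm_coefficients, plot_km, write_glm_tsv, write_survival_tsv
from .survival import km_estimate, logrank_test, median_split, signature_score, univariate_glm


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and its diagnostic."""


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run. Flags mirror the YAML fields."""

    outdir: str = "results"
    # inputs
    genes: str | None = None
    genome: str | None = None
    motifs: str | None = None
    tba_gene: str | None = None
    tf1_bed: str | None = None
    tf2_bed: str | None = None
    gmt: str | None = None
    expression: str | None = None
    clinical: str | None = None
    # stage toggles
    run_tba: bool = False
    # parameters
    upstream: int = 756
    downstream: int = 235
    pseudocount: float = 1.0
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    shuffles: int = 0
    max_distance: int = 5000
    tss_window: int = 1000
    alpha: float = 0.05
    top_k: int = 2
    tail: str = "greater"
    signature_name: str = "SP1-S3"
    time_col: str = "time"
    event_col: str = "event"
    features: tuple[str, ...] = (
        "grade", "er", "chemotherapy", "age_at_diagnosis", "lymph_nodes_positive")
    seed: int = 0

    def validate(self) -> None:
        required = ["genes", "tf1_bed", "tf2_bed", "gmt", "expression", "clinical"]
        if self.run_tba:
            required += ["genome", "motifs"]
        missing = [name for name in required if getattr(self, name) is None]
        if missing:
            raise PipelineError(f"validation: missing required inputs: {missing}")
        absent = [
            name for name in required
            if getattr(self, name) and not Path(getattr(self, name)).exists()
        ]
        if absent:
            paths = {name: getattr(self, name) for name in absent}
            raise PipelineError(f"validation: input paths do not exist: {paths}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("background", "features"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_pipeline(config: PipelineConfig, log=lambda msg: print(msg, file=sys.stderr)) -> dict:
    """Execute tba (optional) -> dualbind -> enrich -> survive; return the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "bindsig",
        "version": __version__,
        "config_hash": _config_hash(config),
        "inputs": {},
        "results": {},
    }
    for name in ("genes", "genome", "motifs", "tf1_bed", "tf2_bed", "gmt",
                 "expression", "clinical"):
        path = getattr(config, name)
        if path:
            manifest["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    failed_marker = outdir / "FAILED"

    def stage(name: str):
        def wrap(fn):
            try:
                log(f"[{name}] running")
                return fn()
            except Exception as exc:
                failed_marker.write_text(f"{name}: {exc}\n")
                raise PipelineError(f"stage {name}: {exc}") from exc
        return wrap

    genes = stage("load")(lambda: read_gene_table(config.genes))
    universe = sorted({g.gene_id for g in genes})

    if config.run_tba:
        def do_tba():
            genome = read_fasta(config.genome)
            motifs = read_jaspar_pfm(config.motifs, pseudocount=config.pseudocount)
            target = config.tba_gene or genes[0].gene_id
            gene = next(g for g in genes if g.gene_id == target)
            window = extract_promoter_window(
                gene, genome, upstream=config.upstream, downstream=config.downstream)
            ranked = rank_tfs(window, motifs, background=config.background,
                              n_shuffles=config.shuffles, seed=config.seed)
            write_tba_report(ranked, outdir / "tba_ranking.tsv")
            return {"gene": target, "top_motif": ranked[0].motif_name,
                    "n_motifs": len(ranked)}
        manifest["results"]["tba"] = stage("tba")(do_tba)

    def do_dualbind():
        peaks1 = read_bed(config.tf1_bed)
        peaks2 = read_bed(config.tf2_bed)
        a1 = assign_peaks(peaks1, genes, max_distance=config.max_distance)
        a2 = assign_peaks(peaks2, genes, max_distance=config.max_distance)
        write_assignments(a1, outdir / "assignments_tf1.tsv")
        write_assignments(a2, outdir / "assignments_tf2.tsv")
        dual = dual_bound_genes(a1, a2)
        (outdir / "dual_bound_genes.txt").write_text(
            "".join(f"{g}\n" for g in dual))
        return {
            "dual": dual,
            "summary": {
                "n_peaks_tf1": len(peaks1), "n_peaks_tf2": len(peaks2),
                "n_assigned_tf1": len(a1), "n_assigned_tf2": len(a2),
                "n_dual_bound_genes": len(dual),
                "tss_fraction_tf1": tss_proximity_fraction(a1, config.tss_window),
                "tss_fraction_tf2": tss_proximity_fraction(a2, config.tss_window),
            },
        }
    dual_out = stage("dualbind")(do_dualbind)
    dual = dual_out["dual"]
    manifest["results"]["dualbind"] = dual_out["summary"]

    def do_enrich():
        sets = read_gmt(config.gmt)
        results = [
            fisher_enrichment(dual, s, universe, alpha=config.alpha, tail=config.tail)
            for s in sets
        ]
        top = rank_and_select(results, k_top=config.top_k, alpha=config.alpha)
        write_enrichment_table(results, outdir / "enrichment.tsv")
        by_name = {s.name: s for s in sets}
        sig = build_signature(dual, by_name[top[0]], by_name[top[1]],
                              name=config.signature_name)
        (outdir / "signature_genes.txt").write_text(
            "".join(f"{g}\n" for g in sorted(sig.members)))
        with open(outdir / "signature_provenance.json", "w") as fh:
            json.dump({"name": sig.name, "sets": list(sig.provenance),
                       "n_genes": len(sig.members)}, fh, indent=2)
        return {
            "signature": sig,
            "summary": {
                "n_gene_sets": len(sets),
                "n_significant": sum(r.significant for r in results),
                "selected_sets": list(top),
                "p_values": {r.set_name: r.p_value for r in results},
                "signature_size": len(sig.members),
            },
        }
    enrich_out = stage("enrich")(do_enrich)
    signature = enrich_out["signature"]
    manifest["results"]["enrich"] = enrich_out["summary"]

    def do_survive():
        expression = pd.read_csv(config.expression, sep="\t", index_col=0)
        clinical = pd.read_csv(config.clinical, sep="\t", index_col=0)
        scores, coverage = signature_score(expression, signature)
        cohort = clinical.join(scores, how="inner")
        groups = median_split(cohort["score"])
        cohort["group"] = groups
        cohort[["score", "group"]].to_csv(outdir / "scores.tsv", sep="\t")
        times = cohort[config.time_col].to_numpy()
        events = cohort[config.event_col].to_numpy()
        curves = {
            label: km_estimate(times[groups == label], events[groups == label])
            for label in ("high", "low") if (groups == label).any()
        }
        if len(curves) == 2:
            lr = logrank_test(times, events, groups.to_numpy())
        else:
            lr = None
        glms = [
            univariate_glm(cohort, feat)
            for feat in config.features if feat in cohort.columns
        ]
        write_survival_tsv(curves, outdir / "survival.tsv")
        write_glm_tsv(glms, outdir / "glm.tsv")
        if lr is not None:
            with open(outdir / "logrank.json", "w") as fh:
                json.dump({"chi_square": lr.chi_square, "df": lr.df,
                           "p_value": lr.p_value, "observed": lr.observed,
                           "expected": lr.expected}, fh, indent=2)
        plot_km(curves, lr, outdir / "km_plot.svg")
        plot_glm_coefficients(glms, outdir / "glm_plot.svg")
        return {
            "n_samples": int(len(cohort)),
            "signature_coverage": coverage,
            "n_high": int((groups == "high").sum()),
            "n_low": int((groups == "low").sum()),
            "logrank_chi_square": lr.chi_square if lr else None,
            "logrank_p": lr.p_value if lr else None,
            "glm": [
                {"feature": g.feature, "family": g.family, "estimate": g.estimate,
                 "std_error": g.std_error, "p_value": g.p_value}
                for g in glms
            ],
        }
    manifest["results"]["survive"] = stage("survive")(do_survive)

    blob = json.dumps(manifest, sort_keys=True, default=str)
    manifest["manifest_hash"] = hashlib.sha256(blob.encode()).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    if failed_marker.exists():
        failed_marker.unlink()
    log(f"[done] manifest written to {outdir / 'manifest.json'}")
    return manifest
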