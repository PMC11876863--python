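"""End-to-end pipeline: simulate -> normalize/DE -> TE/DTEG -> footprint QC
-> enrichment -> integration, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from contextlib import contextmanager
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, enrich, formats, integrate, normde, ribo, synthio

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    outdir: str = "ribomics_out"
    seed: int = 0
    n_genes: int = 500
    n_reps_per_condition: int = 3
    baseline_mean: float = 200.0
    nb_dispersion: float = 0.05
    effect_log2fc: float = 1.0
    q_threshold: float = 0.05
    count_pseudocount: float = 0.5
    te_min_mean: float = 1.0
    n_perm: int = 1000
    min_set_size: int = 10
    max_set_size: int = 500
    n_gene_sets: int = 10
    footprint_reads: int = 50000
    transcript_codons: int = 120
    pause_codon: str = "GCT"
    pause_multiplier: float = 2.0
    edge_trim: int = 5
    min_coverage: float = 0.5
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "te": True,
            "footprints": True,
            "enrich": True,
            "integrate": True,
        }
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage, write all outputs, and return the manifest.

    Any stage failure aborts with a :class:`PipelineError` naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool_version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }

    @contextmanager
    def stage(name: str):
        t0 = time.perf_counter()
        files: dict[str, Path] = {}
        try:
            yield files
        except Exception as exc:  # noqa: BLE001 - abort with stage context
            raise PipelineError(name, exc) from exc
        manifest["stages"][name] = {"wall_time_s": round(time.perf_counter() - t0, 3)}
        for key, path in files.items():
            manifest["outputs"][key] = {"path": str(path), "sha256": _sha256(path)}
        logger.info("stage %s done (%.2fs)", name, time.perf_counter() - t0)

    sim_cfg = synthio.SimulationConfig(
        n_genes=config.n_genes,
        n_reps_per_condition=config.n_reps_per_condition,
        baseline_mean=config.baseline_mean,
        nb_dispersion=config.nb_dispersion,
        effect_log2fc=config.effect_log2fc,
        seed=config.seed,
    )

    with stage("simulate") as files:
        data = synthio.generate_multiomics(sim_cfg)
        loc, drug, sets, meta = synthio.generate_annotation(
            data.truth, n_gene_sets=config.n_gene_sets, seed=config.seed
        )
        for name, mat in (("rna", data.rna), ("rpf", data.rpf), ("protein", data.protein)):
            files[f"{name}_matrix"] = outdir / f"{name}_counts.tsv"
            formats.write_matrix(mat.data, files[f"{name}_matrix"])
        files["conditions"] = outdir / "conditions.tsv"
        formats.write_conditions(data.rna.conditions, files["conditions"])
        files["truth"] = outdir / "truth.tsv"
        formats.write_table(data.truth, files["truth"])
        files["localisation"] = outdir / "localisation.tsv"
        formats.write_table(loc, files["localisation"])
        files["druggable"] = outdir / "druggable.tsv"
        formats.write_table(drug, files["druggable"])
        files["gene_sets"] = outdir / "gene_sets.gmt"
        formats.write_gmt(sets, files["gene_sets"])
        files["gene_sets_meta"] = outdir / "gene_sets_meta.json"
        files["gene_sets_meta"].write_text(json.dumps(meta))

    results: dict = {}
    if config.stages.get("de", True):
        with stage("de") as files:
            for name, mat, pc, complete in (
                ("rna", data.rna, config.count_pseudocount, False),
                ("rpf", data.rpf, config.count_pseudocount, False),
                ("protein", data.protein, 0.0, True),
            ):
                filtered = normde.filter_features(mat, require_complete=complete)
                norm = normde.normalize_matrix(
                    filtered, normde.compute_size_factors(filtered)
                )
                de = normde.welch_differential(
                    norm, threshold=config.q_threshold, pseudocount=pc
                )
                results[name] = (norm, de)
                files[f"{name}_de"] = outdir / f"{name}_de.tsv"
                formats.write_table(de, files[f"{name}_de"])

    if config.stages.get("te", True):
        with stage("te") as files:
            te = ribo.compute_te(
                results["rna"][0],
                results["rpf"][0],
                min_mean=config.te_min_mean,
                pseudocount=config.count_pseudocount,
            )
            te = ribo.differential_te(te, threshold=config.q_threshold)
            dteg = ribo.classify_dteg(results["rna"][1], te.stats)
            files["log2_te"] = outdir / "log2_te.tsv"
            formats.write_table(te.log2_te, files["log2_te"])
            files["te_stats"] = outdir / "te_stats.tsv"
            formats.write_table(te.stats, files["te_stats"])
            files["dteg"] = outdir / "dteg.tsv"
            formats.write_table(dteg, files["dteg"])

    if config.stages.get("footprints", True):
        with stage("footprints") as files:
            model = synthio.generate_transcript(
                "TX0001", config.transcript_codons, seed=config.seed
            )
            fp_cfg = synthio.FootprintSimConfig(
                n_reads=config.footprint_reads,
                pause_multipliers={config.pause_codon: config.pause_multiplier},
                seed=config.seed,
            )
            fp = synthio.generate_footprints(model, fp_cfg)
            models = {model.transcript_id: model}
            assigned, dropped = ribo.assign_psites(fp, models)
            qc = ribo.riboseq_qc(assigned, models)
            occupancy = ribo.codon_occupancy(
                assigned, models, edge_trim=config.edge_trim, min_coverage=config.min_coverage
            )
            pauses = ribo.pause_scores(
                assigned, models, edge_trim=config.edge_trim, min_coverage=config.min_coverage
            )
            files["footprints"] = outdir / "footprints.tsv"
            formats.write_footprints(fp, files["footprints"])
            files["models"] = outdir / "transcript_models.tsv"
            formats.write_transcript_models(models, files["models"])
            files["fasta"] = outdir / "transcripts.fa"
            formats.write_fasta({model.transcript_id: model.sequence}, files["fasta"])
            files["qc"] = outdir / "riboseq_qc.json"
            files["qc"].write_text(
                json.dumps(
                    {
                        "length_histogram": qc.length_histogram,
                        "region_fractions": qc.region_fractions,
                        "n_reads": qc.n_reads,
                        "dropped": dropped,
                    },
                    indent=1,
                )
            )
            files["codon_occupancy"] = outdir / "codon_occupancy.tsv"
            formats.write_table(occupancy, files["codon_occupancy"])
            files["pause_scores"] = outdir / "pause_scores.tsv"
            pauses.to_csv(files["pause_scores"], sep="\t", index=False)

    if config.stages.get("enrich", True):
        with stage("enrich") as files:
            rna_de = results["rna"][1]
            ranked = enrich.rank_genes(rna_de["log2fc"])
            gsea = enrich.preranked_gsea(ranked, sets, n_perm=config.n_perm, seed=config.seed)
            hits = list(rna_de.index[rna_de["significant"]])
            ora = enrich.hypergeometric_ora(
                hits,
                list(rna_de.index),
                sets,
                min_size=config.min_set_size,
                max_size=config.max_set_size,
                threshold=config.q_threshold,
            )
            files["gsea"] = outdir / "gsea.tsv"
            formats.write_table(gsea, files["gsea"])
            files["ora"] = outdir / "ora.tsv"
            formats.write_table(ora, files["ora"])

    if config.stages.get("integrate", True):
        with stage("integrate") as files:
            records = integrate.stratify_five_groups(results["rna"][1], results["protein"][1])
            records = integrate.assign_localisation(records, loc["localisation"], default="IC")
            summary = integrate.subcategory_proportions(records)
            drugs = integrate.druggable_overlap(results["protein"][1], drug, config.q_threshold)
            files["concordance"] = outdir / "concordance.tsv"
            formats.write_table(records, files["concordance"])
            files["group_summary"] = outdir / "group_summary.tsv"
            formats.write_table(summary, files["group_summary"], index_label="group")
            files["druggable_summary"] = outdir / "druggable_summary.json"
            files["druggable_summary"].write_text(json.dumps(asdict(drugs), indent=1))
            sig = results["rna"][1].index[results["rna"][1]["significant"]]
            if len(sig) >= 2:
                log2 = np.log2(results["rna"][0].data.loc[sig].to_numpy() + 0.5)
                cluster = integrate.hierarchical_cluster(log2, metric="euclidean")
                files["linkage"] = outdir / "linkage.tsv"
                with open(files["linkage"], "w", encoding="utf-8") as fh:
                    fh.write("left\tright\theight\tsize\n")
                    for left, right, height, size in cluster.linkage:
                        fh.write(f"{int(left)}\t{int(right)}\t{height:.10g}\t{int(size)}\n")

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline complete: %d outputs in %s", len(manifest["outputs"]), outdir)
    return manifest
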