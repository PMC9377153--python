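"""End-to-end pipeline orchestration with a flat config and a run manifest.

Stages, in dependency order: simulate -> extract -> discover -> type_dmr ->
signature -> train -> score -> evaluate.  Every stage writes its outputs
under the configured output directory; the manifest records parameters and
SHA-256 hashes of each output, so a rerun with the same config and seed is
verifiably identical for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import io as uio
from .dmr import DMRDiscovery
from .entropy import EntropyDMRTyper
from .evaluation import estimate_lod, roc_auc
from .haplotypes import QCParams, amplicons_from_bed, build_haplotype_table, parse_sam
from .models import blcas_model, score_samples, ucas_model
from .signature import HaplotypeSignature
from .simulate import (
    SimulationConfig,
    build_reference,
    simulate_beta_matrix,
    simulate_cohort,
    simulate_dilution_series,
    simulate_reads,
    write_amplicon_bed,
    write_fasta,
    write_sam,
)

logger = logging.getLogger("urometh")

STAGES = ("simulate", "extract", "discover", "type_dmr", "signature",
          "train", "score", "evaluate")


@dataclass
class PipelineConfig:
    """Flat pipeline configuration with assay-default thresholds."""

    outdir: str = "urometh_run"
    seed: int = 0
    # simulation
    n_amplicons: int = 20
    n_t1dmr: int = 10
    n_t2dmr: int = 10
    coverage: int = 2000
    entropy_contrast: float = 2.0
    replicates_per_fraction: int = 5
    n_hg: int = 16
    n_lg: int = 16
    n_urine: int = 12
    read_level_samples: int = 2     # samples simulated down to SAM reads
    read_level_coverage: int = 200
    # DMR discovery
    dml_p: float = 0.01
    dml_delta: float = 0.1
    merge_gap: int = 100
    cbs_alpha: float = 0.01
    cbs_n_perm: int = 1000
    kmeans_k: int = 3
    # haplotype QC
    min_conversion: float = 0.99
    min_mapq: int = 30
    # typing / signature
    typing_alpha: float = 0.05
    class_alpha: float = 0.001
    class_min_freq: float = 0.10
    min_reads: int = 20
    # scoring / evaluation
    ucas_cutoff: float = 0.42
    blcas_cutoff: float = 0.52
    lod_alpha: float = 0.05

    def validate(self) -> None:
        checks = [
            (self.merge_gap >= 0, "merge_gap must be >= 0"),
            (0 < self.dml_p < 1, "dml_p must be in (0, 1)"),
            (0 <= self.dml_delta <= 1, "dml_delta must be in [0, 1]"),
            (0 < self.cbs_alpha < 1, "cbs_alpha must be in (0, 1)"),
            (self.cbs_n_perm > 0, "cbs_n_perm must be positive"),
            (0 < self.typing_alpha < 1, "typing_alpha must be in (0, 1)"),
            (0 < self.class_alpha < 1, "class_alpha must be in (0, 1)"),
            (0 <= self.class_min_freq <= 1, "class_min_freq must be in [0, 1]"),
            (0 < self.min_conversion <= 1, "min_conversion must be in (0, 1]"),
            (self.min_mapq >= 0, "min_mapq must be >= 0"),
            (0 < self.lod_alpha < 1, "lod_alpha must be in (0, 1)"),
            (self.coverage >= 1, "coverage must be >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(
            n_amplicons=self.n_amplicons, n_t1dmr=self.n_t1dmr,
            n_t2dmr=self.n_t2dmr, coverage=self.coverage,
            entropy_contrast=self.entropy_contrast,
            replicates_per_fraction=self.replicates_per_fraction, seed=self.seed,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages on a synthetic cohort; returns the run manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}}
    sim = config.sim_config()

    def record(stage: str, paths: list[Path]) -> None:
        manifest["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in paths}
        }
        logger.info("stage %s: wrote %s", stage, [p.name for p in paths])

    # --- simulate ----------------------------------------------------------
    cohort = simulate_cohort(sim, config.n_hg, config.n_lg, config.n_urine)
    dilution = simulate_dilution_series(sim)
    reference = build_reference(sim)
    seqs, amplicons = reference
    paths = []
    p = out / "cohort_haplotypes.tsv"; uio.write_haplotype_table(cohort.haplotype_table, p); paths.append(p)
    p = out / "cohort_truth.tsv"; cohort.truth.to_csv(p, sep="\t"); paths.append(p)
    p = out / "dilution_haplotypes.tsv"; uio.write_haplotype_table(dilution.haplotype_table, p); paths.append(p)
    p = out / "dilution_truth.tsv"; dilution.truth.to_csv(p, sep="\t"); paths.append(p)
    p = out / "reference.fa"; write_fasta(seqs, p); paths.append(p)
    p = out / "amplicons.bed"; write_amplicon_bed(amplicons, p); paths.append(p)
    sam_samples = cohort.truth.index[: config.read_level_samples]
    read_cfg = dataclasses.replace(sim, coverage=config.read_level_coverage)
    for sid in sam_samples:
        cls = cohort.truth.loc[sid, "class"]
        records, _, _ = simulate_reads(cohort.profiles[cls], read_cfg, sid, reference)
        p = out / f"{sid}.sam"; write_sam(records, seqs, p); paths.append(p)
    beta, beta_labels, truth_dmrs, peaks = simulate_beta_matrix(
        n_per_group=10, n_cpg=200, planted_dmrs=[(40, 50), (120, 132)],
        effect=0.3, seed=config.seed,
    )
    p = out / "beta_matrix.tsv"; uio.write_beta_matrix(beta, p); paths.append(p)
    p = out / "beta_labels.tsv"; uio.write_labels(beta_labels, p, "group"); paths.append(p)
    p = out / "peaks.bed"; uio.write_bed(peaks, p); paths.append(p)
    record("simulate", paths)

    # --- extract (read-level samples through the full QC path) -------------
    amp_defs = amplicons_from_bed(out / "amplicons.bed", out / "reference.fa")
    qc = QCParams(min_conversion=config.min_conversion, min_mapq=config.min_mapq)
    tables = []
    for sid in sam_samples:
        reads = parse_sam(out / f"{sid}.sam", amp_defs, out / "reference.fa")
        table, _ = build_haplotype_table(reads, amp_defs, sid, qc)
        tables.append(table)
    extracted = pd.concat(tables, ignore_index=True)
    p = out / "extracted_haplotypes.tsv"; uio.write_haplotype_table(extracted, p)
    record("extract", [p])

    # --- discover ----------------------------------------------------------
    disc = DMRDiscovery(p_thresh=config.dml_p, delta_thresh=config.dml_delta,
                        max_gap=config.merge_gap, alpha=config.cbs_alpha,
                        n_perm=config.cbs_n_perm, k=config.kmeans_k,
                        random_state=config.seed)
    disc.fit(beta, beta_labels, pathology=beta_labels, peaks=peaks)
    p = out / "dmr_candidates.bed"
    uio.write_bed(disc.filtered_candidates_, p, extra_cols=["mean"])
    record("discover", [p])

    # --- type_dmr ----------------------------------------------------------
    tumour = cohort.truth[cohort.truth["class"] != "URINE"]
    typer = EntropyDMRTyper(min_reads=config.min_reads, alpha=config.typing_alpha)
    typer.fit(
        cohort.haplotype_table[cohort.haplotype_table["sample"].isin(tumour.index)],
        tumour["class"],
    )
    p1 = out / "entropy_matrix.tsv"; typer.entropy_.to_csv(p1, sep="\t")
    p2 = out / "dmr_type_calls.tsv"; typer.calls_.to_csv(p2, sep="\t")
    record("type_dmr", [p1, p2])

    # --- signature ---------------------------------------------------------
    sig = HaplotypeSignature(alpha=config.class_alpha, min_freq=config.class_min_freq)
    sig.fit(cohort.haplotype_table, cohort.truth["class"])
    features = sig.transform(cohort.haplotype_table)
    dil_features = sig.transform(dilution.haplotype_table)
    p1 = out / "haplotype_classes.tsv"; sig.assignment_.to_csv(p1, sep="\t")
    p2 = out / "reference_profiles.tsv"; sig.reference_profiles_.to_csv(p2, sep="\t")
    p3 = out / "cohort_features.tsv"; features.to_csv(p3, sep="\t")
    p4 = out / "dilution_features.tsv"; dil_features.to_csv(p4, sep="\t")
    record("signature", [p1, p2, p3, p4])

    # --- train -------------------------------------------------------------
    is_cancer = (cohort.truth["class"] != "URINE").astype(int)
    ucas = ucas_model(config.ucas_cutoff).fit(features, is_cancer.reindex(features.index))
    tissue = features.loc[cohort.truth["class"] != "URINE"]
    is_hg = (cohort.truth.loc[tissue.index, "class"] == "HG").astype(int)
    blcas = blcas_model(config.blcas_cutoff).fit(tissue, is_hg)
    p1 = out / "ucas_model.txt"; ucas.to_text(p1)
    p2 = out / "blcas_model.txt"; blcas.to_text(p2)
    record("train", [p1, p2])

    # --- score -------------------------------------------------------------
    scores = score_samples(ucas, blcas, features)
    dil_scores = score_samples(ucas, blcas, dil_features)
    p1 = out / "cohort_scores.tsv"; scores.to_csv(p1, sep="\t")
    p2 = out / "dilution_scores.tsv"; dil_scores.to_csv(p2, sep="\t")
    record("score", [p1, p2])

    # --- evaluate ----------------------------------------------------------
    _, auc = roc_auc(scores["ucas_score"], is_cancer.reindex(scores.index))
    lod = estimate_lod(dil_scores["ucas_score"],
                       dilution.truth.reindex(dil_scores.index)["fraction"],
                       alpha=config.lod_alpha)
    summary = {
        "ucas_auc_in_sample": auc,
        "lod_fraction": lod.lod,
        "lod_percent": None if lod.lod is None else 100 * lod.lod,
        "lod_reached": lod.reached,
        "n_core_dmrs": int(len(disc.core_dmrs_)) if disc.core_dmrs_ is not None else None,
        "n_t2_called": int((typer.dmr_types_ == "T2").sum()),
    }
    p = out / "evaluation.json"
    p.write_text(json.dumps(summary, indent=2))
    record("evaluate", [p])

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
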