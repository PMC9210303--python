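"""End-to-end orchestration: simulate/ingest, consensus, QC, ordination,
differential testing, annotation and the peak-to-gene overlay.

A run is driven by a single :class:`RunConfig` (loadable from YAML);
every stage writes its table under the output directory and the run
finishes with a manifest listing each artifact with a checksum plus the
counts surviving every filtering stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as ann
from . import differential as diff
from . import intervals as iv
from . import ordination as ordn
from . import qc as qcmod
from . import simulate as sim

__all__ = ["RunConfig", "run_all"]

log = logging.getLogger("peakforge")


@dataclass
class RunConfig:
    out_dir: str = "peakforge_run"
    seed: int = 0
    merge_gap: int = 10
    min_support: int = 3
    fdr: float = 0.10
    lfc_min: float = 2.0
    overlay_window: int = 10000
    per_sample_depth: int = 8000
    nmds_components: int = 3
    de_timepoint: str = "D90"
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.merge_gap < 0 or self.min_support < 1:
            raise ValueError("merge_gap must be >=0 and min_support >=1")
        if not (0 < self.fdr < 1) or self.overlay_window <= 0:
            raise ValueError("fdr must be in (0,1) and overlay_window positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Run the full synthetic analysis; returns the output manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stage_counts: dict[str, int] = {}
    artifacts: dict[str, Path] = {}
    try:
        sim_cfg = sim.SimulationConfig(seed=config.seed, **config.simulation)
        log.info("simulating inputs (seed=%d)", config.seed)
        genome = sim.make_annotation(sim_cfg)
        design = sim.make_design_table(sim_cfg)
        calls = sim.make_peak_calls(genome, sim_cfg, design, merge_gap=config.merge_gap)
        frags_raw = sim.make_fragments(
            genome, sim_cfg, config.per_sample_depth, list(design.index),
            calls=calls, design=design,
        )
        ann.write_annotation(genome.genes, out / "annotation.gtf")
        design.to_csv(out / "design.tsv", sep="\t")
        artifacts["annotation"] = out / "annotation.gtf"
        artifacts["design"] = out / "design.tsv"
        n_input_peaks = sum(len(v) for v in calls.by_sample.values())
        stage_counts["input_peak_calls"] = n_input_peaks
        stage_counts["raw_fragments"] = len(frags_raw)

        # --- fragment filtering and QC -----------------------------------
        frags = qcmod.filter_fragments(frags_raw)
        stage_counts["filtered_fragments"] = len(frags)
        log.info("fragments: %d raw -> %d after filtering",
                 len(frags_raw), len(frags))
        report = qcmod.qc_report(
            frags, calls.by_sample, genome.tss_list(), genome.chrom_sizes
        )
        report.to_csv(out / "qc_report.tsv", sep="\t")
        with (out / "qc_report.json").open("w") as fh:
            json.dump(json.loads(report.to_json(orient="index")), fh, indent=1)
        artifacts["qc_report"] = out / "qc_report.tsv"

        # --- consensus ----------------------------------------------------
        all_calls = [p for ivs in calls.by_sample.values() for p in ivs]
        merged = iv.merge_with_support(all_calls, merge_gap=config.merge_gap)
        consensus = iv.filter_support(merged, min_support=config.min_support)
        stage_counts["merged_peaks"] = len(merged)
        stage_counts["consensus_peaks"] = len(consensus)
        log.info("consensus: %d calls -> %d merged -> %d with support >= %d",
                 n_input_peaks, len(merged), len(consensus), config.min_support)
        iv.write_consensus(consensus, out / "consensus.bed")
        artifacts["consensus"] = out / "consensus.bed"

        # --- counting and ordination ---------------------------------------
        cm = iv.count_fragments(consensus, frags)
        cm.counts.to_csv(out / "peak_counts.tsv", sep="\t")
        artifacts["peak_counts"] = out / "peak_counts.tsv"
        empty = len(consensus) == 0
        if not empty:
            norm = ordn.normalize_counts(cm)
            dist = ordn.manhattan_distance(norm)
            nm = ordn.nmds(dist, k=config.nmds_components, seed=config.seed)
            nm.frame().to_csv(out / "nmds_coords.tsv", sep="\t")
            log.info("NMDS stress %.4f after %d iterations", nm.stress,
                     nm.n_iterations)
        else:
            pd.DataFrame(columns=[f"MDS{i+1}" for i in range(config.nmds_components)]
                         ).to_csv(out / "nmds_coords.tsv", sep="\t")
        artifacts["nmds"] = out / "nmds_coords.tsv"

        # --- differential peaks --------------------------------------------
        dp_cols = ["lrt_stat", "df", "pvalue", "padj", "max_abs_log2fc",
                   "significant", "converged"]
        if not empty:
            dp = diff.diff_peaks(cm, design, fdr=config.fdr, lfc_min=config.lfc_min)
        else:
            dp = pd.DataFrame(columns=dp_cols)
        dp.to_csv(out / "diff_peaks.tsv", sep="\t")
        artifacts["diff_peaks"] = out / "diff_peaks.tsv"
        stage_counts["tested_peaks"] = int(dp["pvalue"].notna().sum()) if not empty else 0
        stage_counts["significant_peaks"] = int(dp["significant"].sum()) if not empty else 0
        log.info("differential peaks: %d significant of %d tested",
                 stage_counts["significant_peaks"], stage_counts["tested_peaks"])

        # --- annotation -----------------------------------------------------
        peak_ivs = [p.as_interval() for p in consensus]
        feats = ann.classify_peaks(peak_ivs, genome.genes)
        if feats:
            summary = ann.summarize_features(feats)
        else:
            summary = pd.DataFrame(columns=["count", "percent", "percent_printed"])
        summary.to_csv(out / "feature_summary.tsv", sep="\t")
        artifacts["feature_summary"] = out / "feature_summary.tsv"
        sig_names = set(dp.index[dp["significant"]]) if not empty else set()
        sig_feats = [f for pk, f in zip(consensus, feats) if pk.name in sig_names]
        if sig_feats:
            coarse = pd.Series(
                [ann.table3_category(f.category) for f in sig_feats]
            ).value_counts()
            ann.summarize_features(coarse.to_dict()).to_csv(
                out / "diff_peak_features.tsv", sep="\t"
            )
            artifacts["diff_peak_features"] = out / "diff_peak_features.tsv"

        # --- expression: PCA + day-90 DE ------------------------------------
        em, _ = sim.make_expression_matrix(genome, design, sim_cfg)
        em.counts.to_csv(out / "expression_counts.tsv", sep="\t")
        pc = ordn.pca(ordn.normalize_counts(em))
        pc.scores.to_csv(out / "pca_scores.tsv", sep="\t")
        artifacts["pca"] = out / "pca_scores.tsv"
        dg = diff.diff_genes_day90(em, design, fdr=config.fdr,
                                   timepoint=config.de_timepoint)
        dg.to_csv(out / "diff_genes_day90.tsv", sep="\t")
        artifacts["diff_genes"] = out / "diff_genes_day90.tsv"
        stage_counts["significant_genes"] = int(dg["significant"].sum())

        # --- size-specific peaks + overlay ----------------------------------
        d90 = design[design["timepoint"].astype(str) == config.de_timepoint]
        by_class: dict[str, list] = {}
        for size, grp in d90.groupby("size", observed=True):
            pooled = [p for s in grp.index for p in calls.by_sample[s]]
            by_class[str(size)] = [
                m.as_interval()
                for m in iv.merge_with_support(pooled, merge_gap=config.merge_gap)
            ]
        split = iv.separate_size_specific(by_class)
        peaks_by_spec = {"shared": split.shared[next(iter(by_class))]}
        for size, specific in split.specific.items():
            peaks_by_spec[f"{size}-only"] = specific
        de_genes = list(dg.index[dg["significant"]])
        overlay = ann.overlay_table(de_genes, peaks_by_spec, genome.genes,
                                    window=config.overlay_window)
        overlay.to_csv(out / "overlay.tsv", sep="\t", index=False)
        artifacts["overlay"] = out / "overlay.tsv"
        stage_counts["overlay_records"] = len(overlay)

        manifest = {
            "config": asdict(config),
            "stage_counts": stage_counts,
            "artifacts": {
                name: {"path": str(p), "sha256": _sha256(p)}
                for name, p in artifacts.items()
            },
        }
        with (out / "manifest.json").open("w") as fh:
            json.dump(manifest, fh, indent=1)
        log.info("run complete: %d artifacts", len(artifacts))
        return manifest
    finally:
        log.removeHandler(handler)
        handler.close()
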