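"""End-to-end orchestration: simulate -> io -> qc -> scan -> curve -> candidate.

A :class:`RunConfig` (fully serializable; YAML round-trippable) selects
stages and carries every threshold and seed. ``run_pipeline`` writes a
fixed artifact set under the output directory:

    cohort.bed/.bim/.fam, pheno.tsv       (simulate)
    qc_report.tsv, qc_summary.json        (qc)
    scan.tsv, scan_summary.json           (gwis) [+ PNGs with plots=True]
    cascade.json, moderation.tsv          (curve)
    candidate.json                        (candidate)
    manifest.json                         (always; config + versions + counts)

The manifest contains no timestamps, so a rerun with the same config
reproduces every deterministic output byte-for-byte. A stage failure
aborts with a stage-labelled error and leaves a FAILED marker file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import pandas as pd
import yaml

from . import __version__
from .candidate import run_candidate_analysis
from .core import GenotypeMatrix, validate_cohort
from .curvilinear import demographic_moderation, fit_cascade
from .exceptions import GxescanError
from .genio import read_bed, read_pheno, write_bed, write_pheno
from .qc import QCThresholds, apply_qc
from .scan import dichotomize_env, genome_scan, save_plots, scan_summary, write_scan_tsv
from .simulate import SimulationConfig, simulate_cohort

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "qc", "gwis", "curve", "candidate")


@dataclass
class RunConfig:
    stages: List[str] = field(default_factory=lambda: list(ALL_STAGES))
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc_thresholds: QCThresholds = field(default_factory=QCThresholds)
    tail_q: float = 0.27
    candidate_snp: Optional[str] = None  # default: the simulated causal SNP
    genotype_prefix: Optional[str] = None  # read instead of simulating
    pheno_path: Optional[str] = None
    split_seed: int = 0
    plots: bool = False

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise GxescanError(f"unknown stage(s) {unknown}; choose from {ALL_STAGES}")
        if "simulate" not in self.stages and not (
            self.genotype_prefix and self.pheno_path
        ):
            raise GxescanError(
                "without the simulate stage, genotype_prefix and pheno_path are required"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("simulation"), dict):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if isinstance(d.get("qc_thresholds"), dict):
            d["qc_thresholds"] = QCThresholds(**d["qc_thresholds"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the selected stages; returns the manifest dict."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    manifest: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }
    gm: Optional[GenotypeMatrix] = None
    cohort: Optional[pd.DataFrame] = None
    stage = "load"
    t0 = time.perf_counter()
    try:
        if "simulate" in config.stages:
            stage = "simulate"
            log.info("[simulate] seed=%d", config.simulation.seed)
            gm, cohort = simulate_cohort(config.simulation)
            write_bed(
                gm, outdir / "cohort", sex=cohort.set_index("sample_id")["sex"]
            )
            write_pheno(cohort, outdir / "pheno.tsv")
            manifest["stages"]["simulate"] = {
                "n_samples": gm.n_samples,
                "n_snps": gm.n_snps,
                "seed": config.simulation.seed,
            }
        else:
            stage = "load"
            gm, skeleton = read_bed(config.genotype_prefix)
            cohort = read_pheno(config.pheno_path)
            manifest["stages"]["load"] = {
                "n_samples": gm.n_samples,
                "n_snps": gm.n_snps,
            }
        validate_cohort(cohort)

        if "qc" in config.stages:
            stage = "qc"
            gm, report = apply_qc(gm, config.qc_thresholds)
            report.to_tsv(outdir / "qc_report.tsv")
            _write_json(report.summary, outdir / "qc_summary.json")
            keep = cohort["sample_id"].isin(gm.sample_ids)
            cohort = cohort[keep].reset_index(drop=True)
            manifest["stages"]["qc"] = report.summary

        if "gwis" in config.stages:
            stage = "gwis"
            assignment = dichotomize_env(cohort, q=config.tail_q)
            records = genome_scan(gm, cohort, assignment)
            write_scan_tsv(records, outdir / "scan.tsv")
            summary = scan_summary(records)
            summary["lower_cut"] = assignment.lower_cut
            summary["upper_cut"] = assignment.upper_cut
            summary["stratum_counts"] = assignment.counts()
            _write_json(summary, outdir / "scan_summary.json")
            if config.plots:
                save_plots(records, outdir / "manhattan.png", outdir / "qq.png")
            manifest["stages"]["gwis"] = {
                k: summary[k]
                for k in ("n_snps_tested", "n_significant", "n_suggestive", "lambda_gc")
            }

        if "curve" in config.stages:
            stage = "curve"
            cascade = fit_cascade(cohort)
            _write_json(cascade.to_dict(), outdir / "cascade.json")
            moderation = demographic_moderation(
                cohort, degree=cascade.selected_degree
            )
            moderation.to_csv(outdir / "moderation.tsv", sep="\t", index=False)
            manifest["stages"]["curve"] = {
                "selected_degree": cascade.selected_degree,
                "n": cascade.fits[1].n,
            }

        if "candidate" in config.stages:
            stage = "candidate"
            snp = config.candidate_snp or config.simulation.causal_snp_id
            dosage = gm.dosage(snp)
            idx = cohort.set_index("sample_id")
            aligned = idx.reindex(gm.sample_ids).reset_index()
            result = run_candidate_analysis(
                aligned,
                dosage,
                mode=config.simulation.genotype_coding_mode,
                split_seed=config.split_seed,
            )
            _write_json(result.to_dict(), outdir / "candidate.json")
            manifest["stages"]["candidate"] = {
                "snp": snp,
                "n": result.n,
                "replicated": bool(
                    result.split_half.replicated if result.split_half else False
                ),
            }
    except Exception as exc:
        failed_marker.write_text(f"stage={stage}: {exc}\n")
        raise GxescanError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    log.info("pipeline finished in %.1f s", time.perf_counter() - t0)
    _write_json(manifest, outdir / "manifest.json")
    return manifest
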