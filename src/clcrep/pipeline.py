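"""End-to-end orchestration: ingest → pair → clonotype → diversity → SHM → selection.

The pipeline consumes an annotated rearrangement table (AIRR TSV or 10x
CSV), applies the exactly-one-heavy/one-light pairing filter, clusters
clonotypes, optionally down-samples (with mandatory seed) and re-clusters,
computes diversity statistics and the light-chain mutation profile, and
ranks clones for expression.  Every stage writes a TSV, the run writes one
JSON report echoing all thresholds and seeds, and a MANIFEST lists each
output with a content hash so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import clonotyping, diversity, germlines as gl, io as airr_io, shm
from .errors import ClcrepError, ConfigurationError

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    input_path: str
    output_dir: str
    dialect: str = "airr-tsv"
    clonotype_threshold: float = 0.8
    min_consensus_size: int = 5
    selection_k: int = 48
    downsample_n: int | None = None
    downsample_seed: int | None = None
    light_v_gene: str = "IGKV10-96"
    numbering_path: str | None = None
    regions_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not Path(self.input_path).exists():
            raise ConfigurationError(f"input file not found: {self.input_path}")
        if self.downsample_n is not None and self.downsample_seed is None:
            raise ConfigurationError("downsample_n requires downsample_seed")


def validate_inputs(config: PipelineConfig) -> dict:
    """Schema checks on the configured inputs; fatal errors vs warnings."""
    errors: list[str] = []
    warnings: list[str] = []
    path = Path(config.input_path)
    if not path.exists():
        errors.append(f"input file not found: {path}")
        return {"errors": errors, "warnings": warnings}
    try:
        records = airr_io.read_rearrangements(path, config.dialect)
    except ClcrepError as exc:
        errors.append(str(exc))
        return {"errors": errors, "warnings": warnings}
    if records.empty:
        errors.append(f"{path}: no usable records")
    skipped = records.attrs.get("n_skipped_locus", 0)
    if skipped:
        warnings.append(f"{path}: {skipped} non-IG record(s) skipped")
    n_heavy = int((records["locus"] == "IGH").sum())
    n_light = int(records["locus"].isin(["IGK", "IGL"]).sum())
    if n_heavy == 0 or n_light == 0:
        warnings.append(f"{path}: {n_heavy} heavy / {n_light} light records")
    return {"errors": errors, "warnings": warnings}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the JSON-serializable report."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    report: dict = {
        "config": dataclasses.asdict(config),
        "stages": {},
        "complete": False,
    }

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out_dir / name
        df.to_csv(path, sep="\t", index=False)
        outputs.append(path)

    def finish(failed_stage: str | None = None, reason: str | None = None) -> dict:
        report["complete"] = failed_stage is None
        if failed_stage is not None:
            report["failed_stage"] = failed_stage
            report["failure_reason"] = reason
        report_path = out_dir / "report.json"
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
        outputs.append(report_path)
        manifest = {
            str(p.name): _sha256(p) for p in outputs
        }
        manifest["__complete__"] = report["complete"]
        (out_dir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return report

    stage = "ingest"
    try:
        records = airr_io.read_rearrangements(config.input_path, config.dialect)
        report["stages"]["ingest"] = {
            "n_records": len(records),
            "n_skipped_locus": records.attrs.get("n_skipped_locus", 0),
        }

        stage = "pair"
        paired, pairing = airr_io.pair_cells(records)
        report["stages"]["pair"] = dataclasses.asdict(pairing)

        stage = "downsample"
        if config.downsample_n is not None:
            paired = diversity.downsample(paired, config.downsample_n, config.downsample_seed)
            report["stages"]["downsample"] = {
                "n": config.downsample_n, "seed": config.downsample_seed,
            }

        stage = "clonotype"
        clonotypes, membership = clonotyping.assign_clonotypes(
            paired, config.clonotype_threshold
        )
        emit("clonotypes.tsv", clonotypes)
        emit("membership.tsv", membership)
        report["stages"]["clonotype"] = {
            "threshold": config.clonotype_threshold,
            "n_clonotypes": len(clonotypes),
            "n_cells": int(clonotypes["size"].sum()),
        }

        stage = "diversity"
        sizes = clonotypes["size"].to_numpy()
        summary = diversity.summarize(sizes)
        heavy_usage = membership["heavy_v_call"].value_counts().sort_index()
        light_usage = membership["light_v_call"].value_counts().sort_index()
        emit("heavy_usage.tsv", heavy_usage.rename("count").reset_index())
        emit("light_usage.tsv", light_usage.rename("count").reset_index())
        report["stages"]["diversity"] = {
            "clonotype": summary.to_dict(),
            "gini_heavy_usage": diversity.gini(heavy_usage.to_numpy()),
            "dominant_light_v": str(light_usage.idxmax()),
            "dominant_light_v_fraction": float(light_usage.max() / light_usage.sum()),
        }

        stage = "shm_profile"
        germ = gl.default_germlines()
        lights = membership[membership["light_v_call"] == config.light_v_gene]
        if len(lights):
            prof = shm.profile(lights["light_sequence_aa"].tolist(), germ)
            emit("shm_profile.tsv", prof.to_frame())
            report["stages"]["shm_profile"] = {
                "n_records": prof.n_records,
                "n_rejected": prof.n_rejected,
                "mean_mutations": prof.mean_mutations,
                "no_cdr_mutation_fraction": prof.no_cdr_mutation_fraction,
                "region_any_mutation_fraction": prof.region_any_mutation_fraction,
                "hotspots_top5": shm.hotspot_report(prof, 5),
            }
        else:
            report["stages"]["shm_profile"] = {
                "n_records": 0,
                "note": f"no light chains assigned to {config.light_v_gene}",
            }

        stage = "selection"
        scores, _ = clonotyping.score_members(
            clonotypes, membership, config.min_consensus_size
        )
        selection = clonotyping.select_clones(scores, config.selection_k)
        emit("selection.tsv", selection)
        report["stages"]["selection"] = {
            "k": config.selection_k,
            "n_selected": len(selection),
            "n_eligible": int((scores["liabilities"] == "").sum()) if len(scores) else 0,
        }
    except ClcrepError as exc:
        logger.error("stage %s failed: %s", stage, exc)
        return finish(failed_stage=stage, reason=str(exc))

    return finish()
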