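"""End-to-end orchestration of the dual-branch screening workflow.

Stage order: read -> IPC QC -> (delta branch: calibrate -> filter ->
delta-Ct | raw branch: filter only) -> per comparison: moderated t +
permutation sampling p -> candidate selection -> branch intersection ->
group intersection -> (optional) target mapping + term enrichment.  One TSV
is written per analysis box plus a JSON manifest sufficient to re-execute
the run (inputs, parameters, per-task seeds, file list, stage counts).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .calibration import calibrate, filter_expressed, ipc_qc
from .containers import CtTable, SampleSheet
from .differential import (
    CandidateSet,
    GroupComparison,
    build_diff_table,
    fit_moderated_t,
    intersect_candidates,
    sampling_p,
    select_candidates,
    write_diff_table,
)
from .enrichment import enrich_terms, map_targets, write_enrichment
from .io import read_ct_table, read_sample_sheet, read_target_map, read_term_map
from .normalization import DEFAULT_REFERENCES, delta_ct, make_reference_set
from .normalization import NormalizedTable

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class PipelineConfig:
    """Everything a run needs; ``seed`` is mandatory."""

    ct_path: str
    samples_path: str
    out_dir: str
    seed: int
    layout: str = "wide"
    branches: tuple[str, ...] = ("raw", "ipc_delta_ct")
    comparisons: tuple[str, ...] = ("normal:mild", "normal:severe")
    B: int = 10_000
    alpha: float = 0.05
    references: tuple[str, ...] = DEFAULT_REFERENCES
    panel_policy: str = "panel_I_only"
    target_map_path: str | None = None
    term_map_path: str | None = None
    enrichment_variant: str = "hypergeometric"
    smoothing: bool = False
    qc_override: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        blob = yaml.safe_load(Path(path).read_text())
        for key in ("branches", "comparisons", "references"):
            if key in blob and isinstance(blob[key], list):
                blob[key] = tuple(blob[key])
        return cls(**blob)


def _task_seed(base_seed: int, branch: str, comparison: str) -> int:
    """Deterministic per-task seed, independent of execution order."""
    h = 0
    for ch in f"{branch}|{comparison}":
        h = (h * 131 + ord(ch)) % 1_000_000_007
    return int((base_seed * 2_654_435_761 + h) % (2**31 - 1))


def _targets_only(values_index, table: CtTable):
    return [f for f in values_index if table.roles.get(f) == "target"]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns (and writes) the run manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()},
        "files": [],
        "counts": {},
        "seeds": {},
    }

    def stage(name):
        logger.info("stage: %s", name)
        return name

    try:
        stage("read")
        table = read_ct_table(config.ct_path, layout=config.layout)
        sheet = read_sample_sheet(config.samples_path)
        sheet.check_covers(table)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("read", str(exc)) from exc

    try:
        stage("qc")
        report = ipc_qc(table)
        manifest["counts"]["ipc_sd"] = report.ipc_sd
        manifest["counts"]["qc_passed"] = report.passed
        qc_path = out_dir / "qc.json"
        qc_path.write_text(
            json.dumps(
                {
                    "plate_ipc_means": report.plate_ipc_means,
                    "global_mean": report.global_mean,
                    "calibration_factors": report.factors,
                    "ipc_sd": report.ipc_sd,
                    "passed": report.passed,
                    "threshold": report.threshold,
                },
                indent=2,
            )
        )
        manifest["files"].append(str(qc_path))
        if not report.passed and not config.qc_override:
            raise RuntimeError(
                f"IPC QC failed (SD {report.ipc_sd:.4f} >= {report.threshold})"
            )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("qc", str(exc)) from exc

    branch_data: dict[str, object] = {}
    try:
        stage("normalize")
        if "raw" in config.branches:
            filtered_raw = filter_expressed(table, panel_policy=config.panel_policy)
            branch_data["raw"] = NormalizedTable(
                values=filtered_raw.values.loc[_targets_only(filtered_raw.features, filtered_raw)],
                provenance="raw",
            )
            manifest["counts"]["raw_features"] = len(branch_data["raw"].values.index)
        if "ipc_delta_ct" in config.branches:
            calibrated = calibrate(table, report, override=config.qc_override)
            filtered = filter_expressed(calibrated, panel_policy=config.panel_policy)
            refs = make_reference_set(filtered, config.references)
            norm = delta_ct(filtered, refs)
            branch_data["ipc_delta_ct"] = NormalizedTable(
                values=norm.values.loc[_targets_only(norm.features, filtered)],
                provenance="ipc_delta_ct",
            )
            manifest["counts"]["delta_features"] = len(branch_data["ipc_delta_ct"].values.index)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("normalize", str(exc)) from exc

    candidates: dict[tuple[str, str], CandidateSet] = {}
    try:
        stage("differential")
        for branch in config.branches:
            data = branch_data[branch]
            for spec in config.comparisons:
                comparison = GroupComparison.from_spec(spec, branch=branch)
                seed = _task_seed(config.seed, branch, comparison.name)
                manifest["seeds"][f"{branch}:{comparison.name}"] = seed
                fit = fit_moderated_t(data, sheet, comparison)
                sp = sampling_p(
                    data, sheet, comparison, B=config.B, seed=seed, smoothing=config.smoothing
                )
                diff = build_diff_table(fit, sp)
                path = out_dir / f"diff_{branch}_{comparison.name}.tsv"
                write_diff_table(diff, path)
                manifest["files"].append(str(path))
                cset = select_candidates(
                    diff, alpha=config.alpha, comparison=comparison.name, branch=branch
                )
                candidates[(branch, comparison.name)] = cset
                manifest["counts"][f"candidates_{branch}_{comparison.name}"] = len(cset)
                _write_candidates(cset, out_dir / f"candidates_{branch}_{comparison.name}.tsv")
                manifest["files"].append(
                    str(out_dir / f"candidates_{branch}_{comparison.name}.tsv")
                )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("differential", str(exc)) from exc

    try:
        stage("intersect")
        per_comparison: dict[str, CandidateSet] = {}
        comp_names = [GroupComparison.from_spec(s).name for s in config.comparisons]
        for name in comp_names:
            sets = [candidates[(b, name)] for b in config.branches if (b, name) in candidates]
            merged = sets[0]
            for other in sets[1:]:
                merged = intersect_candidates(merged, other)
            per_comparison[name] = merged
            manifest["counts"][f"branch_intersection_{name}"] = len(merged)
            _write_candidates(merged, out_dir / f"intersection_branches_{name}.tsv")
            manifest["files"].append(str(out_dir / f"intersection_branches_{name}.tsv"))
        group_core = None
        if len(comp_names) >= 2:
            group_core = per_comparison[comp_names[0]]
            for name in comp_names[1:]:
                group_core = intersect_candidates(group_core, per_comparison[name])
            manifest["counts"]["group_intersection"] = len(group_core)
            _write_candidates(group_core, out_dir / "intersection_groups.tsv")
            manifest["files"].append(str(out_dir / "intersection_groups.tsv"))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("intersect", str(exc)) from exc

    if config.target_map_path and config.term_map_path:
        try:
            stage("enrichment")
            tmap = read_target_map(config.target_map_path)
            terms = read_term_map(config.term_map_path)
            enrich_sets = dict(per_comparison)
            if group_core is not None:
                enrich_sets["core"] = group_core
            for name, cset in enrich_sets.items():
                genes = map_targets(cset, tmap)
                manifest["counts"][f"genes_{name}"] = len(genes)
                results = enrich_terms(
                    genes, terms, alpha=config.alpha, variant=config.enrichment_variant
                )
                path = out_dir / f"enrichment_{name}.tsv"
                write_enrichment(results, path)
                manifest["files"].append(str(path))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("enrichment", str(exc)) from exc

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["files"].append(str(manifest_path))
    return manifest


def _write_candidates(cset: CandidateSet, path) -> None:
    lines = ["MicroRNA Name\tdirection"]
    lines += [f"{f}\t{d}" for f, d in cset.members]
    Path(path).write_text("\n".join(lines) + "\n")
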