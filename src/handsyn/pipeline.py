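"""End-to-end orchestration: preprocess -> extract -> cluster -> classify ->
enumerate -> fit/score/select -> evaluate, with every stage artifact written to
a run directory as self-describing CSV and a JSON manifest for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import ClusterPartition, SynergyCluster, cluster_synergies, linkage_to_frame, partition_to_frames
from .dof import DOF_NAMES
from .errors import HandsynError, ParameterError
from .estimation import score_and_select, scores_to_frame
from .evaluation import evaluate, export_traces, rom_table
from .extraction import extract_synergies
from .io import ColumnMap, group_by_subject, read_recordings, write_recordings
from .preprocess import preprocess_recording, zscore_concat
from .selection import (
    RepresentativeSet,
    classification_to_frame,
    classify_clusters,
    combinations_to_frame,
    enumerate_combinations,
)
from .simulate import SynthConfig, generate_cohort, write_cohort


@dataclass
class RunConfig:
    """Validated, serialisable configuration for one analysis run.

    With ``simulate`` true the training and evaluation cohorts are generated
    (seed and seed+1); otherwise ``train_path``/``eval_path`` name recording
    CSVs in the documented layout (``column_map`` optionally remaps headers).
    """

    simulate: bool = True
    train_path: str | None = None
    eval_path: str | None = None
    column_map: str | None = None
    seed: int = 0
    # synthetic cohort size (used only when simulate=True)
    n_subjects: int = 8
    n_tasks: int = 6
    frames_per_task: int = 600
    noise_sd_deg: float = 1.0
    subject_loading_jitter_deg: float = 5.0
    # preprocessing
    cutoff_hz: float = 5.0
    filter_order: int = 2
    vel_threshold_deg_s: float = 2.0
    min_run_s: float = 0.2
    resample_frames: int = 1000
    # analysis thresholds
    var_threshold: float = 0.95
    fixed_k: int | None = None
    min_subject_fraction: float = 0.10
    cc_high: float = 0.8
    cc_low: float = 0.3
    cc_candidate: float = 0.4
    outdir: str = "handsyn_run"

    def validate(self) -> None:
        if not 0 < self.var_threshold <= 1:
            raise ParameterError(f"var_threshold {self.var_threshold} not in (0, 1]")
        if not 0 <= self.min_subject_fraction <= 1:
            raise ParameterError("min_subject_fraction must be in [0, 1]")
        for name in ("cc_high", "cc_low", "cc_candidate"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ParameterError(f"{name} must be in (0, 1)")
        if self.cutoff_hz <= 0 or self.filter_order < 1:
            raise ParameterError("invalid filter parameters")
        if self.resample_frames < 2:
            raise ParameterError("resample_frames must be >= 2")
        if not self.simulate and not self.train_path:
            raise ParameterError("train_path required when simulate is false")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def partition_from_summary(summary: pd.DataFrame) -> ClusterPartition:
    """Rebuild a partition (averaged loadings + subject fractions) from its
    summary CSV, enough to re-run classification from files alone."""
    clusters = []
    cc_cols = [f"cc_{n}" for n in DOF_NAMES]
    for _, row in summary.iterrows():
        clusters.append(
            SynergyCluster(
                members=[],
                averaged_pc=row[cc_cols].to_numpy(dtype=float),
                subject_fraction=float(row["subject_pct"]) / 100.0,
                mean_variance_explained=float(row["mean_variance_explained"]),
            )
        )
    return ClusterPartition(clusters=clusters)


def rep_set_from_row(row: pd.Series) -> RepresentativeSet:
    """Rebuild a representative set from one combinations.csv row."""
    chosen = str(row["candidates"]).split()
    labels = str(row["representative"]).split()
    independent = [l for l in labels if l not in chosen]
    return RepresentativeSet(independent, chosen)


def run_pipeline(config: RunConfig, progress=None) -> Path:
    """Execute the full analysis; returns the run directory.

    Stage artifacts (all CSV with DoF-label headers) are written as each stage
    completes, so a failure retains partial outputs; the manifest records the
    completed stages, timings, config hash and package version.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "stages": [],
    }

    def log(msg):
        if progress:
            progress(msg)

    def done(stage, t0):
        manifest["stages"].append(
            {"stage": stage, "seconds": round(time.perf_counter() - t0, 3)}
        )
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    try:
        # stage 1: acquire data -------------------------------------------
        t0 = time.perf_counter()
        layout = ColumnMap.from_file(config.column_map) if config.column_map else None
        if config.simulate:
            train_cfg = SynthConfig(
                n_subjects=config.n_subjects,
                n_tasks=config.n_tasks,
                frames_per_task=config.frames_per_task,
                noise_sd_deg=config.noise_sd_deg,
                subject_loading_jitter_deg=config.subject_loading_jitter_deg,
                seed=config.seed,
            )
            eval_cfg = SynthConfig(
                n_subjects=config.n_subjects,
                n_tasks=config.n_tasks,
                frames_per_task=config.frames_per_task,
                noise_sd_deg=config.noise_sd_deg,
                subject_loading_jitter_deg=config.subject_loading_jitter_deg,
                seed=config.seed + 1,
            )
            train_raw, truth = generate_cohort(train_cfg)
            eval_raw, _ = generate_cohort(eval_cfg)
            write_cohort(train_raw, truth, outdir / "train_raw.csv",
                         outdir / "ground_truth.json")
            write_recordings(eval_raw, outdir / "eval_raw.csv")
        else:
            train_raw = read_recordings(config.train_path, layout)
            eval_raw = (
                read_recordings(config.eval_path, layout) if config.eval_path else None
            )
        done("acquire", t0)
        log("acquired data")

        # stage 2: preprocess ---------------------------------------------
        t0 = time.perf_counter()
        pp = dict(
            cutoff_hz=config.cutoff_hz,
            order=config.filter_order,
            vel_threshold_deg_s=config.vel_threshold_deg_s,
            min_run_s=config.min_run_s,
        )
        train_native = [preprocess_recording(r, **pp) for r in train_raw]
        train_resampled = [
            preprocess_recording(r, **pp, n_frames=config.resample_frames)
            for r in train_raw
        ]
        eval_native = (
            [preprocess_recording(r, **pp) for r in eval_raw] if eval_raw else None
        )
        write_recordings(train_resampled, outdir / "train_resampled.csv")
        if eval_native:
            write_recordings(eval_native, outdir / "eval_preprocessed.csv")
        done("preprocess", t0)
        log("preprocessed recordings")

        # stage 3: extract synergies --------------------------------------
        t0 = time.perf_counter()
        synergy_sets = []
        for subject, recs in group_by_subject(train_resampled).items():
            std, params = zscore_concat(recs)
            params.to_csv(outdir / f"norm_{subject}.csv")
            s = extract_synergies(
                std, subject, config.var_threshold, fixed_k=config.fixed_k
            )
            s.to_csv(outdir / f"synergies_{subject}.csv")
            synergy_sets.append(s)
        done("extract", t0)
        log(f"extracted synergies for {len(synergy_sets)} subjects")

        # stage 4: cluster -------------------------------------------------
        t0 = time.perf_counter()
        partition = cluster_synergies(synergy_sets)
        members, summary = partition_to_frames(partition)
        members.to_csv(outdir / "clusters_members.csv", index=False)
        summary.to_csv(outdir / "clusters_summary.csv", index=False)
        linkage_to_frame(partition.linkage_tree).to_csv(
            outdir / "linkage.csv", index=False
        )
        done("cluster", t0)
        log(f"{partition.n_clusters} clusters at cut {partition.cut_distance:.0f} deg")

        # stage 5: classify + enumerate -----------------------------------
        t0 = time.perf_counter()
        independent, groups, discarded = classify_clusters(
            partition,
            min_subject_fraction=config.min_subject_fraction,
            cc_high=config.cc_high,
            cc_low=config.cc_low,
            cc_candidate=config.cc_candidate,
        )
        combos = enumerate_combinations(independent, groups)
        classification_to_frame(independent, groups, discarded).to_csv(
            outdir / "classification.csv", index=False
        )
        combinations_to_frame(combos).to_csv(outdir / "combinations.csv", index=False)
        done("classify", t0)
        log(f"{len(independent)} independent DoF, {len(groups)} groups, "
            f"{len(combos)} combinations")

        # stage 6: fit / score / select -----------------------------------
        t0 = time.perf_counter()
        pooled = np.concatenate([r.angles for r in train_resampled], axis=0)
        scores, best, bank = score_and_select(combos, pooled, dataset_id="train")
        scores_to_frame(scores).to_csv(outdir / "combination_scores.csv", index=False)
        bank.to_csv(outdir / "estimators.csv")
        (outdir / "best_combination.json").write_text(
            json.dumps(
                {
                    "case": combos.index(best) + 1,
                    "representative": best.labels,
                    "mean_rmse_deg": scores[combos.index(best)].mean_rmse,
                },
                indent=1,
            )
        )
        done("fit", t0)
        log(f"best combination: {best.labels}")

        # stage 7: evaluate -----------------------------------------------
        t0 = time.perf_counter()
        eval_set = eval_native if eval_native else train_native
        rom = rom_table(
            [train_native, eval_native] if eval_native else [train_native]
        )
        rom.to_csv(outdir / "rom.csv")
        report = evaluate(bank, eval_set, rom)
        report.save(outdir / "errors_global.csv", outdir / "errors_per_activity.csv")
        avg = report.per_activity_pct_rom["AVG"]
        for tag, task in (("worst", avg.idxmax()), ("best", avg.idxmin())):
            rec = next(r for r in eval_set if r.task_id == task)
            export_traces(bank, rec, outdir / f"traces_{tag}_{task}.csv")
        done("evaluate", t0)
        log(f"evaluated {report.n_frames} frames")
    except HandsynError as exc:
        stage = len(manifest["stages"]) + 1
        raise HandsynError(f"pipeline halted at stage {stage}: {exc}") from exc
    return outdir
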