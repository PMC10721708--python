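"""End-to-end pipeline: simulate → detect → track → split → train →
evaluate → donor statistics → (optional) ramping.

Every stage writes plain CSV/JSON outputs into the run directory, and a
run summary records the configuration hash, seed, package versions and
per-stage wall times so a run is fully reproducible from (config, seed).
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, config_hash, dump_config
from .detection import detect_sequence
from .donor_stats import (anova_class_difference, anova_donor_fixed,
                          lrt_random_effect)
from dataclasses import replace as _replace_params

from .synthetic import (DonorSpec, build_manifest, default_class_params,
                        generate_donor_video)
from .tracking import build_tracks, extract_clips
from .training import (ClipDataset, build_model, compute_metrics,
                       fold_mean_metrics, make_splits, per_donor_accuracy,
                       run_cv, run_ramping, train_model)

__all__ = ["run_pipeline", "cohort_donor_specs", "simulate_and_extract"]


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name and context."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def cohort_donor_specs(cfg: PipelineConfig, seed: int) -> list[DonorSpec]:
    """Donor specifications for the configured synthetic cohort."""
    donors = []
    c = cfg.cohort
    for label, n in (("fetal", c.n_fetal), ("adult", c.n_adult)):
        for i in range(n):
            donors.append(DonorSpec(
                donor_id=f"{label[0].upper()}{i + 1:03d}",
                class_label=label,
                n_cells=c.cells_per_donor,
                donor_effect_sd=c.donor_effect_sd,
                seed=seed + 7919 * len(donors) + 13,
            ))
    return donors


def _class_params(cfg: PipelineConfig) -> dict:
    out = {}
    for label in ("fetal", "adult"):
        p = default_class_params(label)
        c = cfg.cohort
        if label == "fetal":
            if c.fetal_area_scale is not None:
                adult = default_class_params("adult")
                p = _replace_params(
                    p, projected_area_mean=adult.projected_area_mean
                    * c.fetal_area_scale)
            if c.fetal_deformation_amplitude is not None:
                p = _replace_params(
                    p, deformation_amplitude=c.fetal_deformation_amplitude)
        elif c.adult_deformation_amplitude is not None:
            p = _replace_params(
                p, deformation_amplitude=c.adult_deformation_amplitude)
        out[label] = p
    return out


def simulate_and_extract(cfg: PipelineConfig, seed: int):
    """Simulate the cohort and run detection + tracking per donor.

    Returns (manifest, dataset, tracks_per_donor, truths). Videos are
    processed one donor at a time and released, so memory stays bounded.
    """
    donors = cohort_donor_specs(cfg, seed)
    manifest = build_manifest(donors)
    params = _class_params(cfg)
    det, trk = cfg.detection, cfg.tracking
    all_clips = []
    track_counts = {}
    truths = {}
    for d in donors:
        seq, truth = generate_donor_video(cfg.scene, d, params[d.class_label])
        truths[d.donor_id] = truth
        frames_regions = detect_sequence(
            seq, threshold=det.threshold, min_area=det.min_area,
            sigma=det.sigma, connectivity=det.connectivity,
            n_background_samples=det.n_background_samples, seed=seed)
        tracks = build_tracks(frames_regions, min_track_len=trk.min_track_len,
                              donor_id=d.donor_id, class_label=d.class_label)
        track_counts[d.donor_id] = len(tracks)
        all_clips.extend(extract_clips(tracks, seq, size=trk.clip_size,
                                       n_frames=trk.clip_frames))
    dataset = ClipDataset.from_clips(all_clips)
    return manifest, dataset, track_counts, truths


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path,
                 seed: int | None = None) -> dict:
    """Run all stages and write per-stage outputs under ``out_dir``.

    Returns a results dict (metrics, per-donor table, donor statistics,
    optional ramping table). Any stage failure raises :class:`StageFailure`
    naming the stage.
    """
    seed = cfg.seed if seed is None else seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings = {}
    results: dict = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, et, ev, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if ev is not None and not isinstance(ev, StageFailure):
                    raise StageFailure(name, ev) from ev
        return _Timer()

    with stage("simulate_detect_track"):
        manifest, dataset, track_counts, _ = simulate_and_extract(cfg, seed)
        manifest = manifest.assign(
            n_tracks=[track_counts[d] for d in manifest.donor_id])
        manifest.to_csv(out / "manifest.csv", index=False)

    with stage("split"):
        splits = make_splits(manifest, k=cfg.evaluation.n_splits, seed=seed,
                             stratify=cfg.evaluation.stratify_splits)
        pd.DataFrame(sorted(splits.assignment.items()),
                     columns=["donor_id", "split"]).to_csv(
            out / "splits.csv", index=False)
        splits.summary(manifest).to_csv(out / "split_summary.csv", index=False)

    test_donors = splits.donors_in(splits.test_split)
    test_data = dataset.donors_subset(test_donors)

    with stage("train"):
        if cfg.evaluation.mode == "cv":
            models, histories = run_cv(dataset, splits, cfg.model,
                                       cfg.training, seed=seed)
        elif cfg.evaluation.mode == "single":
            val_split = splits.cv_splits[-1]
            train_donors = [d for s in splits.cv_splits if s != val_split
                            for d in splits.donors_in(s)]
            model = build_model(cfg.model, seed=seed)
            hist = train_model(model, dataset.donors_subset(train_donors),
                               dataset.donors_subset(splits.donors_in(val_split)),
                               cfg.training, seed=seed + 1)
            models, histories = [model], [hist]
        else:
            raise ValueError(f"unknown evaluation mode {cfg.evaluation.mode!r}")
        (out / "histories.json").write_text(json.dumps(histories, default=str))

    with stage("evaluate"):
        fold_scores = [m.predict_proba(test_data.clips) for m in models]
        fold_reports = [compute_metrics(s, test_data.labels)
                        for s in fold_scores]
        agg = fold_mean_metrics(fold_reports)
        pooled = compute_metrics(np.mean(fold_scores, axis=0),
                                 test_data.labels)
        results["metrics_fold_mean"] = agg.to_dict()
        results["metrics_pooled"] = pooled.to_dict()
        results["metrics_per_fold"] = [r.to_dict() for r in fold_reports]
        acc_table, donor_summary = per_donor_accuracy(
            fold_scores, test_data.labels, test_data.donor_ids)
        acc_table.to_frame().to_csv(out / "per_donor_accuracy.csv")
        donor_summary.to_csv(out / "per_donor_summary.csv", index=False)
        results["per_donor_summary"] = donor_summary.to_dict("records")

    if cfg.evaluation.run_donor_stats:
        with stage("donor_stats"):
            stats_out = {}
            classes = np.array(acc_table.donor_classes)
            if len(models) >= 2 and acc_table.grid.shape[0] >= 2:
                mm = lrt_random_effect(acc_table.grid)
                stats_out["fold_random_effect"] = {
                    "sigma2_A": mm.sigma2_A, "sigma2": mm.sigma2,
                    "lrt": mm.lrt, "df": mm.df, "p_boundary": mm.p_boundary,
                    "loglik_null": mm.loglik_null, "aic_null": mm.aic_null,
                }
                an = anova_donor_fixed(acc_table.grid)
                an.to_frame().to_csv(out / "anova_donor.csv", index=False)
                stats_out["donor_anova"] = {"F": an.f_stat, "p": an.p_value,
                                            "df": an.df}
            if all((classes == c).sum() >= 2 for c in ("fetal", "adult")):
                ac = anova_class_difference(acc_table.grid.mean(axis=1),
                                            classes)
                ac.to_frame().to_csv(out / "anova_class.csv", index=False)
                stats_out["class_anova"] = {"F": ac.f_stat, "p": ac.p_value,
                                            "df": ac.df}
            else:
                stats_out.setdefault(
                    "notes", []).append(
                    "class ANOVA skipped: a class has fewer than 2 test donors")
            results["donor_stats"] = stats_out

    if cfg.evaluation.run_ramping:
        with stage("ramping"):
            ramp = run_ramping(dataset, splits, cfg.model, cfg.training,
                               fractions=cfg.evaluation.ramping_fractions,
                               seed=seed)
            ramp.to_csv(out / "ramping.csv", index=False)
            results["ramping"] = ramp.to_dict("records")

    (out / "metrics.json").write_text(json.dumps(results, indent=2))
    (out / "config.yaml").write_text(dump_config(cfg))
    summary = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed,
        "config_hash": config_hash(cfg),
        "n_clips": int(len(dataset)),
        "stage_wall_times_s": timings,
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2))
    results["summary"] = summary
    return results
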