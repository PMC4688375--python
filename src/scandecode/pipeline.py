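"""End-to-end orchestration: simulate -> preprocess -> select -> train -> test -> decode.

Feature-selection modes mirror the study design. ``whole_brain`` trains
one classifier on all eight day-1 runs using every in-mask voxel.
``p001`` / ``fwe05`` use the split-half GLM masks: the mask fitted on
the odd runs selects voxels for a classifier trained on the even runs
and vice versa, halving the training set; reported decoding scores
average the two halves.

Day-2 preprocessing pools the binary-answer and alternating runs, since
the day-level standardization uses every scan of the day.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .paradigm import Answer
from .synthsim import (
    ExperimentProtocol,
    GroundTruth,
    NoiseConfig,
    SimulatedExperiment,
    make_ground_truth,
    simulate_experiment,
)
from .preprocess import PreprocConfig, preprocess_day
from .glmselect import GlmConfig, ThresholdKind, split_half_masks
from .mvpa import (
    SvmConfig,
    assemble_dataset,
    balanced_block_permutation_test,
    evaluate_classifier,
    loro_cv,
    train_classifier,
)
from .answers import VoteConfig, decode_answers, duration_curve
from .paradigm import response_scan_indices

__all__ = ["PipelineConfig", "run_pipeline", "response_scan_matrix"]


@dataclass
class PipelineConfig:
    """Resolved configuration of one full pipeline run."""

    seed: int = 0
    mode: ThresholdKind = ThresholdKind.WHOLE_BRAIN
    protocol: ExperimentProtocol = field(default_factory=ExperimentProtocol)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    effect_size: float = 0.012
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    glm: GlmConfig = field(default_factory=GlmConfig)
    svm: SvmConfig = field(default_factory=SvmConfig)
    vote: VoteConfig = field(default_factory=VoteConfig)
    shift_seconds: float = 4.0
    n_permutations: int = 5000
    run_permutation_test: bool = True

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def response_scan_matrix(
    runs, feature_mask: np.ndarray, answer_key: list[Answer], shift_seconds: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Stack all shifted response-window scans of the binary runs into (X, y).

    y holds the key's signs (+1 yes / -1 no) and is used only to score
    accuracy, never to fit anything.
    """
    key_signs = [Answer(a).sign for a in answer_key]
    rows, ys = [], []
    for run in runs:
        vox = run.data[feature_mask]
        for trial_i, idx in enumerate(response_scan_indices(run.schedule, shift_seconds)):
            cols = [i - run.t_offset_scans for i in idx]
            rows.append(vox[:, cols].T)
            ys.extend([key_signs[trial_i]] * len(cols))
    return np.vstack(rows), np.asarray(ys)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns a result bundle of plain-type summaries."""
    cfg = config
    truth = make_ground_truth(
        cfg.protocol.acquisition.grid_shape, effect_size=cfg.effect_size
    )
    exp = simulate_experiment(cfg.protocol, truth, cfg.seed, cfg.noise)
    return run_pipeline_on(exp, cfg)


def run_pipeline_on(exp: SimulatedExperiment, cfg: PipelineConfig) -> dict:
    """Run every stage after simulation on an existing dataset."""
    mask = exp.truth.brain_mask
    day1 = preprocess_day(exp.day1, mask, cfg.preproc)
    day2_all = preprocess_day(exp.day2_binary + exp.day2_alt, mask, cfg.preproc)
    day2_binary = day2_all[: len(exp.day2_binary)]
    day2_alt = day2_all[len(exp.day2_binary):]
    answer_key = list(exp.protocol.answer_key)

    bundle: dict = {"config_digest": cfg.digest(), "mode": cfg.mode.value, "seed": exp.seed}

    if cfg.mode is ThresholdKind.WHOLE_BRAIN:
        variants = [("all", mask, day1)]
    else:
        halves = split_half_masks(exp.day1, mask, cfg.glm)
        # mask from odd runs -> train on even runs, and vice versa
        variants = [
            ("odd_mask_even_train", halves["odd"][cfg.mode].mask, day1[1::2]),
            ("even_mask_odd_train", halves["even"][cfg.mode].mask, day1[0::2]),
        ]
        bundle["mask_n_voxels"] = {
            name: int(m.sum()) for name, m, _ in variants
        }

    results = []
    for name, fmask, train_runs in variants:
        if not fmask.any():
            results.append({"variant": name, "error": "empty feature mask"})
            continue
        dataset = assemble_dataset(train_runs, fmask, cfg.shift_seconds, mask_ref=name)
        cv = loro_cv(dataset, cfg.svm)
        clf = train_classifier(dataset, cfg.svm, feature_mask=fmask)

        crossday_acc, crossday_n = None, 0
        if day2_alt:
            alt2 = assemble_dataset(day2_alt, fmask, cfg.shift_seconds, mask_ref=name)
            crossday_acc = evaluate_classifier(clf, alt2.X, alt2.y)
            crossday_n = alt2.n_scans

        res = {
            "variant": name,
            "n_train_scans_per_class": int((dataset.y == 1).sum()),
            "n_features": int(fmask.sum()),
            "loro_pooled_accuracy": cv.pooled_accuracy,
            "loro_fold_accuracies": cv.fold_accuracies,
            "crossday_accuracy": crossday_acc,
            "crossday_n_scans": crossday_n,
        }
        if day2_binary:
            decoded = decode_answers(clf, day2_binary, answer_key, cfg.shift_seconds, cfg.vote)
            res.update({
                "single_scan_accuracy": decoded.single_scan_accuracy,
                "n_response_scans": decoded.n_response_scans,
                "n_correct_per_run": decoded.n_correct_per_run.tolist(),
                "mean_correct": decoded.mean_correct,
                "sd_correct": decoded.sd_correct,
                "consistent_correct": decoded.consistent_correct,
                "duration_curve": duration_curve(
                    decoded.per_scan_labels, answer_key, cfg.vote.k_grid
                ).to_dict(orient="records"),
            })
        if cfg.run_permutation_test and day2_binary:
            eval_X, eval_y = response_scan_matrix(day2_binary, fmask, answer_key, cfg.shift_seconds)
            perm = balanced_block_permutation_test(
                dataset, cfg.svm, cfg.n_permutations, seed=cfg.seed + 1,
                eval_X=eval_X, eval_y=eval_y,
            )
            res["permutation_p_value"] = perm.p_value
            res["permutation_observed_accuracy"] = perm.observed_accuracy
        results.append(res)

    bundle["variants"] = results
    ok = [r for r in results if "error" not in r]
    if ok:
        bundle["summary"] = {
            key: float(np.mean([r[key] for r in ok]))
            for key in (
                "loro_pooled_accuracy", "crossday_accuracy", "single_scan_accuracy",
                "mean_correct", "sd_correct", "consistent_correct",
                "permutation_p_value",
            )
            if all(r.get(key) is not None for r in ok)
        }
    return bundle
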