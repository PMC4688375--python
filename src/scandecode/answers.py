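"""Decode yes/no answers from binary-answer runs and score them.

Each statement's 24 s response window contributes 12 hemodynamically
shifted scans; the trained classifier labels each scan (+1 yes, -1 no)
and the answer is the majority label over the first k scans (k odd,
default 11 of 12, so ties cannot occur). Scoring compares the votes to
the ground-truth answer key -- which decoding itself never reads -- and
the duration-effect analysis recomputes votes from the stored per-scan
labels at k = 3, 5, 7, 9, 11 without re-classifying.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .paradigm import Answer, InvalidConfigError, response_scan_indices
from .mvpa import ScanClassifier
from .synthsim import BoldRun

__all__ = [
    "VoteConfig",
    "DecodedAnswers",
    "classify_response_periods",
    "majority_vote",
    "score_answers",
    "duration_curve",
    "decode_answers",
    "write_report",
]


@dataclass(frozen=True)
class VoteConfig:
    """Number of response-period scans entering the majority vote.

    k must be odd so a vote can never tie; the default uses the first
    11 of the 12 scans in a window.
    """

    k: int = 11
    k_grid: tuple[int, ...] = (3, 5, 7, 9, 11)

    def __post_init__(self) -> None:
        for kk in (self.k, *self.k_grid):
            if kk < 1 or kk % 2 == 0:
                raise InvalidConfigError(f"k must be odd and positive, got {kk}")


def classify_response_periods(
    model: ScanClassifier,
    runs: list[BoldRun],
    shift_seconds: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Label every shifted response-window scan of each binary-answer run.

    Returns (labels, values), each of shape (n_runs, n_sentences,
    n_scans_per_window). Scans are scaled with the model's training
    scaler; the label is the sign of the decision value, with an exact
    0 labeled +1.
    """
    if model.feature_mask is None:
        raise ValueError("classifier carries no feature mask")
    all_labels, all_values = [], []
    for run in runs:
        if run.data.shape[:3] != model.feature_mask.shape:
            raise ValueError("run grid does not match the classifier's feature mask")
        vox = run.data[model.feature_mask]  # (features, t)
        windows = response_scan_indices(run.schedule, shift_seconds)
        run_labels, run_values = [], []
        for idx in windows:
            cols = [i - run.t_offset_scans for i in idx]
            if min(cols) < 0 or max(cols) >= vox.shape[1]:
                raise ValueError("response window falls outside the retained scans")
            X = vox[:, cols].T
            vals = model.decision_values(X)
            run_values.append(vals)
            run_labels.append(np.where(vals >= 0, 1, -1))
        all_labels.append(run_labels)
        all_values.append(run_values)
    return np.asarray(all_labels), np.asarray(all_values)


def majority_vote(scan_labels: np.ndarray, k: int) -> Answer:
    """Most frequent label among the FIRST k scans; yes iff +1 is the majority."""
    scan_labels = np.asarray(scan_labels)
    if k % 2 == 0 or k < 1 or k > len(scan_labels):
        raise InvalidConfigError(f"k must be odd and within 1..{len(scan_labels)}, got {k}")
    n_yes = int(np.sum(scan_labels[:k] == 1))
    return Answer.YES if n_yes > k / 2 else Answer.NO


def _votes_matrix(per_scan_labels: np.ndarray, k: int) -> np.ndarray:
    """(n_runs, n_sentences) array of +1/-1 votes."""
    n_runs, n_sent, _ = per_scan_labels.shape
    out = np.empty((n_runs, n_sent), dtype=int)
    for r in range(n_runs):
        for s in range(n_sent):
            out[r, s] = majority_vote(per_scan_labels[r, s], k).sign
    return out


def score_answers(
    votes: np.ndarray, answer_key: list[Answer]
) -> tuple[np.ndarray, int, float, float]:
    """Score votes against the key: per-run correct, consistency, mean and SD.

    ``consistent_correct`` counts sentences answered correctly in every
    single run.
    """
    votes = np.asarray(votes)
    key = np.array([Answer(a).sign for a in answer_key])
    if votes.ndim != 2 or votes.shape[1] != len(key):
        raise ValueError(f"votes shape {votes.shape} does not match key of {len(key)}")
    correct = votes == key[None, :]
    n_correct_per_run = correct.sum(axis=1)
    consistent_correct = int(correct.all(axis=0).sum())
    return (
        n_correct_per_run,
        consistent_correct,
        float(n_correct_per_run.mean()),
        float(n_correct_per_run.std(ddof=0)),
    )


def duration_curve(
    per_scan_labels: np.ndarray,
    answer_key: list[Answer],
    k_grid: tuple[int, ...] = (3, 5, 7, 9, 11),
) -> pd.DataFrame:
    """Mean (and SD) correctly answered sentences per run as a function of k.

    Votes are recomputed from the stored per-scan labels; no scan is
    re-classified.
    """
    rows = []
    for k in k_grid:
        votes = _votes_matrix(per_scan_labels, k)
        _, consistent, mean_c, sd_c = score_answers(votes, answer_key)
        rows.append({"k": k, "mean_correct": mean_c, "sd_correct": sd_c,
                     "consistent_correct": consistent})
    return pd.DataFrame(rows)


@dataclass
class DecodedAnswers:
    """Per-scan labels and decision values plus the vote/score summary."""

    per_scan_labels: np.ndarray     # (runs, sentences, scans) of +/-1
    per_scan_values: np.ndarray     # same shape, real decision values
    votes: np.ndarray               # (runs, sentences) of +/-1
    n_correct_per_run: np.ndarray
    consistent_correct: int
    mean_correct: float
    sd_correct: float
    single_scan_accuracy: float
    vote_config: VoteConfig = field(default_factory=VoteConfig)

    @property
    def n_response_scans(self) -> int:
        return int(np.prod(self.per_scan_labels.shape))


def decode_answers(
    model: ScanClassifier,
    runs: list[BoldRun],
    answer_key: list[Answer],
    shift_seconds: float = 4.0,
    vote_cfg: VoteConfig | None = None,
) -> DecodedAnswers:
    """Classify response periods, vote, and score against the answer key."""
    vote_cfg = vote_cfg or VoteConfig()
    labels, values = classify_response_periods(model, runs, shift_seconds)
    votes = _votes_matrix(labels, vote_cfg.k)
    n_correct, consistent, mean_c, sd_c = score_answers(votes, answer_key)
    key_signs = np.array([Answer(a).sign for a in answer_key])
    single_scan = float(np.mean(labels == key_signs[None, :, None]))
    return DecodedAnswers(
        per_scan_labels=labels, per_scan_values=values, votes=votes,
        n_correct_per_run=n_correct, consistent_correct=consistent,
        mean_correct=mean_c, sd_correct=sd_c,
        single_scan_accuracy=single_scan, vote_config=vote_cfg,
    )


def write_report(decoded: DecodedAnswers, answer_key: list[Answer], out_dir: str | Path) -> dict:
    """Write the per-run vote table (CSV) and the summary (JSON); return the summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_runs, n_sent = decoded.votes.shape
    rows = []
    key = [Answer(a) for a in answer_key]
    for r in range(n_runs):
        for s in range(n_sent):
            vote = Answer.YES if decoded.votes[r, s] == 1 else Answer.NO
            rows.append({
                "run": r + 1, "sentence": s + 1,
                "vote": vote.value, "true_answer": key[s].value,
                "correct": int(vote is key[s]),
            })
    pd.DataFrame(rows).to_csv(out / "votes.csv", index=False)
    curve = duration_curve(decoded.per_scan_labels, key, decoded.vote_config.k_grid)
    summary = {
        "single_scan_accuracy": decoded.single_scan_accuracy,
        "n_response_scans": decoded.n_response_scans,
        "k": decoded.vote_config.k,
        "n_correct_per_run": decoded.n_correct_per_run.tolist(),
        "mean_correct": decoded.mean_correct,
        "sd_correct": decoded.sd_correct,
        "consistent_correct": decoded.consistent_correct,
        "duration_curve": curve.to_dict(orient="records"),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
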