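"""Synthetic multi-run BOLD data with planted two-class structure.

The generator emulates the two-day paradigm: day 1 contributes eight
alternating task runs used for training, day 2 three more alternating
runs (cross-day generalization) and five binary-answer runs (decoding).
Task-evoked signal is a per-voxel fractional change on a baseline,
driven by task boxcars convolved with a canonical double-gamma HRF.
Structured nuisance -- slow drift, a global fluctuation shared across
the brain, motion-coupled signal -- plus AR(1) Gaussian noise give the
preprocessing regressors something real to remove.

Everything is deterministic given the master seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import nibabel as nib
from scipy.ndimage import gaussian_filter1d
from scipy.stats import gamma as gamma_dist

from .paradigm import (
    AcquisitionParams,
    Answer,
    BlockLabel,
    RunKind,
    RunSchedule,
    build_alternating_run,
    build_binary_answer_run,
    mark_unacknowledged,
    schedule_from_events,
    schedule_to_events,
)

__all__ = [
    "HrfParams",
    "GroundTruth",
    "NoiseConfig",
    "BoldRun",
    "ExperimentProtocol",
    "SimulatedExperiment",
    "canonical_hrf",
    "make_ground_truth",
    "simulate_run",
    "simulate_experiment",
    "write_run",
    "read_run",
    "write_experiment",
    "read_experiment",
    "DEFAULT_ANSWER_KEY",
]

CONFOUND_COLUMNS = [
    "trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z",
    "wm_mean", "csf_mean", "global_mean",
]

#: Answer key of the first subject: yes, no, yes, yes, no, no.
DEFAULT_ANSWER_KEY = (
    Answer.YES, Answer.NO, Answer.YES, Answer.YES, Answer.NO, Answer.NO,
)


@dataclass(frozen=True)
class HrfParams:
    """Double-gamma HRF shape (SPM-style canonical parameterization).

    Response peak at 6 s, undershoot peaking at 16 s with 1/6 the
    amplitude, unit dispersions, 32 s kernel.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 6.0
    duration: float = 32.0


def canonical_hrf(tr: float, duration: float = 32.0, params: HrfParams | None = None) -> np.ndarray:
    """Sample the canonical double-gamma HRF at TR resolution, peak normalized to 1."""
    if tr <= 0:
        raise ValueError("tr must be positive")
    if duration < tr:
        raise ValueError("duration must be at least one TR")
    p = params or HrfParams()
    t = np.arange(0.0, duration, tr)
    kernel = _double_gamma(t, p)
    return kernel / kernel.max()


def _double_gamma(t: np.ndarray, p: HrfParams) -> np.ndarray:
    pos = gamma_dist.pdf(t, p.peak_delay / p.peak_dispersion, scale=p.peak_dispersion)
    neg = gamma_dist.pdf(
        t, p.undershoot_delay / p.undershoot_dispersion, scale=p.undershoot_dispersion
    )
    return pos - neg / p.undershoot_ratio


@dataclass
class GroundTruth:
    """Planted activation maps: per-voxel fractional signal change for each task."""

    beta_a: np.ndarray
    beta_b: np.ndarray
    brain_mask: np.ndarray
    baseline: float = 800.0

    def __post_init__(self) -> None:
        if self.beta_a.shape != self.brain_mask.shape or self.beta_b.shape != self.brain_mask.shape:
            raise ValueError("beta maps and mask must share a grid")
        if not (np.isfinite(self.beta_a).all() and np.isfinite(self.beta_b).all()):
            raise ValueError("beta maps must be finite")
        out = ~self.brain_mask
        if np.any(self.beta_a[out] != 0) or np.any(self.beta_b[out] != 0):
            raise ValueError("beta maps must be zero outside the brain mask")

    @property
    def discriminative_mask(self) -> np.ndarray:
        """Voxels where the two tasks differ (the decodable signal)."""
        return self.brain_mask & (self.beta_a != self.beta_b)


@dataclass(frozen=True)
class NoiseConfig:
    """Noise and nuisance amplitudes, as fractions of the baseline where scaled.

    sigma
        Stationary SD of AR(1) thermal noise (fraction of baseline).
    ar1_rho
        Lag-1 autocorrelation of the voxelwise noise.
    drift_amplitude
        Amplitude of the slow per-run cosine drift (fraction of baseline).
    global_fluct_sd
        SD of the brain-wide shared AR(1) fluctuation (fraction of baseline).
    motion_coupling
        Scale of motion-parameter leakage into voxel signal (fraction of
        baseline per unit motion).
    """

    sigma: float = 0.018
    ar1_rho: float = 0.3
    drift_amplitude: float = 0.01
    global_fluct_sd: float = 0.005
    motion_coupling: float = 0.004
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ar1_rho < 1:
            raise ValueError("ar1_rho must lie in [0, 1)")
        if min(self.sigma, self.drift_amplitude, self.global_fluct_sd, self.motion_coupling) < 0:
            raise ValueError("noise amplitudes must be non-negative")


@dataclass
class BoldRun:
    """One run's 4D time series plus its confound table and provenance.

    ``t_offset_scans`` records how many lead-in scans were removed from
    ``data`` relative to the schedule's full scan grid (0 for raw
    simulator output, ``n_dummy_scans`` after discarding).
    """

    data: np.ndarray
    schedule: RunSchedule
    confounds: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    t_offset_scans: int = 0

    def __post_init__(self) -> None:
        expected = self.schedule.n_scans - self.t_offset_scans
        if self.data.ndim != 4 or self.data.shape[3] != expected:
            raise ValueError(
                f"data has {self.data.shape[-1] if self.data.ndim == 4 else '?'} volumes, "
                f"schedule implies {expected}"
            )
        if len(self.confounds) != expected:
            raise ValueError("confound table must have one row per retained scan")

    @property
    def n_scans(self) -> int:
        return self.data.shape[3]


def make_ground_truth(
    grid_shape: tuple[int, int, int] = (12, 12, 8),
    *,
    effect_size: float = 0.012,
    blob_sigma_vox: float = 1.6,
    baseline: float = 800.0,
) -> GroundTruth:
    """Build the default planted truth: two partially overlapping smooth blobs.

    One blob responds more to task A, the other more to task B, so both
    directed GLM contrasts have voxels to find. ``effect_size`` is the
    blob-peak fractional signal change (0.012 = 1.2%, a typical cortical
    block-design response).
    """
    nx, ny, nz = grid_shape
    mask = _ellipsoid_mask(grid_shape)
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    sep = max(2.0, nx / 4)  # blob centers straddle the midline
    beta_a = effect_size * _gaussian_blob(grid_shape, (cx - sep / 2, cy, cz), blob_sigma_vox)
    beta_b = effect_size * _gaussian_blob(grid_shape, (cx + sep / 2, cy, cz), blob_sigma_vox)
    beta_a[~mask] = 0.0
    beta_b[~mask] = 0.0
    return GroundTruth(beta_a=beta_a, beta_b=beta_b, brain_mask=mask, baseline=baseline)


def _ellipsoid_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    nx, ny, nz = grid_shape
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    rx, ry, rz = max(nx / 2 - 1, 1), max(ny / 2 - 1, 1), max(nz / 2 - 1, 1)
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0


def _gaussian_blob(
    grid_shape: tuple[int, int, int], center: tuple[float, float, float], sigma: float
) -> np.ndarray:
    nx, ny, nz = grid_shape
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    return np.exp(-d2 / (2 * sigma**2))


def task_regressors(schedule: RunSchedule, hrf: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """HRF-convolved task boxcars (x_a, x_b) sampled on the run's scan grid.

    For alternating runs the boxcars follow the task blocks; for
    binary-answer runs each response window carries the task matching
    the trial's true answer. All blocks contribute regardless of
    acknowledgement (the subject performs the task either way).
    """
    tr = schedule.acquisition.tr_seconds
    if hrf is None:
        hrf = canonical_hrf(tr)
    n = schedule.n_scans
    box_a = np.zeros(n)
    box_b = np.zeros(n)
    for ev in schedule.events:
        if ev.label not in (BlockLabel.TASK_A, BlockLabel.TASK_B):
            continue
        i0 = round(ev.onset_seconds / tr)
        i1 = min(n, round(ev.end_seconds / tr))
        target = box_a if ev.label is BlockLabel.TASK_A else box_b
        target[i0:i1] = 1.0
    x_a = np.convolve(box_a, hrf)[:n]
    x_b = np.convolve(box_b, hrf)[:n]
    return x_a, x_b


def simulate_run(
    schedule: RunSchedule,
    truth: GroundTruth,
    noise: NoiseConfig,
    seed: int,
) -> BoldRun:
    """Simulate one run's 4D BOLD data.

    signal(v, t) = baseline * (1 + beta_a(v) x_a(t) + beta_b(v) x_b(t))
                   + drift + global fluctuation + motion-coupled term
                   + AR(1) Gaussian noise

    Out-of-mask voxels stay at zero. Deterministic given ``seed``.
    """
    if truth.brain_mask.shape != schedule.acquisition.grid_shape:
        raise ValueError(
            f"truth grid {truth.brain_mask.shape} does not match "
            f"acquisition grid {schedule.acquisition.grid_shape}"
        )
    rng = np.random.default_rng(seed)
    n = schedule.n_scans
    mask = truth.brain_mask
    n_vox = int(mask.sum())
    base = truth.baseline

    x_a, x_b = task_regressors(schedule)
    beta_a = truth.beta_a[mask]
    beta_b = truth.beta_b[mask]
    series = base * (1.0 + np.outer(beta_a, x_a) + np.outer(beta_b, x_b))  # (vox, t)

    # slow cosine drift, one phase per run, mild per-voxel amplitude spread
    if noise.drift_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        t_sec = np.arange(n) * schedule.acquisition.tr_seconds
        drift = np.cos(2 * np.pi * t_sec / schedule.duration_seconds + phase)
        amp = base * noise.drift_amplitude * rng.uniform(0.5, 1.5, size=n_vox)
        series += np.outer(amp, drift)

    # shared global fluctuation
    if noise.global_fluct_sd > 0:
        g = _ar1_series(rng, n, noise.ar1_rho, base * noise.global_fluct_sd)
        series += g[None, :]

    # motion: smoothed mean-reverting Gaussian walks (stationary AR(1) steps),
    # broad-band so nuisance regression does not silently eat the task band
    motion = _ar1_matrix(rng, (6, n), 0.4, 0.1).T
    motion = gaussian_filter1d(motion, sigma=1.0, axis=0)
    if noise.motion_coupling > 0:
        loadings = rng.normal(0, 1.0, size=(n_vox, 6))
        series += base * noise.motion_coupling * loadings @ motion.T

    # voxelwise AR(1) thermal noise
    if noise.sigma > 0:
        eps = _ar1_matrix(rng, (n_vox, n), noise.ar1_rho, base * noise.sigma)
        series += eps

    data = np.zeros(mask.shape + (n,), dtype=np.float64)
    data[mask] = series

    wm = gaussian_filter1d(rng.normal(0, 1.0, n), sigma=1.5) * base * 0.003 + base
    csf = gaussian_filter1d(rng.normal(0, 1.0, n), sigma=1.5) * base * 0.003 + base
    confounds = pd.DataFrame(
        np.column_stack([motion, wm, csf, series.mean(axis=0)]),
        columns=CONFOUND_COLUMNS,
    )
    provenance = {
        "seed": int(seed),
        "config_digest": _digest(asdict(noise) | {"baseline": base}),
    }
    return BoldRun(data=data, schedule=schedule, confounds=confounds, provenance=provenance)


def _ar1_series(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    return _ar1_matrix(rng, (1, n), rho, sd)[0]


def _ar1_matrix(rng: np.random.Generator, shape: tuple[int, int], rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) rows with marginal SD ``sd``."""
    n_series, n = shape
    w = rng.normal(0, 1.0, size=shape)
    out = np.empty(shape)
    out[:, 0] = w[:, 0]
    c = np.sqrt(1 - rho**2)
    for t in range(1, n):
        out[:, t] = rho * out[:, t - 1] + c * w[:, t]
    return out * sd


def _digest(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


@dataclass(frozen=True)
class ExperimentProtocol:
    """Run counts, timing, and answer key of the two-day experiment.

    Defaults reproduce the study paradigm: 8 day-1 alternating runs,
    3 day-2 alternating runs, 5 day-2 binary-answer runs with six
    statements each; TR 2 s, 3 dummy scans, 32 s task / 16 s rest
    blocks, 12 s statement-to-prompt delay, 24 s response windows.
    ``missed_acknowledgements`` maps a run key ("day1", "day2_alt",
    "day2_binary") and run index to task-block indices whose start cue
    went unacknowledged.
    """

    acquisition: AcquisitionParams = AcquisitionParams()
    n_day1_runs: int = 8
    n_day2_alt_runs: int = 3
    n_day2_binary_runs: int = 5
    n_cycles: int = 3
    task_seconds: float = 32.0
    rest_seconds: float = 16.0
    pre_prompt_seconds: float = 12.0
    response_seconds: float = 24.0
    inter_trial_rest_seconds: float = 16.0
    answer_key: tuple[Answer, ...] = DEFAULT_ANSWER_KEY
    missed_acknowledgements: tuple[tuple[str, int, tuple[int, ...]], ...] = ()


@dataclass
class SimulatedExperiment:
    day1: list[BoldRun]
    day2_alt: list[BoldRun]
    day2_binary: list[BoldRun]
    truth: GroundTruth
    protocol: ExperimentProtocol
    seed: int

    def groups(self) -> dict[str, list[BoldRun]]:
        return {"day1": self.day1, "day2_alt": self.day2_alt, "day2_binary": self.day2_binary}


def simulate_experiment(
    protocol: ExperimentProtocol,
    truth: GroundTruth,
    seed: int,
    noise: NoiseConfig | None = None,
) -> SimulatedExperiment:
    """Simulate the full two-day dataset; per-run seeds derive from the master seed."""
    noise = noise if noise is not None else NoiseConfig()
    missed = {(grp, idx): blocks for grp, idx, blocks in protocol.missed_acknowledgements}
    ss = np.random.SeedSequence(seed)
    n_total = protocol.n_day1_runs + protocol.n_day2_alt_runs + protocol.n_day2_binary_runs
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_total)]

    runs: dict[str, list[BoldRun]] = {"day1": [], "day2_alt": [], "day2_binary": []}
    k = 0
    for i in range(protocol.n_day1_runs):
        sched = build_alternating_run(
            protocol.acquisition, protocol.n_cycles, protocol.task_seconds,
            protocol.rest_seconds, run_id=i + 1, day=1,
        )
        if ("day1", i) in missed:
            sched = mark_unacknowledged(sched, list(missed[("day1", i)]))
        runs["day1"].append(simulate_run(sched, truth, noise, child_seeds[k]))
        k += 1
    for i in range(protocol.n_day2_alt_runs):
        sched = build_alternating_run(
            protocol.acquisition, protocol.n_cycles, protocol.task_seconds,
            protocol.rest_seconds, run_id=i + 1, day=2,
        )
        if ("day2_alt", i) in missed:
            sched = mark_unacknowledged(sched, list(missed[("day2_alt", i)]))
        runs["day2_alt"].append(simulate_run(sched, truth, noise, child_seeds[k]))
        k += 1
    for i in range(protocol.n_day2_binary_runs):
        sched = build_binary_answer_run(
            protocol.acquisition, list(protocol.answer_key),
            protocol.pre_prompt_seconds, protocol.response_seconds,
            protocol.inter_trial_rest_seconds, run_id=i + 1, day=2,
        )
        if ("day2_binary", i) in missed:
            sched = mark_unacknowledged(sched, list(missed[("day2_binary", i)]))
        runs["day2_binary"].append(simulate_run(sched, truth, noise, child_seeds[k]))
        k += 1

    return SimulatedExperiment(
        day1=runs["day1"], day2_alt=runs["day2_alt"], day2_binary=runs["day2_binary"],
        truth=truth, protocol=protocol, seed=seed,
    )


# ---------------------------------------------------------------------------
# on-disk representation: NIfTI + events TSV + confounds TSV + JSON sidecar

def _affine(acq: AcquisitionParams) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = acq.voxel_size_mm
    return aff


def write_run(run: BoldRun, out_dir: str | Path, prefix: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    acq = run.schedule.acquisition
    nib.save(nib.Nifti1Image(run.data.astype(np.float32), _affine(acq)), out / f"{prefix}_bold.nii.gz")
    schedule_to_events(run.schedule).to_csv(out / f"{prefix}_events.tsv", sep="\t", index=False)
    run.confounds.to_csv(out / f"{prefix}_confounds.tsv", sep="\t", index=False)
    meta = {
        "run_id": run.schedule.run_id,
        "day": run.schedule.day,
        "kind": run.schedule.kind.value,
        "t_offset_scans": run.t_offset_scans,
        "acquisition": {
            "tr_seconds": acq.tr_seconds,
            "n_dummy_scans": acq.n_dummy_scans,
            "grid_shape": list(acq.grid_shape),
            "voxel_size_mm": list(acq.voxel_size_mm),
        },
        "provenance": run.provenance,
    }
    (out / f"{prefix}_meta.json").write_text(json.dumps(meta, indent=2))


def read_run(out_dir: str | Path, prefix: str) -> BoldRun:
    out = Path(out_dir)
    meta = json.loads((out / f"{prefix}_meta.json").read_text())
    acq = AcquisitionParams(
        tr_seconds=meta["acquisition"]["tr_seconds"],
        n_dummy_scans=meta["acquisition"]["n_dummy_scans"],
        grid_shape=tuple(meta["acquisition"]["grid_shape"]),
        voxel_size_mm=tuple(meta["acquisition"]["voxel_size_mm"]),
    )
    events = pd.read_csv(out / f"{prefix}_events.tsv", sep="\t")
    sched = schedule_from_events(
        events, acq, run_id=meta["run_id"], day=meta["day"], kind=RunKind(meta["kind"])
    )
    data = np.asarray(nib.load(out / f"{prefix}_bold.nii.gz").get_fdata(), dtype=np.float64)
    confounds = pd.read_csv(out / f"{prefix}_confounds.tsv", sep="\t")
    return BoldRun(
        data=data, schedule=sched, confounds=confounds,
        provenance=meta.get("provenance", {}), t_offset_scans=meta.get("t_offset_scans", 0),
    )


def write_experiment(exp: SimulatedExperiment, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for group, rs in exp.groups().items():
        for i, run in enumerate(rs):
            write_run(run, out, f"{group}_run-{i + 1:02d}")
    t = exp.truth
    aff = _affine(exp.protocol.acquisition)
    nib.save(nib.Nifti1Image(t.beta_a.astype(np.float32), aff), out / "truth_beta_a.nii.gz")
    nib.save(nib.Nifti1Image(t.beta_b.astype(np.float32), aff), out / "truth_beta_b.nii.gz")
    nib.save(nib.Nifti1Image(t.brain_mask.astype(np.uint8), aff), out / "truth_brain_mask.nii.gz")
    manifest = {
        "seed": exp.seed,
        "baseline": t.baseline,
        "n_runs": {g: len(rs) for g, rs in exp.groups().items()},
        "answer_key": [a.value for a in exp.protocol.answer_key],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_experiment(out_dir: str | Path) -> SimulatedExperiment:
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    groups: dict[str, list[BoldRun]] = {}
    for group, n in manifest["n_runs"].items():
        groups[group] = [read_run(out, f"{group}_run-{i + 1:02d}") for i in range(n)]
    beta_a = np.asarray(nib.load(out / "truth_beta_a.nii.gz").get_fdata())
    beta_b = np.asarray(nib.load(out / "truth_beta_b.nii.gz").get_fdata())
    mask = np.asarray(nib.load(out / "truth_brain_mask.nii.gz").get_fdata()) > 0
    truth = GroundTruth(beta_a=beta_a, beta_b=beta_b, brain_mask=mask, baseline=manifest["baseline"])
    any_run = groups["day1"][0] if groups["day1"] else next(rs[0] for rs in groups.values() if rs)
    protocol = ExperimentProtocol(
        acquisition=any_run.schedule.acquisition,
        n_day1_runs=len(groups.get("day1", [])),
        n_day2_alt_runs=len(groups.get("day2_alt", [])),
        n_day2_binary_runs=len(groups.get("day2_binary", [])),
        answer_key=tuple(Answer(a) for a in manifest["answer_key"]),
    )
    return SimulatedExperiment(
        day1=groups.get("day1", []), day2_alt=groups.get("day2_alt", []),
        day2_binary=groups.get("day2_binary", []),
        truth=truth, protocol=protocol, seed=manifest["seed"],
    )
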