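"""Univariate GLM, task contrasts, and split-half feature-mask generation.

Voxels preferentially engaged by either mental task are found with a
run-concatenated GLM on spatially smoothed data: HRF-convolved 32 s
boxcars for the two tasks (acknowledged blocks only), six motion
parameters, per-run constants and per-run DCT drift terms (0.0078 Hz),
with serial correlation handled by a single pooled AR(1) prewhitening.
Directed contrasts (A > B and B > A) are thresholded voxelwise at
p < 0.001 uncorrected (P001) or p < 0.05 Bonferroni-corrected over
tested voxels (FWE05); the union of the two surviving sets is the
feature mask. Masks are built separately from odd and even runs so the
voxels used to select features never see the scans used for training.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .paradigm import BlockLabel, RunSchedule
from .preprocess import dct_basis, drop_dummy_scans, smooth_run
from .synthsim import BoldRun, canonical_hrf

__all__ = [
    "GlmConfig",
    "GlmFit",
    "TMap",
    "ThresholdKind",
    "FeatureMask",
    "DegenerateDesignError",
    "build_design_matrix",
    "fit_glm",
    "contrast_tmap",
    "threshold_mask",
    "union_contrast_masks",
    "split_half_masks",
    "glm_feature_masks",
]


class DegenerateDesignError(ValueError):
    """Raised when a task condition has no acknowledged blocks or the design is singular."""


class ThresholdKind(str, enum.Enum):
    P001 = "p001"          # p < 0.001 uncorrected
    FWE05 = "fwe05"        # p < 0.05 Bonferroni over tested voxels
    WHOLE_BRAIN = "whole_brain"


@dataclass(frozen=True)
class GlmConfig:
    hp_cutoff_hz: float = 0.0078
    use_ar1: bool = True
    boxcar_seconds: float = 32.0
    smooth_fwhm_mm: float = 8.0


@dataclass
class GlmFit:
    """Fitted GLM: coefficients, residual variance, and the (whitened) design."""

    beta: np.ndarray        # (n_regressors, n_voxels)
    sigma2: np.ndarray      # (n_voxels,)
    dof: float
    rho: float
    design: np.ndarray      # whitened design actually used in the final fit
    column_names: list[str]

    def __post_init__(self) -> None:
        if np.any(self.sigma2 < -1e-12):
            raise ValueError("sigma2 must be non-negative")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")


@dataclass
class TMap:
    t: np.ndarray           # 3D volume, zero outside support
    contrast: np.ndarray
    dof: float
    support: np.ndarray     # boolean volume of evaluated voxels


@dataclass
class FeatureMask:
    mask: np.ndarray        # boolean volume
    threshold_kind: ThresholdKind
    source_runs: list[int]
    cutoff_t: float | None = None

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def build_design_matrix(
    runs: list[BoldRun],
    cfg: GlmConfig | None = None,
    hrf: np.ndarray | None = None,
) -> tuple[np.ndarray, list[slice], list[str]]:
    """Run-concatenated design: task regressors, motion, per-run constants and DCT drift.

    Task boxcars are placed at acknowledged block onsets only and
    convolved with the canonical HRF on the full scan grid before the
    dummy lead-in is cut, so onset timing stays exact. Returns the
    design, per-run row slices, and column names.
    """
    cfg = cfg or GlmConfig()
    if not runs:
        raise DegenerateDesignError("need at least one run")
    tr = runs[0].schedule.acquisition.tr_seconds
    if hrf is None:
        hrf = canonical_hrf(tr)

    n_ack = {BlockLabel.TASK_A: 0, BlockLabel.TASK_B: 0}
    task_cols, motion_rows, run_lengths = [], [], []
    for run in runs:
        sched = run.schedule
        offset = run.t_offset_scans
        full_n = sched.n_scans
        box = {BlockLabel.TASK_A: np.zeros(full_n), BlockLabel.TASK_B: np.zeros(full_n)}
        for ev in sched.events:
            if ev.label in box and ev.acknowledged:
                i0 = round(ev.onset_seconds / tr)
                i1 = min(full_n, round((ev.onset_seconds + cfg.boxcar_seconds) / tr))
                box[ev.label][i0:i1] = 1.0
                n_ack[ev.label] += 1
        # convolve on the full scan grid, then cut whatever lead-in the data lost
        conv = {lab: np.convolve(b, hrf)[:full_n][offset:] for lab, b in box.items()}
        task_cols.append(np.column_stack([conv[BlockLabel.TASK_A], conv[BlockLabel.TASK_B]]))
        motion_rows.append(run.confounds[["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]].to_numpy())
        run_lengths.append(run.n_scans)

    for lab, count in n_ack.items():
        if count == 0:
            raise DegenerateDesignError(f"no acknowledged blocks for {lab.value}")

    n_total = sum(run_lengths)
    slices, start = [], 0
    for ln in run_lengths:
        slices.append(slice(start, start + ln))
        start += ln

    interest = np.vstack(task_cols)
    motion = np.vstack(motion_rows)
    constants = np.zeros((n_total, len(runs)))
    dct_blocks = []
    names = ["task_a", "task_b"] + [f"motion_{i}" for i in range(6)]
    for r, (run, sl) in enumerate(zip(runs, slices)):
        constants[sl, r] = 1.0
        names.append(f"constant_run{r + 1}")
    for r, (run, sl) in enumerate(zip(runs, slices)):
        basis = dct_basis(run.n_scans, tr, cfg.hp_cutoff_hz)
        blk = np.zeros((n_total, basis.shape[1]))
        blk[sl] = basis
        dct_blocks.append(blk)
        names += [f"dct_run{r + 1}_{j + 1}" for j in range(basis.shape[1])]
    X = np.hstack([interest, motion, constants] + dct_blocks)
    return X, slices, names


def _pooled_rho(resid: np.ndarray, slices: list[slice]) -> float:
    """Single AR(1) coefficient pooled over voxels and runs from lag-1 residual products."""
    num = den = 0.0
    for sl in slices:
        r = resid[sl]
        num += float(np.sum(r[1:] * r[:-1]))
        den += float(np.sum(r[:-1] ** 2))
    if den == 0:
        return 0.0
    return float(np.clip(num / den, -0.99, 0.99))


def _whiten(A: np.ndarray, rho: float, slices: list[slice]) -> np.ndarray:
    """AR(1) differencing within each run; each run's first row is dropped."""
    parts = [A[sl][1:] - rho * A[sl][:-1] for sl in slices]
    return np.vstack(parts)


def fit_glm(
    Y: np.ndarray,
    X: np.ndarray,
    cfg: GlmConfig | None = None,
    run_slices: list[slice] | None = None,
    column_names: list[str] | None = None,
) -> GlmFit:
    """Fit the GLM by OLS, optionally with pooled-AR(1) prewhitening.

    With AR(1) enabled, a single rho is estimated from the lag-1
    autocorrelation of the OLS residuals, both sides are prewhitened by
    the differencing transform (dropping each run's first row), and the
    model is refit. dof = rows - rank(X) on the matrix actually fit.
    """
    cfg = cfg or GlmConfig()
    Y = np.asarray(Y, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    if Y.shape[0] != X.shape[0]:
        raise ValueError(f"Y has {Y.shape[0]} rows, X has {X.shape[0]}")
    if X.shape[0] < X.shape[1]:
        raise DegenerateDesignError("fewer rows than design columns")
    slices = run_slices or [slice(0, X.shape[0])]

    rank = np.linalg.matrix_rank(X)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rho = 0.0
    Xw, Yw = X, Y
    if cfg.use_ar1:
        rho = _pooled_rho(resid, slices)
        Xw = _whiten(X, rho, slices)
        Yw = _whiten(Y, rho, slices)
        rank = np.linalg.matrix_rank(Xw)
        beta, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
        resid = Yw - Xw @ beta
    dof = Xw.shape[0] - rank
    if dof <= 0:
        raise DegenerateDesignError("non-positive degrees of freedom")
    sigma2 = np.maximum(np.sum(resid**2, axis=0) / dof, 0.0)
    return GlmFit(
        beta=beta, sigma2=sigma2, dof=float(dof), rho=rho, design=Xw,
        column_names=column_names or [f"x{i}" for i in range(X.shape[1])],
    )


def contrast_tmap(
    fit: GlmFit, c: np.ndarray, support: np.ndarray, grid_shape: tuple[int, int, int] | None = None
) -> TMap:
    """t statistic of contrast c: t = c'beta / sqrt(sigma2 * c'(X'X)^-1 c).

    ``support`` is the boolean volume of voxels the fit covers (in the
    order of Y's columns). t is 0 where both sigma2 and c'beta vanish.
    """
    c = np.asarray(c, dtype=np.float64)
    if c.shape[0] != fit.beta.shape[0]:
        raise ValueError(f"contrast length {c.shape[0]} != {fit.beta.shape[0]} regressors")
    XtX = fit.design.T @ fit.design
    cvc = float(c @ np.linalg.pinv(XtX) @ c)
    cb = c @ fit.beta
    denom = np.sqrt(np.maximum(fit.sigma2 * cvc, 0.0))
    t = np.zeros_like(cb)
    ok = denom > 0
    t[ok] = cb[ok] / denom[ok]
    exact = ~ok & (cb != 0)  # zero residual variance but a real effect
    t[exact] = np.sign(cb[exact]) * np.inf
    vol = np.zeros(support.shape if grid_shape is None else grid_shape)
    vol[support] = t
    return TMap(t=vol, contrast=c, dof=fit.dof, support=support)


def threshold_mask(
    tmap: TMap, kind: ThresholdKind, n_voxels_tested: int | None = None,
    source_runs: list[int] | None = None,
) -> FeatureMask:
    """Keep voxels whose one-sided p beats the threshold for ``kind``.

    P001: p < 0.001 under Student-t(dof). FWE05: Bonferroni,
    p < 0.05 / n_voxels_tested.
    """
    if tmap.dof <= 0:
        raise ValueError("dof must be positive")
    if kind is ThresholdKind.WHOLE_BRAIN:
        return FeatureMask(tmap.support.copy(), kind, source_runs or [], None)
    if kind is ThresholdKind.P001:
        alpha = 0.001
    else:
        if not n_voxels_tested or n_voxels_tested < 1:
            raise ValueError("FWE05 needs the number of voxels tested")
        alpha = 0.05 / n_voxels_tested
    cutoff = float(stats.t.isf(alpha, tmap.dof))
    mask = tmap.support & (tmap.t > cutoff)
    return FeatureMask(mask, kind, source_runs or [], cutoff)


def union_contrast_masks(mask_ab: FeatureMask, mask_ba: FeatureMask) -> FeatureMask:
    """Voxelwise OR of the two directed-contrast masks (disjoint by construction)."""
    if mask_ab.mask.shape != mask_ba.mask.shape:
        raise ValueError("masks must share a grid")
    if mask_ab.threshold_kind is not mask_ba.threshold_kind:
        raise ValueError("masks must share a threshold kind")
    return FeatureMask(
        mask_ab.mask | mask_ba.mask,
        mask_ab.threshold_kind,
        sorted(set(mask_ab.source_runs) | set(mask_ba.source_runs)),
        mask_ab.cutoff_t,
    )


def glm_feature_masks(
    runs: list[BoldRun],
    brain_mask: np.ndarray,
    cfg: GlmConfig | None = None,
    *,
    presmoothed: bool = False,
) -> dict[ThresholdKind, FeatureMask]:
    """GLM branch for one run set: smooth, fit, contrast both directions, threshold, union."""
    cfg = cfg or GlmConfig()
    prepped = []
    for run in runs:
        run = drop_dummy_scans(run)
        if not presmoothed:
            run = smooth_run(run, cfg.smooth_fwhm_mm)
        prepped.append(run)
    X, slices, names = build_design_matrix(prepped, cfg)
    Y = np.concatenate([r.data[brain_mask] for r in prepped], axis=1).T  # (t, vox)
    fit = fit_glm(Y, X, cfg, slices, names)
    c = np.zeros(X.shape[1])
    c[0], c[1] = 1.0, -1.0
    src = [r.schedule.run_id for r in runs]
    n_tested = int(brain_mask.sum())
    out: dict[ThresholdKind, FeatureMask] = {}
    for kind in (ThresholdKind.P001, ThresholdKind.FWE05):
        m_ab = threshold_mask(contrast_tmap(fit, c, brain_mask), kind, n_tested, src)
        m_ba = threshold_mask(contrast_tmap(fit, -c, brain_mask), kind, n_tested, src)
        out[kind] = union_contrast_masks(m_ab, m_ba)
    return out


def split_half_masks(
    day1_runs: list[BoldRun],
    brain_mask: np.ndarray,
    cfg: GlmConfig | None = None,
) -> dict[str, dict[ThresholdKind, FeatureMask]]:
    """Odd/even split of the day-1 runs: masks from one half select features for the other.

    Returns ``{"odd": {...}, "even": {...}}`` keyed by threshold kind;
    the mask fitted on the odd runs (1, 3, 5, 7) is paired with
    training data from the even runs and vice versa.
    """
    if len(day1_runs) < 2 or len(day1_runs) % 2:
        raise DegenerateDesignError("split-half needs an even number of runs, at least 2")
    odd = day1_runs[0::2]   # runs 1, 3, 5, 7 (1-based ids)
    even = day1_runs[1::2]  # runs 2, 4, 6, 8
    return {
        "odd": glm_feature_masks(odd, brain_mask, cfg),
        "even": glm_feature_masks(even, brain_mask, cfg),
    }
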