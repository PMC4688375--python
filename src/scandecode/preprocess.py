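"""Voxelwise clean-up applied before classification, and smoothing for the GLM branch.

The classification branch runs, in order: nuisance regression (motion,
white-matter/CSF means, global signal, per-session constant) -> DCT
high-pass at 0.008 Hz -> per-session grand-mean scaling to 100 ->
day-level per-voxel z-scoring pooled over the day's runs. The GLM
branch instead receives spatially smoothed, unstandardized data; the
two branches share only the raw runs.

Because residualization removes each voxel's mean, the session-mean
image is added back before grand-mean scaling -- a zero-mean series
cannot be scaled to a grand mean of 100. All operations respect the
brain mask: out-of-mask voxels are never touched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .synthsim import BoldRun

__all__ = [
    "PreprocConfig",
    "dct_basis",
    "drop_dummy_scans",
    "regress_nuisance",
    "highpass_dct",
    "grand_mean_scale",
    "standardize_day",
    "gaussian_smooth",
    "smooth_run",
    "preprocess_day",
    "ScalingError",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class ScalingError(ValueError):
    """Raised when grand-mean scaling is impossible (non-positive grand mean)."""


@dataclass(frozen=True)
class PreprocConfig:
    hp_cutoff_hz: float = 0.008
    grand_mean_target: float = 100.0
    smooth_fwhm_mm: float = 8.0  # GLM branch only

    def validate(self, tr_seconds: float) -> None:
        nyquist = 1.0 / (2.0 * tr_seconds)
        if not 0 < self.hp_cutoff_hz < nyquist:
            raise ValueError(f"hp_cutoff_hz must lie in (0, {nyquist}) for TR={tr_seconds}")
        if self.grand_mean_target <= 0:
            raise ValueError("grand_mean_target must be positive")
        if self.smooth_fwhm_mm < 0:
            raise ValueError("smooth_fwhm_mm must be non-negative")


def _with_data(run: BoldRun, data: np.ndarray, step: str) -> BoldRun:
    prov = dict(run.provenance)
    prov["preprocessing"] = list(prov.get("preprocessing", [])) + [step]
    return BoldRun(
        data=data, schedule=run.schedule, confounds=run.confounds,
        provenance=prov, t_offset_scans=run.t_offset_scans,
    )


def drop_dummy_scans(run: BoldRun) -> BoldRun:
    """Discard the lead-in scans (magnetic saturation) from data and confounds."""
    nd = run.schedule.acquisition.n_dummy_scans
    if run.t_offset_scans:
        return run
    prov = dict(run.provenance)
    prov["preprocessing"] = list(prov.get("preprocessing", [])) + [f"drop_dummy_scans({nd})"]
    return BoldRun(
        data=run.data[..., nd:],
        schedule=run.schedule,
        confounds=run.confounds.iloc[nd:].reset_index(drop=True),
        provenance=prov,
        t_offset_scans=nd,
    )


def _residualize(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """OLS residuals of each column of Y against the columns of X."""
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("rank-deficient regressor matrix; using pseudoinverse", stacklevel=3)
        beta = np.linalg.pinv(X) @ Y
    else:
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


def regress_nuisance(
    run: BoldRun,
    mask: np.ndarray,
    regressors: np.ndarray | None = None,
    *,
    add_constant: bool = True,
) -> BoldRun:
    """Replace each in-mask voxel's series by its OLS residual against the nuisance set.

    By default the regressors are the run's confound table (six motion
    parameters, white-matter/CSF means, global signal) plus a session
    constant. Residuals are orthogonal to every regressor column.
    """
    X = run.confounds.to_numpy(dtype=np.float64) if regressors is None else np.asarray(regressors, dtype=np.float64)
    if X.shape[0] != run.n_scans:
        raise ValueError(f"regressors have {X.shape[0]} rows, run has {run.n_scans} scans")
    if add_constant:
        X = np.column_stack([X, np.ones(X.shape[0])])
    Y = run.data[mask].T  # (t, vox)
    resid = _residualize(Y, X)
    data = run.data.copy()
    data[mask] = resid.T
    return _with_data(run, data, "regress_nuisance")


def dct_basis(n_scans: int, tr_seconds: float, cutoff_hz: float) -> np.ndarray:
    """Discrete-cosine drift basis: components j >= 1 with j / (2 D) < cutoff, D = run seconds.

    Basis column j is cos(pi (2t+1) j / (2 N)); all columns have zero
    mean, so residualizing against them preserves the series mean.
    """
    D = n_scans * tr_seconds
    k = int(np.floor(2 * D * cutoff_hz))
    if k * 1.0 / (2 * D) >= cutoff_hz:  # strict inequality at the boundary
        k -= 1
    if k < 1:
        return np.empty((n_scans, 0))
    t = np.arange(n_scans)
    return np.column_stack(
        [np.cos(np.pi * (2 * t + 1) * j / (2 * n_scans)) for j in range(1, k + 1)]
    )


def highpass_dct(run: BoldRun, mask: np.ndarray, cutoff_hz: float = 0.008) -> BoldRun:
    """High-pass filter by residualizing against the low-frequency DCT basis."""
    tr = run.schedule.acquisition.tr_seconds
    if cutoff_hz >= 1.0 / (2 * tr):
        raise ValueError("cutoff must be below the Nyquist frequency")
    X = dct_basis(run.n_scans, tr, cutoff_hz)
    data = run.data.copy()
    if X.shape[1]:
        Y = run.data[mask].T
        data[mask] = _residualize(Y, X).T
    return _with_data(run, data, f"highpass_dct({cutoff_hz})")


def grand_mean_scale(run: BoldRun, mask: np.ndarray, target: float = 100.0) -> BoldRun:
    """Multiplicatively rescale so the mean over in-mask voxels x scans equals ``target``."""
    if not mask.any():
        raise ValueError("brain mask is empty")
    gm = float(run.data[mask].mean())
    if gm <= 0:
        raise ScalingError(f"grand mean {gm} is not positive; cannot scale to {target}")
    data = run.data.copy()
    data[mask] = run.data[mask] * (target / gm)
    return _with_data(run, data, f"grand_mean_scale({target})")


def standardize_day(runs: list[BoldRun], mask: np.ndarray) -> list[BoldRun]:
    """Z-score each voxel using mean/SD pooled over the whole day's runs.

    Statistics are computed on the concatenated series across the day's
    runs -- not per run -- so between-run level differences survive as
    signal. Zero-variance voxels are set to zero with a warning.
    """
    if not runs:
        raise ValueError("need at least one run")
    concat = np.concatenate([r.data[mask] for r in runs], axis=1)  # (vox, t_total)
    mu = concat.mean(axis=1)
    sd = concat.std(axis=1, ddof=0)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} zero-variance voxels set to zero", stacklevel=2)
        sd = np.where(zero_var, 1.0, sd)
    out = []
    for r in runs:
        data = r.data.copy()
        z = (r.data[mask] - mu[:, None]) / sd[:, None]
        z[zero_var] = 0.0
        data[mask] = z
        out.append(_with_data(r, data, "standardize_day"))
    return out


def gaussian_smooth(
    volume: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: tuple[float, float, float],
) -> np.ndarray:
    """Separable Gaussian smoothing with constant (zero) padding; fwhm=0 is the identity."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm_mm == 0:
        return volume.copy()
    sigmas = [fwhm_mm * FWHM_TO_SIGMA / vs for vs in voxel_size_mm]
    # truncate at 6 sigma so the discarded tail mass is < 1e-9 of the kernel
    return gaussian_filter(volume, sigma=sigmas, mode="constant", cval=0.0, truncate=6.0)


def smooth_run(run: BoldRun, fwhm_mm: float = 8.0) -> BoldRun:
    """Smooth each volume of a run (GLM branch)."""
    vs = run.schedule.acquisition.voxel_size_mm
    data = np.stack(
        [gaussian_smooth(run.data[..., t], fwhm_mm, vs) for t in range(run.n_scans)], axis=-1
    )
    return _with_data(run, data, f"gaussian_smooth(fwhm={fwhm_mm})")


def preprocess_day(
    runs: list[BoldRun],
    mask: np.ndarray,
    cfg: PreprocConfig | None = None,
) -> list[BoldRun]:
    """Full classification-branch chain for one day's runs.

    Per run: drop dummies -> nuisance regression (+ session-mean
    add-back) -> DCT high-pass -> grand-mean scaling; then day-level
    z-scoring pooled across the runs.
    """
    cfg = cfg or PreprocConfig()
    if runs:
        cfg.validate(runs[0].schedule.acquisition.tr_seconds)
    staged = []
    for run in runs:
        run = drop_dummy_scans(run)
        session_mean = run.data[mask].mean(axis=1)
        run = regress_nuisance(run, mask)
        # restore the session mean removed by the constant regressor so that
        # grand-mean scaling has a positive level to work with
        data = run.data.copy()
        data[mask] = run.data[mask] + session_mean[:, None]
        run = _with_data(run, data, "restore_session_mean")
        run = highpass_dct(run, mask, cfg.hp_cutoff_hz)
        run = grand_mean_scale(run, mask, cfg.grand_mean_target)
        staged.append(run)
    return standardize_day(staged, mask)
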