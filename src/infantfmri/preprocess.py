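"""Motion realignment, detrending, spatial smoothing, motion summaries.

Realignment follows the correlation-maximisation scheme: every volume is
rigid-body transformed to maximise its Pearson correlation with the image
obtained by averaging intensity at each voxel over the whole session; the
mean is then recomputed from the aligned volumes and the fit repeated.
Slow scan-to-scan intensity effects are handled by per-voxel removal of
linear trends rather than an explicit spin-history model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .session import Session4D, apply_rigid

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


@dataclass
class MotionTrace:
    """Per-volume rigid motion estimates (mm / degrees) with summaries."""

    translations_mm: np.ndarray  # (n_vols, 3)
    rotations_deg: np.ndarray  # (n_vols, 3)
    converged: bool = True

    def __post_init__(self):
        self.translations_mm = np.atleast_2d(np.asarray(self.translations_mm, dtype=float))
        self.rotations_deg = np.atleast_2d(np.asarray(self.rotations_deg, dtype=float))
        if self.translations_mm.shape != self.rotations_deg.shape:
            raise ValueError("translation/rotation shape mismatch")

    @property
    def n_vols(self) -> int:
        return self.translations_mm.shape[0]

    @property
    def max_translation_mm(self) -> float:
        return float(np.abs(self.translations_mm).max())

    @property
    def mean_abs_translation_mm(self) -> float:
        return float(np.abs(self.translations_mm).mean())

    @property
    def max_rotation_deg(self) -> float:
        return float(np.abs(self.rotations_deg).max())

    @property
    def mean_abs_rotation_deg(self) -> float:
        return float(np.abs(self.rotations_deg).mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.hstack([self.translations_mm, self.rotations_deg]),
            columns=["tx", "ty", "tz", "rx", "ry", "rz"],
        ).rename_axis("volume")

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def _neg_corr(params, volume, mean_img, spacing):
    moved = apply_rigid(volume, params, spacing, inverse=True, mode="nearest")
    a = moved.ravel() - moved.mean()
    b = mean_img.ravel() - mean_img.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return -float(a @ b) / denom


def realign(
    session: Session4D,
    max_iter: int = 2,
    tol: float = 0.01,
) -> tuple:
    """Realign every volume to the session's time-average image.

    For each volume a 6-parameter rigid transform (3 translations, 3
    rotations) is fitted by direction-set (Powell) line search to maximise
    the Pearson correlation with the voxelwise mean image.  After one pass
    the mean is recomputed from the aligned volumes and the fit repeated,
    up to ``max_iter`` passes or until no parameter moves by more than
    ``tol`` (mm or degrees).  Returns the aligned session and the motion
    trace (the estimated motion of each volume; the applied correction is
    its inverse).
    """
    if session.n_vols < 2:
        raise ValueError("realignment needs at least 2 volumes")
    data = session.data.astype(float)
    if np.ptp(data) == 0:
        raise ValueError("constant-intensity session cannot be realigned")
    spacing = session.geom.spacing_mm
    n = session.n_vols
    params = np.zeros((n, 6))
    aligned = data.copy()
    converged = True
    for it in range(max_iter):
        mean_img = aligned.mean(axis=3)
        prev = params.copy()
        for v in range(n):
            f0 = _neg_corr(params[v], data[..., v], mean_img, spacing)
            res = optimize.minimize(
                _neg_corr,
                params[v],
                args=(data[..., v], mean_img, spacing),
                method="Powell",
                options={"xtol": tol / 10, "ftol": 1e-8, "maxiter": 50},
            )
            if res.fun <= f0:  # never accept a step that lowers the objective
                params[v] = res.x
            aligned[..., v] = apply_rigid(
                data[..., v], params[v], spacing, inverse=True, mode="nearest"
            )
        if np.abs(params - prev).max() < tol:
            break
    else:
        if np.abs(params - prev).max() >= tol:
            converged = False
            warnings.warn("realignment did not converge; returning best-so-far parameters")
    trace = MotionTrace(params[:, :3], params[:, 3:], converged=converged)
    out = session.with_data(aligned, realigned=True, realign_converged=converged)
    return out, trace


def detrend(session: Session4D) -> Session4D:
    """Remove the per-voxel OLS linear trend, preserving the voxel mean."""
    if session.n_vols < 3:
        raise ValueError("detrending needs at least 3 volumes")
    t = np.arange(session.n_vols, dtype=float)
    t = t - t.mean()
    data = session.data.astype(float)
    slope = (data * t).sum(axis=3, keepdims=True) / (t @ t)
    out = data - slope * t
    return session.with_data(out, detrended=True)


def smooth(session: Session4D, fwhm_mm: float = 7.2) -> Session4D:
    """Isotropic (in mm) Gaussian smoothing, volume by volume.

    The kernel sigma is set per axis in voxel units from the voxel spacing,
    so anisotropic voxels still receive an isotropic smooth in world space.
    Reflective boundary handling preserves the local mean near edges.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return session.copy()
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / session.geom.spacing_mm
    data = session.data.astype(float)
    out = np.empty_like(data)
    for v in range(session.n_vols):
        out[..., v] = ndimage.gaussian_filter(data[..., v], sigma=sigma_vox, mode="reflect")
    return session.with_data(out, smoothed_fwhm_mm=fwhm_mm)


def measured_fwhm_mm(volume: np.ndarray, spacing_mm, centre=None) -> np.ndarray:
    """FWHM of a (roughly Gaussian) peak along each axis, in mm.

    Profiles through the peak are interpolated linearly to locate the
    half-maximum crossings.  Used to verify the smoothing kernel width.
    """
    spacing = np.asarray(spacing_mm, dtype=float)
    if centre is None:
        centre = np.unravel_index(np.argmax(volume), volume.shape)
    half = volume[tuple(centre)] / 2.0
    widths = []
    for ax in range(3):
        idx = list(centre)
        idx[ax] = slice(None)
        prof = volume[tuple(idx)]
        x = np.arange(prof.size, dtype=float)
        above = prof >= half
        if not above.any():
            widths.append(np.nan)
            continue
        lo, hi = np.argmax(above), prof.size - 1 - np.argmax(above[::-1])
        left = x[lo]
        if lo > 0:
            left = np.interp(half, [prof[lo - 1], prof[lo]], [x[lo - 1], x[lo]])
        right = x[hi]
        if hi < prof.size - 1:
            right = np.interp(half, [prof[hi + 1], prof[hi]], [x[hi + 1], x[hi]])
        widths.append((right - left) * spacing[ax])
    return np.array(widths)


def flag_excessive_motion(trace: MotionTrace, max_translation_mm: float) -> bool:
    """Exclusion rule: moved excessively if any translation exceeds the bound.

    The default bound used by the pipeline is one in-plane voxel; this is a
    configurable artifact default, not a literature value.
    """
    return trace.max_translation_mm > max_translation_mm


def compare_motion(traces_a, traces_b, n_perm: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Permutation two-sample comparison of group motion summaries.

    For mean absolute translation and rotation, the observed difference of
    group means is referred to the permutation distribution over random
    relabelings (exhaustive when feasible within ``n_perm``).
    """
    if len(traces_a) < 2 or len(traces_b) < 2:
        raise ValueError("need at least 2 motion traces per group")
    from .inference import two_sample_perm

    rows = []
    for name, get in (
        ("mean_abs_translation_mm", lambda t: t.mean_abs_translation_mm),
        ("mean_abs_rotation_deg", lambda t: t.mean_abs_rotation_deg),
    ):
        a = np.array([[get(t)] for t in traces_a])
        b = np.array([[get(t)] for t in traces_b])
        res = two_sample_perm(a, b, n_perm=n_perm, seed=seed)
        rows.append((name, float(res.t_obs[0]), float(res.p_uncorrected[0])))
    return pd.DataFrame(rows, columns=["measure", "statistic", "p_value"])
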