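"""Data-driven HRF estimation and per-subject GLM fitting.

Adult canonical HRFs are a poor model for infants, so the impulse response
is estimated from the data themselves: an auditory experiment produces a
dominant auditory response, and the HRF is recovered in auditory cortex by
finite-impulse-response (FIR) deconvolution of the ROI-mean time series
against the all-sounds stimulus boxcar.  To avoid statistical bias, each
infant's final GLM uses the mean HRF of all *other* infants
(leave-one-subject-out), so the kernel entering a subject's fit never
depends on that subject's own data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .paradigm import CATEGORIES, DesignMatrix, HRFKernel, ParadigmSchedule
from .session import Session4D

#: canonical contrast weight vectors over (neutral, positive, negative, environmental)
CONTRASTS = {
    "positive_vs_baseline": (0.0, 1.0, 0.0, 0.0),
    "negative_vs_baseline": (0.0, 0.0, 1.0, 0.0),
    "positive_vs_negative": (0.0, 1.0, -1.0, 0.0),
    "all_sounds": (1.0, 1.0, 1.0, 1.0),
}


class SingularDeconvolutionError(np.linalg.LinAlgError):
    pass


@dataclass
class BetaMaps:
    """Per-voxel GLM response estimates, one map per condition."""

    beta: dict  # condition -> 3-D array
    residual_variance: np.ndarray
    dof: int
    design_ref: str
    mask: np.ndarray | None = None
    subject_id: str = ""

    @property
    def conditions(self) -> tuple:
        return tuple(self.beta.keys())

    def stacked(self, conditions=None) -> np.ndarray:
        conds = conditions or self.conditions
        return np.stack([self.beta[c] for c in conds], axis=0)

    def scaled(self, factor: float) -> "BetaMaps":
        return BetaMaps(
            {c: b * factor for c, b in self.beta.items()},
            self.residual_variance * factor**2,
            self.dof,
            self.design_ref,
            self.mask,
            self.subject_id,
        )


@dataclass
class ContrastMap:
    values: np.ndarray
    weights: tuple
    subject_id: str = ""


def roi_mean_timeseries(session: Session4D, mask: np.ndarray, label: int) -> np.ndarray:
    """Arithmetic mean time series over voxels with ``mask == label``."""
    if mask.shape != session.grid_shape:
        raise ValueError("mask does not match the session grid")
    sel = mask == label
    if not sel.any():
        raise ValueError(f"no voxels carry label {label}")
    return session.data[sel].mean(axis=0)


def stimulus_boxcar(schedule: ParadigmSchedule, tr_s: float, n_vols: int, categories=None) -> np.ndarray:
    """Stimulus indicator sampled at frame times (1 when a block is on)."""
    cats = tuple(categories) if categories is not None else CATEGORIES
    t = np.arange(n_vols) * tr_s
    box = np.zeros(n_vols)
    for b in schedule.blocks:
        if b.category in cats:
            box[(t >= b.onset_s) & (t < b.end_s)] = 1.0
    return box


def deconvolve_hrf(
    series: np.ndarray,
    schedule: ParadigmSchedule,
    tr_s: float = 3.0,
    window_s: float = 24.0,
    ridge: float = 0.01,
    categories=None,
) -> HRFKernel:
    """FIR deconvolution of a time series against the stimulus boxcar.

    The series is regressed on lagged copies of the (by default
    category-agnostic, all-sounds) stimulus boxcar at lags 0..window_s in
    TR steps, with an intercept.  A ridge penalty of
    ``ridge * mean(diag(X'X))`` stabilises the normal equations; ``ridge=0``
    requests plain least squares and raises if the design is singular.
    Returns the kernel normalised to unit peak; the raw peak amplitude is
    kept in the kernel metadata.
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    if window_s > n * tr_s:
        raise ValueError("deconvolution window exceeds the series duration")
    n_lags = int(round(window_s / tr_s))
    box = stimulus_boxcar(schedule, tr_s, n, categories)
    X = np.zeros((n, n_lags + 1))
    X[:, 0] = 1.0
    for j in range(n_lags):
        X[j:, j + 1] = box[: n - j]
    XtX = X.T @ X
    Xty = X.T @ series
    if ridge > 0:
        penalty = ridge * float(np.mean(np.diag(XtX))) * np.eye(XtX.shape[0])
        penalty[0, 0] = 0.0  # never penalise the intercept
        coef = np.linalg.solve(XtX + penalty, Xty)
    else:
        if np.linalg.matrix_rank(XtX) < XtX.shape[0]:
            raise SingularDeconvolutionError(
                "FIR design is rank deficient; use ridge > 0 to regularise"
            )
        coef = np.linalg.solve(XtX, Xty)
    values = coef[1:]
    peak = float(np.max(np.abs(values))) if values.size else 0.0
    # standard error of the FIR coefficients under white residuals
    resid = series - X @ coef
    dof = max(n - X.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    try:
        se = np.sqrt(sigma2 * np.diag(np.linalg.inv(XtX + (penalty if ridge > 0 else 0.0))))[1:]
    except np.linalg.LinAlgError:
        se = np.full(values.size, np.nan)
    meta = {
        "kind": "fir",
        "name": "fir",
        "raw_peak_amplitude": peak,
        "raw_values": values.copy(),
        "raw_se": se,
        "ridge": ridge,
    }
    kern = HRFKernel(tr_s, values if peak == 0 else values / peak, meta)
    return kern


def fir_reference(kernel: HRFKernel, tr_s: float, n_lags: int) -> HRFKernel:
    """Resample a finely sampled kernel onto the FIR lag grid.

    The FIR coefficient at lag j is the response to a TR-long stimulus bin,
    i.e. the continuous kernel averaged over ((j-1)*TR, j*TR].  Use this as
    the like-for-like reference when comparing a deconvolved kernel with a
    known ground-truth kernel.
    """
    t = kernel.times_s
    vals = []
    for j in range(n_lags):
        sel = (t > (j - 1) * tr_s) & (t <= j * tr_s)
        vals.append(kernel.values[sel].mean() if sel.any() else 0.0)
    return HRFKernel(tr_s, np.array(vals), {"kind": "fir_reference"}).normalized()


def loo_mean_hrf(kernels, held_out_index: int) -> HRFKernel:
    """Mean HRF over all kernels except ``held_out_index``, unit-peak.

    Each kernel is peak-normalised before averaging so subjects contribute
    shape, not amplitude.  The result is, by construction, independent of
    the held-out subject's kernel — the property that makes the final
    per-subject GLM unbiased by that subject's own data.
    """
    kernels = list(kernels)
    if len(kernels) < 2:
        raise ValueError("leave-one-out averaging needs at least 2 kernels")
    if not 0 <= held_out_index < len(kernels):
        raise IndexError("held_out_index out of range")
    dt = kernels[0].dt_s
    size = kernels[0].values.size
    rest = [k for i, k in enumerate(kernels) if i != held_out_index]
    for k in rest:
        if abs(k.dt_s - dt) > 1e-12 or k.values.size != size:
            raise ValueError("kernels must share a common time grid")
    mean = np.mean([k.normalized().values for k in rest], axis=0)
    return HRFKernel(dt, mean, {"kind": "loo_mean", "name": "loo", "n": len(rest)}).normalized()


def analysis_mask(session: Session4D, fraction: float = 0.1) -> np.ndarray:
    """In-brain mask: voxels whose temporal mean exceeds ``fraction`` of the
    grid-wide mean intensity."""
    mean_img = session.mean_volume()
    return mean_img > fraction * mean_img.mean()


def fit_glm(
    session: Session4D,
    design: DesignMatrix,
    percent: bool = True,
    mask: np.ndarray | None = None,
    beta_mode: str = "first",
) -> BetaMaps:
    """Ordinary-least-squares GLM at every voxel.

    An intercept column is added internally.  With ``percent=True`` betas
    are converted to percent signal change about the voxel baseline (the
    fitted intercept, which unlike the temporal mean is uncontaminated by
    task signal), i.e. percent per unit regressor.  When a condition has
    several basis columns, the per-condition beta is the first-basis
    coefficient (``beta_mode='first'``, sign-preserving) or the
    root-sum-square amplitude (``beta_mode='rss'``).
    """
    if design.columns.shape[0] != session.n_vols:
        raise ValueError("design rows must equal the number of volumes")
    X = np.column_stack([np.ones(session.n_vols), design.columns])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X, ("intercept", *design.column_labels))
        raise np.linalg.LinAlgError(f"rank-deficient design; collinear columns: {bad}")

    shape = session.grid_shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    Y = session.data[mask].T.astype(float)  # (n_vols, n_masked)
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    dof = session.n_vols - rank
    sigma2 = (resid**2).sum(axis=0) / dof
    if percent:
        baseline = np.where(np.abs(coef[0]) > 1e-12, coef[0], 1.0)
        coef = coef * (100.0 / baseline)
        sigma2 = sigma2 * (100.0 / baseline) ** 2

    # group basis columns by condition prefix "condition:kernel"
    conditions, col_idx = [], {}
    for j, lab in enumerate(design.column_labels):
        cond = lab.split(":", 1)[0]
        if cond not in col_idx:
            col_idx[cond] = []
            conditions.append(cond)
        col_idx[cond].append(j + 1)  # +1 for the intercept column

    beta = {}
    for cond in conditions:
        idx = col_idx[cond]
        if len(idx) == 1 or beta_mode == "first":
            flat = coef[idx[0]]
        elif beta_mode == "rss":
            flat = np.sign(coef[idx[0]]) * np.sqrt(sum(coef[i] ** 2 for i in idx))
        else:
            raise ValueError(f"unknown beta_mode {beta_mode!r}")
        vol = np.zeros(shape)
        vol[mask] = flat
        beta[cond] = vol
    var = np.zeros(shape)
    var[mask] = sigma2
    return BetaMaps(beta, var, dof, design.hrf_used, mask, session.subject_id)


def _collinear_columns(X, labels):
    bad = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        proj, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        if np.linalg.norm(X[:, j] - others @ proj) < 1e-8 * max(np.linalg.norm(X[:, j]), 1.0):
            bad.append(labels[j])
    return bad or list(labels)


def plateau_scale(kernel: HRFKernel) -> float:
    """Sum of kernel samples: the asymptotic block-plateau amplitude of a
    boxcar regressor built from this kernel.  Multiplying GLM betas by this
    factor converts them to percent signal change at block plateau."""
    return float(kernel.values.sum())


def make_contrast(betas: BetaMaps, weights, subject_id: str | None = None) -> ContrastMap:
    """Per-voxel weighted sum of condition betas."""
    weights = tuple(float(w) for w in weights)
    if len(weights) != len(betas.conditions):
        raise ValueError(
            f"{len(weights)} weights for {len(betas.conditions)} conditions"
        )
    values = np.zeros_like(next(iter(betas.beta.values())))
    for w, cond in zip(weights, betas.conditions):
        values = values + w * betas.beta[cond]
    return ContrastMap(values, weights, subject_id if subject_id is not None else betas.subject_id)
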