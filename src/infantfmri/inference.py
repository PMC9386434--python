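"""Permutation-based group inference on voxel maps.

Group statistics are referred to permutation null distributions rather than
parametric ones — an assumption-light choice suited to small infant
cohorts.  The one-sample test flips the signs of per-subject effects; the
two-sample test (which, applied to per-subject positive-minus-negative
contrasts, is the group x valence interaction test) relabels group
membership.  One set of flips/relabelings per permutation is shared across
all voxels, preserving the spatial structure of the null so that
cluster-level summaries of permuted maps are valid.

Cluster handling: supra-threshold voxels are labelled into connected
components and small components dropped; multiple comparisons are handled
either by Benjamini-Yekutieli FDR over voxel-wise permutation p values or
by a cluster-size threshold calibrated so the expected number of
false-positive clusters per null image stays below a target.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}
_PERM_CHUNK = 4000  # permutations per block, bounds memory at many voxels


@dataclass
class PermutationResult:
    t_obs: np.ndarray
    p_uncorrected: np.ndarray
    n_perm: int
    seed: int
    null_mean: np.ndarray
    null_sd: np.ndarray
    zero_variance: np.ndarray
    exhaustive: bool = False
    shape: tuple = ()
    t_null: np.ndarray | None = None  # (n_perm, n_voxels), kept on request

    def p_volume(self) -> np.ndarray:
        return self.p_uncorrected.reshape(self.shape) if self.shape else self.p_uncorrected

    def t_volume(self) -> np.ndarray:
        return self.t_obs.reshape(self.shape) if self.shape else self.t_obs


def _flatten(values):
    values = np.asarray(values, dtype=float)
    if values.ndim < 2:
        raise ValueError("values must be (n_subjects, n_voxels) or (n_subjects, *grid)")
    shape = values.shape[1:]
    return values.reshape(values.shape[0], -1), shape


def _one_sample_t(mean, sumsq, n):
    var = (sumsq - n * mean**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
        return np.where(var > 0, t, np.where(mean == 0, 0.0, np.copysign(np.inf, mean)))


def one_sample_perm(
    values,
    n_perm: int = 40_000,
    seed: int = 0,
    return_null: bool = False,
) -> PermutationResult:
    """Sign-flip permutation test of mean 0, two-sided on the one-sample t.

    The null is built by randomly negating each subject's values (the same
    flips applied to every voxel within a permutation);
    ``p = (#{|t_perm| >= |t_obs|} + 1) / (n_perm + 1)``.  When ``n_perm``
    covers all ``2^n`` sign patterns the enumeration is exhaustive and the
    p value is exact (``#{|t_full| >= |t_obs|} / 2^n``).  Zero-variance
    voxels are flagged and given p = 1.
    """
    V, shape = _flatten(values)
    n = V.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    sumsq = (V**2).sum(axis=0)
    t_obs = _one_sample_t(V.mean(axis=0), sumsq, n)
    zero_var = (sumsq - n * V.mean(axis=0) ** 2) <= 1e-300
    t_obs = np.where(zero_var, 0.0, t_obs)

    exhaustive = n <= 20 and n_perm >= 2**n
    if exhaustive:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        n_total = signs.shape[0]
    else:
        rng = np.random.default_rng(seed)
        signs = None
        n_total = n_perm

    count = np.zeros(V.shape[1])
    s1 = np.zeros(V.shape[1])
    s2 = np.zeros(V.shape[1])
    kept = [] if return_null else None
    abs_obs = np.abs(t_obs)
    done = 0
    while done < n_total:
        m = min(_PERM_CHUNK, n_total - done)
        S = signs[done:done + m] if exhaustive else rng.choice([-1.0, 1.0], size=(m, n))
        mean_p = (S @ V) / n
        t_p = _one_sample_t(mean_p, sumsq, n)
        t_p = np.where(np.isfinite(t_p), t_p, 0.0)
        count += (np.abs(t_p) >= abs_obs - 1e-12).sum(axis=0)
        s1 += t_p.sum(axis=0)
        s2 += (t_p**2).sum(axis=0)
        if return_null:
            kept.append(t_p)
        done += m

    if exhaustive:
        p = count / n_total
    else:
        p = (count + 1.0) / (n_total + 1.0)
    p = np.where(zero_var, 1.0, np.minimum(p, 1.0))
    null_mean = s1 / n_total
    null_sd = np.sqrt(np.maximum(s2 / n_total - null_mean**2, 0.0))
    return PermutationResult(
        t_obs, p, n_total, seed, null_mean, null_sd, zero_var, exhaustive, shape,
        np.vstack(kept) if return_null else None,
    )


def _two_sample_t(sum_a, sumsq_a, na, sum_b, sumsq_b, nb):
    mean_a, mean_b = sum_a / na, sum_b / nb
    ss = (sumsq_a - na * mean_a**2) + (sumsq_b - nb * mean_b**2)
    sp2 = np.maximum(ss, 0.0) / (na + nb - 2)
    diff = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        return np.where(sp2 > 0, t, np.where(diff == 0, 0.0, np.copysign(np.inf, diff)))


def two_sample_perm(
    values_a,
    values_b,
    n_perm: int = 40_000,
    seed: int = 0,
    return_null: bool = False,
) -> PermutationResult:
    """Group-relabeling permutation test on the two-sample pooled-variance t.

    Applied to per-subject positive-minus-negative contrast maps with the
    exposure groups as labels, this is the group x valence interaction
    test.  Exhaustive over all ``C(na+nb, na)`` relabelings when ``n_perm``
    covers them.
    """
    A, shape_a = _flatten(values_a)
    B, shape_b = _flatten(values_b)
    if shape_a != shape_b:
        raise ValueError("groups must share the voxel grid")
    na, nb = A.shape[0], B.shape[0]
    if min(na, nb) < 2:
        raise ValueError("need at least 2 subjects per group")
    V = np.vstack([A, B])
    n = na + nb
    tot = V.sum(axis=0)
    totsq = (V**2).sum(axis=0)
    sum_a, sumsq_a = A.sum(axis=0), (A**2).sum(axis=0)
    t_obs = _two_sample_t(sum_a, sumsq_a, na, tot - sum_a, totsq - sumsq_a, nb)
    pooled_var = totsq - sum_a**2 / na - (tot - sum_a) ** 2 / nb
    zero_var = pooled_var <= 1e-300
    t_obs = np.where(zero_var, 0.0, t_obs)

    n_comb = math.comb(n, na)
    exhaustive = n <= 30 and n_comb <= n_perm
    if exhaustive:
        combos = list(itertools.combinations(range(n), na))
        n_total = n_comb
    else:
        rng = np.random.default_rng(seed)
        n_total = n_perm

    count = np.zeros(V.shape[1])
    s1 = np.zeros(V.shape[1])
    s2 = np.zeros(V.shape[1])
    kept = [] if return_null else None
    abs_obs = np.abs(t_obs)
    done = 0
    idx_all = np.arange(n)
    while done < n_total:
        m = min(_PERM_CHUNK, n_total - done)
        sel = np.zeros((m, n))
        if exhaustive:
            for i, combo in enumerate(combos[done:done + m]):
                sel[i, list(combo)] = 1.0
        else:
            for i in range(m):
                sel[i, rng.choice(idx_all, size=na, replace=False)] = 1.0
        sum_pa = sel @ V
        sumsq_pa = sel @ (V**2)
        t_p = _two_sample_t(sum_pa, sumsq_pa, na, tot - sum_pa, totsq - sumsq_pa, nb)
        t_p = np.where(np.isfinite(t_p), t_p, 0.0)
        count += (np.abs(t_p) >= abs_obs - 1e-12).sum(axis=0)
        s1 += t_p.sum(axis=0)
        s2 += (t_p**2).sum(axis=0)
        if return_null:
            kept.append(t_p)
        done += m

    p = count / n_total if exhaustive else (count + 1.0) / (n_total + 1.0)
    p = np.where(zero_var, 1.0, np.minimum(p, 1.0))
    null_mean = s1 / n_total
    null_sd = np.sqrt(np.maximum(s2 / n_total - null_mean**2, 0.0))
    return PermutationResult(
        t_obs, p, n_total, seed, null_mean, null_sd, zero_var, exhaustive, shape_a,
        np.vstack(kept) if return_null else None,
    )


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _structure(connectivity: int):
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be one of 6, 18, 26")
    return ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])


def threshold_and_cluster(
    result: PermutationResult,
    alpha: float = 0.005,
    min_size: int = 3,
    connectivity: int = 6,
    q_values: np.ndarray | None = None,
    q_alpha: float | None = None,
    roi_masks: np.ndarray | None = None,
):
    """Label supra-threshold voxels into connected components.

    Voxels with ``p <= alpha`` (and, when given, ``q <= q_alpha``) are
    labelled under the stated connectivity; components smaller than
    ``min_size`` are dropped.  Returns ``(table, labels)`` where the table
    rows are sorted by size descending and ``labels`` is the surviving
    component volume.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if not result.shape or len(result.shape) != 3:
        raise ValueError("clustering needs a 3-D result (pass (n_subj, x, y, z) values)")
    p = result.p_volume()
    t = result.t_volume()
    supra = (p <= alpha) & ~result.zero_variance.reshape(result.shape)
    if q_values is not None and q_alpha is not None:
        supra &= np.asarray(q_values).reshape(result.shape) <= q_alpha
    labels, n_lab = ndimage.label(supra, structure=_structure(connectivity))
    rows = []
    out_labels = np.zeros_like(labels)
    next_id = 1
    for lab in range(1, n_lab + 1):
        member = labels == lab
        size = int(member.sum())
        if size < min_size:
            continue
        tm = np.where(member, np.abs(t), -np.inf)
        peak = np.unravel_index(np.argmax(tm), tm.shape)
        roi_set = ()
        if roi_masks is not None:
            roi_set = tuple(sorted(int(v) for v in np.unique(roi_masks[member]) if v > 0))
        rows.append(
            {
                "cluster_id": next_id,
                "size_voxels": size,
                "peak_statistic": float(t[peak]),
                "peak_x": peak[0],
                "peak_y": peak[1],
                "peak_z": peak[2],
                "member_roi_labels": roi_set,
                "p_cluster": float(p[member].min()),
                "q_fdr": float(np.asarray(q_values).reshape(result.shape)[member].min())
                if q_values is not None
                else np.nan,
            }
        )
        out_labels[member] = next_id
        next_id += 1
    table = pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "size_voxels", "peak_statistic", "peak_x", "peak_y",
            "peak_z", "member_roi_labels", "p_cluster", "q_fdr",
        ],
    )
    if len(table):
        table = table.sort_values("size_voxels", ascending=False, ignore_index=True)
        remap = {old: new for new, old in enumerate(table["cluster_id"], start=1)}
        out_labels = np.vectorize(lambda v: remap.get(v, 0))(out_labels)
        table["cluster_id"] = np.arange(1, len(table) + 1)
    return table, out_labels


def fdr_correct(p_values, method: str = "by") -> np.ndarray:
    """Benjamini-Yekutieli step-up q values (valid under arbitrary
    dependence via the sum(1/i) correction factor)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p values must lie in (0, 1]")
    key = {"by": "fdr_by", "bh": "fdr_bh"}[method.lower()]
    _, q, _, _ = multipletests(p.ravel(), alpha=0.05, method=key)
    return q.reshape(p.shape)


def cluster_size_null(
    t_null: np.ndarray,
    shape,
    alpha: float = 0.005,
    connectivity: int = 6,
) -> list:
    """Per-permutation supra-threshold cluster sizes from a stored null.

    Each permuted map is converted to within-stream voxel p values (the
    rank of its |t| among that voxel's null draws) and thresholded at
    ``alpha``; sizes of the resulting connected components are returned per
    permutation.
    """
    n_perm = t_null.shape[0]
    abs_t = np.abs(t_null)
    # p of permutation j at voxel v = fraction of null draws with |t| >= |t_j(v)|
    ranks = stats.rankdata(abs_t, axis=0, method="min")
    p_null = (n_perm - ranks + 1) / n_perm
    struct = _structure(connectivity)
    sizes = []
    for j in range(n_perm):
        supra = p_null[j].reshape(shape) <= alpha
        labels, n_lab = ndimage.label(supra, structure=struct)
        if n_lab:
            sizes.append(np.bincount(labels.ravel())[1:].tolist())
        else:
            sizes.append([])
    return sizes


def cluster_fp_threshold(null_cluster_sizes, expected_fp: float = 1.0, min_size: int = 1) -> int:
    """Smallest cluster-size threshold keeping the imagewise expected number
    of false-positive clusters below ``expected_fp``.

    ``null_cluster_sizes`` is a list (one entry per permuted image) of the
    cluster sizes observed in that image.
    """
    if not null_cluster_sizes:
        raise ValueError("empty null distribution")
    if not np.isfinite(expected_fp):
        return min_size
    n_img = len(null_cluster_sizes)
    all_sizes = [s for img in null_cluster_sizes for s in img]
    max_size = max(all_sizes, default=0)
    for s in range(min_size, max_size + 2):
        mean_count = sum(1 for sz in all_sizes if sz >= s) / n_img
        if mean_count < expected_fp:
            return s
    warnings.warn("requested false-positive expectation unattainable; returning max size + 1")
    return max_size + 1


# ---------------------------------------------------------------------------
# two-way ANOVA with permutation p values
# ---------------------------------------------------------------------------

def _dummies(labels):
    levels = list(pd.unique(labels))
    return np.column_stack([(labels == lev).astype(float) for lev in levels[1:]]), len(levels)


class _AnovaDesigns:
    """QR-projection machinery for type-II two-way ANOVA F statistics.

    RSS under each nested model is ``||y||^2 - ||Q'y||^2`` with Q an
    orthonormal basis of the model's column space; only y changes across
    permutations, so each F evaluation costs a few mat-vecs.
    """

    def __init__(self, a_codes, b_codes):
        n = len(a_codes)
        one = np.ones((n, 1))
        Da, ka = _dummies(np.asarray(a_codes))
        Db, kb = _dummies(np.asarray(b_codes))
        Dab = np.column_stack([Da[:, i] * Db[:, j] for i in range(Da.shape[1]) for j in range(Db.shape[1])]) if Da.size and Db.size else np.empty((n, 0))
        self.df_a, self.df_b = ka - 1, kb - 1
        self.df_ab = self.df_a * self.df_b
        self.Q = {
            "b_only": np.linalg.qr(np.column_stack([one, Db]))[0],
            "a_only": np.linalg.qr(np.column_stack([one, Da]))[0],
            "add": np.linalg.qr(np.column_stack([one, Da, Db]))[0],
            "full": np.linalg.qr(np.column_stack([one, Da, Db, Dab]))[0],
        }
        self.df_res = n - self.Q["full"].shape[1]
        if self.df_res <= 0:
            raise ValueError("no residual degrees of freedom for the full model")

    def _rss(self, key, y, yy):
        q = self.Q[key].T @ y
        return yy - q @ q

    def f_stats(self, y):
        yy = y @ y
        tol = 1e-12 * max(yy, 1.0)  # numerical floor for sums of squares
        rss_full = self._rss("full", y, yy)
        rss_add = self._rss("add", y, yy)
        ms_res = rss_full / self.df_res
        out = {}
        for name, ss, df in (
            ("A", self._rss("b_only", y, yy) - rss_add, self.df_a),
            ("B", self._rss("a_only", y, yy) - rss_add, self.df_b),
            ("A:B", rss_add - rss_full, self.df_ab),
        ):
            ss = 0.0 if ss < tol else ss
            if ms_res < tol:
                out[name] = 0.0 if ss == 0.0 else np.inf
            else:
                out[name] = ss / df / ms_res
        return out

    def additive_fit(self, y):
        Q = self.Q["add"]
        fitted = Q @ (Q.T @ y)
        return fitted, y - fitted


def _anova_f(y, a_codes, b_codes):
    """Classical two-way ANOVA F statistics (type II sums of squares)."""
    return _AnovaDesigns(a_codes, b_codes).f_stats(np.asarray(y, dtype=float))


def twoway_anova_perm(
    values,
    factor_a,
    factor_b,
    n_perm: int = 2000,
    seed: int = 0,
    exhaustive: bool = False,
) -> dict:
    """Two-way ANOVA with permutation p values per effect.

    F statistics are the classical (type II) ones.  The interaction p comes
    from permutation of residuals under the additive model (Freedman-Lane);
    each main effect's p from restricted permutation of observations within
    the levels of the other factor.  With ``exhaustive=True`` (two-level
    factors) main-effect p values enumerate all within-stratum label
    assignments exactly.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    if y.ndim != 1 or y.size != a.size or y.size != b.size:
        raise ValueError("values and factor labels must be equal-length 1-D")
    for la in np.unique(a):
        for lb in np.unique(b):
            if not np.any((a == la) & (b == lb)):
                raise ValueError(f"empty cell: A={la!r}, B={lb!r}")
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        raise ValueError("need at least 2 levels per factor")

    designs = _AnovaDesigns(a, b)
    f_obs = designs.f_stats(y)
    rng = np.random.default_rng(seed)
    out = {}

    # interaction: Freedman-Lane permutation of additive-model residuals
    fitted, resid = designs.additive_fit(y)
    if np.allclose(resid, 0):
        out["A:B"] = {"F": f_obs["A:B"], "p": 1.0}
    else:
        count = 0
        for _ in range(n_perm):
            y_star = fitted + rng.permutation(resid)
            count += designs.f_stats(y_star)["A:B"] >= f_obs["A:B"] - 1e-12
        out["A:B"] = {"F": f_obs["A:B"], "p": (count + 1) / (n_perm + 1)}

    # main effects: permute observations within the strata of the other
    # factor (equivalent to relabeling that factor within strata)
    for name, fac, strat in (("A", a, b), ("B", b, a)):
        if exhaustive:
            perms = _exhaustive_within_strata(fac, strat)
            count = 0
            for pf in perms:
                d = _AnovaDesigns(pf, b) if name == "A" else _AnovaDesigns(a, pf)
                count += d.f_stats(y)[name] >= f_obs[name] - 1e-12
            out[name] = {"F": f_obs[name], "p": count / len(perms)}
        else:
            strata = [np.where(strat == lev)[0] for lev in np.unique(strat)]
            count = 0
            for _ in range(n_perm):
                y_p = y.copy()
                for idx in strata:
                    y_p[idx] = y_p[idx][rng.permutation(len(idx))]
                count += designs.f_stats(y_p)[name] >= f_obs[name] - 1e-12
            out[name] = {"F": f_obs[name], "p": (count + 1) / (n_perm + 1)}
    return out


def _exhaustive_within_strata(fac, strat):
    """All distinct within-stratum reassignments of a two-level factor."""
    levels = np.unique(fac)
    if levels.size != 2:
        raise ValueError("exhaustive enumeration supports two-level factors only")
    strata = [np.where(strat == lev)[0] for lev in np.unique(strat)]
    per_stratum = []
    for idx in strata:
        k = int(np.sum(fac[idx] == levels[0]))
        per_stratum.append([set(c) for c in itertools.combinations(idx, k)])
    perms = []
    for combo in itertools.product(*per_stratum):
        pf = np.empty_like(fac)
        pf[:] = levels[1]
        for chosen in combo:
            for i in chosen:
                pf[i] = levels[0]
        perms.append(pf)
    return perms


# ---------------------------------------------------------------------------
# interaction summaries
# ---------------------------------------------------------------------------

def interaction_summary(
    cluster_table: pd.DataFrame,
    cluster_labels: np.ndarray,
    betas_by_subject,
    groups,
    conditions=("positive", "negative"),
    n_boot: int = 1000,
    seed: int = 0,
) -> list:
    """Per-cluster group x condition cell means with bootstrap bounds.

    ``betas_by_subject`` is one mapping per subject from condition name to a
    3-D beta/contrast map; ``groups`` the per-subject group labels.  Cell
    means are in-cluster spatial means averaged over the subjects of each
    group; 95% percentile bootstrap bounds resample subjects within group.
    The direction flag encodes the valence preference ordering:
    ``control>PMD_for_positive`` / ``PMD>control_for_negative`` when the
    control group prefers positive and the PMD group (weakly) prefers
    negative sounds, ``mixed`` otherwise.
    """
    if cluster_table.empty:
        raise ValueError("cluster table is empty")
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    group_levels = ("control", "PMD") if set(groups) == {"control", "PMD"} else tuple(pd.unique(groups))
    summaries = []
    for _, row in cluster_table.iterrows():
        member = cluster_labels == row["cluster_id"]
        per_subj = {
            cond: np.array([maps[cond][member].mean() for maps in betas_by_subject])
            for cond in conditions
        }
        cells = {}
        for g in group_levels:
            gi = np.where(groups == g)[0]
            for cond in conditions:
                vals = per_subj[cond][gi]
                boots = np.array([
                    vals[rng.integers(0, vals.size, vals.size)].mean() for _ in range(n_boot)
                ])
                cells[(g, cond)] = {
                    "mean": float(vals.mean()),
                    "lo": float(np.percentile(boots, 2.5)),
                    "hi": float(np.percentile(boots, 97.5)),
                }
        flag = _direction_flag(cells, group_levels, conditions)
        summaries.append({"cluster_id": int(row["cluster_id"]), "cells": cells, "direction": flag})
    return summaries


def _direction_flag(cells, group_levels, conditions):
    if set(group_levels) != {"control", "PMD"} or len(conditions) != 2:
        return "mixed"
    pos, neg = conditions
    c_pos, c_neg = cells[("control", pos)]["mean"], cells[("control", neg)]["mean"]
    p_pos, p_neg = cells[("PMD", pos)]["mean"], cells[("PMD", neg)]["mean"]
    if c_pos > c_neg and p_neg >= p_pos:
        if (c_pos - p_pos) >= (p_neg - c_neg):
            return "control>PMD_for_positive"
        return "PMD>control_for_negative"
    return "mixed"
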