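"""End-to-end orchestration: simulate -> preprocess -> fit -> infer -> report.

The pipeline chains the stage modules under a single serializable
configuration with explicit seeds, tracks per-subject inclusion/exclusion
with reasons, and emits a run manifest sufficient to re-run identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .hrf_glm import (
    CONTRASTS,
    deconvolve_hrf,
    fit_glm,
    loo_mean_hrf,
    make_contrast,
    plateau_scale,
    roi_mean_timeseries,
)
from .inference import (
    fdr_correct,
    interaction_summary,
    threshold_and_cluster,
    twoway_anova_perm,
    two_sample_perm,
)
from .paradigm import build_design, build_schedule
from .preprocess import MotionTrace, compare_motion, detrend, flag_excessive_motion, smooth, realign
from .session import AcquisitionGeometry
from .synthetic import (
    EffectSpec,
    cohort_table,
    make_cohort,
    make_roi_masks,
    roi_label,
    simulate_session,
)

log = logging.getLogger("infantfmri")


def _check_unknown(d: dict, cls) -> dict:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    return d


@dataclass(frozen=True)
class ParadigmConfig:
    blocks_per_category: int = 8
    block_s: float = 21.0
    rest_s: float = 9.0
    sounds_range: tuple = (7, 11)
    gap_range_s: tuple = (0.47, 0.75)


@dataclass(frozen=True)
class PreprocessConfig:
    fwhm_mm: float = 7.2
    realign: str = "auto"  # "always" | "never" | "auto" (only when motion present)
    exclusion_translation_mm: float = 3.5  # one in-plane voxel; artifact default


@dataclass(frozen=True)
class HRFConfig:
    window_s: float = 24.0
    ridge: float = 0.01
    mode: str = "loo"  # "loo" (data-driven, leave-one-out) | "gamma" (two-basis)


@dataclass(frozen=True)
class InferenceConfig:
    alpha: float = 0.005
    min_cluster_size: int = 3
    n_perm: int = 40_000
    connectivity: int = 6
    fdr: str = "by"  # "by" | "cluster-fp" | "none"
    q_alpha: float | None = None  # set to gate clusters on BY q as well
    expected_fp_clusters: float = 1.0
    n_boot: int = 1000


@dataclass(frozen=True)
class PipelineConfig:
    n_per_group: object = 29  # int or (n_pmd, n_control)
    n_corrupted: tuple = (0, 0)
    seed: int = 0
    grid_shape: tuple = (24, 24, 24)
    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    hrf: HRFConfig = field(default_factory=HRFConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    effects: EffectSpec = field(default_factory=EffectSpec)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(_check_unknown(d, cls))
        for key, sub in (
            ("paradigm", ParadigmConfig),
            ("preprocess", PreprocessConfig),
            ("hrf", HRFConfig),
            ("inference", InferenceConfig),
            ("effects", EffectSpec),
        ):
            if key in d and isinstance(d[key], dict):
                sub_d = _check_unknown(d[key], sub)
                if key == "effects" and "beta_true" in sub_d:
                    sub_d = dict(sub_d)
                    sub_d["beta_true"] = {tuple(k.split("|")): v for k, v in sub_d["beta_true"].items()}
                d[key] = sub(**sub_d)
        for tup_key in ("n_corrupted", "grid_shape"):
            if tup_key in d and isinstance(d[tup_key], list):
                d[tup_key] = tuple(d[tup_key])
        if isinstance(d.get("n_per_group"), list):
            d["n_per_group"] = tuple(d["n_per_group"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effects"]["beta_true"] = {"|".join(k): v for k, v in self.effects.beta_true.items()}
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    config: dict
    config_hash: str
    version: str
    subjects: list  # dicts: subject_id, group, included, reason
    stages: dict = field(default_factory=dict)

    def included(self, group: str | None = None) -> list:
        return [
            s for s in self.subjects
            if s["included"] and (group is None or s["group"] == group)
        ]

    def counts(self) -> dict:
        out = {}
        for g in ("PMD", "control"):
            subj = [s for s in self.subjects if s["group"] == g]
            out[g] = {
                "recruited": len(subj),
                "included": sum(s["included"] for s in subj),
                "excluded": sum(not s["included"] for s in subj),
            }
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "config_hash": self.config_hash,
                "version": self.version,
                "subjects": self.subjects,
                "stages": self.stages,
            },
            indent=2,
            default=str,
        )


@dataclass
class PipelineResult:
    manifest: RunManifest
    cluster_table: pd.DataFrame
    cluster_labels: np.ndarray
    interaction: list
    t_map: np.ndarray
    p_map: np.ndarray
    motion_comparison: pd.DataFrame | None
    anovas: dict
    cohort: pd.DataFrame


def apply_exclusions(records, traces, threshold_mm: float) -> list:
    """Inclusion/exclusion bookkeeping mirroring infant-fMRI practice:
    sessions flagged corrupted (infant woke) or with excessive motion are
    dropped, each with a recorded reason."""
    rows = []
    for rec, trace in zip(records, traces):
        if rec.corrupted:
            rows.append(
                {"subject_id": rec.subject_id, "group": rec.group, "included": False,
                 "reason": "woke or moved excessively"}
            )
        elif trace is not None and flag_excessive_motion(trace, threshold_mm):
            rows.append(
                {"subject_id": rec.subject_id, "group": rec.group, "included": False,
                 "reason": f"max translation > {threshold_mm} mm"}
            )
        else:
            rows.append(
                {"subject_id": rec.subject_id, "group": rec.group, "included": True,
                 "reason": ""}
            )
    return rows


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineResult:
    """Execute the full chain on a synthetic cohort.

    Deterministic under the config seed: re-running with an identical
    config reproduces every map and table bitwise.
    """
    cfg = config
    geom = AcquisitionGeometry(grid_shape=tuple(cfg.grid_shape))
    schedule = build_schedule(
        blocks_per_category=cfg.paradigm.blocks_per_category,
        block_s=cfg.paradigm.block_s,
        rest_s=cfg.paradigm.rest_s,
        sounds_range=tuple(cfg.paradigm.sounds_range),
        gap_range_s=tuple(cfg.paradigm.gap_range_s),
        seed=cfg.seed,
    )
    roi_masks = make_roi_masks(geom.grid_shape)
    records = make_cohort(cfg.n_per_group, cfg.effects, seed=cfg.seed, n_corrupted=tuple(cfg.n_corrupted))
    log.info("cohort: %d subjects", len(records))

    motion_on = (
        cfg.effects.max_translation_mm > 0
        or cfg.effects.max_rotation_deg > 0
        or any(r.corrupted for r in records)
    )
    do_realign = cfg.preprocess.realign == "always" or (
        cfg.preprocess.realign == "auto" and motion_on
    )

    traces, kernels, sessions_pre = [], [], []
    for rec in records:
        if rec.corrupted:
            # corrupted sessions are excluded up front; skip simulation work
            traces.append(None)
            sessions_pre.append(None)
            kernels.append(None)
            continue
        ses = simulate_session(rec, schedule, geom, cfg.effects, roi_masks)
        if do_realign:
            ses, trace = realign(ses)
        elif "true_motion" in ses.provenance:
            tm = ses.provenance["true_motion"]
            trace = MotionTrace(tm["translations_mm"], tm["rotations_deg"])
        else:
            trace = MotionTrace(np.zeros((ses.n_vols, 3)), np.zeros((ses.n_vols, 3)))
        ses = detrend(ses)
        if cfg.preprocess.fwhm_mm > 0:
            ses = smooth(ses, cfg.preprocess.fwhm_mm)
        traces.append(trace)
        sessions_pre.append(ses)
        series = roi_mean_timeseries(ses, roi_masks, roi_label("auditory"))
        kernels.append(
            deconvolve_hrf(series, schedule, geom.tr_s, cfg.hrf.window_s, cfg.hrf.ridge)
        )

    subjects = apply_exclusions(records, traces, cfg.preprocess.exclusion_translation_mm)
    included_idx = [i for i, s in enumerate(subjects) if s["included"]]
    if len(included_idx) < 4:
        raise RuntimeError("too few included subjects for group inference")

    # leave-one-out HRF per included subject, then per-subject GLM + contrasts
    inc_kernels = [kernels[i] for i in included_idx]
    contrasts, betas_by_subject, groups = [], [], []
    for j, i in enumerate(included_idx):
        rec = records[i]
        if cfg.hrf.mode == "loo":
            kern = loo_mean_hrf(inc_kernels, j)
        else:
            from .paradigm import gamma_basis

            kern = gamma_basis(4.0, dt_s=geom.tr_s)
        design = build_design(schedule, [kern], geom.tr_s, geom.n_vols)
        betas = fit_glm(sessions_pre[i], design).scaled(plateau_scale(kern))
        contrasts.append(make_contrast(betas, CONTRASTS["positive_vs_negative"]).values)
        betas_by_subject.append(
            {
                "positive": make_contrast(betas, CONTRASTS["positive_vs_baseline"]).values,
                "negative": make_contrast(betas, CONTRASTS["negative_vs_baseline"]).values,
            }
        )
        groups.append(rec.group)
    groups = np.asarray(groups)

    # group x valence interaction: two-sample test on positive-minus-negative
    con = np.stack(contrasts)
    res = two_sample_perm(
        con[groups == "control"], con[groups == "PMD"],
        n_perm=cfg.inference.n_perm, seed=cfg.seed + 1,
    )
    q = None
    if cfg.inference.fdr == "by":
        q_flat = np.ones_like(res.p_uncorrected)
        ok = ~res.zero_variance
        q_flat[ok] = fdr_correct(res.p_uncorrected[ok])
        q = q_flat
    table, labels = threshold_and_cluster(
        res,
        alpha=cfg.inference.alpha,
        min_size=cfg.inference.min_cluster_size,
        connectivity=cfg.inference.connectivity,
        q_values=q,
        q_alpha=cfg.inference.q_alpha if cfg.inference.fdr == "by" else None,  # None: annotate only
        roi_masks=roi_masks,
    )

    interaction = (
        interaction_summary(
            table, labels, betas_by_subject, groups,
            n_boot=cfg.inference.n_boot, seed=cfg.seed + 2,
        )
        if len(table)
        else []
    )

    inc_traces = [traces[i] for i in included_idx]
    tr_pmd = [t for t, g in zip(inc_traces, groups) if g == "PMD"]
    tr_ctl = [t for t, g in zip(inc_traces, groups) if g == "control"]
    motion_cmp = None
    if min(len(tr_pmd), len(tr_ctl)) >= 2:
        motion_cmp = compare_motion(tr_ctl, tr_pmd, n_perm=min(cfg.inference.n_perm, 10_000),
                                    seed=cfg.seed + 3)

    anovas = _posthoc_anovas(records, included_idx, betas_by_subject, labels, table,
                             n_perm=min(cfg.inference.n_perm, 2000), seed=cfg.seed + 4)

    manifest = RunManifest(
        config=cfg.to_dict(),
        config_hash=cfg.hash(),
        version=__version__,
        subjects=subjects,
        stages={
            "paradigm": {"n_blocks": len(schedule.blocks), "total_s": schedule.total_s},
            "inference": {
                "n_perm": res.n_perm,
                "alpha": cfg.inference.alpha,
                "min_cluster_size": cfg.inference.min_cluster_size,
                "fdr": cfg.inference.fdr,
                "n_clusters": int(len(table)),
            },
        },
    )
    result = PipelineResult(
        manifest=manifest,
        cluster_table=table,
        cluster_labels=labels,
        interaction=interaction,
        t_map=res.t_volume(),
        p_map=res.p_volume(),
        motion_comparison=motion_cmp,
        anovas=anovas,
        cohort=cohort_table(records),
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir), geom)
    return result


def _posthoc_anovas(records, included_idx, betas_by_subject, labels, table, n_perm, seed):
    """Group-by-sex ANOVA on cluster-mean interaction contrasts and, within
    the PMD group, an SSRI x valence ANOVA — both on the largest cluster."""
    out = {}
    if not len(table):
        return out
    member = labels == int(table.iloc[0]["cluster_id"])
    inc = [records[i] for i in included_idx]
    diff = np.array(
        [m["positive"][member].mean() - m["negative"][member].mean() for m in betas_by_subject]
    )
    group = np.array([r.group for r in inc])
    sex = np.array([r.sex for r in inc])
    try:
        out["group_by_sex"] = twoway_anova_perm(diff, group, sex, n_perm=n_perm, seed=seed)
    except ValueError as exc:
        out["group_by_sex"] = {"error": str(exc)}
    pmd = [i for i, r in enumerate(inc) if r.group == "PMD"]
    if len(pmd) >= 4:
        vals, ssri_f, sound_f = [], [], []
        for i in pmd:
            for cond in ("positive", "negative"):
                vals.append(betas_by_subject[i][cond][member].mean())
                ssri_f.append(inc[i].ssri)
                sound_f.append(cond)
        try:
            out["ssri_by_valence"] = twoway_anova_perm(
                np.array(vals), np.array(ssri_f), np.array(sound_f), n_perm=n_perm, seed=seed + 1
            )
        except ValueError as exc:
            out["ssri_by_valence"] = {"error": str(exc)}
    return out


def _write_outputs(result: PipelineResult, out_dir: Path, geom: AcquisitionGeometry):
    import nibabel as nib

    out_dir.mkdir(parents=True, exist_ok=True)
    run_id = result.manifest.config_hash
    base = out_dir / run_id
    base.mkdir(exist_ok=True)
    aff = geom.affine()
    nib.save(nib.Nifti1Image(result.t_map.astype(np.float32), aff), base / "t_map.nii")
    nib.save(nib.Nifti1Image(result.p_map.astype(np.float32), aff), base / "p_map.nii")
    nib.save(nib.Nifti1Image(result.cluster_labels.astype(np.int16), aff), base / "clusters.nii")
    result.cluster_table.to_csv(base / "clusters.tsv", sep="\t", index=False)
    result.cohort.to_csv(base / "cohort.tsv", sep="\t", index=False)
    (base / "manifest.json").write_text(result.manifest.to_json())
    (base / "interaction.json").write_text(
        json.dumps(
            [
                {
                    "cluster_id": s["cluster_id"],
                    "direction": s["direction"],
                    "cells": {f"{g}|{c}": v for (g, c), v in s["cells"].items()},
                }
                for s in result.interaction
            ],
            indent=2,
        )
    )
    if result.motion_comparison is not None:
        result.motion_comparison.to_csv(base / "motion_comparison.tsv", sep="\t", index=False)


def report(result: PipelineResult) -> str:
    """Human-readable run report."""
    m = result.manifest
    lines = [
        f"infantfmri run {m.config_hash} (v{m.version})",
        "",
        "Cohort:",
    ]
    for g, c in m.counts().items():
        lines.append(
            f"  {g}: recruited {c['recruited']}, included {c['included']}, excluded {c['excluded']}"
        )
    inf = m.stages.get("inference", {})
    lines += [
        "",
        f"Inference: n_perm={inf.get('n_perm')}, alpha={inf.get('alpha')}, "
        f"min_cluster_size={inf.get('min_cluster_size')}, fdr={inf.get('fdr')}",
        "",
    ]
    if result.cluster_table.empty:
        lines.append("No suprathreshold clusters.")
    else:
        lines.append(f"Clusters ({len(result.cluster_table)}):")
        lines.append(result.cluster_table.to_string(index=False))
        for s in result.interaction:
            lines.append(f"  cluster {s['cluster_id']}: direction={s['direction']}")
            for (g, c), v in s["cells"].items():
                lines.append(
                    f"    {g:8s} {c:8s} mean={v['mean']:+.3f} [{v['lo']:+.3f}, {v['hi']:+.3f}]"
                )
    if result.motion_comparison is not None:
        lines += ["", "Motion comparison (control vs PMD):",
                  result.motion_comparison.to_string(index=False)]
    for name, res in result.anovas.items():
        if "error" in res:
            lines.append(f"{name}: {res['error']}")
        else:
            lines.append(
                f"{name}: " + ", ".join(
                    f"{k}: F={v['F']:.2f} p={v['p']:.3f}" for k, v in res.items()
                )
            )
    return "\n".join(lines)
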