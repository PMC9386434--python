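"""Synthetic infant BOLD cohorts with known ground truth.

Generates sessions with the acquisition geometry of the emulated protocol
(320 volumes, TR 3 s), subject-varying hemodynamic responses, AR(1) +
linear-drift + thermal noise, optional rigid motion, and a group x valence
effect structure: infants of non-depressed mothers (controls) respond more
strongly to positive (laughter) than negative (crying) sounds in
frontal-limbic regions, while infants exposed to prenatal maternal
depression (PMD) show the reverse (or no) preference.  Auditory cortex
responds to all sound categories in both groups.

Effect amplitudes are expressed in percent signal change around a baseline
intensity of 1000.  They are synthetic defaults chosen for adequate power
at 29 subjects per group, not estimates taken from any study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .paradigm import CATEGORIES, HRFKernel, ParadigmSchedule, build_design, gamma_basis
from .session import AcquisitionGeometry, Session4D, apply_rigid

BASELINE = 1000.0

ROI_NAMES = (
    "auditory",
    "amygdala_parahippocampal",
    "superior_temporal",
    "putamen",
    "orbitofrontal",
    "inferior_frontal",
)
#: regions carrying the group x valence interaction
FRONTAL_LIMBIC = ROI_NAMES[1:]

# fractional ROI centres on the simulation grid; boxes are kept disjoint
_ROI_CENTRES = {
    "auditory": (0.20, 0.30, 0.50),
    "amygdala_parahippocampal": (0.50, 0.30, 0.30),
    "superior_temporal": (0.80, 0.30, 0.50),
    "putamen": (0.20, 0.70, 0.40),
    "orbitofrontal": (0.50, 0.70, 0.60),
    "inferior_frontal": (0.80, 0.70, 0.40),
}


def _default_betas():
    """(group, category) -> %-signal-change amplitude per ROI class."""
    betas = {}
    for group in ("control", "PMD"):
        for cat in CATEGORIES:
            for roi in ROI_NAMES:
                if roi == "auditory":
                    amp = 1.0
                elif cat == "positive":
                    amp = 0.9 if group == "control" else 0.3
                elif cat == "negative":
                    amp = 0.3 if group == "control" else 0.7
                else:  # neutral / environmental engage emotion regions weakly
                    amp = 0.2
                betas[(group, cat, roi)] = amp
    return betas


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth effect structure for the simulated cohort.

    ``beta_true`` maps (group, category, roi) to percent signal change;
    ``beta_sd`` is the between-subject standard deviation on each amplitude.
    Noise: an AR(1) process with lag-1 autocorrelation ``ar1_rho`` and
    stationary standard deviation ``sigma_thermal`` (intensity units), plus
    a per-voxel linear drift of random amplitude up to ``drift_amplitude``
    over the session.  Motion defaults to zero (sleeping infants; motion is
    injected explicitly where the realignment stage is under test).
    """

    beta_true: dict = field(default_factory=_default_betas)
    beta_sd: float = 0.15
    hrf_peak_jitter_s: float = 0.5
    ar1_rho: float = 0.3
    sigma_thermal: float = 5.0
    drift_amplitude: float = 10.0
    max_translation_mm: float = 0.0
    max_rotation_deg: float = 0.0
    corrupted_translation_mm: float = 8.0

    def beta(self, group: str, category: str, roi: str) -> float:
        return self.beta_true.get((group, category, roi), 0.0)


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # "PMD" | "control"
    sex: str  # "F" | "M"
    ssri: str  # "SSRI+" | "SSRI-" | "n/a"
    seed: int
    true_hrf: HRFKernel
    true_betas: dict  # (category, roi) -> % signal change
    corrupted: bool = False


def make_roi_masks(grid_shape, half_width: int | None = None) -> np.ndarray:
    """Integer-labelled ROI volume: 0 background, 1.. per ROI_NAMES order."""
    shape = np.asarray(grid_shape)
    if half_width is None:
        half_width = max(1, int(round(shape.min() / 16)))
    labels = np.zeros(tuple(shape), dtype=np.int16)
    for i, name in enumerate(ROI_NAMES, start=1):
        centre = np.round(np.array(_ROI_CENTRES[name]) * (shape - 1)).astype(int)
        lo = np.maximum(centre - half_width, 0)
        hi = np.minimum(centre + half_width + 1, shape)
        if np.any(lo >= shape) or np.any(hi <= 0):
            raise ValueError(f"ROI {name} exceeds grid {tuple(shape)}")
        region = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        if np.any(region):
            raise ValueError(f"ROI {name} overlaps another ROI on grid {tuple(shape)}")
        region[...] = i
    return labels


def roi_label(name: str) -> int:
    return ROI_NAMES.index(name) + 1


def make_cohort(
    n_per_group=29,
    effects: EffectSpec | None = None,
    seed: int = 0,
    n_corrupted=(0, 0),
) -> list:
    """Draw a cohort of subject records (PMD group first, then controls).

    ``n_per_group`` may be an int (balanced) or a (n_pmd, n_control) pair;
    ``n_corrupted`` marks that many subjects per group as corrupted sessions
    (infant woke / moved excessively), to exercise exclusion logic.  Each
    subject gets a unique sub-seed, a jittered gamma-variate true HRF
    (nominal 4 s peak), and noisy copies of the group-level true betas.
    """
    effects = effects or EffectSpec()
    if isinstance(n_per_group, int):
        n_pmd = n_ctl = n_per_group
    else:
        n_pmd, n_ctl = n_per_group
    if min(n_pmd, n_ctl) < 2:
        raise ValueError("need at least 2 subjects per group")
    ss = np.random.SeedSequence(seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    records = []
    idx = 0
    for group, n_group, n_bad in (("PMD", n_pmd, n_corrupted[0]), ("control", n_ctl, n_corrupted[1])):
        if n_bad > n_group:
            raise ValueError("more corrupted sessions than subjects")
        bad = set(master.choice(n_group, size=n_bad, replace=False)) if n_bad else set()
        for j in range(n_group):
            sub_ss = ss.spawn(1)[0]
            sub_seed = int(sub_ss.generate_state(1)[0] % (2**31 - 1))
            rng = np.random.default_rng(sub_seed)
            sex = "F" if rng.random() < 0.5 else "M"
            ssri = ("SSRI+" if rng.random() < 0.5 else "SSRI-") if group == "PMD" else "n/a"
            peak = float(np.clip(4.0 + rng.normal(0.0, effects.hrf_peak_jitter_s), 1.5, 10.0))
            hrf = gamma_basis(peak_s=peak)
            betas = {
                (cat, roi): effects.beta(group, cat, roi) + rng.normal(0.0, effects.beta_sd)
                for cat in CATEGORIES
                for roi in ROI_NAMES
            }
            records.append(
                SubjectRecord(
                    subject_id=f"sub-{idx + 1:03d}",
                    group=group,
                    sex=sex,
                    ssri=ssri,
                    seed=sub_seed,
                    true_hrf=hrf,
                    true_betas=betas,
                    corrupted=j in bad,
                )
            )
            idx += 1
    return records


def cohort_table(records):
    import pandas as pd

    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "group": [r.group for r in records],
            "sex": [r.sex for r in records],
            "ssri": [r.ssri for r in records],
            "seed": [r.seed for r in records],
            "corrupted": [r.corrupted for r in records],
        }
    )


def _ar1_noise(rng, shape_vox, n_vols, rho, sigma):
    """AR(1) noise with stationary sd ``sigma`` and lag-1 autocorrelation rho."""
    n_extra = 50  # burn-in toward stationarity
    w = rng.standard_normal((*shape_vox, n_vols + n_extra))
    innov_sd = sigma * np.sqrt(max(1.0 - rho**2, 1e-12))
    e = _signal.lfilter([1.0], [1.0, -rho], w * innov_sd, axis=-1)
    return e[..., n_extra:]


def percent_response_curves(schedule, hrf, tr_s, n_vols):
    """Per-category fractional response curves, unit block plateau.

    The design regressor (boxcar convolved with the unit-peak kernel) is
    divided by the kernel sample sum, so that a sustained block approaches a
    plateau of 1; multiplying by beta/100 then yields percent signal change.
    """
    design = build_design(schedule, [hrf], tr_s=tr_s, n_vols=n_vols)
    plateau = hrf.values.sum()
    return {cat: design.columns[:, i] / plateau for i, cat in enumerate(CATEGORIES)}, design


def simulate_session(
    record: SubjectRecord,
    schedule: ParadigmSchedule,
    geom: AcquisitionGeometry | None = None,
    effects: EffectSpec | None = None,
    roi_masks: np.ndarray | None = None,
) -> Session4D:
    """Simulate one subject's 4-D BOLD session.

    Signal model per voxel:
    ``y(t) = B * (1 + sum_c beta_c(roi)/100 * r_c(t)) + drift(t) + AR(1)``
    with B the baseline intensity, ``r_c`` the fractional response of
    category c under the subject's true HRF, drift a linear ramp, and AR(1)
    noise of stationary sd ``sigma_thermal``.  Motion (random walk within
    the EffectSpec bounds, or large excursions for corrupted sessions) is
    applied as per-volume rigid resampling; ground truth is recorded in
    provenance.
    """
    geom = geom or AcquisitionGeometry()
    effects = effects or EffectSpec()
    if roi_masks is None:
        roi_masks = make_roi_masks(geom.grid_shape)
    if roi_masks.shape != tuple(geom.grid_shape):
        raise ValueError("ROI mask grid does not match acquisition grid")
    if schedule.total_s > geom.duration_s + geom.tr_s:
        raise ValueError("schedule longer than the acquisition window")
    rng = np.random.default_rng(record.seed)
    curves, design = percent_response_curves(schedule, record.true_hrf, geom.tr_s, geom.n_vols)

    shape = tuple(geom.grid_shape)
    pct = np.zeros((*shape, geom.n_vols), dtype=np.float64)
    for cat in CATEGORIES:
        amp = np.zeros(shape)
        for i, roi in enumerate(ROI_NAMES, start=1):
            amp[roi_masks == i] = record.true_betas[(cat, roi)]
        pct += amp[..., None] / 100.0 * curves[cat][None, None, None, :]
    data = BASELINE * (1.0 + pct)

    if effects.drift_amplitude > 0:
        ramp = np.linspace(-0.5, 0.5, geom.n_vols)
        amp = rng.uniform(-effects.drift_amplitude, effects.drift_amplitude, size=shape)
        data = data + amp[..., None] * ramp[None, None, None, :]
    if effects.sigma_thermal > 0:
        data = data + _ar1_noise(rng, shape, geom.n_vols, effects.ar1_rho, effects.sigma_thermal)

    session = Session4D(data, geom, record.subject_id)
    session.provenance["true_betas"] = dict(record.true_betas)
    session.provenance["group"] = record.group
    session.provenance["corrupted"] = record.corrupted

    max_t = effects.corrupted_translation_mm if record.corrupted else effects.max_translation_mm
    max_r = effects.max_rotation_deg if not record.corrupted else 2.0
    if max_t > 0 or max_r > 0:
        n = geom.n_vols
        trans = np.cumsum(rng.normal(0.0, max_t / np.sqrt(n) * 3, size=(n, 3)), axis=0)
        trans = np.clip(trans, -max_t, max_t)
        rots = np.clip(
            np.cumsum(rng.normal(0.0, max_r / np.sqrt(n) * 3, size=(n, 3)), axis=0),
            -max_r,
            max_r,
        )
        trans[0] = 0.0
        rots[0] = 0.0
        if record.corrupted:  # a sudden large movement mid-session
            k = rng.integers(n // 4, 3 * n // 4)
            trans[k:] += rng.choice([-1.0, 1.0]) * max_t
        session = inject_motion(session, trans, rots)
    return session


def inject_motion(session: Session4D, translations_mm, rotations_deg) -> Session4D:
    """Resample each volume under its own rigid transform (trilinear).

    True transforms are stored in provenance for recovery tests.  All-zero
    transforms return a bitwise-identical copy.
    """
    trans = np.asarray(translations_mm, dtype=float)
    rots = np.asarray(rotations_deg, dtype=float)
    if trans.shape != (session.n_vols, 3) or rots.shape != (session.n_vols, 3):
        raise ValueError("need one 3-vector per volume for translations and rotations")
    if not (np.all(np.isfinite(trans)) and np.all(np.isfinite(rots))):
        raise ValueError("motion parameters must be finite")
    spacing = session.geom.spacing_mm
    out = np.empty_like(session.data, dtype=float)
    for v in range(session.n_vols):
        params = np.concatenate([trans[v], rots[v]])
        out[..., v] = apply_rigid(
            session.data[..., v], params, spacing, mode="nearest"
        )
    return session.with_data(
        out, true_motion={"translations_mm": trans.copy(), "rotations_deg": rots.copy()}
    )
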