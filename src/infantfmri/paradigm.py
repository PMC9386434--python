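"""Block-design auditory paradigm construction and GLM design matrices.

The experiment alternates 21 s stimulation blocks with 9 s of silent rest.
Four sound categories (neutral vocalisations, positive/laughter,
negative/crying, non-vocal environmental) are each presented in eight
blocks, giving 32 blocks and a 16-minute session.  Each block packs 7-11
individual sounds separated by short gaps.

Regressors are built at block granularity: a per-category boxcar convolved
with one or more hemodynamic kernels, sampled on the volume-acquisition
grid.  Rest is the implicit baseline; the intercept is added at fit time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CATEGORIES = ("neutral", "positive", "negative", "environmental")

#: internal sampling step (s) for boxcar/kernel convolution
_FINE_DT = 0.1


class SoundPackingError(ValueError):
    """Requested number of sounds cannot fit in the block at minimum gap."""


@dataclass(frozen=True)
class HRFKernel:
    """Sampled hemodynamic impulse response on a fixed time grid.

    ``values[0]`` is the response at lag 0; samples are spaced ``dt_s``
    apart over a ``support_s`` window.
    """

    dt_s: float
    values: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("kernel values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("kernel values must be finite")

    @property
    def support_s(self) -> float:
        return self.values.size * self.dt_s

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt_s

    def normalized(self) -> "HRFKernel":
        """Return a copy scaled to unit peak absolute amplitude."""
        peak = np.max(np.abs(self.values))
        if peak == 0:
            return self
        return HRFKernel(self.dt_s, self.values / peak, dict(self.meta))


@dataclass(frozen=True)
class StimulusBlock:
    category: str
    onset_s: float
    duration_s: float
    sound_onsets_s: tuple
    sound_durations_s: tuple

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if len(self.sound_onsets_s) != len(self.sound_durations_s):
            raise ValueError("sound onset/duration length mismatch")
        on = np.asarray(self.sound_onsets_s)
        if on.size and (on.min() < 0 or on.max() >= self.duration_s):
            raise ValueError("sound onsets must lie within the block")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s

    def sound_gaps_s(self) -> np.ndarray:
        """Silent gaps between consecutive sounds (end of one to start of next)."""
        on = np.asarray(self.sound_onsets_s)
        du = np.asarray(self.sound_durations_s)
        return on[1:] - (on[:-1] + du[:-1])


@dataclass(frozen=True)
class ParadigmSchedule:
    blocks: tuple
    rest_s: float

    @property
    def total_s(self) -> float:
        return sum(b.duration_s for b in self.blocks) + self.rest_s * len(self.blocks)

    def onsets(self, category: str | None = None) -> np.ndarray:
        blocks = self.blocks if category is None else self.blocks_of(category)
        return np.array([b.onset_s for b in blocks])

    def blocks_of(self, category: str) -> tuple:
        return tuple(b for b in self.blocks if b.category == category)

    def boxcar(self, categories, dt_s: float = _FINE_DT, total_s: float | None = None) -> np.ndarray:
        """Indicator time course (1 during blocks of the given categories)."""
        if isinstance(categories, str):
            categories = (categories,)
        total = self.total_s if total_s is None else total_s
        n = int(np.ceil(total / dt_s))
        t = np.arange(n) * dt_s
        out = np.zeros(n)
        for b in self.blocks:
            if b.category in categories:
                out[(t >= b.onset_s) & (t < b.end_s)] = 1.0
        return out

    def to_events(self) -> pd.DataFrame:
        """BIDS-events-like table (onset, duration, trial_type)."""
        return pd.DataFrame(
            {
                "onset": [round(b.onset_s, 3) for b in self.blocks],
                "duration": [round(b.duration_s, 3) for b in self.blocks],
                "trial_type": [b.category for b in self.blocks],
            }
        )

    def to_sound_events(self) -> pd.DataFrame:
        """Per-sound onset sidecar table (session-relative seconds)."""
        rows = []
        for i, b in enumerate(self.blocks):
            for on, du in zip(b.sound_onsets_s, b.sound_durations_s):
                rows.append((i, b.category, round(b.onset_s + on, 3), round(du, 3)))
        return pd.DataFrame(rows, columns=["block", "trial_type", "onset", "duration"])


@dataclass(frozen=True)
class DesignMatrix:
    times_s: np.ndarray
    columns: np.ndarray  # (n_vols, n_regressors)
    column_labels: tuple
    hrf_used: str

    def __post_init__(self):
        if self.columns.shape != (self.times_s.size, len(self.column_labels)):
            raise ValueError("design shape inconsistent with labels/times")
        if not np.all(np.isfinite(self.columns)):
            raise ValueError("design matrix must be finite")


def _pack_sounds(rng, block_s, n_sounds, gap_range_s, dur_range_s):
    """Place ``n_sounds`` sounds with inter-sound gaps inside one block.

    Raises SoundPackingError when the tightest packing (shortest sounds,
    minimum gaps) cannot fit.
    """
    gmin, gmax = gap_range_s
    dmin, dmax = dur_range_s
    if n_sounds * dmin + (n_sounds - 1) * gmin > block_s:
        raise SoundPackingError(
            f"{n_sounds} sounds of >= {dmin}s with gaps >= {gmin}s exceed a {block_s}s block"
        )
    for _ in range(100):
        gaps = rng.uniform(gmin, gmax, size=max(n_sounds - 1, 0))
        durs = rng.uniform(dmin, dmax, size=n_sounds)
        if durs.sum() + gaps.sum() <= block_s:
            break
        # shrink sounds toward the feasible minimum, keep gaps as drawn
        slack = block_s - gaps.sum() - n_sounds * dmin
        if slack < 0:
            continue
        durs = dmin + (durs - dmin) * slack / max((durs - dmin).sum(), 1e-12)
    onsets = np.concatenate([[0.0], np.cumsum(durs[:-1] + gaps)]) if n_sounds else np.array([])
    return tuple(onsets), tuple(durs)


def _order_without_repeats(rng, labels):
    """Seeded shuffle with no immediate repeats (rejection sampling)."""
    labels = list(labels)
    for _ in range(10_000):
        order = list(rng.permutation(labels))
        if all(a != b for a, b in zip(order, order[1:])):
            return order
    raise RuntimeError("could not find a no-repeat ordering")


def build_schedule(
    blocks_per_category: int = 8,
    block_s: float = 21.0,
    rest_s: float = 9.0,
    sounds_range: tuple = (7, 11),
    gap_range_s: tuple = (0.47, 0.75),
    seed: int = 0,
    sound_duration_range_s: tuple = (0.9, 1.8),
) -> ParadigmSchedule:
    """Construct a pseudo-randomized block schedule.

    Defaults reproduce the session layout: 8 blocks per each of the four
    sound categories (32 blocks), 21 s blocks, 9 s rests, 960 s total.
    Category order is a seeded shuffle constrained to no immediate
    category repeats; each block packs 7-11 sounds with 0.47-0.75 s gaps.
    Deterministic given ``seed``.
    """
    if blocks_per_category < 1:
        raise ValueError("blocks_per_category must be >= 1")
    if gap_range_s[0] <= 0 or gap_range_s[1] < gap_range_s[0]:
        raise ValueError("gap range must be positive and ordered")
    rng = np.random.default_rng(seed)
    labels = [c for c in CATEGORIES for _ in range(blocks_per_category)]
    if blocks_per_category == 1:
        order = list(rng.permutation(labels))
    else:
        order = _order_without_repeats(rng, labels)
    blocks = []
    t = 0.0
    for cat in order:
        n_sounds = int(rng.integers(sounds_range[0], sounds_range[1] + 1))
        onsets, durs = _pack_sounds(rng, block_s, n_sounds, gap_range_s, sound_duration_range_s)
        blocks.append(StimulusBlock(cat, t, block_s, onsets, durs))
        t += block_s + rest_s
    return ParadigmSchedule(tuple(blocks), rest_s)


def gamma_basis(peak_s: float, dt_s: float = _FINE_DT, support_s: float = 24.0,
                shape: float | None = None) -> HRFKernel:
    """Gamma-variate hemodynamic kernel with its mode at ``peak_s``.

    Parameterized as f(t) = (t/peak)^a exp(a (1 - t/peak)), which has its
    maximum (value 1) exactly at t = peak_s and f(0) = 0.  The shape
    parameter ``a`` defaults to 6*peak_s/8, keeping width roughly
    proportional to latency.  Normalized to unit peak amplitude.
    """
    if peak_s <= 0 or peak_s >= support_s:
        raise ValueError("require 0 < peak_s < support_s")
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    a = 6.0 * peak_s / 8.0 if shape is None else shape
    t = np.arange(int(round(support_s / dt_s))) * dt_s
    with np.errstate(divide="ignore"):
        vals = np.where(t > 0, (t / peak_s) ** a * np.exp(a * (1.0 - t / peak_s)), 0.0)
    vals = vals / vals.max()  # unit peak on the sampled grid
    return HRFKernel(dt_s, vals, {"kind": "gamma", "peak_s": peak_s, "shape": a})


def build_design(
    schedule: ParadigmSchedule,
    kernels,
    tr_s: float = 3.0,
    n_vols: int = 320,
    categories=CATEGORIES,
) -> DesignMatrix:
    """Convolve per-category boxcars with each kernel, sampled at frame times.

    One column per condition x kernel, ordered condition-major.  Regressors
    are truncated to the acquisition window; a condition with no blocks
    yields an all-zero column.  No intercept is included.
    """
    kernels = list(kernels)
    if not kernels:
        raise ValueError("at least one kernel required")
    for k in kernels:
        if k.values.size == 0:
            raise ValueError("empty kernel")
    dt = kernels[0].dt_s
    if any(abs(k.dt_s - dt) > 1e-12 for k in kernels):
        raise ValueError("kernels must share a time grid")
    frame_t = np.arange(n_vols) * tr_s
    total = max(schedule.total_s, n_vols * tr_s) + max(k.support_s for k in kernels)
    fine_t = np.arange(int(np.ceil(total / dt))) * dt
    cols, labels = [], []
    for cat in categories:
        box = schedule.boxcar(cat, dt_s=dt, total_s=total)
        for k in kernels:
            conv = np.convolve(box, k.values)[: fine_t.size]
            name = k.meta.get("name") or k.meta.get("kind", "hrf")
            if "peak_s" in k.meta:
                name = f"{name}{k.meta['peak_s']:g}s"
            cols.append(np.interp(frame_t, fine_t, conv))
            labels.append(f"{cat}:{name}")
    hrf_desc = ",".join(sorted({lab.split(":", 1)[1] for lab in labels}))
    return DesignMatrix(frame_t, np.column_stack(cols), tuple(labels), hrf_desc)


def write_events_tsv(schedule: ParadigmSchedule, path, sounds_path=None) -> None:
    schedule.to_events().to_csv(path, sep="\t", index=False, float_format="%.3f")
    if sounds_path is not None:
        schedule.to_sound_events().to_csv(sounds_path, sep="\t", index=False, float_format="%.3f")
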