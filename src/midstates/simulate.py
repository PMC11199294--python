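"""Synthetic MID-task ERP data with planted microstate structure.

This module is the test bed standing in for raw EEG from a monetary
incentive delay (MID) study: it generates task schedules, smooth planted
template topographies, multi-subject ERP datasets whose microstate
sequences (onset/offset timing and amplitude) can differ by group and
condition, and clinical score tables linearly linked to a planted ERP
amplitude parameter.

The default study conditions mirror the emulated design: two groups of
30 and 23 subjects, three merged conditions (reward, loss, neutral),
30 channels at 256 Hz, epochs from -500 to +1000 ms around cue onset.
Each subject-condition ERP is a sum of non-overlapping microstate
segments (amplitude x template, with per-subject jitter on onsets and
log-amplitudes) plus spatially smoothed Gaussian noise, then
average-referenced.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import ChannelLayout, ERPDataset, average_reference

INCENTIVE_CONDITIONS = ("small_reward", "large_reward", "small_loss", "large_loss")

CUE_MS = 250.0
DELAY_RANGE_MS = (2000.0, 2500.0)
FEEDBACK_MS = 1650.0
TRIAL_MS = 6000.0


@dataclasses.dataclass(frozen=True)
class Trial:
    condition: str
    cue_ms: float
    delay_ms: float
    target_ms: float
    feedback_ms: float


@dataclasses.dataclass
class TaskSchedule:
    """Randomized MID trial sequence; each trial lasts 6 s in total."""

    trials: list[Trial]
    seed: int | None

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def total_duration_s(self) -> float:
        return self.n_trials * TRIAL_MS / 1000.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(t) for t in self.trials])


def make_task_schedule(
    n_per_incentive: int = 18, n_neutral: int = 24, seed: int | None = None
) -> TaskSchedule:
    """Build a randomized MID schedule.

    Four incentive cue types (small/large reward, small/large loss) with
    ``n_per_incentive`` trials each plus ``n_neutral`` neutral trials, in
    seeded random order.  Cue 250 ms, delay uniform in [2000, 2500] ms,
    feedback 1650 ms; the target interval absorbs the remainder so every
    trial lasts exactly 6 s.
    """
    if n_per_incentive < 0 or n_neutral < 0:
        raise ValueError("trial counts must be non-negative")
    rng = np.random.default_rng(seed)
    conditions = [c for c in INCENTIVE_CONDITIONS for _ in range(n_per_incentive)]
    conditions += ["neutral"] * n_neutral
    order = rng.permutation(len(conditions))
    trials = []
    for i in order:
        delay = float(rng.uniform(*DELAY_RANGE_MS))
        target = TRIAL_MS - CUE_MS - delay - FEEDBACK_MS
        trials.append(Trial(conditions[i], CUE_MS, delay, target, FEEDBACK_MS))
    return TaskSchedule(trials, seed)


# ---------------------------------------------------------------------------
# layouts and templates


def make_layout(n_channels: int = 30, seed: int | None = None) -> ChannelLayout:
    """Electrode layout on the upper unit hemisphere (Fibonacci spiral)."""
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    i = np.arange(n_channels)
    golden = (1 + 5**0.5) / 2
    # z in (0, 1]: upper hemisphere only, like a scalp montage
    z = 1 - i / (2 * n_channels)
    r = np.sqrt(1 - z**2)
    phi = 2 * np.pi * i / golden
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    labels = tuple(f"E{j + 1:02d}" for j in range(n_channels))
    return ChannelLayout(labels, pos)


def _smooth_basis(positions: np.ndarray) -> np.ndarray:
    """Spatially smooth map basis: linear + quadratic monomials of position."""
    x, y, z = positions.T
    cols = [x, y, z, x * y, x * z, y * z, x**2 - y**2, 2 * z**2 - x**2 - y**2]
    return np.column_stack(cols)


def make_templates(
    k: int,
    layout: ChannelLayout,
    seed: int | None = None,
    max_cosine: float = 0.6,
    max_tries: int = 2000,
) -> np.ndarray:
    """Draw k smooth, mutually distinct template topographies.

    Maps are random combinations of low-order spatial polynomials over
    the electrode positions (spatially low-pass over the sphere),
    average-referenced and unit-L2-normalized, with pairwise
    |cosine| <= ``max_cosine`` enforced by rejection sampling.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if layout.positions is None:
        raise ValueError("layout must carry electrode positions")
    if k > layout.n_channels - 1:
        raise ValueError(f"k={k} exceeds channels - 1 = {layout.n_channels - 1}")
    rng = np.random.default_rng(seed)
    basis = _smooth_basis(layout.positions)
    templates: list[np.ndarray] = []
    for _ in range(max_tries):
        w = rng.standard_normal(basis.shape[1])
        cand = average_reference(basis @ w)
        norm = np.linalg.norm(cand)
        if norm < 1e-12:
            continue
        cand = cand / norm
        if all(abs(cand @ t) <= max_cosine for t in templates):
            templates.append(cand)
            if len(templates) == k:
                return np.stack(templates)
    raise RuntimeError(
        f"could not draw {k} templates with pairwise |cosine| <= {max_cosine}"
    )


# ---------------------------------------------------------------------------
# ground truth and ERP simulation

Segment = tuple[int, float, float, float]  # (class_id, onset_ms, offset_ms, amplitude_uv)


@dataclasses.dataclass
class GroundTruth:
    """Planted generative structure for a simulated dataset.

    ``timeline`` maps (group, condition) to a list of non-overlapping
    (class_id 1-based, onset_ms, offset_ms, amplitude µV) segments.
    ``subject_onset_jitter_ms`` and ``subject_log_amp_sd`` are the SDs of
    per-subject Gaussian perturbations of segment boundaries and
    log-amplitudes.  ``clinical_beta`` links the named ERP feature to the
    anticipatory-pleasure score (see :func:`simulate_clinical_scores`).
    """

    templates: np.ndarray
    timeline: dict[tuple[str, str], list[Segment]]
    noise_sd: float = 1.0
    subject_onset_jitter_ms: float = 0.0
    subject_log_amp_sd: float = 0.0
    clinical_beta: float = 0.0
    clinical_noise_sd: float = 1.0
    clinical_feature: str = "amplitude"
    # filled by simulate_erp_dataset: per-subject realized amplitude of the
    # clinical target segment (group, condition, class)
    clinical_target: tuple[str, int] | None = None  # (condition, class_id)
    subject_amplitudes: dict[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.templates = np.atleast_2d(np.asarray(self.templates, dtype=float))
        k = self.templates.shape[0]
        gram = np.abs(self.templates @ self.templates.T)
        if k > 1 and np.any(gram[~np.eye(k, dtype=bool)] >= 0.99):
            raise ValueError("templates must be mutually distinct (|cosine| < 0.99)")
        for cell, segs in self.timeline.items():
            ordered = sorted(segs, key=lambda s: s[1])
            for s in ordered:
                if s[3] <= 0:
                    raise ValueError(f"non-positive amplitude in cell {cell}")
                if not 1 <= s[0] <= k:
                    raise ValueError(f"segment class {s[0]} outside 1..{k}")
            for a, b in zip(ordered, ordered[1:]):
                if b[1] < a[2]:
                    raise ValueError(f"overlapping segments in cell {cell}")


def default_timeline(
    conditions: Sequence[str] = ("reward", "loss", "neutral"),
    groups: Sequence[str] = ("patient", "control"),
    boundaries_ms: Sequence[float] = (0.0, 180.0, 420.0, 560.0, 700.0),
    amplitudes_uv: Sequence[float] = (3.0, 4.0, 2.5, 2.0),
) -> dict[tuple[str, str], list[Segment]]:
    """A four-class sequential timeline, identical in every cell.

    Classes 1..4 occupy consecutive windows spanning 0-700 ms after cue
    onset (the consistency-tested analysis range), with amplitudes of a
    few µV as typical of cue-locked ERP components.
    """
    segs = [
        (j + 1, boundaries_ms[j], boundaries_ms[j + 1], amplitudes_uv[j])
        for j in range(len(boundaries_ms) - 1)
    ]
    return {(g, c): list(segs) for g in groups for c in conditions}


def _spatial_smoother(positions: np.ndarray, scale: float = 0.6) -> np.ndarray:
    """Row-normalized Gaussian kernel over inter-electrode distances."""
    d2 = np.sum((positions[:, None, :] - positions[None, :, :]) ** 2, axis=-1)
    k = np.exp(-d2 / (2 * scale**2))
    return k / k.sum(axis=1, keepdims=True)


def simulate_erp_dataset(
    truth: GroundTruth,
    n_per_group: tuple[int, int] = (30, 23),
    layout: ChannelLayout | None = None,
    fs: float = 256.0,
    epoch_window_ms: tuple[float, float] = (-500.0, 1000.0),
    seed: int | None = None,
    groups: tuple[str, str] = ("patient", "control"),
) -> ERPDataset:
    """Simulate a two-group, three-condition ERP dataset.

    Each subject-condition ERP is the planted timeline's segments
    (amplitude x template, hard switches, subject-jittered) plus
    spatially smoothed Gaussian noise of SD ``truth.noise_sd`` µV,
    average-referenced.  Per-subject realized amplitudes of the clinical
    target segment are recorded in ``truth.subject_amplitudes`` for the
    clinical-score generator.  Deterministic given the seed.
    """
    if layout is None:
        layout = make_layout(truth.templates.shape[1])
    if layout.n_channels != truth.templates.shape[1]:
        raise ValueError("layout channel count does not match templates")
    rng = np.random.default_rng(seed)
    start, end = epoch_window_ms
    n_samples = round(fs * (end - start) / 1000.0)
    times = start + np.arange(n_samples) * 1000.0 / fs
    for cell, segs in truth.timeline.items():
        for s in segs:
            if s[1] < start or s[2] > end:
                raise ValueError(f"segment {s} outside epoch window in cell {cell}")

    smoother = (
        _spatial_smoother(layout.positions) if layout.positions is not None else None
    )
    conditions = sorted({c for _, c in truth.timeline})
    erps: dict[tuple[str, str], np.ndarray] = {}
    group_of: dict[str, str] = {}
    truth.subject_amplitudes.clear()
    sid_counter = 0
    for group, n_subj in zip(groups, n_per_group):
        for _ in range(n_subj):
            sid_counter += 1
            sid = f"S{sid_counter:03d}"
            group_of[sid] = group
            amp_factor = float(np.exp(rng.normal(0.0, truth.subject_log_amp_sd)))
            onset_shift = float(rng.normal(0.0, truth.subject_onset_jitter_ms))
            for cond in conditions:
                segs = truth.timeline[(group, cond)]
                erp = np.zeros((layout.n_channels, n_samples))
                for class_id, onset, offset, amp in segs:
                    a, b = onset + onset_shift, offset + onset_shift
                    mask = (times >= a) & (times < b)
                    erp[:, mask] += amp * amp_factor * truth.templates[class_id - 1][:, None]
                    if truth.clinical_target == (cond, class_id):
                        truth.subject_amplitudes[sid] = amp * amp_factor
                if truth.noise_sd > 0:
                    noise = rng.normal(0.0, 1.0, size=erp.shape)
                    if smoother is not None:
                        noise = smoother @ noise
                        noise *= truth.noise_sd / noise.std()
                    else:
                        noise *= truth.noise_sd
                    erp += noise
                erps[(sid, cond)] = average_reference(erp)
    return ERPDataset(layout, fs, times, erps, group_of, groups=groups)


def simulate_clinical_scores(
    dataset: ERPDataset,
    truth: GroundTruth,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate a clinical score table with a planted linear link.

    The anticipatory-pleasure score is ``clinical_beta`` times the named
    per-subject ERP feature plus Gaussian noise of SD
    ``clinical_noise_sd``; the covariate (general cognitive ability
    proxy) is drawn independently.  The table is attached to
    ``dataset.clinical`` and returned.
    """
    rng = np.random.default_rng(seed)
    if truth.clinical_feature != "amplitude":
        raise ValueError(f"unknown clinical feature {truth.clinical_feature!r}")
    subjects = dataset.subjects
    if truth.clinical_target is not None:
        missing = [s for s in subjects if s not in truth.subject_amplitudes]
        if missing:
            raise ValueError(
                "subject amplitudes not recorded; simulate_erp_dataset must run "
                "with clinical_target set"
            )
        feature = np.array([truth.subject_amplitudes[s] for s in subjects])
    else:
        feature = np.zeros(len(subjects))
    anticipatory = truth.clinical_beta * feature + rng.normal(
        0.0, truth.clinical_noise_sd, size=len(subjects)
    )
    consummatory = rng.normal(0.0, 1.0, size=len(subjects))
    covariate = rng.normal(0.0, 1.0, size=len(subjects))
    table = pd.DataFrame(
        {
            "anticipatory": anticipatory,
            "consummatory": consummatory,
            "covariate": covariate,
        },
        index=pd.Index(subjects, name="subject_id"),
    )
    dataset.clinical = table
    return table


def clinical_noise_for_rho(beta: float, feature_sd: float, rho: float) -> float:
    """Noise SD giving correlation ``rho`` between score and feature.

    For score = beta*f + e, corr = sign(beta)*|beta|*sd(f) /
    sqrt(beta^2 sd(f)^2 + sd(e)^2); solving for sd(e) at |rho|.
    """
    if not 0 < abs(rho) < 1:
        raise ValueError("rho must be in (0, 1) in absolute value")
    return abs(beta) * feature_sd * np.sqrt(1.0 / rho**2 - 1.0)
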