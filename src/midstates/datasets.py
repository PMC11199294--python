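"""Core data containers and dataset I/O for multi-subject ERP analyses.

The central object is :class:`ERPDataset`: per (subject, condition)
average-referenced channels-by-time ERP matrices from a two-group,
three-condition cue paradigm (reward / loss / neutral), together with
channel layout, sampling metadata and a per-subject clinical score table.

Datasets are stored on disk as a YAML manifest plus one tab-delimited
matrix file per ERP (channels as rows, a header row of latencies in ms),
so every fixture is plain text and inspectable.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

RAW_CONDITIONS = ("small_reward", "large_reward", "small_loss", "large_loss", "neutral")
MERGED_CONDITIONS = ("reward", "loss", "neutral")

#: raw cue label -> merged analysis condition
MERGE_MAP = {
    "small_reward": "reward",
    "large_reward": "reward",
    "small_loss": "loss",
    "large_loss": "loss",
    "neutral": "neutral",
}

#: trial minima for inclusion of a subject, per merged condition
MIN_INCENTIVE_TRIALS = 9
MIN_NEUTRAL_TRIALS = 12


def average_reference(data: np.ndarray) -> np.ndarray:
    """Re-reference to the average reference.

    For a 1-D map, subtracts the channel mean; for a channels x time
    matrix, subtracts the per-time-point channel mean so every column
    sums to zero.  Idempotent and linear.

    Parameters
    ----------
    data : array, shape (channels,) or (channels, time)

    Returns
    -------
    array of the same shape with zero channel mean at every time point.
    """
    data = np.asarray(data, dtype=float)
    if data.shape[0] < 2:
        raise ValueError("average reference requires at least 2 channels")
    return data - data.mean(axis=0, keepdims=True)


@dataclasses.dataclass(frozen=True)
class ChannelLayout:
    """Ordered electrode labels, optionally with unit-sphere 3-D positions."""

    labels: tuple[str, ...]
    positions: np.ndarray | None = None  # (n_channels, 3), unit norm

    def __post_init__(self):
        if len(self.labels) == 0:
            raise ValueError("layout needs at least one channel label")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.positions is not None:
            pos = np.asarray(self.positions, dtype=float)
            if pos.shape != (len(self.labels), 3):
                raise ValueError("positions must be (n_channels, 3)")
            norms = np.linalg.norm(pos, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("positions must have unit norm")
            object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.labels)


@dataclasses.dataclass
class EpochSet:
    """Single-trial epochs of one subject and condition.

    ``epochs`` is trials x channels x time in microvolts; ``t0_offset``
    is the latency of the first sample relative to cue onset, in ms.
    """

    subject_id: str
    condition: str
    epochs: np.ndarray
    fs: float
    t0_offset: float

    def __post_init__(self):
        if self.condition not in RAW_CONDITIONS + MERGED_CONDITIONS:
            raise ValueError(f"unknown condition label {self.condition!r}")
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be trials x channels x time")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Per-sample latencies in ms relative to cue onset."""
        n = self.epochs.shape[2]
        return self.t0_offset + np.arange(n) * 1000.0 / self.fs


@dataclasses.dataclass(frozen=True)
class ExclusionReport:
    """Record of one excluded subject and why."""

    subject_id: str
    reason: str  # behavioral_accuracy | insufficient_trials
    detail: str

    VALID_REASONS = ("behavioral_accuracy", "insufficient_trials")

    def __post_init__(self):
        if self.reason not in self.VALID_REASONS:
            raise ValueError(f"unknown exclusion reason {self.reason!r}")


class ERPDataset:
    """Multi-subject, two-group, three-condition ERP dataset.

    Every stored ERP matrix is average-referenced on entry; the time axis
    is strictly increasing with step 1000/fs ms.  ``clinical`` is an
    optional per-subject score table (anticipatory, consummatory and
    covariate scores) indexed by subject id.
    """

    def __init__(
        self,
        layout: ChannelLayout,
        fs: float,
        times: np.ndarray,
        erps: Mapping[tuple[str, str], np.ndarray],
        group_of: Mapping[str, str],
        groups: Sequence[str] | None = None,
        clinical: pd.DataFrame | None = None,
    ):
        self.layout = layout
        self.fs = float(fs)
        self.times = np.asarray(times, dtype=float)
        step = 1000.0 / self.fs
        if len(self.times) > 1 and not np.allclose(np.diff(self.times), step, atol=1e-6):
            raise ValueError("times must increase with step 1000/fs ms")
        self.erps: dict[tuple[str, str], np.ndarray] = {}
        for (sid, cond), mat in erps.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (layout.n_channels, len(self.times)):
                raise ValueError(
                    f"ERP for {sid}/{cond} has shape {mat.shape}, expected "
                    f"({layout.n_channels}, {len(self.times)})"
                )
            self.erps[(sid, cond)] = average_reference(mat)
        self.group_of = dict(group_of)
        if groups is None:
            groups = sorted(set(self.group_of.values()))
        self.groups = tuple(groups)
        if len(self.groups) != 2:
            raise ValueError("dataset must have exactly two groups")
        for sid in self.subjects:
            for cond in MERGED_CONDITIONS:
                if (sid, cond) not in self.erps:
                    raise ValueError(f"subject {sid} is missing condition {cond}")
        self.clinical = clinical

    @property
    def subjects(self) -> list[str]:
        return sorted({sid for sid, _ in self.erps})

    def subjects_in(self, group: str) -> list[str]:
        return [s for s in self.subjects if self.group_of[s] == group]

    def get(self, subject_id: str, condition: str) -> np.ndarray:
        return self.erps[(subject_id, condition)]

    @property
    def conditions(self) -> tuple[str, ...]:
        return MERGED_CONDITIONS

    def time_mask(self, start_ms: float, end_ms: float) -> np.ndarray:
        """Boolean sample mask for the closed window [start_ms, end_ms]."""
        tol = 1e-9
        return (self.times >= start_ms - tol) & (self.times <= end_ms + tol)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<ERPDataset {len(self.subjects)} subjects, groups {self.groups}, "
            f"{self.layout.n_channels} ch, {len(self.times)} samples @ {self.fs:g} Hz>"
        )


# ---------------------------------------------------------------------------
# preprocessing operations


def merge_conditions(epochsets: Iterable[EpochSet]) -> list[EpochSet]:
    """Merge small/large reward and small/large loss cue epochs.

    Pools trials so reward = small_reward + large_reward epochs (and the
    same for loss); neutral passes through.  Trial counts add.
    """
    by_key: dict[tuple[str, str], list[EpochSet]] = {}
    for es in epochsets:
        if es.condition not in MERGE_MAP:
            raise ValueError(f"unknown raw condition label {es.condition!r}")
        by_key.setdefault((es.subject_id, MERGE_MAP[es.condition]), []).append(es)
    merged = []
    for (sid, cond), parts in sorted(by_key.items()):
        fs = parts[0].fs
        t0 = parts[0].t0_offset
        for p in parts:
            if p.fs != fs or p.t0_offset != t0:
                raise ValueError(f"inconsistent sampling metadata for subject {sid}")
        epochs = np.concatenate([p.epochs for p in parts], axis=0)
        merged.append(EpochSet(sid, cond, epochs, fs, t0))
    return merged


def average_epochs(
    epochsets: Iterable[EpochSet],
    min_incentive_trials: int = MIN_INCENTIVE_TRIALS,
    min_neutral_trials: int = MIN_NEUTRAL_TRIALS,
) -> tuple[dict[tuple[str, str], np.ndarray], list[ExclusionReport]]:
    """Average merged-condition epochs into per-subject ERPs.

    Subjects with fewer than ``min_incentive_trials`` reward or loss
    trials, or fewer than ``min_neutral_trials`` neutral trials, are
    excluded and reported rather than silently dropped.

    Returns
    -------
    erps : dict mapping (subject_id, condition) to channels x time ERP
    exclusions : list of :class:`ExclusionReport`
    """
    by_subject: dict[str, dict[str, EpochSet]] = {}
    for es in epochsets:
        if es.condition not in MERGED_CONDITIONS:
            raise ValueError(
                f"average_epochs expects merged conditions, got {es.condition!r}"
            )
        by_subject.setdefault(es.subject_id, {})[es.condition] = es

    erps: dict[tuple[str, str], np.ndarray] = {}
    exclusions: list[ExclusionReport] = []
    for sid, conds in sorted(by_subject.items()):
        failing = []
        for cond in MERGED_CONDITIONS:
            n = conds[cond].n_trials if cond in conds else 0
            minimum = min_neutral_trials if cond == "neutral" else min_incentive_trials
            if n < minimum:
                failing.append((cond, n))
        if failing:
            detail = "; ".join(f"{cond}: {n} trials" for cond, n in failing)
            exclusions.append(ExclusionReport(sid, "insufficient_trials", detail))
            continue
        for cond in MERGED_CONDITIONS:
            erps[(sid, cond)] = average_reference(conds[cond].epochs.mean(axis=0))
    return erps, exclusions


def bandpass(epochset: EpochSet, lo_hz: float, hi_hz: float, order: int = 4) -> EpochSet:
    """Zero-phase Butterworth band-pass of every epoch and channel.

    Forward-backward filtering (``scipy.signal.sosfiltfilt``) so no phase
    distortion is introduced; DC is rejected by the high-pass edge.
    """
    from scipy.signal import butter, sosfiltfilt

    fs = epochset.fs
    if not (0 < lo_hz < hi_hz < fs / 2):
        raise ValueError(f"invalid band ({lo_hz}, {hi_hz}) for fs={fs}")
    sos = butter(order, [lo_hz, hi_hz], btype="bandpass", fs=fs, output="sos")
    filtered = sosfiltfilt(sos, epochset.epochs, axis=-1)
    return EpochSet(epochset.subject_id, epochset.condition, filtered, fs, epochset.t0_offset)


# ---------------------------------------------------------------------------
# manifest layout I/O

_MANIFEST_NAME = "manifest.yaml"
_CLINICAL_NAME = "clinical.csv"


def _matrix_path(sid: str, cond: str) -> str:
    return f"erp_{sid}_{cond}.tsv"


def write_matrix(path: Path, matrix: np.ndarray, times: np.ndarray) -> None:
    """Write a channels x time matrix as TSV with a latency header row."""
    header = "\t".join(f"{t:.6f}" for t in times)
    np.savetxt(path, matrix, delimiter="\t", header=header, comments="", fmt="%.10g")


def read_matrix(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a TSV matrix; returns (matrix, times_ms)."""
    with open(path) as fh:
        times = np.array([float(x) for x in fh.readline().split("\t")])
    matrix = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    return matrix, times


def write_manifest_dataset(dataset: ERPDataset, path: str | Path) -> Path:
    """Write a dataset as manifest + per-ERP delimited matrices.

    Returns the directory written.  The inverse of
    :func:`read_manifest_dataset` to within 1e-9.
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    subjects = []
    for sid in dataset.subjects:
        entry = {"id": sid, "group": dataset.group_of[sid], "erps": {}}
        for cond in MERGED_CONDITIONS:
            fname = _matrix_path(sid, cond)
            write_matrix(root / fname, dataset.get(sid, cond), dataset.times)
            entry["erps"][cond] = fname
        subjects.append(entry)
    manifest = {
        "fs": dataset.fs,
        "channels": list(dataset.layout.labels),
        "groups": list(dataset.groups),
        "subjects": subjects,
    }
    if dataset.layout.positions is not None:
        manifest["positions"] = [[float(v) for v in p] for p in dataset.layout.positions]
    if dataset.clinical is not None:
        dataset.clinical.to_csv(root / _CLINICAL_NAME)
        manifest["clinical"] = _CLINICAL_NAME
    with open(root / _MANIFEST_NAME, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return root


def read_manifest_dataset(path: str | Path) -> ERPDataset:
    """Load a manifest-layout dataset directory into an :class:`ERPDataset`.

    Matrices are re-referenced to average reference on load if needed.
    Missing matrix files and channel-count mismatches are hard errors
    naming the offending subject/condition.
    """
    root = Path(path)
    mpath = root / _MANIFEST_NAME
    if not mpath.exists():
        raise FileNotFoundError(f"no {_MANIFEST_NAME} in {root}")
    with open(mpath) as fh:
        manifest = yaml.safe_load(fh)
    positions = manifest.get("positions")
    layout = ChannelLayout(
        tuple(manifest["channels"]),
        np.asarray(positions, dtype=float) if positions is not None else None,
    )
    fs = float(manifest["fs"])
    erps: dict[tuple[str, str], np.ndarray] = {}
    group_of: dict[str, str] = {}
    times = None
    for entry in manifest["subjects"]:
        sid = str(entry["id"])
        group_of[sid] = entry["group"]
        for cond, fname in entry["erps"].items():
            fpath = root / fname
            if not fpath.exists():
                raise FileNotFoundError(
                    f"matrix file {fpath} for subject {sid}, condition {cond} is missing"
                )
            mat, mat_times = read_matrix(fpath)
            if mat.shape[0] != layout.n_channels:
                raise ValueError(
                    f"subject {sid}, condition {cond}: {mat.shape[0]} channels, "
                    f"layout has {layout.n_channels}"
                )
            if times is None:
                times = mat_times
            erps[(sid, cond)] = mat
    clinical = None
    if "clinical" in manifest:
        clinical = pd.read_csv(root / manifest["clinical"], index_col=0)
        clinical.index = clinical.index.astype(str)
    return ERPDataset(
        layout,
        fs,
        times,
        erps,
        group_of,
        groups=manifest.get("groups"),
        clinical=clinical,
    )


def write_exclusion_report(reports: Sequence[ExclusionReport], path: str | Path) -> None:
    """Write exclusions as a delimited table (subject, reason, detail)."""
    df = pd.DataFrame(
        [(r.subject_id, r.reason, r.detail) for r in reports],
        columns=["subject_id", "reason", "detail"],
    )
    df.to_csv(path, sep="\t", index=False)
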