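"""Modified k-means microstate clustering, backfitting and parameters.

ERP microstates are brief periods during which the scalp topography
stays quasi-stable.  They are identified by clustering the instantaneous
maps of the concatenated group x condition grand-mean ERPs with a
modified k-means that scores a map by its projection onto unit-norm
template topographies (rather than Euclidean distance), then assigned
back to the grand means ("backfitting") to obtain per-time-point class
labels and explained-variance curves.

Because ERPs are phase-locked averages, opposite-polarity maps are
treated as distinct states by default (``polarity_sensitive=True``);
resting-state-style polarity invariance is available as a flag.

Six parameters summarize each appearance of a class within an analysis
window: onset, offset, duration, area under the explained-variance
curve, center of gravity of that curve, and mean global field power.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Sequence

import numpy as np

from .erp import gfp


@dataclasses.dataclass
class MicrostateModel:
    """Fitted microstate template maps.

    ``templates`` is (k, n_channels); each template is average-referenced
    with unit L2 norm.  ``train_explained_variance`` is the fraction of
    topographic variance the assigned templates explain in the training
    maps.
    """

    templates: np.ndarray
    polarity_sensitive: bool = True
    fit_seed: int | None = None
    train_explained_variance: float | None = None

    def __post_init__(self):
        self.templates = np.atleast_2d(np.asarray(self.templates, dtype=float))
        means = self.templates.mean(axis=1)
        norms = np.linalg.norm(self.templates, axis=1)
        if not np.allclose(means, 0, atol=1e-9):
            raise ValueError("templates must be average-referenced")
        if not np.allclose(norms, 1, atol=1e-9):
            raise ValueError("templates must have unit L2 norm")

    @property
    def k(self) -> int:
        return self.templates.shape[0]

    def summary(self) -> str:
        ev = self.train_explained_variance
        lines = [
            "Microstate model",
            f"  classes:            {self.k}",
            f"  channels:           {self.templates.shape[1]}",
            f"  polarity sensitive: {self.polarity_sensitive}",
            f"  train expl. var.:   {'n/a' if ev is None else f'{100 * ev:.1f}%'}",
        ]
        return "\n".join(lines)


@dataclasses.dataclass
class Segmentation:
    """Backfitted class labels and curves for one grand-mean ERP.

    ``labels`` holds 1-based class indices per retained time point;
    ``ev_curve`` is the explained sum of squares per time point divided
    by the channel count, so it is bounded by ``gfp_curve**2`` and has
    µV² units; ``times_ms`` are the latencies of the retained window.
    """

    labels: np.ndarray
    ev_curve: np.ndarray
    gfp_curve: np.ndarray
    times_ms: np.ndarray
    k: int

    @property
    def window(self) -> tuple[float, float]:
        return float(self.times_ms[0]), float(self.times_ms[-1])


@dataclasses.dataclass
class MicrostateFeatures:
    """The six per-appearance microstate parameters.

    Latencies in ms; ``auc`` in µV²·ms (explained variance integrated
    over the labeled samples); ``mean_gfp`` in µV.
    """

    class_id: int
    window: tuple[float, float]
    onset: float
    offset: float
    duration: float
    auc: float
    cog: float
    mean_gfp: float

    FEATURE_NAMES = ("onset", "offset", "duration", "auc", "cog", "mean_gfp")

    def value(self, feature: str) -> float:
        if feature not in self.FEATURE_NAMES:
            raise ValueError(f"unknown feature {feature!r}")
        return getattr(self, feature)


@dataclasses.dataclass
class CrossValidationCurve:
    """Mean held-out explained variance per candidate class count."""

    k_values: tuple[int, ...]
    test_ev: np.ndarray
    selected_k: int
    scheme: str
    seed: int | None
    epsilon: float


# ---------------------------------------------------------------------------
# fitting


def _assign(maps: np.ndarray, templates: np.ndarray, polarity_sensitive: bool):
    """Return (labels, projections) for maps (n, C) against unit templates."""
    proj = maps @ templates.T  # (n, k)
    score = proj if polarity_sensitive else proj**2
    labels = np.argmax(score, axis=1)
    return labels, proj


def _update_templates(
    maps: np.ndarray,
    labels: np.ndarray,
    k: int,
    polarity_sensitive: bool,
    rng: np.random.Generator,
    old: np.ndarray,
) -> np.ndarray:
    new = old.copy()
    for j in range(k):
        members = maps[labels == j]
        if members.shape[0] == 0:
            # re-seed an empty class from a random map
            cand = maps[rng.integers(maps.shape[0])]
            new[j] = _unit(cand)
            continue
        if polarity_sensitive:
            new[j] = _unit(members.mean(axis=0))
        else:
            # dominant direction: first right singular vector
            _, _, vt = np.linalg.svd(members, full_matrices=False)
            new[j] = _unit(vt[0])
    return new


def _unit(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalize an all-zero map")
    return v / n


def fit_microstates(
    maps: np.ndarray,
    k: int,
    n_restarts: int = 20,
    seed: int | None = None,
    polarity_sensitive: bool = True,
    max_iter: int = 200,
) -> MicrostateModel:
    """Cluster instantaneous topographies with a modified k-means.

    Parameters
    ----------
    maps : array, shape (n_maps, n_channels)
        Concatenated average-referenced maps (e.g. the columns of every
        group x condition grand mean over the retained window).
    k : number of microstate classes; must be <= n_channels - 1.
    n_restarts : random restarts; the run with the highest explained
        variance wins.
    polarity_sensitive : assignment by signed projection when True, by
        squared projection (polarity-invariant) when False.

    Returns
    -------
    :class:`MicrostateModel` with ``train_explained_variance`` set.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 2 or maps.shape[0] == 0:
        raise ValueError("maps must be a non-empty (n_maps, n_channels) array")
    n, c = maps.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > c - 1:
        raise ValueError(f"k={k} exceeds channels - 1 = {c - 1}")
    maps = maps - maps.mean(axis=1, keepdims=True)
    total_ss = float(np.sum(maps**2))
    if total_ss == 0:
        raise ValueError("all-zero data cannot be clustered")
    rng = np.random.default_rng(seed)

    best_ev, best_templates = -np.inf, None
    for _ in range(n_restarts):
        idx = rng.choice(n, size=k, replace=False)
        templates = np.stack([_unit(maps[i]) for i in idx])
        labels = np.full(n, -1)
        for _ in range(max_iter):
            new_labels, proj = _assign(maps, templates, polarity_sensitive)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            templates = _update_templates(
                maps, labels, k, polarity_sensitive, rng, templates
            )
        _, proj = _assign(maps, templates, polarity_sensitive)
        ev = float(np.sum(proj[np.arange(n), labels] ** 2) / total_ss)
        if ev > best_ev:
            best_ev, best_templates = ev, templates
    return MicrostateModel(
        best_templates,
        polarity_sensitive=polarity_sensitive,
        fit_seed=seed,
        train_explained_variance=best_ev,
    )


def match_templates(
    model: MicrostateModel, reference: np.ndarray
) -> MicrostateModel:
    """Reorder (and sign-align) a model's templates against reference maps.

    Classes of a fitted model are numbered arbitrarily; this returns a
    model whose class j is the fitted template best matching reference
    map j, by Hungarian assignment on the absolute cosine similarity.
    When the model is polarity-sensitive each matched template keeps its
    sign aligned with its reference.  Requires as many fitted templates
    as reference maps.
    """
    from scipy.optimize import linear_sum_assignment

    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    if reference.shape != model.templates.shape:
        raise ValueError("reference maps must match the templates' shape")
    ref = reference / np.linalg.norm(reference, axis=1, keepdims=True)
    cos = ref @ model.templates.T  # (ref, fitted)
    _, cols = linear_sum_assignment(-np.abs(cos))
    ordered = model.templates[cols].copy()
    if model.polarity_sensitive:
        signs = np.sign(cos[np.arange(len(cols)), cols])
        signs[signs == 0] = 1.0
        ordered *= signs[:, None]
    return MicrostateModel(
        ordered,
        polarity_sensitive=model.polarity_sensitive,
        fit_seed=model.fit_seed,
        train_explained_variance=model.train_explained_variance,
    )


def explained_variance(model: MicrostateModel, maps: np.ndarray) -> float:
    """Fraction of topographic variance explained by assigned templates.

    sum_t (u_best(t) . v_t)^2 / sum_t ||v_t||^2 over the supplied maps,
    with best(t) the assigned class.  In [0, 1].
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    maps = maps - maps.mean(axis=1, keepdims=True)
    total = float(np.sum(maps**2))
    if total == 0:
        raise ValueError("explained variance is undefined for all-zero data")
    labels, proj = _assign(maps, model.templates, model.polarity_sensitive)
    return float(np.sum(proj[np.arange(maps.shape[0]), labels] ** 2) / total)


def cross_validate_k(
    grand_mean_builder: Callable[[Sequence[str]], np.ndarray],
    subjects: Sequence[str],
    k_range: Sequence[int],
    n_splits: int = 5,
    seed: int | None = None,
    epsilon: float = 0.01,
    n_restarts: int = 10,
    polarity_sensitive: bool = True,
    groups_of: dict[str, str] | None = None,
) -> CrossValidationCurve:
    """Choose the class count by held-out explained variance.

    Subjects are split into ``n_splits`` folds (stratified by group when
    ``groups_of`` is given).  For each fold and each k, templates are fit
    on the concatenated grand means of the training subjects and scored
    by :func:`explained_variance` on the held-out subjects' grand means.
    The selected k is the smallest whose mean test gain over k-1 falls
    below ``epsilon`` (in explained-variance fraction); if the curve
    never plateaus the largest k wins.
    """
    k_range = tuple(int(k) for k in k_range)
    if len(k_range) == 0:
        raise ValueError("k_range must be non-empty")
    if sorted(k_range) != list(k_range):
        raise ValueError("k_range must be increasing")
    subjects = list(subjects)
    rng = np.random.default_rng(seed)

    # build folds, stratified by group so each fold sees both groups
    if groups_of is not None:
        folds = [[] for _ in range(n_splits)]
        for g in sorted(set(groups_of.values())):
            members = [s for s in subjects if groups_of[s] == g]
            order = rng.permutation(len(members))
            for i, j in enumerate(order):
                folds[i % n_splits].append(members[j])
    else:
        order = rng.permutation(len(subjects))
        folds = [[subjects[j] for j in order[i::n_splits]] for i in range(n_splits)]

    test_ev = np.zeros((n_splits, len(k_range)))
    for f, test_subjects in enumerate(folds):
        train_subjects = [s for s in subjects if s not in test_subjects]
        train_maps = grand_mean_builder(train_subjects)
        test_maps = grand_mean_builder(test_subjects)
        for i, k in enumerate(k_range):
            model = fit_microstates(
                train_maps,
                k,
                n_restarts=n_restarts,
                seed=int(rng.integers(2**31)),
                polarity_sensitive=polarity_sensitive,
            )
            test_ev[f, i] = explained_variance(model, test_maps)
    curve = test_ev.mean(axis=0)

    selected = k_range[-1]
    for i in range(1, len(k_range)):
        if curve[i] - curve[i - 1] < epsilon:
            selected = k_range[i - 1]
            break
    if len(k_range) == 1:
        selected = k_range[0]
    return CrossValidationCurve(
        k_range, curve, selected, f"{n_splits}-fold subject CV", seed, epsilon
    )


# ---------------------------------------------------------------------------
# backfitting and features


def backfit(
    model: MicrostateModel,
    erp: np.ndarray,
    times_ms: np.ndarray,
    window: tuple[float, float] | None = None,
) -> Segmentation:
    """Assign every time point of an ERP to its best-matching template.

    The label at time t is the argmax over classes of the (signed, when
    polarity-sensitive; otherwise squared) projection of the map onto the
    unit templates; ties go to the lowest class index.  No temporal
    smoothing is applied.  Labels are 1-based.
    """
    erp = np.asarray(erp, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    if erp.shape[1] != times_ms.shape[0]:
        raise ValueError("ERP columns must align with times_ms")
    if window is not None:
        tol = 1e-9
        if window[1] < times_ms[0] - tol or window[0] > times_ms[-1] + tol:
            raise ValueError(f"window {window} outside data range")
        mask = (times_ms >= window[0] - tol) & (times_ms <= window[1] + tol)
        erp, times_ms = erp[:, mask], times_ms[mask]
    if erp.shape[1] == 0:
        raise ValueError("empty analysis window")
    n_ch = erp.shape[0]
    erp = erp - erp.mean(axis=0, keepdims=True)
    proj = model.templates @ erp  # (k, T)
    score = proj if model.polarity_sensitive else proj**2
    labels = np.argmax(score, axis=0) + 1
    ev_curve = proj[labels - 1, np.arange(erp.shape[1])] ** 2 / n_ch
    gfp_curve = gfp(erp)
    return Segmentation(labels, ev_curve, gfp_curve, times_ms, model.k)


def extract_features(
    seg: Segmentation,
    class_id: int,
    analysis_window: tuple[float, float] | None = None,
    check_contiguous: bool = True,
) -> MicrostateFeatures | None:
    """Extract the six parameters of one class appearance.

    The appearance is the set of samples assigned to ``class_id`` within
    ``analysis_window`` (defaults to the whole segmentation window); the
    analysis window should isolate a single appearance — a warning is
    issued if the labeled samples are not contiguous.  Returns None when
    the class never appears in the window (the absent-feature signal).
    """
    if not 1 <= class_id <= seg.k:
        raise ValueError(f"class_id {class_id} outside 1..{seg.k}")
    tol = 1e-9
    if analysis_window is None:
        mask = np.ones_like(seg.labels, dtype=bool)
        window = seg.window
    else:
        window = (float(analysis_window[0]), float(analysis_window[1]))
        mask = (seg.times_ms >= window[0] - tol) & (seg.times_ms <= window[1] + tol)
    sel = mask & (seg.labels == class_id)
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        return None
    if check_contiguous and not np.all(np.diff(idx) == 1):
        warnings.warn(
            f"class {class_id} appears more than once in window {window}; "
            "features pool all its samples",
            stacklevel=2,
        )
    t = seg.times_ms[idx]
    ev = seg.ev_curve[idx]
    dt = 1000.0 / _fs_from_times(seg.times_ms)
    onset, offset = float(t[0]), float(t[-1])
    ev_sum = float(ev.sum())
    cog = float((t * ev).sum() / ev_sum) if ev_sum > 0 else float(t.mean())
    return MicrostateFeatures(
        class_id=class_id,
        window=window,
        onset=onset,
        offset=offset,
        duration=offset - onset,
        auc=ev_sum * dt,
        cog=cog,
        mean_gfp=float(seg.gfp_curve[idx].mean()),
    )


def _fs_from_times(times_ms: np.ndarray) -> float:
    if len(times_ms) < 2:
        raise ValueError("need at least two samples to infer the sampling rate")
    return 1000.0 / float(times_ms[1] - times_ms[0])


def appearance_windows(
    seg: Segmentation, class_id: int, min_gap_samples: int = 1
) -> list[tuple[float, float]]:
    """Split a class's labeled samples into contiguous appearance windows.

    Returns one (start_ms, end_ms) pair per maximal run of consecutive
    samples assigned to ``class_id``; runs separated by fewer than
    ``min_gap_samples`` unlabeled samples are merged.
    """
    idx = np.flatnonzero(seg.labels == class_id)
    if idx.size == 0:
        return []
    windows = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev > min_gap_samples:
            windows.append((float(seg.times_ms[start]), float(seg.times_ms[prev])))
            start = i
        prev = i
    windows.append((float(seg.times_ms[start]), float(seg.times_ms[prev])))
    return windows
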