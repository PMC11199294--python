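"""Global field power, grand means, and the topographic consistency test.

The topographic consistency test (TCT) asks, at each time point, whether
the subjects' scalp maps share a common topography: the statistic is the
global field power (GFP) of the mean of the individually L2-normalized
maps, and the null distribution is built by randomly permuting channel
values within each subject's map.  Normalizing before averaging keeps
between-subject amplitude differences from masquerading as consistency.

Time points where the test fails at the beginning and end of the epoch
are trimmed from the analysis window; interior non-significant gaps are
retained.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .datasets import ERPDataset, average_reference


def gfp(map_or_matrix: np.ndarray) -> float | np.ndarray:
    """Global field power: spatial standard deviation of the map.

    For an average-referenced map v with C channels this is
    sqrt((1/C) * sum_c (v_c - mean(v))^2) — the root-mean-square across
    channels after removing the channel mean.  Accepts a single map
    (returns a scalar) or a channels x time matrix (returns a per-time
    series).  Scale-equivariant: gfp(a*v) = |a|*gfp(v).
    """
    v = np.asarray(map_or_matrix, dtype=float)
    if v.shape[0] < 2:
        raise ValueError("GFP requires at least 2 channels")
    centered = v - v.mean(axis=0, keepdims=True)
    out = np.sqrt(np.mean(centered**2, axis=0))
    return float(out) if out.ndim == 0 else out


def grand_mean(dataset: ERPDataset, group: str, condition: str) -> np.ndarray:
    """Unweighted mean ERP over the subjects of one group x condition cell."""
    subjects = dataset.subjects_in(group)
    if not subjects:
        raise ValueError(f"no subjects in group {group!r}")
    stack = np.stack([dataset.get(s, condition) for s in subjects])
    return stack.mean(axis=0)


@dataclasses.dataclass
class TCTResult:
    """Per-time-point consistency test outcome and the retained window."""

    times_ms: np.ndarray
    p_per_timepoint: np.ndarray
    statistic_per_timepoint: np.ndarray
    n_rand: int
    alpha: float
    window: tuple[float, float] | None  # retained [start_ms, end_ms], None if empty

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_ms": self.times_ms,
                "statistic": self.statistic_per_timepoint,
                "p": self.p_per_timepoint,
            }
        )


def tct(maps: np.ndarray, n_rand: int = 1000, seed: int | None = None) -> float:
    """Topographic consistency test at a single time point.

    Parameters
    ----------
    maps : array, shape (n_subjects, n_channels)
        One average-referenced map per subject.
    n_rand : number of channel permutations for the null.
    seed : RNG seed.

    Returns
    -------
    Monte-Carlo p-value by the add-one rule
    (1 + #{null >= observed}) / (1 + n_rand); ties count toward the null.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 2 or maps.shape[0] < 2:
        raise ValueError("tct needs maps from at least 2 subjects")
    if n_rand < 100:
        raise ValueError("n_rand must be at least 100")
    rng = np.random.default_rng(seed)
    normed = _normalize_maps(maps)
    observed = gfp(normed.mean(axis=0))
    null = _tct_null(normed, n_rand, rng)
    return float((1 + np.sum(null >= observed)) / (1 + n_rand))


def _normalize_maps(maps: np.ndarray) -> np.ndarray:
    """Average-reference and L2-normalize each subject's map (rows)."""
    centered = maps - maps.mean(axis=-1, keepdims=True)
    norms = np.linalg.norm(centered, axis=-1, keepdims=True)
    norms[norms == 0] = 1.0
    return centered / norms

def _tct_null(normed: np.ndarray, n_rand: int, rng: np.random.Generator) -> np.ndarray:
    """Null GFP values: channels permuted independently within each subject."""
    n_subj, n_ch = normed.shape
    tiled = np.broadcast_to(normed, (n_rand, n_subj, n_ch)).copy()
    permuted = rng.permuted(tiled, axis=2)
    mean_maps = permuted.mean(axis=1)  # (n_rand, n_ch)
    centered = mean_maps - mean_maps.mean(axis=1, keepdims=True)
    return np.sqrt(np.mean(centered**2, axis=1))


def tct_series(
    maps: np.ndarray,
    times_ms: np.ndarray,
    n_rand: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> TCTResult:
    """Run the consistency test at every time point of a maps stack.

    ``maps`` is subjects x channels x time.  Returns a :class:`TCTResult`
    whose ``window`` is the leading/trailing-trimmed consistent window
    (see :func:`find_consistent_window`).
    """
    maps = np.asarray(maps, dtype=float)
    n_subj, n_ch, n_t = maps.shape
    if n_subj < 2:
        raise ValueError("tct needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    p = np.empty(n_t)
    stat = np.empty(n_t)
    for t in range(n_t):
        normed = _normalize_maps(maps[:, :, t])
        stat[t] = gfp(normed.mean(axis=0))
        null = _tct_null(normed, n_rand, rng)
        p[t] = (1 + np.sum(null >= stat[t])) / (1 + n_rand)
    window = find_consistent_window(p, times_ms, alpha)
    return TCTResult(np.asarray(times_ms, float), p, stat, n_rand, alpha, window)


def dataset_tct(
    dataset: ERPDataset,
    n_rand: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> TCTResult:
    """Consistency test over a whole dataset.

    Runs the test per group x condition cell and combines conservatively:
    the per-time-point p is the maximum over cells, so the retained
    window is where every cell shows topographic consistency.
    """
    results = []
    rng = np.random.default_rng(seed)
    for group in dataset.groups:
        for cond in dataset.conditions:
            subjects = dataset.subjects_in(group)
            maps = np.stack([dataset.get(s, cond) for s in subjects])
            results.append(
                tct_series(
                    maps, dataset.times, n_rand, alpha,
                    seed=int(rng.integers(2**31)),
                )
            )
    p = np.max([r.p_per_timepoint for r in results], axis=0)
    stat = np.mean([r.statistic_per_timepoint for r in results], axis=0)
    window = find_consistent_window(p, dataset.times, alpha)
    return TCTResult(dataset.times, p, stat, n_rand, alpha, window)


def find_consistent_window(
    p_series: np.ndarray, times_ms: np.ndarray, alpha: float = 0.05
) -> tuple[float, float] | None:
    """Trim leading and trailing runs of non-significant time points.

    Only the beginning and end of the epoch are excluded; interior
    non-significant gaps are retained.  Returns (start_ms, end_ms) on
    sample latencies, or None if no time point is significant.
    """
    p_series = np.asarray(p_series, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    if p_series.shape != times_ms.shape:
        raise ValueError("p_series and times_ms must align")
    sig = np.flatnonzero(p_series < alpha)
    if sig.size == 0:
        return None
    return float(times_ms[sig[0]]), float(times_ms[sig[-1]])
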