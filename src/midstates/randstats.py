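"""Randomization tests for group, condition and interaction effects.

Microstate parameters are computed on cell grand means (one value per
group x condition cell), so classical subject-level ANOVA does not
apply.  Instead, effects observed in the real cell-means table are
compared with effects obtained after randomly reassigning ERPs to
factor levels: group labels are permuted across subjects, condition
labels are permuted within subjects (each subject keeps their three
ERPs), grand means are rebuilt, the fixed microstate templates are
backfitted, and the parameter table and effect statistic are recomputed.
The Monte-Carlo p-value uses the add-one rule
(1 + #{null >= observed}) / (1 + n_rand), with ties counting toward the
null, so p is never zero.

Templates are NOT refit per randomization: only backfitting and feature
extraction are recomputed.  Refitting the clustering thousands of times
would be prohibitive, and keeping maps fixed is the convention of
topographic randomization software; it is exposed for sensitivity
analysis via the ``refit`` hook left out deliberately.

Effect statistics on the 2 x 3 cell-mean table x_gc:
  group:        sum_g (x_g. - x_..)^2
  condition:    sum_c (x_.c - x_..)^2
  interaction:  sum_gc (x_gc - x_g. - x_.c + x_..)^2
  contrast:     |x_cell1 - x_cell2| (or cell-set mean difference)
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .datasets import ERPDataset
from .erp import grand_mean
from .microstates import (
    MicrostateModel,
    appearance_windows,
    backfit,
    extract_features,
)

EFFECTS = ("group", "condition", "interaction", "contrast")


def class_analysis_window(
    dataset: ERPDataset,
    model: MicrostateModel,
    class_id: int,
    window: tuple[float, float] | None = None,
) -> tuple[float, float] | None:
    """Analysis window isolating one appearance of a class.

    Backfits every group x condition grand mean (optionally restricted
    to ``window``) and returns the union over cells of the class's
    longest contiguous appearance, so the window covers the appearance
    in every cell while excluding stray isolated samples elsewhere in
    the epoch.  Returns None if the class appears in no cell.
    """
    lo, hi = np.inf, -np.inf
    for g in dataset.groups:
        for c in dataset.conditions:
            seg = backfit(model, grand_mean(dataset, g, c), dataset.times,
                          window=window)
            apps = appearance_windows(seg, class_id)
            if apps:
                a, b = max(apps, key=lambda w: w[1] - w[0])
                lo, hi = min(lo, a), max(hi, b)
    if lo > hi:
        return None
    return float(lo), float(hi)


@dataclasses.dataclass
class RandomizationResult:
    """Observed statistic, null distribution and Monte-Carlo p-value."""

    effect: str
    feature: str
    class_id: int
    window: tuple[float, float]
    observed: float
    null_distribution: np.ndarray
    p: float
    n_rand: int
    seed: int | None
    n_redraws: int = 0
    detail: str = ""

    def __post_init__(self):
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        if not np.isfinite(self.observed):
            raise ValueError("observed statistic must be finite")

    def summary(self) -> str:
        lines = [
            f"Randomization test: {self.effect}" + (f" ({self.detail})" if self.detail else ""),
            f"  feature:   {self.feature} (class {self.class_id}, "
            f"window {self.window[0]:g}-{self.window[1]:g} ms)",
            f"  observed:  {self.observed:.6g}",
            f"  p-value:   {self.p:.4g}  ({self.n_rand} randomizations)",
        ]
        if self.n_redraws:
            lines.append(f"  redraws:   {self.n_redraws} (absent feature in a cell)")
        return "\n".join(lines)


def _monte_carlo_p(null: np.ndarray, observed: float) -> float:
    return float((1 + np.sum(null >= observed - 1e-12)) / (1 + len(null)))


# ---------------------------------------------------------------------------
# feature computation on cells


def cell_feature(
    dataset: ERPDataset,
    model: MicrostateModel,
    group: str,
    condition: str,
    class_id: int,
    window: tuple[float, float],
    feature: str,
) -> float | None:
    """One microstate parameter for one group x condition cell.

    Grand mean -> backfit with the fixed templates -> extract the named
    parameter of ``class_id`` within ``window``.  Returns None when the
    class does not appear in the window (the absent-feature signal).
    """
    gm = grand_mean(dataset, group, condition)
    seg = backfit(model, gm, dataset.times, window=window)
    feats = extract_features(seg, class_id, check_contiguous=False)
    return None if feats is None else feats.value(feature)


class _PermutationEngine:
    """Vectorized recomputation of cell features under label permutations.

    Holds the windowed ERP stack X (n_subj, n_cond, C, T) and the
    precomputed template projections P (n_subj, n_cond, k, T); because
    projection is linear, the projection of a cell grand mean is the
    mean of the member subjects' projections, so backfitting a permuted
    cell costs one small matrix mean plus an argmax.
    """

    def __init__(
        self,
        dataset: ERPDataset,
        model: MicrostateModel,
        class_id: int,
        window: tuple[float, float],
        feature: str,
    ):
        from .microstates import MicrostateFeatures

        if feature not in MicrostateFeatures.FEATURE_NAMES:
            raise ValueError(f"unknown feature {feature!r}")
        if not 1 <= class_id <= model.k:
            raise ValueError(f"class_id {class_id} outside 1..{model.k}")
        self.model = model
        self.class_id = class_id
        self.feature = feature
        self.window = (float(window[0]), float(window[1]))
        mask = dataset.time_mask(*self.window)
        if not mask.any():
            raise ValueError(f"window {window} contains no samples")
        self.times = dataset.times[mask]
        self.dt = 1000.0 / dataset.fs
        self.subjects = dataset.subjects
        self.conditions = dataset.conditions
        self.groups = dataset.groups
        self.group_codes = np.array(
            [self.groups.index(dataset.group_of[s]) for s in self.subjects]
        )
        n_s, n_c = len(self.subjects), len(self.conditions)
        ch = dataset.layout.n_channels
        self.n_channels = ch
        self.X = np.empty((n_s, n_c, ch, mask.sum()))
        for i, s in enumerate(self.subjects):
            for j, c in enumerate(self.conditions):
                self.X[i, j] = dataset.get(s, c)[:, mask]
        # P[s, c] = templates @ X[s, c]
        self.P = np.einsum("kc,sjct->sjkt", model.templates, self.X)
        self.polarity = model.polarity_sensitive

    # -- single-cell feature from subject index sets ------------------------

    def _cell_value(self, subj_idx: np.ndarray, cond_idx: np.ndarray) -> float | None:
        """Feature of the grand mean over (subject i, condition cond_idx[i])."""
        proj = self.P[subj_idx, cond_idx].mean(axis=0)  # (k, T)
        score = proj if self.polarity else proj**2
        labels = np.argmax(score, axis=0) + 1
        sel = labels == self.class_id
        if not sel.any():
            return None
        idx = np.flatnonzero(sel)
        if self.feature == "onset":
            return float(self.times[idx[0]])
        if self.feature == "offset":
            return float(self.times[idx[-1]])
        if self.feature == "duration":
            return float(self.times[idx[-1]] - self.times[idx[0]])
        ev = proj[self.class_id - 1, idx] ** 2 / self.n_channels
        if self.feature == "auc":
            return float(ev.sum() * self.dt)
        if self.feature == "cog":
            s = ev.sum()
            t = self.times[idx]
            return float((t * ev).sum() / s) if s > 0 else float(t.mean())
        # mean_gfp: needs the cell mean map itself
        m = self.X[subj_idx, cond_idx].mean(axis=0)  # (C, T)
        m = m - m.mean(axis=0, keepdims=True)
        g = np.sqrt(np.mean(m[:, idx] ** 2, axis=0))
        return float(g.mean())

    def cell_table(
        self, group_assign: np.ndarray, cond_assign: np.ndarray
    ) -> np.ndarray | None:
        """2 x n_cond feature table under the given label assignment.

        ``group_assign[i]`` is the (possibly permuted) group code of
        subject i; ``cond_assign[i, c]`` is the index of the ERP of
        subject i that carries condition label c.  Returns None if the
        class is absent from any cell.
        """
        n_c = len(self.conditions)
        table = np.empty((2, n_c))
        for g in range(2):
            subj = np.flatnonzero(group_assign == g)
            if subj.size < 2:
                raise ValueError("degenerate group with fewer than 2 subjects")
            for c in range(n_c):
                v = self._cell_value(subj, cond_assign[subj, c])
                if v is None:
                    return None
                table[g, c] = v
        return table

    def identity_assignment(self) -> tuple[np.ndarray, np.ndarray]:
        n_s, n_c = len(self.subjects), len(self.conditions)
        return self.group_codes.copy(), np.tile(np.arange(n_c), (n_s, 1))


def _interaction_stat(table: np.ndarray) -> float:
    resid = (
        table
        - table.mean(axis=1, keepdims=True)
        - table.mean(axis=0, keepdims=True)
        + table.mean()
    )
    return float(np.sum(resid**2))


def _main_effect_stat(table: np.ndarray, factor: str) -> float:
    if factor == "group":
        level_means = table.mean(axis=1)
    elif factor == "condition":
        level_means = table.mean(axis=0)
    else:
        raise ValueError(f"unknown factor {factor!r}")
    return float(np.sum((level_means - table.mean()) ** 2))


def _run_randomization(
    engine: _PermutationEngine,
    stat_fn,
    permute_group: bool,
    permute_cond: bool,
    n_rand: int,
    seed: int | None,
    max_redraw_factor: int = 20,
) -> tuple[float, np.ndarray, int]:
    """Observed statistic plus a null distribution of size n_rand.

    Randomizations in which the class is absent from any cell are
    redrawn (up to ``max_redraw_factor * n_rand`` total draws).
    """
    rng = np.random.default_rng(seed)
    group0, cond0 = engine.identity_assignment()
    table = engine.cell_table(group0, cond0)
    if table is None:
        raise ValueError(
            f"class {engine.class_id} absent from an observed cell in "
            f"window {engine.window}"
        )
    observed = stat_fn(table)
    n_s, n_c = len(engine.subjects), len(engine.conditions)
    null = np.empty(n_rand)
    redraws = 0
    budget = max_redraw_factor * n_rand
    filled = 0
    while filled < n_rand:
        if redraws + filled >= budget:
            raise RuntimeError(
                "too many randomizations produced an absent feature; "
                "the class is unstable in this window"
            )
        g = rng.permutation(group0) if permute_group else group0
        if permute_cond:
            c = rng.permuted(np.tile(np.arange(n_c), (n_s, 1)), axis=1)
        else:
            c = cond0
        t = engine.cell_table(g, c)
        if t is None:
            redraws += 1
            continue
        null[filled] = stat_fn(t)
        filled += 1
    return observed, null, redraws


def interaction_test(
    dataset: ERPDataset,
    model: MicrostateModel,
    class_id: int,
    window: tuple[float, float],
    feature: str,
    n_rand: int = 5000,
    seed: int | None = None,
) -> RandomizationResult:
    """Group x condition interaction randomization test.

    The observed statistic is the double-centered sum of squares of the
    2 x 3 cell-means table of the named microstate parameter.  Per
    randomization, group labels are permuted across subjects and each
    subject's condition labels are permuted independently, grand means
    are rebuilt, the fixed templates are backfitted and the statistic is
    recomputed.
    """
    if n_rand < 100:
        raise ValueError("n_rand must be at least 100")
    engine = _PermutationEngine(dataset, model, class_id, window, feature)
    observed, null, redraws = _run_randomization(
        engine, _interaction_stat, True, True, n_rand, seed
    )
    return RandomizationResult(
        "interaction", feature, class_id, engine.window, observed, null,
        _monte_carlo_p(null, observed), n_rand, seed, redraws,
    )


def main_effect_test(
    dataset: ERPDataset,
    model: MicrostateModel,
    class_id: int,
    window: tuple[float, float],
    feature: str,
    factor: str,
    n_rand: int = 5000,
    seed: int | None = None,
) -> RandomizationResult:
    """Main-effect randomization test for ``factor`` (group or condition).

    Statistic: sum over factor levels of (level mean - grand mean)^2 on
    the cell-means table; only the tested factor's labels are permuted.
    """
    if n_rand < 100:
        raise ValueError("n_rand must be at least 100")
    if factor not in ("group", "condition"):
        raise ValueError(f"unknown factor {factor!r}")
    engine = _PermutationEngine(dataset, model, class_id, window, feature)
    observed, null, redraws = _run_randomization(
        engine,
        lambda t: _main_effect_stat(t, factor),
        permute_group=(factor == "group"),
        permute_cond=(factor == "condition"),
        n_rand=n_rand,
        seed=seed,
    )
    return RandomizationResult(
        factor, feature, class_id, engine.window, observed, null,
        _monte_carlo_p(null, observed), n_rand, seed, redraws,
    )


def posthoc_contrast(
    dataset: ERPDataset,
    model: MicrostateModel,
    class_id: int,
    window: tuple[float, float],
    feature: str,
    cell_a: tuple[str, str],
    cell_b: tuple[str, str],
    n_rand: int = 5000,
    seed: int | None = None,
) -> RandomizationResult:
    """Post-hoc contrast between two group x condition cells.

    Statistic: |feature(cell_a) - feature(cell_b)|.  The permutation is
    restricted to the labels that distinguish the two cells: group
    labels for a between-group contrast (same condition), the two
    condition labels within the group's subjects for a within-group
    contrast (same group).  Cells differing in both factors are not
    supported.
    """
    if n_rand < 100:
        raise ValueError("n_rand must be at least 100")
    if cell_a == cell_b:
        raise ValueError("contrast cells must differ")
    ga, ca = cell_a
    gb, cb = cell_b
    if ga not in dataset.groups or gb not in dataset.groups:
        raise ValueError("unknown group in contrast cells")
    if ca not in dataset.conditions or cb not in dataset.conditions:
        raise ValueError("unknown condition in contrast cells")
    if ga != gb and ca != cb:
        raise ValueError("contrast cells may differ in only one factor")

    engine = _PermutationEngine(dataset, model, class_id, window, feature)
    rng = np.random.default_rng(seed)
    group0, cond0 = engine.identity_assignment()
    gi_a, gi_b = dataset.groups.index(ga), dataset.groups.index(gb)
    ci_a, ci_b = dataset.conditions.index(ca), dataset.conditions.index(cb)

    def cells_value(gcodes: np.ndarray, cassign: np.ndarray) -> float | None:
        sa = np.flatnonzero(gcodes == gi_a)
        sb = np.flatnonzero(gcodes == gi_b)
        va = engine._cell_value(sa, cassign[sa, ci_a])
        vb = engine._cell_value(sb, cassign[sb, ci_b])
        if va is None or vb is None:
            return None
        return abs(va - vb)

    observed = cells_value(group0, cond0)
    if observed is None:
        raise ValueError(
            f"class {class_id} absent from an observed contrast cell in window {window}"
        )
    null = np.empty(n_rand)
    redraws, filled = 0, 0
    budget = 20 * n_rand
    between_group = ga != gb
    members = np.flatnonzero(group0 == gi_a)  # within-group contrast subjects
    while filled < n_rand:
        if redraws + filled >= budget:
            raise RuntimeError("too many absent-feature redraws in contrast")
        if between_group:
            g = rng.permutation(group0)
            c = cond0
        else:
            g = group0
            c = cond0.copy()
            swap = rng.random(members.size) < 0.5
            swap_rows = members[swap]
            c[swap_rows, ci_a], c[swap_rows, ci_b] = (
                cond0[swap_rows, ci_b],
                cond0[swap_rows, ci_a],
            )
        v = cells_value(g, c)
        if v is None:
            redraws += 1
            continue
        null[filled] = v
        filled += 1
    return RandomizationResult(
        "contrast", feature, class_id, engine.window, observed, null,
        _monte_carlo_p(null, observed), n_rand, seed, redraws,
        detail=f"{ga}/{ca} vs {gb}/{cb}",
    )


def results_table(results: list[RandomizationResult]) -> pd.DataFrame:
    """Tabulate randomization results for export as delimited text."""
    rows = []
    for r in results:
        rows.append(
            {
                "effect": r.effect,
                "detail": r.detail,
                "feature": r.feature,
                "class": r.class_id,
                "window_start_ms": r.window[0],
                "window_end_ms": r.window[1],
                "observed": r.observed,
                "p": r.p,
                "n_rand": r.n_rand,
                "seed": r.seed,
                "n_redraws": r.n_redraws,
            }
        )
    return pd.DataFrame(rows)
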