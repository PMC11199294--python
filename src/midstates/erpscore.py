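"""Individual ERP scores by template-map projection, and partial correlation.

When a microstate window shows a group x condition interaction, a
*template map* is formed as the mean group-difference topography of the
condition of interest, averaged over that window.  Projecting each
subject's window-averaged map onto the template (a plain dot product)
yields one scalar per subject — the ERP score — measuring how strongly
that subject expresses the topography that separates the groups.  A
positive score means the subject leans toward the first group of the
sign convention; scores are in µV² (map times map).

Scores are then related to clinical variables with Pearson partial
correlation, controlling a covariate (e.g. general cognitive ability):

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))

with a two-tailed t test on n - 3 degrees of freedom and a 95% CI by
Fisher's z transform with SE = 1/sqrt(n - 4).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ERPDataset, average_reference


@dataclasses.dataclass
class TemplateMap:
    """Group-difference topography for one condition and window.

    ``sign_convention`` records which group mean was subtracted from
    which (``"A-B"`` means mean(group A) - mean(group B)); the sign of
    every downstream score and correlation depends on it.
    """

    map: np.ndarray
    window: tuple[float, float]
    condition: str
    sign_convention: str

    def __post_init__(self):
        self.map = np.asarray(self.map, dtype=float)
        if abs(self.map.mean()) > 1e-6 * max(1.0, np.abs(self.map).max()):
            raise ValueError("template map must be average-referenced")


@dataclasses.dataclass
class PartialCorrelationResult:
    r: float
    p: float
    ci95: tuple[float, float]
    n: int

    def summary(self) -> str:
        lo, hi = self.ci95
        return (
            f"partial r = {self.r:.3f}, p = {self.p:.4g}, "
            f"95% CI [{lo:.3f}, {hi:.3f}], n = {self.n}"
        )


def window_mean_map(
    erp: np.ndarray, times_ms: np.ndarray, window: tuple[float, float]
) -> np.ndarray:
    """Per-channel time average of an ERP over a closed window (ms)."""
    times_ms = np.asarray(times_ms, dtype=float)
    tol = 1e-9
    mask = (times_ms >= window[0] - tol) & (times_ms <= window[1] + tol)
    if not mask.any():
        raise ValueError(f"window {window} contains no samples")
    return np.asarray(erp, dtype=float)[:, mask].mean(axis=1)


def compute_template(
    dataset: ERPDataset,
    window: tuple[float, float],
    condition: str,
    reference_group_order: tuple[str, str] | None = None,
) -> TemplateMap:
    """Mean group-difference map over a window for one condition.

    template = mean over group-A subjects of the window-averaged map
    minus the same for group B, where (A, B) is
    ``reference_group_order`` (defaults to ``dataset.groups``).
    """
    if reference_group_order is None:
        reference_group_order = dataset.groups
    ga, gb = reference_group_order
    means = []
    for g in (ga, gb):
        subjects = dataset.subjects_in(g)
        if not subjects:
            raise ValueError(f"group {g!r} is empty")
        maps = [
            window_mean_map(dataset.get(s, condition), dataset.times, window)
            for s in subjects
        ]
        means.append(np.mean(maps, axis=0))
    template = average_reference(means[0] - means[1])
    return TemplateMap(template, (float(window[0]), float(window[1])), condition,
                       f"{ga}-{gb}")


def project_scores(dataset: ERPDataset, template: TemplateMap) -> pd.DataFrame:
    """Project each subject's window-averaged map onto the template.

    score_i = <window mean map of subject i (template's condition),
    template map>.  Returns a table indexed by subject with the score,
    group, and any clinical columns the dataset carries.
    """
    if np.linalg.norm(template.map) == 0:
        raise ValueError("template map is zero; no group difference to project onto")
    rows = {}
    for s in dataset.subjects:
        m = window_mean_map(dataset.get(s, template.condition), dataset.times,
                            template.window)
        rows[s] = float(m @ template.map)
    table = pd.DataFrame(
        {"erp_score": pd.Series(rows), "group": pd.Series(dataset.group_of)}
    )
    table.index.name = "subject_id"
    if dataset.clinical is not None:
        table = table.join(dataset.clinical, how="left")
    return table


def partial_correlation(
    x: np.ndarray, y: np.ndarray, z: np.ndarray
) -> PartialCorrelationResult:
    """Pearson partial correlation of x and y controlling z.

    Uses the closed form on the pairwise correlations; significance by
    t = r sqrt((n-3)/(1-r^2)) on n-3 df, two-tailed; 95% CI by Fisher z
    with SE = 1/sqrt(n-4).
    """
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    n = len(x)
    if not (len(y) == len(z) == n):
        raise ValueError("x, y, z must have equal length")
    if n < 4:
        raise ValueError("partial correlation needs n >= 4")
    for name, v in (("x", x), ("y", y), ("z", z)):
        if np.std(v) == 0:
            raise ValueError(f"{name} has zero variance")
    rxy = _pearson(x, y)
    rxz = _pearson(x, z)
    ryz = _pearson(y, z)
    denom = np.sqrt((1 - rxz**2) * (1 - ryz**2))
    if denom == 0:
        raise ValueError("covariate is collinear with x or y")
    r = float((rxy - rxz * ryz) / denom)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 3) / (1 - r**2))
        p = float(2 * stats.t.sf(abs(t), df=n - 3))
    if n > 4 and abs(r) < 1.0:
        zr = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 4)
        half = stats.norm.ppf(0.975) * se
        ci = (float(np.tanh(zr - half)), float(np.tanh(zr + half)))
    else:
        ci = (r, r)
    return PartialCorrelationResult(r, p, ci, n)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def score_correlations(
    scores: pd.DataFrame,
    clinical_col: str = "anticipatory",
    covariate_col: str = "covariate",
) -> PartialCorrelationResult:
    """Partial correlation of ERP scores with a clinical score.

    Computed on the whole sample (both groups pooled), adjusting for the
    covariate column; rows with missing values are dropped.
    """
    cols = ["erp_score", clinical_col, covariate_col]
    sub = scores[cols].dropna()
    return partial_correlation(
        sub["erp_score"].to_numpy(),
        sub[clinical_col].to_numpy(),
        sub[covariate_col].to_numpy(),
    )
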