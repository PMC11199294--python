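"""Configuration-driven orchestration of the full microstate analysis.

Stages, in order: load or simulate the dataset; topographic consistency
testing to fix the analysis window; cross-validation of the microstate
class count; modified k-means clustering of the concatenated cell grand
means; backfitting and per-appearance feature extraction; randomization
tests of group, condition and interaction effects; ERP-score projection
and partial correlation with clinical scores.  Every stage writes its
artifact (delimited text) to the output directory before the next stage
starts, and all stage seeds are derived from one master seed by a
stable, stage-name-keyed scheme, so identical configurations reproduce
identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import erpscore as es
from .datasets import ERPDataset, read_manifest_dataset, write_manifest_dataset
from .erp import dataset_tct, grand_mean
from .microstates import (
    MicrostateFeatures,
    backfit,
    cross_validate_k,
    extract_features,
    fit_microstates,
)
from .randstats import class_analysis_window, interaction_test, main_effect_test, results_table
from .simulate import (
    GroundTruth,
    default_timeline,
    make_layout,
    make_templates,
    simulate_clinical_scores,
    simulate_erp_dataset,
)

log = logging.getLogger("midstates.pipeline")


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a stage seed from the master seed, keyed by stage name.

    Stable under pipeline evolution: adding a stage never reshuffles the
    seeds of existing stages.  Always below 2**31.
    """
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclasses.dataclass
class PipelineConfig:
    """Resolved configuration of one analysis run."""

    # dataset source: a manifest directory, or simulation parameters
    manifest: str | None = None
    simulate: dict[str, Any] | None = None
    epoch_window_ms: tuple[float, float] = (-500.0, 1000.0)
    filter_band_hz: tuple[float, float] = (1.0, 15.0)
    tct_n_rand: int = 1000
    tct_alpha: float = 0.05
    k_range: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    cv_splits: int = 5
    cv_epsilon: float = 0.01
    k_override: int | None = None
    n_restarts: int = 20
    polarity_sensitive: bool = True
    analysis_windows: dict[int, tuple[float, float]] | None = None
    features: tuple[str, ...] = MicrostateFeatures.FEATURE_NAMES
    test_effects: tuple[str, ...] = ("interaction", "group", "condition")
    test_n_rand: int = 5000
    test_alpha: float = 0.05
    score_specs: list[tuple[int, str]] | None = None
    seed: int = 0
    outdir: str = "midstates_run"
    write_dataset: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("epoch_window_ms", "filter_band_hz", "k_range", "features",
                    "test_effects"):
            d[key] = list(d[key])
        return d


@dataclasses.dataclass
class RunReport:
    """Everything a finished run computed, plus where it was written."""

    config: PipelineConfig
    outdir: Path
    tct_window: tuple[float, float] | None
    selected_k: int
    cv_curve: pd.DataFrame | None
    train_explained_variance: float
    class_windows: dict[int, tuple[float, float]]
    features: pd.DataFrame
    tests: pd.DataFrame
    scores: dict[tuple[int, str], pd.DataFrame]
    correlations: pd.DataFrame
    stage_log: list[dict]

    def summary(self) -> str:
        lines = [
            "Microstate pipeline report",
            f"  output:           {self.outdir}",
            f"  consistency window: {self.tct_window}",
            f"  classes (k):      {self.selected_k}",
            f"  train expl. var.: {100 * self.train_explained_variance:.1f}%",
            f"  feature rows:     {len(self.features)}",
            f"  tests run:        {len(self.tests)} (no multiplicity adjustment)",
        ]
        if len(self.correlations):
            for _, row in self.correlations.iterrows():
                lines.append(
                    f"  class {row['class']} {row.condition}: partial r = "
                    f"{row.r:.3f} (p = {row.p:.3g})"
                )
        return "\n".join(lines)


def _log_stage(stage_log: list[dict], name: str, t0: float, **params):
    entry = {"stage": name, "wall_s": round(time.time() - t0, 3), **params}
    stage_log.append(entry)
    log.info("stage %s done in %.2fs %s", name, entry["wall_s"], params)


def _build_dataset(config: PipelineConfig) -> tuple[ERPDataset, GroundTruth | None]:
    if (config.manifest is None) == (config.simulate is None):
        raise ValueError("config must set exactly one of manifest / simulate")
    if config.manifest is not None:
        return read_manifest_dataset(config.manifest), None
    sim = dict(config.simulate)
    seed = stage_seed(config.seed, "simulate")
    n_channels = int(sim.get("n_channels", 30))
    fs = float(sim.get("fs", 256.0))
    n_per_group = tuple(sim.get("n_per_group", (30, 23)))
    groups = tuple(sim.get("groups", ("patient", "control")))
    k = int(sim.get("k", 4))
    layout = make_layout(n_channels, seed=seed)
    templates = make_templates(k, layout, seed=seed + 1)
    timeline = sim.get("timeline")
    if timeline is None:
        timeline = default_timeline(groups=groups)
    else:
        timeline = {
            (g, c): [tuple(s) for s in segs]
            for (g, c), segs in timeline.items()
        }
    truth = GroundTruth(
        templates,
        timeline,
        noise_sd=float(sim.get("noise_sd", 1.0)),
        subject_onset_jitter_ms=float(sim.get("subject_onset_jitter_ms", 10.0)),
        subject_log_amp_sd=float(sim.get("subject_log_amp_sd", 0.1)),
        clinical_beta=float(sim.get("clinical_beta", 0.0)),
        clinical_noise_sd=float(sim.get("clinical_noise_sd", 1.0)),
        clinical_target=sim.get("clinical_target"),
    )
    dataset = simulate_erp_dataset(
        truth,
        n_per_group=n_per_group,
        layout=layout,
        fs=fs,
        epoch_window_ms=tuple(config.epoch_window_ms),
        seed=seed + 2,
        groups=groups,
    )
    if sim.get("clinical", True):
        simulate_clinical_scores(dataset, truth, seed=seed + 3)
    return dataset, truth


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage of the analysis and write all artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_log: list[dict] = []
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)

    t0 = time.time()
    dataset, truth = _build_dataset(config)
    if config.write_dataset and config.simulate is not None:
        write_manifest_dataset(dataset, outdir / "dataset")
    _log_stage(stage_log, "dataset", t0, n_subjects=len(dataset.subjects))

    # --- topographic consistency window
    t0 = time.time()
    tct = dataset_tct(
        dataset,
        n_rand=config.tct_n_rand,
        alpha=config.tct_alpha,
        seed=stage_seed(config.seed, "tct"),
    )
    tct.to_frame().to_csv(outdir / "tct.tsv", sep="\t", index=False)
    if tct.window is None:
        raise RuntimeError("stage tct: no topographically consistent time window")
    window = tct.window
    _log_stage(stage_log, "tct", t0, window=list(window))

    # --- concatenated grand means over the retained window
    mask = dataset.time_mask(*window)
    times_win = dataset.times[mask]

    def builder(subjects: Sequence[str]) -> np.ndarray:
        maps = []
        for g in dataset.groups:
            members = [s for s in subjects if dataset.group_of[s] == g]
            if not members:
                continue
            for c in dataset.conditions:
                gm = np.mean([dataset.get(s, c)[:, mask] for s in members], axis=0)
                maps.append(gm.T)  # time points as rows
        return np.concatenate(maps, axis=0)

    # --- cross-validate the class count
    t0 = time.time()
    cv_frame = None
    if config.k_override is not None and len(config.k_range) <= 1:
        selected_k = config.k_override
    else:
        cv = cross_validate_k(
            builder,
            dataset.subjects,
            config.k_range,
            n_splits=config.cv_splits,
            seed=stage_seed(config.seed, "cv"),
            epsilon=config.cv_epsilon,
            n_restarts=max(5, config.n_restarts // 2),
            polarity_sensitive=config.polarity_sensitive,
            groups_of=dataset.group_of,
        )
        cv_frame = pd.DataFrame({"k": cv.k_values, "test_ev": cv.test_ev})
        cv_frame.to_csv(outdir / "cv_curve.tsv", sep="\t", index=False)
        selected_k = config.k_override or cv.selected_k
    _log_stage(stage_log, "cross_validation", t0, selected_k=selected_k)

    # --- fit the microstate model on all cells' grand means
    t0 = time.time()
    model = fit_microstates(
        builder(dataset.subjects),
        selected_k,
        n_restarts=config.n_restarts,
        seed=stage_seed(config.seed, "fit"),
        polarity_sensitive=config.polarity_sensitive,
    )
    np.savetxt(
        outdir / "templates.tsv", model.templates, delimiter="\t", fmt="%.10g"
    )
    _log_stage(
        stage_log, "fit", t0, k=selected_k, train_ev=model.train_explained_variance
    )

    # --- backfit each cell; analysis window per class = union over cells
    # of the class's longest appearance (isolates one appearance while
    # covering its between-cell variation)
    t0 = time.time()
    class_windows: dict[int, tuple[float, float]] = {}
    for class_id in range(1, model.k + 1):
        if config.analysis_windows and class_id in config.analysis_windows:
            class_windows[class_id] = tuple(config.analysis_windows[class_id])
            continue
        cw = class_analysis_window(dataset, model, class_id, window=window)
        if cw is not None:
            class_windows[class_id] = cw

    feat_rows = []
    for g in dataset.groups:
        for c in dataset.conditions:
            seg = backfit(model, grand_mean(dataset, g, c)[:, mask], times_win)
            pd.DataFrame(
                {
                    "time_ms": seg.times_ms,
                    "label": seg.labels,
                    "ev_uv2": seg.ev_curve,
                    "gfp_uv": seg.gfp_curve,
                }
            ).to_csv(outdir / f"segmentation_{g}_{c}.tsv", sep="\t", index=False)
            for class_id, cw in class_windows.items():
                f = extract_features(seg, class_id, cw, check_contiguous=False)
                row = {
                    "group": g,
                    "condition": c,
                    "class": class_id,
                    "window_start_ms": cw[0],
                    "window_end_ms": cw[1],
                }
                if f is None:
                    row["absent"] = True
                else:
                    row["absent"] = False
                    row.update({name: f.value(name) for name in f.FEATURE_NAMES})
                feat_rows.append(row)
    features = pd.DataFrame(feat_rows)
    features.to_csv(outdir / "features.tsv", sep="\t", index=False)
    _log_stage(stage_log, "features", t0, n_rows=len(features))

    # --- randomization tests
    t0 = time.time()
    results = []
    test_seed = stage_seed(config.seed, "tests")
    for class_id, cw in class_windows.items():
        present = features[(features["class"] == class_id) & ~features.absent]
        if len(present) < 6:
            continue  # class absent from some cell: no factorial table
        for fi, feature in enumerate(config.features):
            for i, effect in enumerate(config.test_effects):
                s = (test_seed + 7919 * class_id + 101 * i + 13 * fi) % 2**31
                if effect == "interaction":
                    r = interaction_test(
                        dataset, model, class_id, cw, feature,
                        n_rand=config.test_n_rand, seed=s,
                    )
                else:
                    r = main_effect_test(
                        dataset, model, class_id, cw, feature, effect,
                        n_rand=config.test_n_rand, seed=s,
                    )
                results.append(r)
    tests = results_table(results) if results else pd.DataFrame(
        columns=["effect", "feature", "class", "p"]
    )
    tests.to_csv(outdir / "tests.tsv", sep="\t", index=False)
    _log_stage(stage_log, "tests", t0, n_tests=len(tests))

    # --- ERP scores and clinical correlations
    t0 = time.time()
    score_specs = config.score_specs
    if score_specs is None:
        score_specs = []
        if len(tests):
            sig = tests[(tests.effect == "interaction") & (tests.p <= config.test_alpha)]
            for class_id in sorted(sig["class"].unique()):
                for cond in dataset.conditions:
                    score_specs.append((int(class_id), cond))
    scores: dict[tuple[int, str], pd.DataFrame] = {}
    corr_rows = []
    for class_id, cond in score_specs:
        if class_id not in class_windows:
            continue
        template = es.compute_template(dataset, class_windows[class_id], cond)
        table = es.project_scores(dataset, template)
        table.to_csv(outdir / f"scores_class{class_id}_{cond}.tsv", sep="\t")
        scores[(class_id, cond)] = table
        if dataset.clinical is not None:
            pc = es.score_correlations(table)
            corr_rows.append(
                {
                    "class": class_id,
                    "condition": cond,
                    "window_start_ms": class_windows[class_id][0],
                    "window_end_ms": class_windows[class_id][1],
                    "r": pc.r,
                    "p": pc.p,
                    "ci_low": pc.ci95[0],
                    "ci_high": pc.ci95[1],
                    "n": pc.n,
                }
            )
    correlations = pd.DataFrame(corr_rows)
    correlations.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
    _log_stage(stage_log, "scores", t0, n_specs=len(score_specs))

    report = RunReport(
        config=config,
        outdir=outdir,
        tct_window=window,
        selected_k=selected_k,
        cv_curve=cv_frame,
        train_explained_variance=model.train_explained_variance,
        class_windows=class_windows,
        features=features,
        tests=tests,
        scores=scores,
        correlations=correlations,
        stage_log=stage_log,
    )
    with open(outdir / "report.json", "w") as fh:
        json.dump(
            {
                "tct_window": list(window),
                "selected_k": selected_k,
                "train_explained_variance": model.train_explained_variance,
                "class_windows": {str(k): list(v) for k, v in class_windows.items()},
                "stage_log": stage_log,
                "seed": config.seed,
            },
            fh,
            indent=2,
        )
    return report


# ---------------------------------------------------------------------------
# report rendering


def render_report(outdir: str | Path) -> list[Path]:
    """Regenerate the report figures from a run's saved artifacts alone.

    Produces a GFP curve with microstate color bands per cell, a bar
    chart of each feature per cell, and score scatter plots where score
    tables exist.  Returns the written figure paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    missing = [f for f in ("features.tsv", "tests.tsv") if not (outdir / f).exists()]
    seg_files = sorted(outdir.glob("segmentation_*.tsv"))
    if not seg_files:
        missing.append("segmentation_*.tsv")
    if missing:
        raise FileNotFoundError(f"missing artifacts in {outdir}: {missing}")
    written = []

    features = pd.read_csv(outdir / "features.tsv", sep="\t")
    classes = sorted(features["class"].unique())
    cmap = plt.get_cmap("tab10")
    colors = {c: cmap((c - 1) % 10) for c in classes}

    fig, axes = plt.subplots(
        len(seg_files), 1, figsize=(8, 1.8 * len(seg_files)), sharex=True, squeeze=False
    )
    for ax, f in zip(axes.ravel(), seg_files):
        seg = pd.read_csv(f, sep="\t")
        ax.plot(seg.time_ms, seg.gfp_uv, color="k", lw=1)
        for c in classes:
            m = seg.label == c
            ax.fill_between(
                seg.time_ms, 0, seg.gfp_uv, where=m, color=colors[c], alpha=0.5,
                label=f"class {c}",
            )
        ax.set_ylabel("GFP (µV)")
        ax.set_title(f.stem.replace("segmentation_", ""), fontsize=9)
    axes.ravel()[-1].set_xlabel("time (ms)")
    handles = [plt.Rectangle((0, 0), 1, 1, color=colors[c]) for c in classes]
    fig.legend(handles, [f"class {c}" for c in classes], loc="upper right", fontsize=8)
    fig.tight_layout()
    p = outdir / "fig_gfp_segments.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    present = features[~features.absent] if "absent" in features else features
    feat_names = [c for c in MicrostateFeatures.FEATURE_NAMES if c in present]
    if len(present):
        fig, axes = plt.subplots(
            len(feat_names), 1, figsize=(7, 2.0 * len(feat_names)), squeeze=False
        )
        for ax, name in zip(axes.ravel(), feat_names):
            piv = present.pivot_table(
                index=["group", "condition"], columns="class", values=name
            )
            piv.plot.bar(ax=ax, color=[colors[c] for c in piv.columns], legend=False)
            ax.set_ylabel(name)
            ax.tick_params(axis="x", labelsize=7, rotation=30)
        fig.tight_layout()
        p = outdir / "fig_features.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    for f in sorted(outdir.glob("scores_*.tsv")):
        table = pd.read_csv(f, sep="\t", index_col=0)
        if "anticipatory" not in table:
            continue
        fig, ax = plt.subplots(figsize=(5, 4))
        for g, sub in table.groupby("group"):
            ax.scatter(sub.erp_score, sub.anticipatory, label=g, s=18)
        b, a = np.polyfit(table.erp_score, table.anticipatory, 1)
        xs = np.linspace(table.erp_score.min(), table.erp_score.max(), 50)
        ax.plot(xs, a + b * xs, "k-", lw=1)
        ax.set_xlabel("ERP score (µV²)")
        ax.set_ylabel("anticipatory score")
        ax.legend(fontsize=8)
        fig.tight_layout()
        p = outdir / (f.stem + ".png")
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
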