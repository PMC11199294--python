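"""Simulation studies of the randomization machinery.

Reusable simulation harnesses, each run at a desk scale chosen to keep a
full study within minutes on one core while leaving the statistical
question intact (the scales are documented in the methods note):

* :func:`null_rejection_rate` — simulate datasets with identical
  generative parameters in every group x condition cell and measure how
  often the group x condition interaction test rejects at 0.05.  A
  calibrated test rejects at the nominal rate.
* :func:`crossover_power` — plant a ±40 ms duration crossover (a class
  lasts longer in reward than neutral for one group, shorter for the
  other) and measure the interaction test's rejection rate.
* :func:`erpscore_chain` — plant a negative correlation between the
  anticipatory-pleasure score and a group-differing microstate
  amplitude, run the full template-projection scoring chain, and check
  the recovered partial correlation's sign.
* :func:`cv_plateau_study` — how often held-out explained variance
  recovers a planted class count.

All randomness is driven by one master seed; replicate seeds are derived
deterministically and stay below 2**31.
"""

from __future__ import annotations

import numpy as np

from .erpscore import compute_template, project_scores, score_correlations
from .microstates import fit_microstates, match_templates
from .randstats import class_analysis_window, interaction_test
from .simulate import (
    GroundTruth,
    clinical_noise_for_rho,
    make_layout,
    make_templates,
    simulate_clinical_scores,
    simulate_erp_dataset,
)

GROUPS = ("patient", "control")
CONDITIONS = ("reward", "loss", "neutral")


def _timeline(boundaries: dict[tuple[str, str], tuple[float, ...]], amplitudes):
    out = {}
    for cell, bounds in boundaries.items():
        out[cell] = [
            (j + 1, bounds[j], bounds[j + 1], amplitudes[j])
            for j in range(len(bounds) - 1)
        ]
    return out


def _base_boundaries() -> tuple[float, ...]:
    return (0.0, 150.0, 350.0, 500.0)


def _concat_grand_means(dataset) -> np.ndarray:
    from .erp import grand_mean

    maps = []
    for g in dataset.groups:
        for c in dataset.conditions:
            maps.append(grand_mean(dataset, g, c).T)
    return np.concatenate(maps, axis=0)


def _simulate_cell_dataset(
    boundaries: dict[tuple[str, str], tuple[float, ...]],
    n_per_group: tuple[int, int],
    n_channels: int,
    fs: float,
    window: tuple[float, float],
    noise_sd: float,
    onset_jitter_ms: float,
    log_amp_sd: float,
    seed: int,
    amplitudes=(3.0, 3.5, 2.5),
):
    layout = make_layout(n_channels, seed=seed)
    templates = make_templates(3, layout, seed=seed + 1)
    truth = GroundTruth(
        templates,
        _timeline(boundaries, amplitudes),
        noise_sd=noise_sd,
        subject_onset_jitter_ms=onset_jitter_ms,
        subject_log_amp_sd=log_amp_sd,
    )
    dataset = simulate_erp_dataset(
        truth, n_per_group, layout, fs=fs, epoch_window_ms=window,
        seed=seed + 2, groups=GROUPS,
    )
    return dataset, truth


def _wilson_ci(k: int, n: int, z: float = 1.959964) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return center - half, center + half


def _rep_seed(master: int, rep: int) -> int:
    return (master * 100003 + rep * 7919 + 17) % (2**31)


def null_rejection_rate(
    n_datasets: int = 200,
    n_rand: int = 500,
    n_per_group: int = 12,
    n_channels: int = 20,
    n_times: int = 100,
    noise_sd: float = 1.0,
    onset_jitter_ms: float = 10.0,
    log_amp_sd: float = 0.1,
    feature: str = "duration",
    class_id: int = 2,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Rejection rate of the interaction test on null datasets.

    Every cell of every dataset shares one generative timeline (three
    sequential microstate classes over 0-500 ms), so any rejection is a
    false positive.  Per dataset, templates are fit to the observed
    concatenated grand means (as in the pipeline) and held fixed during
    the randomization test on the middle class's ``feature``.
    """
    fs = n_times / 0.5  # n_times samples spanning the 0-500 ms timeline
    window = (0.0, 500.0)
    bounds = _base_boundaries()
    boundaries = {(g, c): bounds for g in GROUPS for c in CONDITIONS}
    n_reject = 0
    pvals = np.empty(n_datasets)
    for rep in range(n_datasets):
        s = _rep_seed(seed, rep)
        dataset, truth = _simulate_cell_dataset(
            boundaries, (n_per_group, n_per_group), n_channels, fs, window,
            noise_sd, onset_jitter_ms, log_amp_sd, s,
        )
        model = match_templates(
            fit_microstates(_concat_grand_means(dataset), 3, n_restarts=5, seed=s + 3),
            truth.templates,
        )
        cw = class_analysis_window(dataset, model, class_id)
        res = interaction_test(
            dataset, model, class_id, cw, feature, n_rand=n_rand, seed=s + 4
        )
        pvals[rep] = res.p
        if res.p <= alpha:
            n_reject += 1
    lo, hi = _wilson_ci(n_reject, n_datasets)
    return {
        "n_datasets": n_datasets,
        "n_rand": n_rand,
        "n_reject": n_reject,
        "rate": n_reject / n_datasets,
        "ci_low": lo,
        "ci_high": hi,
        "alpha": alpha,
        "p_values": pvals.tolist(),
    }


def crossover_power(
    n_replicates: int = 100,
    delta_ms: float = 40.0,
    n_rand: int = 500,
    n_per_group: tuple[int, int] = (30, 23),
    n_channels: int = 20,
    n_times: int = 100,
    noise_sd: float = 1.0,
    onset_jitter_ms: float = 10.0,
    log_amp_sd: float = 0.1,
    feature: str = "duration",
    class_id: int = 2,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Interaction-test power against a planted duration crossover.

    The middle class lasts ``delta_ms`` longer in reward than neutral
    for the first group and ``delta_ms`` shorter for the second (loss
    stays at baseline), the classic disordinal interaction, at the
    emulated study's group sizes (30 + 23).  The generative parameters
    otherwise match :func:`null_rejection_rate`.
    """
    fs = n_times / 0.5
    window = (0.0, 500.0)
    b = _base_boundaries()
    longer = (b[0], b[1], b[2] + delta_ms, b[3])
    shorter = (b[0], b[1], b[2] - delta_ms, b[3])
    boundaries = {(g, c): b for g in GROUPS for c in CONDITIONS}
    boundaries[(GROUPS[0], "reward")] = longer
    boundaries[(GROUPS[1], "reward")] = shorter
    n_reject = 0
    pvals = np.empty(n_replicates)
    for rep in range(n_replicates):
        s = _rep_seed(seed, rep)
        dataset, truth = _simulate_cell_dataset(
            boundaries, tuple(n_per_group), n_channels, fs, window,
            noise_sd, onset_jitter_ms, log_amp_sd, s,
        )
        model = match_templates(
            fit_microstates(_concat_grand_means(dataset), 3, n_restarts=5, seed=s + 3),
            truth.templates,
        )
        cw = class_analysis_window(dataset, model, class_id)
        res = interaction_test(
            dataset, model, class_id, cw, feature, n_rand=n_rand, seed=s + 4
        )
        pvals[rep] = res.p
        if res.p <= alpha:
            n_reject += 1
    lo, hi = _wilson_ci(n_reject, n_replicates)
    return {
        "n_replicates": n_replicates,
        "delta_ms": delta_ms,
        "n_reject": n_reject,
        "power": n_reject / n_replicates,
        "ci_low": lo,
        "ci_high": hi,
        "alpha": alpha,
        "p_values": pvals.tolist(),
    }


def erpscore_chain(
    n_replicates: int = 200,
    rho: float = -0.4,
    n_per_group: tuple[int, int] = (30, 23),
    n_channels: int = 20,
    n_times: int = 100,
    noise_sd: float = 1.0,
    log_amp_sd: float = 0.25,
    group_amp_uv: tuple[float, float] = (2.5, 3.5),
    seed: int = 0,
) -> dict:
    """Recovery of a planted clinical correlation through the score chain.

    The middle class's reward amplitude differs between groups
    (``group_amp_uv``) and varies across subjects; the
    anticipatory-pleasure score is generated from each subject's
    realized amplitude with noise calibrated so the planted correlation
    is ``rho``.  Per replicate the chain runs end to end: group
    difference template over the class window, dot-product projection,
    partial correlation with the anticipatory score controlling the
    independent covariate.  Reports the fraction of replicates with a
    negative partial r and mean recovered r.
    """
    fs = n_times / 0.5
    window = (0.0, 500.0)
    b = _base_boundaries()
    class_window = (b[1], b[2] - 1000.0 / fs)  # the middle class's samples
    rs = np.empty(n_replicates)
    amplitudes = (3.0, None, 2.5)  # middle amplitude set per group below
    for rep in range(n_replicates):
        s = _rep_seed(seed, rep)
        layout = make_layout(n_channels, seed=s)
        templates = make_templates(3, layout, seed=s + 1)
        timeline = {}
        for gi, g in enumerate(GROUPS):
            amps = (amplitudes[0], group_amp_uv[gi], amplitudes[2])
            for c in CONDITIONS:
                timeline[(g, c)] = [
                    (j + 1, b[j], b[j + 1], amps[j]) for j in range(3)
                ]
        truth = GroundTruth(
            templates,
            timeline,
            noise_sd=noise_sd,
            subject_log_amp_sd=log_amp_sd,
            clinical_beta=-1.0,
            clinical_target=("reward", 2),
        )
        dataset = simulate_erp_dataset(
            truth, n_per_group, layout, fs=fs, epoch_window_ms=window,
            seed=s + 2, groups=GROUPS,
        )
        amps = np.array([truth.subject_amplitudes[x] for x in dataset.subjects])
        truth.clinical_noise_sd = clinical_noise_for_rho(
            truth.clinical_beta, float(amps.std()), rho
        )
        simulate_clinical_scores(dataset, truth, seed=s + 3)
        template = compute_template(dataset, class_window, "reward",
                                    reference_group_order=("control", "patient"))
        scores = project_scores(dataset, template)
        rs[rep] = score_correlations(scores).r
    n_negative = int(np.sum(rs < 0))
    lo, hi = _wilson_ci(n_negative, n_replicates)
    return {
        "n_replicates": n_replicates,
        "rho_planted": rho,
        "n_negative": n_negative,
        "fraction_negative": n_negative / n_replicates,
        "ci_low": lo,
        "ci_high": hi,
        "mean_r": float(rs.mean()),
        "r_values": rs.tolist(),
    }


def cv_plateau_study(
    n_replicates: int = 50,
    k_planted: int = 3,
    k_range: tuple[int, ...] = (1, 2, 3, 4, 5),
    n_per_group: tuple[int, int] = (8, 8),
    n_channels: int = 20,
    n_times: int = 100,
    noise_sd: float = 0.3,
    epsilon: float = 0.01,
    n_splits: int = 3,
    seed: int = 0,
) -> dict:
    """How often cross-validation recovers the planted class count.

    High-SNR datasets with ``k_planted`` sequential classes; per
    replicate the held-out explained-variance curve is computed over
    ``k_range`` and the plateau rule (first test gain below ``epsilon``)
    picks k.  Reports the fraction of replicates selecting the truth.
    """
    from .microstates import cross_validate_k

    fs = n_times / 0.5
    window = (0.0, 500.0)
    bounds = _base_boundaries()
    boundaries = {(g, c): bounds for g in GROUPS for c in CONDITIONS}
    selections = []
    for rep in range(n_replicates):
        s = _rep_seed(seed, rep)
        dataset, _ = _simulate_cell_dataset(
            boundaries, n_per_group, n_channels, fs, window,
            noise_sd, 5.0, 0.05, s,
        )

        def builder(subjects):
            maps = []
            for g in dataset.groups:
                members = [x for x in subjects if dataset.group_of[x] == g]
                if not members:
                    continue
                for c in dataset.conditions:
                    maps.append(
                        np.mean([dataset.get(x, c) for x in members], axis=0).T
                    )
            return np.concatenate(maps, axis=0)

        cv = cross_validate_k(
            builder, dataset.subjects, k_range, n_splits=n_splits,
            seed=s + 5, epsilon=epsilon, n_restarts=8,
            groups_of=dataset.group_of,
        )
        selections.append(cv.selected_k)
    selections = np.asarray(selections)
    n_correct = int(np.sum(selections == k_planted))
    lo, hi = _wilson_ci(n_correct, n_replicates)
    return {
        "n_replicates": n_replicates,
        "k_planted": k_planted,
        "n_correct": n_correct,
        "fraction_correct": n_correct / n_replicates,
        "ci_low": lo,
        "ci_high": hi,
        "selections": selections.tolist(),
    }
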