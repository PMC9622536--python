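"""Canned simulation studies: parameter-recovery and calibration checks.

Each study generates synthetic experiments with known ground truth, runs
the corresponding analysis stage, and returns the recovered quantity next
to the injected one.  They are the package's evidence that the pipeline
measures what it claims to measure; the problem sizes default to values
that keep a full study in the minutes range on one CPU (see the methods
note for the rationale behind each configuration).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import decoding as dec
from .behavior import assign_parts
from .erp import peak_mean_amplitude, average_by_cell
from .preprocess import PreprocConfig, ocular_correct, preprocess_mvpa, \
    rereference_linked_mastoids
from .synthetic import (
    BlockSpec,
    ExperimentLayout,
    GroundTruth,
    _spread_subset,
    generate_experiment,
    half_cosine_bump,
)

#: quick RT regime for decoding studies: mean ~790 ms, tight spread, so
#: the pre-stimulus baseline window stays inside the epoch for nearly all
#: trials
_FAST_RT = {"correct": (6.67, 0.15), "error": (6.67, 0.15)}


# --------------------------------------------------------------------------
# ERP component recovery
# --------------------------------------------------------------------------
def bump_peak_mean(amplitude: float, window_ms: tuple[float, float],
                   times: np.ndarray, halfwidth: int = 2) -> float:
    """Closed-form expected peak-anchored mean of an injected half-cosine
    bump sampled on ``times``: the mean of the 2*halfwidth+1 samples
    centred on the sampled extremum."""
    b = amplitude * half_cosine_bump(np.asarray(times, float), window_ms)
    k = int(np.argmin(b)) if amplitude < 0 else int(np.argmax(b))
    return float(b[k - halfwidth:k + halfwidth + 1].mean())


@dataclass
class ComponentRecovery:
    measured_ne_diff: float
    expected_ne_diff: float
    measured_pe_diff: float
    expected_pe_diff: float


def component_recovery_run(
    seed: int,
    noise_sd: float = 5.0,
    trials_per_cell: int = 200,
    ne_amps: tuple[float, float] = (-8.0, -2.0),   # (error, correct)
    pe_amps: tuple[float, float] = (8.0, 2.0),
    n_scalp: int = 10,
) -> ComponentRecovery:
    """Recover injected error-vs-correct component amplitude differences
    from per-cell averages on the mastoid-referenced signal."""
    truth = GroundTruth.null(
        seed=seed, noise_sd=noise_sd, error_rate=0.5,
        ne_amp_by_celltype={"error": ne_amps[0], "correct": ne_amps[1]},
        pe_amp_by_celltype={"error": pe_amps[0], "correct": pe_amps[1]},
    )
    layout = ExperimentLayout(
        blocks=[BlockSpec("no_self_eval", 2 * trials_per_cell)],
        scalp_channels=_spread_subset(n_scalp),
        epoch_span_ms=(-200.0, 500.0),
    )
    epochs, table = generate_experiment(truth, layout)
    table = table.copy()
    table["cell"] = table["accuracy"]
    cells = average_by_cell(epochs, table, "cell")
    fcz = epochs.channel_index("FCz")
    cz = epochs.channel_index("Cz")
    ne = {c: peak_mean_amplitude(w[fcz], epochs.times, truth.ne_window_ms,
                                 "negative")[0] for c, (w, _) in cells.items()}
    pe = {c: peak_mean_amplitude(w[cz], epochs.times, truth.pe_window_ms,
                                 "positive")[0] for c, (w, _) in cells.items()}
    exp_ne = (bump_peak_mean(ne_amps[0], truth.ne_window_ms, epochs.times)
              - bump_peak_mean(ne_amps[1], truth.ne_window_ms, epochs.times))
    exp_pe = (bump_peak_mean(pe_amps[0], truth.pe_window_ms, epochs.times)
              - bump_peak_mean(pe_amps[1], truth.pe_window_ms, epochs.times))
    return ComponentRecovery(
        measured_ne_diff=ne["error"] - ne["correct"], expected_ne_diff=exp_ne,
        measured_pe_diff=pe["error"] - pe["correct"], expected_pe_diff=exp_pe,
    )


# --------------------------------------------------------------------------
# ocular-correction recovery
# --------------------------------------------------------------------------
@dataclass
class OcularRecovery:
    max_abs_coef_error: float
    max_blink_corr: float


def ocular_recovery_run(
    seed: int,
    b_range: tuple[float, float] = (0.05, 0.3),
    noise_sd: float = 5.0,
    blink_rate: float = 0.9,
    n_scalp: int = 12,
    n_trials: int = 144,
) -> OcularRecovery:
    """Inject blinks with known propagation coefficients, run the
    regression correction, and report the worst coefficient error and the
    worst residual EEG-vEOG correlation at planted-blink samples."""
    layout = ExperimentLayout(
        blocks=[BlockSpec("no_self_eval", n_trials)],
        scalp_channels=_spread_subset(n_scalp),
        epoch_span_ms=(-500.0, 500.0),
    )
    scalp = layout.scalp_channels
    prop = dict(zip(scalp, np.linspace(*b_range, len(scalp))))
    truth = GroundTruth.null(
        seed=seed, noise_sd=noise_sd, blink_rate=blink_rate,
        blink_propagation=prop,
    )
    epochs, _ = generate_experiment(truth, layout)
    epochs = rereference_linked_mastoids(epochs)
    corrected, coeffs = ocular_correct(epochs)
    err = max(abs(coeffs["vEOG"][c] - prop[c]) for c in scalp)

    veog = epochs.channel_index("vEOG")
    half = truth.blink_width_ms / 2 - 20.0
    idx = {t: i for i, t in enumerate(epochs.trial_ids)}
    worst = 0.0
    for ch in ("FCz", scalp[0], scalp[-1]):
        ci = epochs.channel_index(ch)
        eeg, eog = [], []
        for tid, centre in truth.record["blinks"]:
            i = idx[tid]
            m = epochs.time_mask(centre - half, centre + half)
            eeg.append(corrected.data[i, ci, m])
            eog.append(epochs.data[i, veog, m])
        r = np.corrcoef(np.concatenate(eeg), np.concatenate(eog))[0, 1]
        worst = max(worst, abs(float(r)))
    return OcularRecovery(max_abs_coef_error=float(err), max_blink_corr=worst)


# --------------------------------------------------------------------------
# decoding studies
# --------------------------------------------------------------------------
def _fast_decoding_config(analysis_window, seed):
    """Reduced cross-validation settings for simulation studies: 3 folds x
    1 repetition and 2 shuffled-label runs keep the accuracy and chance
    estimates unbiased while cutting classifier fits per window to 9."""
    return dec.DecodingConfig(
        analysis_window_ms=analysis_window, n_folds=3, n_repetitions=1,
        n_permutation_runs=2, seed=seed,
    )


def onset_recovery_run(
    onset_ms: float,
    base_seed: int,
    n_participants: int = 20,
    n_scalp: int = 8,
    trials_per_condition: int = 40,
    analysis_window: tuple[float, float] = (-650.0, -50.0),
    noise_sd: float = 5.0,
    pattern_amp: float = 8.0,
) -> float:
    """Recover the onset of the injected condition-specific pattern as the
    start of the first Bonferroni-significant decoding window.

    One cohort of synthetic participants, full stimulus-baselined MVPA
    preprocessing, condition contrast.  Returns the recovered onset in ms
    (nan when no window reaches significance).
    """
    layout = ExperimentLayout(
        blocks=[BlockSpec("no_self_eval", trials_per_condition),
                BlockSpec("self_eval", trials_per_condition)],
        scalp_channels=_spread_subset(n_scalp),
        epoch_span_ms=(-1150.0, 50.0),
    )
    truth0 = GroundTruth.null(
        seed=0, noise_sd=noise_sd, cond_pattern_amp=pattern_amp,
        cond_pattern_onset_ms=onset_ms, rt_params=_FAST_RT,
    )
    pcfg = PreprocConfig(mvpa_window_ms=analysis_window)
    results = []
    for i in range(n_participants):
        t = dataclasses.replace(truth0, seed=base_seed * 1009 + i, record={})
        epochs, table = generate_experiment(t, layout, participant_id=f"P{i:02d}")
        mv = preprocess_mvpa(epochs, table, pcfg)
        cfg = _fast_decoding_config(analysis_window, base_seed * 1009 + i)
        r = dec.first_level(mv, table,
                            dec.Contrast("condition", "no_self_eval", "self_eval"),
                            cfg)
        if r is not None:
            results.append(r)
    second = dec.second_level(results)
    return dec.first_significant_onset(second)


def type_one_null_run(
    sim_seed: int,
    n_participants: int = 20,
    n_scalp: int = 4,
    trials_per_condition: int = 26,
    analysis_window: tuple[float, float] = (-120.0, -40.0),
    noise_sd: float = 5.0,
) -> bool:
    """One null simulation: no injected effects anywhere; returns whether
    any window survives Bonferroni at the second level.

    Epochs are decoded raw (noise only) — the quantity under test is the
    calibration of the decoding + inference machinery itself.
    """
    layout = ExperimentLayout(
        blocks=[BlockSpec("no_self_eval", trials_per_condition),
                BlockSpec("self_eval", trials_per_condition)],
        scalp_channels=_spread_subset(n_scalp),
        epoch_span_ms=(-120.0, 0.0),
    )
    truth0 = GroundTruth.null(seed=0, noise_sd=noise_sd)
    results = []
    for i in range(n_participants):
        t = dataclasses.replace(truth0, seed=sim_seed * 1013 + i, record={})
        epochs, table = generate_experiment(t, layout, participant_id=f"P{i:02d}")
        cfg = _fast_decoding_config(analysis_window, sim_seed * 1013 + i)
        r = dec.first_level(epochs, table,
                            dec.Contrast("condition", "no_self_eval", "self_eval"),
                            cfg)
        results.append(r)
    second = dec.second_level(results)
    return bool(second["significant"].any())


def decoding_group_run(
    base_seed: int,
    n_participants: int = 10,
    n_scalp: int = 10,
    trials_per_block: int = 12,
    cond_pattern_amp: float = 2.6,
    drift_rate: float = 1.4,
    noise_sd: float = 5.0,
    analysis_window: tuple[float, float] = (-300.0, 100.0),
) -> pd.DataFrame:
    """Part-split decoding-group study on a scaled-down session with the
    full 7 + 11 block geometry; returns the per-group mean scores.

    With a condition pattern and a time-on-task drift both present, the
    group means should reproduce the distance-plus-condition ordering:
    the most distant cross-condition pair scores highest, cross pairs
    beat the equally distant within-condition pairs.
    """
    layout = ExperimentLayout(
        blocks=[BlockSpec("no_self_eval", max(2, trials_per_block // 2), practice=True)] * 2
        + [BlockSpec("no_self_eval", trials_per_block)] * 5
        + [BlockSpec("self_eval", trials_per_block)] * 11,
        scalp_channels=_spread_subset(n_scalp),
        epoch_span_ms=(-1150.0, 150.0),
    )
    truth0 = GroundTruth.null(
        seed=0, noise_sd=noise_sd, cond_pattern_amp=cond_pattern_amp,
        cond_pattern_onset_ms=-550.0, drift_rate=drift_rate, rt_params=_FAST_RT,
    )
    pcfg = PreprocConfig(mvpa_window_ms=analysis_window)
    res: dict[str, dict[str, dec.DecodingResult]] = {}
    for i in range(n_participants):
        t = dataclasses.replace(truth0, seed=base_seed * 1019 + i, record={})
        epochs, table = generate_experiment(t, layout, participant_id=f"P{i:02d}")
        table = table.copy()
        table["part"] = assign_parts(table)
        mv = preprocess_mvpa(epochs, table, pcfg)
        cfg = _fast_decoding_config(analysis_window, base_seed * 1019 + i)
        res[f"P{i:02d}"] = {
            f"{a}v{b}": dec.first_level(mv, table, dec.part_contrast(a, b), cfg)
            for a, b in dec.PART_CONTRASTS
        }
    scores = dec.decoding_group_scores(res)
    return scores.groupby("group")["score"].mean().to_frame().reset_index()


def group_ordering_holds(group_means: pd.DataFrame) -> bool:
    """The distance-plus-condition ordering: largest-distance cross pair on top,
    medium-distance cross pairs next, the small-distance cross pair above
    both within-condition pairs."""
    m = group_means.set_index("group")["score"]
    return bool(
        m["1.1v2.2"] > max(m["1.1v2.1"], m["1.2v2.2"])
        and min(m["1.1v2.1"], m["1.2v2.2"]) > m["1.2v2.1"]
        and m["1.2v2.1"] > max(m["1.1v1.2"], m["2.1v2.2"])
    )
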