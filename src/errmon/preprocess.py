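"""Preprocessing chain for response-locked epochs.

Fixed stage order, recorded in the epoch history:

    re-reference (linked mastoids) -> crop/baseline -> ocular correction
    -> artifact rejection -> CSD

No spectral filtering is applied anywhere in the chain: high- or low-pass
filters smear component latencies and attenuate amplitudes, so the only
temporal operations are cropping and per-trial baseline subtraction.
Re-running a stage that is already applied is a logged no-op.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import csd as _csd
from .containers import EpochSet, align
from .montage import EOG, MASTOIDS


@dataclass
class PreprocConfig:
    """Windows, thresholds and CSD settings of the preprocessing chain.

    ``erp_window_ms`` and ``erp_baseline_ms`` are relative to the response;
    ``mvpa_baseline_ms`` is relative to the stimulus.  ``reject_uv`` is the
    absolute single-sample threshold on scalp channels.
    """

    erp_window_ms: tuple[float, float] = (-100.0, 800.0)
    mvpa_window_ms: tuple[float, float] = (-900.0, 200.0)
    erp_baseline_ms: tuple[float, float] = (-100.0, 0.0)
    mvpa_baseline_ms: tuple[float, float] = (-100.0, 0.0)   # pre-stimulus
    reject_uv: float = 100.0
    csd_m: int = 4
    csd_lambda: float = 1e-5
    csd_legendre_terms: int = 50
    apply_csd_for_mvpa: bool = False

    def __post_init__(self):
        for w in (self.erp_window_ms, self.mvpa_window_ms,
                  self.erp_baseline_ms, self.mvpa_baseline_ms):
            if w[1] <= w[0]:
                raise ValueError(f"empty window {w}")
        if self.reject_uv <= 0:
            raise ValueError("rejection threshold must be positive")
        if self.csd_m < 2 or self.csd_lambda < 0:
            raise ValueError("require m >= 2 and lambda >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PreprocConfig":
        import yaml

        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        for k, v in raw.items():
            if isinstance(v, list):
                raw[k] = tuple(v)
        return cls(**raw)


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------
def rereference_linked_mastoids(epochs: EpochSet) -> EpochSet:
    """Subtract the mean of M1/M2 from every scalp channel.

    EOG channels are bipolar and stay untouched.  Guarded by the
    reference flag: calling this on already linked-mastoid data is a
    warning no-op, never a second subtraction.
    """
    if epochs.reference == "linked_mastoid":
        warnings.warn("epochs already linked-mastoid referenced; no-op")
        return epochs.copy()
    if epochs.reference == "csd":
        raise ValueError("cannot re-reference CSD-transformed data")
    for ch in MASTOIDS:
        if ch not in epochs.channels:
            raise ValueError(f"mastoid channel {ch!r} missing")
    m = np.mean(
        [epochs.data[:, epochs.channel_index(c), :] for c in MASTOIDS], axis=0
    )
    out = epochs.copy(reference="linked_mastoid")
    targets = [i for i, c in enumerate(epochs.channels) if c not in EOG]
    out.data[:, targets, :] -= m[:, None, :].astype(out.data.dtype)
    out.log("re-referenced to linked mastoids")
    return out


def baseline_correct(
    epochs: EpochSet,
    interval_ms: tuple[float, float],
    lock: str = "response",
    table: pd.DataFrame | None = None,
) -> EpochSet:
    """Per-trial, per-channel mean subtraction over a baseline interval.

    ``lock="response"``: one interval for all trials, relative to the
    response.  ``lock="stimulus"``: the interval is relative to each
    trial's stimulus onset (``stimulus_onset_ms`` from the trial table),
    so the absolute window differs per trial.  Trials whose baseline
    window is not fully inside the epoch are dropped and logged.
    """
    if epochs.baseline_interval is not None:
        warnings.warn("epochs already baseline-corrected; no-op")
        return epochs.copy()
    if lock not in ("response", "stimulus"):
        raise ValueError(f"unknown lock {lock!r}")
    t0, t1 = interval_ms
    out = epochs.copy()
    if lock == "response":
        m = epochs.time_mask(t0, t1)
        if not m.any() or t0 < epochs.times[0] - 1e-9 or t1 > epochs.times[-1] + 1e-9:
            raise ValueError(f"baseline interval {interval_ms} outside epoch")
        out.data -= out.data[:, :, m].mean(axis=2, keepdims=True).astype(out.data.dtype)
        keep = np.ones(epochs.n_trials, bool)
    else:
        if table is None:
            raise ValueError("stimulus-locked baseline needs the trial table")
        tab = align(epochs, table)
        onsets = tab["stimulus_onset_ms"].to_numpy(float)
        keep = np.ones(epochs.n_trials, bool)
        for i, s in enumerate(onsets):
            lo, hi = s + t0, s + t1
            if lo < epochs.times[0] - 1e-9 or hi > epochs.times[-1] + 1e-9:
                keep[i] = False
                continue
            m = epochs.time_mask(lo, hi)
            out.data[i] -= out.data[i][:, m].mean(axis=1, keepdims=True).astype(out.data.dtype)
        n_drop = int((~keep).sum())
        if n_drop:
            out.log(f"baseline: dropped {n_drop} trials with out-of-epoch "
                    f"stimulus-locked baseline")
        out.data = out.data[keep]
        out.trial_ids = out.trial_ids[keep]
    out.baseline_interval = (t0, t1)
    out.log(f"baseline {interval_ms} ms, {lock}-locked")
    return out


def ocular_correct(
    epochs: EpochSet,
) -> tuple[EpochSet, dict[str, dict[str, float]]]:
    """Regression-based blink correction (average-subtraction variant).

    The event-related average is first subtracted from both EEG and EOG
    single trials; propagation coefficients are then estimated by least
    squares of the EEG residuals on the two EOG residuals, pooled over
    trials and samples, and the scaled raw EOG is subtracted from the raw
    EEG.  Returns the corrected epochs and the per-channel coefficients
    ``{eog_channel: {eeg_channel: b}}``.
    """
    for ch in EOG:
        if ch not in epochs.channels:
            raise ValueError(f"EOG channel {ch!r} missing")
    if any(h.startswith("ocular") for h in epochs.history):
        warnings.warn("ocular correction already applied; no-op")
        return epochs.copy(), {e: {} for e in EOG}
    eog_idx = [epochs.channel_index(c) for c in EOG]
    targets = [i for i, c in enumerate(epochs.channels) if c not in EOG]

    data = epochs.data.astype(float, copy=False)
    erp = data.mean(axis=0, keepdims=True)
    resid = data - erp
    X = resid[:, eog_idx, :].transpose(1, 0, 2).reshape(len(eog_idx), -1).T
    Y = resid[:, targets, :].transpose(1, 0, 2).reshape(len(targets), -1).T

    var = X.var(axis=0)
    dead = var < 1e-12
    if dead.any():
        warnings.warn("zero-variance EOG channel; its coefficients set to 0")
        X = X[:, ~dead]
    if X.shape[1] == 0:
        B = np.zeros((len(eog_idx), len(targets)))
    else:
        b, *_ = np.linalg.lstsq(X, Y, rcond=None)
        B = np.zeros((len(eog_idx), len(targets)))
        B[~dead] = b

    out = epochs.copy()
    corr = np.einsum("et,nes->nts", B, data[:, eog_idx, :])
    out.data[:, targets, :] -= corr.astype(out.data.dtype)
    out.log("ocular correction (average-subtracted EOG regression)")
    coeffs = {
        eog: {epochs.channels[t]: float(B[e, j]) for j, t in enumerate(targets)}
        for e, eog in enumerate(EOG)
    }
    return out, coeffs


def reject_artifacts(
    epochs: EpochSet, threshold_uv: float = 100.0
) -> tuple[EpochSet, np.ndarray]:
    """Drop trials where any scalp channel exceeds ±threshold at any sample.

    The comparison is strict (a sample at exactly the threshold
    survives); EOG channels are not consulted.  Returns the surviving
    epochs and the rejected trial ids.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    picks = epochs.scalp_picks()
    bad = np.any(np.abs(epochs.data[:, picks, :]) > threshold_uv, axis=(1, 2))
    if bad.all():
        raise ValueError(
            f"all {epochs.n_trials} trials exceed ±{threshold_uv} µV; "
            "nothing left to analyse"
        )
    out = epochs.copy()
    out.data = out.data[~bad]
    out.trial_ids = out.trial_ids[~bad]
    frac = 100.0 * bad.mean()
    out.log(f"artifact rejection ±{threshold_uv} µV: removed {bad.sum()} "
            f"trials ({frac:.1f}%)")
    return out, epochs.trial_ids[bad]


def csd_transform(epochs: EpochSet, config: PreprocConfig | None = None, **kw) -> EpochSet:
    """Spherical-spline surface Laplacian; see :mod:`errmon.csd`."""
    if config is not None:
        kw.setdefault("m", config.csd_m)
        kw.setdefault("lam", config.csd_lambda)
        kw.setdefault("n_legendre", config.csd_legendre_terms)
    return _csd.csd_transform(epochs, **kw)


# --------------------------------------------------------------------------
# full chains
# --------------------------------------------------------------------------
def preprocess_erp(
    epochs: EpochSet,
    table: pd.DataFrame,
    config: PreprocConfig | None = None,
    apply_csd: bool = True,
) -> EpochSet:
    """Raw epochs -> analysis-ready ERP epochs (CSD-transformed)."""
    cfg = config or PreprocConfig()
    out = rereference_linked_mastoids(epochs)
    out = out.crop(*cfg.erp_window_ms)
    out = baseline_correct(out, cfg.erp_baseline_ms, lock="response")
    out, _ = ocular_correct(out)
    out, _ = reject_artifacts(out, cfg.reject_uv)
    if apply_csd:
        out = csd_transform(out, cfg)
    return out


def preprocess_mvpa(
    epochs: EpochSet,
    table: pd.DataFrame,
    config: PreprocConfig | None = None,
) -> EpochSet:
    """Raw epochs -> decoding-ready epochs (mastoid-referenced unless
    ``config.apply_csd_for_mvpa``); stimulus-locked baseline."""
    cfg = config or PreprocConfig()
    out = rereference_linked_mastoids(epochs)
    out = baseline_correct(out, cfg.mvpa_baseline_ms, lock="stimulus", table=table)
    out, _ = ocular_correct(out)
    out = out.crop(*cfg.mvpa_window_ms)
    out, _ = reject_artifacts(out, cfg.reject_uv)
    if cfg.apply_csd_for_mvpa:
        out = csd_transform(out, cfg)
    return out
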