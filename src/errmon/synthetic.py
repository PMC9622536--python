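"""Synthetic eight-alternative response task (8ART) experiments.

Generates complete experiments — epoched EEG plus a trial table — with
known ground-truth effect parameters, so every downstream stage
(preprocessing, component quantification, behavioral metrics, decoding)
can be validated by parameter recovery instead of against unavailable
recordings.

The emulated design: a no-self-evaluation condition (7 blocks, 394 trials,
the first two blocks being practice) followed by a self-evaluation
condition (11 blocks x 64 trials = 704 trials) in which each response is
evaluated as correct/error and rated for certainty (1-4).  EEG epochs are
response-locked at 500 Hz and carry:

* a fronto-central negativity 0-150 ms post-response (Ne/c) and a
  centro-parietal positivity 150-300 ms (Pe/c), with response-cell
  dependent amplitudes, as half-cosine bumps under spherical-Gaussian
  topographies;
* a condition-specific spatial pattern switching on several hundred ms
  before the response, present only in self-evaluation trials;
* a slow time-on-task spatial drift growing linearly with the global
  block index;
* eye blinks on vEOG with known per-channel propagation coefficients;
* spatially correlated 1/f background noise.

Everything is additive, so a run with all effect amplitudes at zero and
the same seed isolates the noise term exactly.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import montage
from .containers import EpochSet

SFREQ = 500.0
STEP_MS = 1000.0 / SFREQ

RT_LIMIT_MS = 1200.0
EVAL_LIMIT_MS = 3000.0
FORCE_THRESHOLD_CN = 40.0


# --------------------------------------------------------------------------
# layout
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class BlockSpec:
    condition: str           # "no_self_eval" | "self_eval"
    n_trials: int
    practice: bool = False


@dataclass
class ExperimentLayout:
    """Block structure, montage subset, and epoch geometry."""

    blocks: list[BlockSpec]
    scalp_channels: list[str] = field(default_factory=lambda: list(montage.SCALP_63))
    include_mastoids: bool = True
    include_eog: bool = True
    epoch_span_ms: tuple[float, float] = (-1300.0, 800.0)

    def __post_init__(self):
        if not self.blocks:
            raise ValueError("layout needs at least one block")
        for b in self.blocks:
            if b.n_trials <= 0:
                raise ValueError(f"non-positive trial count in block: {b}")
            if b.condition not in ("no_self_eval", "self_eval"):
                raise ValueError(f"unknown condition {b.condition!r}")
        t0, t1 = self.epoch_span_ms
        if t1 <= t0:
            raise ValueError("empty epoch span")

    @property
    def channels(self) -> list[str]:
        ch = list(self.scalp_channels)
        if self.include_mastoids:
            ch += list(montage.MASTOIDS)
        if self.include_eog:
            ch += list(montage.EOG)
        return ch

    @property
    def times(self) -> np.ndarray:
        t0, t1 = self.epoch_span_ms
        n = int(round((t1 - t0) / STEP_MS)) + 1
        return t0 + STEP_MS * np.arange(n)

    @property
    def n_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks)

    @classmethod
    def default(cls) -> "ExperimentLayout":
        """The full session: 394 no-self-evaluation trials (two practice
        blocks of 37, then 5 x 64) followed by 704 self-evaluation trials
        (11 x 64)."""
        blocks = (
            [BlockSpec("no_self_eval", 37, practice=True)] * 2
            + [BlockSpec("no_self_eval", 64)] * 5
            + [BlockSpec("self_eval", 64)] * 11
        )
        return cls(blocks=list(blocks))

    @classmethod
    def reduced(
        cls,
        trials_per_block: int = 16,
        n_scalp: int = 16,
        epoch_span_ms: tuple[float, float] = (-1100.0, 400.0),
        n_blocks: tuple[int, int] = (5, 11),
        practice_blocks: int = 2,
        practice_trials: int = 6,
    ) -> "ExperimentLayout":
        """A small-session layout with the same block geometry, for
        simulation studies where runtime matters more than trial counts."""
        scalp = _spread_subset(n_scalp)
        blocks = (
            [BlockSpec("no_self_eval", practice_trials, practice=True)] * practice_blocks
            + [BlockSpec("no_self_eval", trials_per_block)] * n_blocks[0]
            + [BlockSpec("self_eval", trials_per_block)] * n_blocks[1]
        )
        return cls(blocks=list(blocks), scalp_channels=scalp, epoch_span_ms=epoch_span_ms)


def _spread_subset(n: int) -> list[str]:
    """n scalp labels spread over the cap (always keeping FCz and Cz)."""
    if n >= 63:
        return list(montage.SCALP_63)
    keep = ["FCz", "Cz"]
    rest = [c for c in montage.SCALP_63 if c not in keep]
    idx = np.linspace(0, len(rest) - 1, n - len(keep)).round().astype(int)
    sel = keep + [rest[i] for i in np.unique(idx)]
    return [c for c in montage.SCALP_63 if c in sel]


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------
def _default_blink_propagation(scalp: Sequence[str]) -> dict[str, float]:
    """Frontal-dominant propagation: strongest at the frontal pole, decaying
    toward posterior sites (classic vertical-EOG forward pattern)."""
    pos = montage.unit_positions(scalp)
    ref = montage.unit_positions(["Fp1"])[0] + montage.unit_positions(["Fp2"])[0]
    ref /= np.linalg.norm(ref)
    theta = montage.angular_distance(pos, ref)
    b = 0.35 * np.exp(-theta / np.deg2rad(55.0))
    return dict(zip(scalp, b))


@dataclass
class GroundTruth:
    """Generative parameters of one synthetic participant.

    Amplitudes are pre-CSD scalp values in µV.  Component amplitude maps
    are keyed by response cell: a response-type label
    (``signaled_correct``, ``signaled_error``, ``nonsignaled_error``,
    ``nonsignaled_correct``) when one applies, with fallback to the
    accuracy label (``correct`` / ``error``).
    """

    ne_amp_by_celltype: Mapping[str, float] = field(
        default_factory=lambda: {
            "correct": -2.0, "error": -7.5,
            "signaled_error": -8.0, "nonsignaled_error": -7.0,
        }
    )
    pe_amp_by_celltype: Mapping[str, float] = field(
        default_factory=lambda: {
            "correct": 2.0, "error": 7.0,
            "signaled_error": 8.0, "nonsignaled_error": 5.0,
        }
    )
    ne_window_ms: tuple[float, float] = (0.0, 150.0)
    pe_window_ms: tuple[float, float] = (150.0, 300.0)
    topo_fwhm_deg: float = 70.0

    cond_pattern_onset_ms: float = -550.0
    cond_pattern_amp: float = 4.0
    cond_pattern_rise_ms: float = 0.0

    drift_rate: float = 0.3           # µV (channel RMS) per global block
    blink_rate: float = 0.10          # blinks per trial
    blink_amp_uv: float = 200.0       # vEOG blink peak
    blink_width_ms: float = 300.0
    blink_propagation: Mapping[str, float] | None = None  # None -> frontal default

    noise_sd: float = 10.0            # per-channel background SD, µV
    noise_slope: float = 1.0          # 1/f^slope power spectrum
    noise_decay_deg: float = 40.0     # spatial correlation e-folding angle

    rt_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"correct": (6.62, 0.35), "error": (6.64, 0.35)}
    )
    post_error_slowing_ms: float = 40.0
    error_rate: float = 0.12
    p_multi_given: Mapping[str, float] = field(
        default_factory=lambda: {"correct": 0.05, "error": 0.25}
    )
    #: P(evaluate "correct" | accuracy, multiple-response flag)
    signaling_model: Mapping[tuple[str, bool], float] = field(
        default_factory=lambda: {
            ("correct", False): 0.995, ("correct", True): 0.95,
            ("error", False): 0.25, ("error", True): 0.60,
        }
    )
    p_eval_timeout: float = 0.02
    eval_rt_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "signaled_correct": (5.93, 0.35),
            "signaled_error": (6.44, 0.35),
            "nonsignaled_error": (6.15, 0.35),
            "nonsignaled_correct": (6.15, 0.35),
        }
    )
    #: P(certainty = 1..4 | response type)
    certainty_model: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "signaled_correct": (0.02, 0.05, 0.18, 0.75),
            "signaled_error": (0.03, 0.08, 0.25, 0.64),
            "nonsignaled_error": (0.12, 0.25, 0.33, 0.30),
            "nonsignaled_correct": (0.12, 0.25, 0.33, 0.30),
        }
    )
    force_mean_cn: Mapping[str, float] = field(
        default_factory=lambda: {"correct": 160.0, "error": 105.0}
    )
    p_correction_given_multi: float = 0.8
    seed: int = 0

    #: filled by generate_experiment: blink times, pattern weights, ...
    record: dict = field(default_factory=dict, repr=False)

    def validate(self, mvpa_span: tuple[float, float] = (-900.0, 200.0)) -> None:
        probs = (
            [self.blink_rate, self.error_rate, self.p_eval_timeout]
            + list(self.p_multi_given.values())
            + list(self.signaling_model.values())
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.blink_propagation is not None and not np.all(
            np.isfinite(list(self.blink_propagation.values()))
        ):
            raise ValueError("blink_propagation must be finite")
        lo, hi = mvpa_span
        if self.cond_pattern_amp != 0.0 and self.cond_pattern_onset_ms > hi:
            # an onset before the epoch simply means the pattern is on
            # throughout; one after the epoch end can never be observed
            raise ValueError(
                f"cond_pattern_onset_ms lies after the epoch end ({hi} ms)"
            )

    def to_json(self, path=None) -> str:
        """Serialize (without the provenance record); tuple keys of the
        signaling model become ``"accuracy|multi"`` strings."""
        import dataclasses
        import json

        d = dataclasses.asdict(self)
        d.pop("record", None)
        d["signaling_model"] = {
            f"{acc}|{int(multi)}": p for (acc, multi), p in self.signaling_model.items()
        }
        d["rt_params"] = {k: list(v) for k, v in self.rt_params.items()}
        d["eval_rt_params"] = {k: list(v) for k, v in self.eval_rt_params.items()}
        d["certainty_model"] = {k: list(v) for k, v in self.certainty_model.items()}
        s = json.dumps(d, indent=1)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source) -> "GroundTruth":
        import json
        from pathlib import Path

        text = Path(source).read_text() if not str(source).lstrip().startswith("{") \
            else str(source)
        d = json.loads(text)
        d["signaling_model"] = {
            (k.split("|")[0], bool(int(k.split("|")[1]))): p
            for k, p in d["signaling_model"].items()
        }
        for f in ("rt_params", "eval_rt_params", "certainty_model"):
            d[f] = {k: tuple(v) for k, v in d[f].items()}
        for f in ("ne_window_ms", "pe_window_ms"):
            d[f] = tuple(d[f])
        return cls(**d)

    @classmethod
    def null(cls, seed: int = 0, **kw) -> "GroundTruth":
        """All effects off: zero components, no condition pattern, no
        drift, no blinks.  Background noise stays on unless overridden."""
        defaults = dict(
            ne_amp_by_celltype={}, pe_amp_by_celltype={},
            cond_pattern_amp=0.0, drift_rate=0.0, blink_rate=0.0,
            post_error_slowing_ms=0.0, seed=seed,
        )
        defaults.update(kw)
        return cls(**defaults)


# --------------------------------------------------------------------------
# injection primitives
# --------------------------------------------------------------------------
def half_cosine_bump(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Raised-cosine bump: 0 at the window edges, 1 at the midpoint."""
    t0, t1 = window
    out = np.zeros_like(times, dtype=float)
    m = (times >= t0) & (times <= t1)
    out[m] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (times[m] - t0) / (t1 - t0)))
    return out


def inject_component(
    epochs: EpochSet,
    topography: Mapping[str, float] | np.ndarray,
    window: tuple[float, float],
    amplitude: float,
    trial_mask: np.ndarray | None = None,
) -> EpochSet:
    """Add a half-cosine bump of peak ``amplitude`` x topography to the
    selected trials; other trials are untouched."""
    t0, t1 = window
    if t0 < epochs.times[0] - 1e-9 or t1 > epochs.times[-1] + 1e-9:
        raise ValueError(f"window {window} outside epoch "
                         f"({epochs.times[0]}, {epochs.times[-1]}) ms")
    if isinstance(topography, Mapping):
        w = np.array([topography.get(c, 0.0) for c in epochs.channels])
    else:
        w = np.asarray(topography, float)
        if w.shape != (len(epochs.channels),):
            raise ValueError("topography does not match channel count")
    out = epochs.copy()
    if amplitude == 0.0:
        return out
    mask = np.ones(epochs.n_trials, bool) if trial_mask is None else np.asarray(trial_mask, bool)
    bump = amplitude * half_cosine_bump(epochs.times, window)
    out.data[mask] += (w[:, None] * bump[None, :]).astype(out.data.dtype)
    return out


def inject_blinks(
    epochs: EpochSet,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> EpochSet:
    """Add blink artifacts: a raised-cosine waveform on vEOG, propagated
    to each EEG channel via the per-channel coefficients b_ch.  Occurrence
    times are appended to ``truth.record["blinks"]``."""
    if "vEOG" not in epochs.channels:
        raise ValueError("vEOG channel required to inject blinks")
    rng = np.random.default_rng(truth.seed + 7) if rng is None else rng
    out = epochs.copy()
    if truth.blink_rate == 0.0:
        return out
    scalp = epochs.scalp_channels
    prop = truth.blink_propagation or _default_blink_propagation(scalp)
    b = np.array([prop.get(c, 0.0) for c in epochs.channels])
    b[epochs.channel_index("vEOG")] = 1.0
    width = truth.blink_width_ms
    t_lo = epochs.times[0] + width / 2
    t_hi = epochs.times[-1] - width / 2
    log = truth.record.setdefault("blinks", [])
    has_blink = rng.random(epochs.n_trials) < truth.blink_rate
    centres = rng.uniform(t_lo, t_hi, size=epochs.n_trials)
    for i in np.flatnonzero(has_blink):
        c = centres[i]
        wave = truth.blink_amp_uv * half_cosine_bump(
            epochs.times, (c - width / 2, c + width / 2)
        )
        out.data[i] += (b[:, None] * wave[None, :]).astype(out.data.dtype)
        log.append((epochs.trial_ids[i], float(c)))
    return out


# --------------------------------------------------------------------------
# noise
# --------------------------------------------------------------------------
def one_over_f_noise(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    sd: float,
    slope: float,
    mixing: np.ndarray | None,
) -> np.ndarray:
    """Spatially correlated 1/f^slope Gaussian noise, per-channel SD ``sd``.

    The temporal spectrum is shaped in the frequency domain and rescaled
    analytically (Parseval) so the expected per-channel variance is sd².
    ``mixing`` is a Cholesky factor applied over the channel axis.
    """
    n_tr, n_ch, n_s = shape
    if sd == 0.0:
        return np.zeros(shape, np.float32)
    white = rng.standard_normal(shape)
    freqs = np.fft.rfftfreq(n_s, d=1.0 / SFREQ)
    gain = np.zeros_like(freqs)
    nz = freqs > 0
    gain[nz] = freqs[nz] ** (-slope / 2.0)
    spec = np.fft.rfft(white, axis=-1) * gain
    x = np.fft.irfft(spec, n=n_s, axis=-1)
    # expected variance of x for unit-variance white input
    g2 = gain**2
    var = (2.0 * g2[1:-1].sum() + g2[0] + (g2[-1] if n_s % 2 == 0 else 2 * g2[-1])) / n_s
    x *= sd / np.sqrt(var)
    if mixing is not None:
        x = np.einsum("ij,tjs->tis", mixing, x)
    return x.astype(np.float32)


def _spatial_mixing(scalp: Sequence[str], decay_deg: float) -> np.ndarray:
    corr = montage.spatial_correlation(scalp, decay_deg)
    corr = corr + 1e-6 * np.eye(len(scalp))
    L = np.linalg.cholesky(corr)
    # keep unit variance per channel after mixing
    return L / np.sqrt(np.sum(L**2, axis=1, keepdims=True))


# --------------------------------------------------------------------------
# behavioral simulation
# --------------------------------------------------------------------------
def _simulate_behavior(
    truth: GroundTruth, layout: ExperimentLayout, rng: np.random.Generator,
    participant_id: str,
) -> pd.DataFrame:
    rows = []
    trial_no = 0
    block_in_cond = {"no_self_eval": 0, "self_eval": 0}
    for g, blk in enumerate(layout.blocks, start=1):
        block_in_cond[blk.condition] += 1
        prev_error = False
        for _ in range(blk.n_trials):
            trial_no += 1
            acc = "error" if rng.random() < truth.error_rate else "correct"
            multi = rng.random() < truth.p_multi_given[acc]
            mu, sg = truth.rt_params[acc]
            rt = float(rng.lognormal(mu, sg))
            if prev_error:
                rt += truth.post_error_slowing_ms
            timeout = (not blk.practice) and rt > RT_LIMIT_MS

            if blk.condition == "self_eval":
                p_corr = truth.signaling_model[(acc, multi)]
                ev = "correct" if rng.random() < p_corr else "error"
                if acc == "correct":
                    rtype = "signaled_correct" if ev == "correct" else "nonsignaled_correct"
                else:
                    rtype = "nonsignaled_error" if ev == "correct" else "signaled_error"
                emu, esg = truth.eval_rt_params[rtype]
                eval_rt = float(rng.lognormal(emu, esg))
                if rng.random() < truth.p_eval_timeout:
                    eval_rt = EVAL_LIMIT_MS + float(rng.uniform(1, 500))
                certainty = float(rng.choice(4, p=truth.certainty_model[rtype]) + 1)
            else:
                ev, eval_rt, certainty = "none", np.nan, np.nan

            forces = rng.uniform(0.0, 25.0, size=8)
            target = int(rng.integers(8))
            if acc == "correct":
                key = target
            else:
                key = int((target + 1 + rng.integers(7)) % 8)
            forces[key] = max(
                45.0, float(rng.gamma(16.0, truth.force_mean_cn[acc] / 16.0))
            )
            if multi:
                # on errors the extra press is usually the (late) correct
                # key — the immediate-correction behavior that drives
                # non-signaled errors
                if acc == "error" and rng.random() < truth.p_correction_given_multi:
                    other = target
                else:
                    other = int((key + 1 + rng.integers(7)) % 8)
                forces[other] = max(forces[other], float(rng.uniform(45.0, 90.0)))

            rows.append({
                "trial_id": f"{participant_id}_t{trial_no:04d}",
                "participant_id": participant_id,
                "condition": blk.condition,
                "block": block_in_cond[blk.condition],
                "block_global": g,
                "practice": blk.practice,
                "accuracy": acc,
                "rt": rt,
                "timeout": timeout,
                "multiple_response": multi,
                "eval_response": ev,
                "eval_rt": eval_rt,
                "certainty": certainty,
                "stimulus_onset_ms": -rt,
                "target_key": target + 1,
                "response_key": key + 1,
                **{f"force_k{i + 1}": forces[i] for i in range(8)},
            })
            prev_error = acc == "error" and not timeout
    return pd.DataFrame(rows)


def _resolve_cell_amp(amps: Mapping[str, float], rtype: str, acc: str) -> float:
    if rtype in amps:
        return float(amps[rtype])
    return float(amps.get(acc, 0.0))


def _response_type(row) -> str:
    if row["condition"] != "self_eval" or row["eval_response"] == "none":
        return row["accuracy"]
    if row["accuracy"] == "correct":
        return "signaled_correct" if row["eval_response"] == "correct" else "nonsignaled_correct"
    return "nonsignaled_error" if row["eval_response"] == "correct" else "signaled_error"


# --------------------------------------------------------------------------
# the generator
# --------------------------------------------------------------------------
def generate_experiment(
    truth: GroundTruth,
    layout: ExperimentLayout | None = None,
    participant_id: str = "P01",
) -> tuple[EpochSet, pd.DataFrame]:
    """Simulate one participant: response-locked epochs plus trial table.

    The epochs come back left-mastoid referenced and un-baselined, exactly
    as a raw export would; provenance of every injected effect is stored
    in ``truth.record`` for recovery tests.  Generation is reproducible:
    identical (truth, layout) including ``truth.seed`` yields bit-identical
    outputs.
    """
    layout = ExperimentLayout.default() if layout is None else layout
    truth.validate(mvpa_span=layout.epoch_span_ms)
    ss = np.random.SeedSequence(truth.seed)
    rng_beh, rng_noise, rng_blink, rng_pat = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )

    table = _simulate_behavior(truth, layout, rng_beh, participant_id)
    channels = layout.channels
    times = layout.times
    n_tr, n_ch, n_s = len(table), len(channels), len(times)
    scalp = [c for c in channels if c not in montage.MASTOIDS + montage.EOG]
    scalp_idx = np.array([channels.index(c) for c in scalp])

    data = np.zeros((n_tr, n_ch, n_s), np.float32)
    epochs = EpochSet(
        data=data, times=times, channels=channels,
        trial_ids=table["trial_id"].to_numpy(),
        lock="response", reference="left_mastoid",
    )

    # --- background noise ------------------------------------------------
    if truth.noise_sd > 0:
        mixing = _spatial_mixing(scalp, truth.noise_decay_deg)
        block_len = max(1, int(4e7 / (n_ch * n_s)))  # cap working memory
        for lo in range(0, n_tr, block_len):
            hi = min(n_tr, lo + block_len)
            chunk = one_over_f_noise(
                rng_noise, (hi - lo, len(scalp), n_s),
                truth.noise_sd, truth.noise_slope, mixing,
            )
            data[lo:hi, scalp_idx, :] += chunk
            # mastoids & EOG: weaker, spatially independent background
            aux = [i for i in range(n_ch) if i not in scalp_idx]
            if aux:
                data[lo:hi][:, aux, :] += one_over_f_noise(
                    rng_noise, (hi - lo, len(aux), n_s),
                    0.3 * truth.noise_sd, truth.noise_slope, None,
                )

    # --- ERP components ---------------------------------------------------
    rtypes = table.apply(_response_type, axis=1)
    ne_topo = montage.gaussian_topography(scalp, "FCz", truth.topo_fwhm_deg)
    pe_topo = montage.gaussian_topography(scalp, "Cz", truth.topo_fwhm_deg)
    truth.record["ne_topography"] = dict(zip(scalp, ne_topo))
    truth.record["pe_topography"] = dict(zip(scalp, pe_topo))
    full_ne = np.zeros(n_ch); full_ne[scalp_idx] = ne_topo
    full_pe = np.zeros(n_ch); full_pe[scalp_idx] = pe_topo

    for amps, topo, window in (
        (truth.ne_amp_by_celltype, full_ne, truth.ne_window_ms),
        (truth.pe_amp_by_celltype, full_pe, truth.pe_window_ms),
    ):
        if not amps:
            continue
        amp_per_trial = np.array([
            _resolve_cell_amp(amps, rtypes.iloc[i], table["accuracy"].iloc[i])
            for i in range(n_tr)
        ])
        if times[0] > window[0] or times[-1] < window[1]:
            raise ValueError("epoch span does not cover the component window")
        bump = half_cosine_bump(times, window)
        data += (
            amp_per_trial[:, None, None] * topo[None, :, None] * bump[None, None, :]
        ).astype(np.float32)

    # --- condition-specific pre-response pattern -------------------------
    w_cond = rng_pat.standard_normal(len(scalp))
    w_cond /= np.sqrt(np.mean(w_cond**2))          # unit channel-RMS
    truth.record["cond_pattern_weights"] = dict(zip(scalp, w_cond))
    if truth.cond_pattern_amp != 0.0:
        profile = _onset_profile(
            times, truth.cond_pattern_onset_ms, truth.cond_pattern_rise_ms
        )
        mask = (table["condition"] == "self_eval").to_numpy()
        full_w = np.zeros(n_ch)
        full_w[scalp_idx] = w_cond
        patt = (truth.cond_pattern_amp * full_w[:, None] * profile[None, :]).astype(np.float32)
        data[mask] += patt
    # --- time-on-task drift ----------------------------------------------
    w_drift = rng_pat.standard_normal(len(scalp))
    w_drift /= np.sqrt(np.mean(w_drift**2))
    truth.record["drift_weights"] = dict(zip(scalp, w_drift))
    if truth.drift_rate != 0.0:
        span = times[-1] - times[0]
        drift_profile = 0.5 * (1.0 - np.cos(2 * np.pi * (times - times[0]) / span))
        amp = truth.drift_rate * (table["block_global"].to_numpy() - 1.0)
        full = np.zeros(n_ch); full[scalp_idx] = w_drift
        data += (
            amp[:, None, None] * full[None, :, None] * drift_profile[None, None, :]
        ).astype(np.float32)

    # --- blinks -----------------------------------------------------------
    epochs = EpochSet(
        data=data, times=times, channels=channels,
        trial_ids=table["trial_id"].to_numpy(),
        lock="response", reference="left_mastoid",
    )
    if truth.blink_rate > 0:
        epochs = inject_blinks(epochs, truth, rng_blink)
    epochs.log(f"synthetic experiment, seed={truth.seed}, {n_tr} trials")
    return epochs, table


def _onset_profile(times: np.ndarray, onset_ms: float, rise_ms: float) -> np.ndarray:
    """0 before onset, linear rise over ``rise_ms``, then sustained at 1
    through the epoch end (so a response-locked baseline after the onset
    removes it as a per-trial constant)."""
    if rise_ms > 0:
        return np.clip((times - onset_ms) / rise_ms, 0.0, 1.0)
    return (times >= onset_ms).astype(float)


def generate_cohort(
    truth_template: GroundTruth,
    layout: ExperimentLayout,
    n_participants: int,
    base_seed: int = 0,
) -> list[tuple[EpochSet, pd.DataFrame, GroundTruth]]:
    """Independent synthetic participants sharing the template's effect
    parameters; per-participant seeds derive from ``base_seed``."""
    import dataclasses

    out = []
    for i in range(n_participants):
        t = dataclasses.replace(
            truth_template, seed=int(base_seed) * 10_000 + i, record={}
        )
        pid = f"P{i + 1:02d}"
        ep, tab = generate_experiment(t, layout, participant_id=pid)
        out.append((ep, tab, t))
    return out
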