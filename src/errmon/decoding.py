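"""Time-resolved multivariate decoding with empirical chance.

The response-locked epoch is cut into consecutive non-overlapping 10-ms
windows of five samples; within each window the samples of all scalp
electrodes form one spatio-temporal feature vector per trial.  A linear
support-vector classifier (libsvm, cost C) separates the two conditions
of a contrast under repeated k-fold cross-validation (10 repetitions x
10 folds by default = 100 classification processes, averaged into one
accuracy per window).  Chance is estimated empirically by re-running the
identical pipeline on label-shuffled data.  Second-level inference tests
accuracy against its own empirical chance per window across participants
with Bonferroni-corrected paired t tests.

For the part-split (time-on-task) analysis, each of the six part-pair
contrasts yields a per-participant decoding-group score: the mean over
windows of (accuracy − chance), in percentage points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import EpochSet, align

PART_CONTRASTS = (
    ("1.1", "1.2"), ("2.1", "2.2"), ("1.2", "2.1"),
    ("1.1", "2.1"), ("1.2", "2.2"), ("1.1", "2.2"),
)


@dataclass
class DecodingConfig:
    window_ms: float = 10.0
    samples_per_window: int = 5
    analysis_window_ms: tuple[float, float] = (-900.0, 200.0)
    n_folds: int = 10
    n_repetitions: int = 10
    C: float = 1.0
    n_permutation_runs: int = 100
    #: repetitions used inside each shuffled-labels run (the chance
    #: pipeline is otherwise identical to the real one)
    n_permutation_repetitions: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_folds < 2 or self.n_repetitions < 1:
            raise ValueError("need n_folds >= 2 and n_repetitions >= 1")
        if self.n_permutation_runs < 1:
            raise ValueError("need at least one permutation run")


@dataclass
class DecodingResult:
    participant_id: str
    contrast: str
    window_start_ms: np.ndarray
    accuracy: np.ndarray
    chance: np.ndarray
    n_trials: tuple[int, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "participant": self.participant_id,
            "contrast": self.contrast,
            "window_start_ms": self.window_start_ms,
            "accuracy": self.accuracy,
            "chance": self.chance,
        })


# --------------------------------------------------------------------------
# windowing and features
# --------------------------------------------------------------------------
def make_windows(times: np.ndarray, config: DecodingConfig) -> list[tuple[int, int]]:
    """Consecutive disjoint sample-index windows covering the analysis
    window from its start; a trailing remainder shorter than one window
    is dropped (logged)."""
    times = np.asarray(times, float)
    step = times[1] - times[0]
    spw = config.samples_per_window
    if not np.isclose(step * spw, config.window_ms):
        raise ValueError(
            f"{spw} samples at {step} ms do not span {config.window_ms} ms windows"
        )
    lo, hi = config.analysis_window_ms
    if lo < times[0] - 1e-9 or hi > times[-1] + 1e-9:
        raise ValueError(f"analysis window ({lo}, {hi}) not covered by epoch "
                         f"({times[0]}, {times[-1]})")
    m = (times >= lo - 1e-9) & (times <= hi + 1e-9)
    idx = np.flatnonzero(m)
    n_win, rem = divmod(len(idx), spw)
    if rem:
        warnings.warn(f"dropping trailing remainder of {rem} sample(s)")
    return [(int(idx[0] + w * spw), int(idx[0] + (w + 1) * spw)) for w in range(n_win)]


def build_feature_vectors(epochs: EpochSet, window: tuple[int, int]) -> np.ndarray:
    """Per-trial feature vectors for one window: scalp channels only,
    channel-major layout (all samples of channel 1, then channel 2, ...)."""
    lo, hi = window
    if lo < 0 or hi > epochs.data.shape[2]:
        raise ValueError(f"window {window} outside epoch samples")
    picks = epochs.scalp_picks()
    if picks.size == 0:
        raise ValueError("no scalp channels present")
    seg = epochs.data[:, picks, lo:hi]
    return np.ascontiguousarray(seg.reshape(epochs.n_trials, -1), dtype=float)


# --------------------------------------------------------------------------
# first level
# --------------------------------------------------------------------------
def stratified_fold_ids(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Random fold id per trial for two classes of ``n`` trials each
    (class 0 first).  Class-stratified: each fold holds ~n/k trials of
    either class, so train and test sets stay balanced, and every trial
    sits in exactly one test fold."""
    fold_of = np.empty(2 * n, int)
    for base in (0, n):
        order = rng.permutation(n)
        for f, chunk in enumerate(np.array_split(order, k)):
            fold_of[base + chunk] = f
    return fold_of


def _cv_accuracy(
    X: np.ndarray, y: np.ndarray, config: DecodingConfig,
    rng: np.random.Generator, n_repetitions: int,
) -> float:
    """Repeated balanced k-fold SVC accuracy (mean of fold accuracies).

    Per repetition the majority class is randomly subsampled to the
    minority count, trials are randomly partitioned into folds, features
    are z-scored with training-fold statistics only, and a linear SVC
    (cost C) is trained on k-1 folds and tested on the held-out fold.
    """
    from sklearn.svm import SVC

    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    n = min(len(idx0), len(idx1))
    k = config.n_folds
    if n < k:
        raise ValueError(f"class with {n} trials cannot fill {k} folds")
    accs = []
    for _ in range(n_repetitions):
        pick0 = rng.choice(idx0, n, replace=False)
        pick1 = rng.choice(idx1, n, replace=False)
        Xb = X[np.concatenate([pick0, pick1])]
        yb = np.repeat([0, 1], n)
        fold_of = stratified_fold_ids(rng, n, k)
        for f in range(k):
            test = fold_of == f
            train = ~test
            mu = Xb[train].mean(axis=0)
            sd = Xb[train].std(axis=0)
            sd[sd < 1e-12] = 1.0
            clf = SVC(kernel="linear", C=config.C)
            clf.fit((Xb[train] - mu) / sd, yb[train])
            pred = clf.predict((Xb[test] - mu) / sd)
            accs.append(float(np.mean(pred == yb[test])))
    return float(np.mean(accs))


def decode_window(
    X: np.ndarray, y: np.ndarray, config: DecodingConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Cross-validated accuracy for one window's feature vectors."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    return _cv_accuracy(X, y, config, rng, config.n_repetitions)


def empirical_chance(
    X: np.ndarray, y: np.ndarray, config: DecodingConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Mean accuracy of the identical pipeline over label-shuffled runs."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    reps = config.n_permutation_repetitions or config.n_repetitions
    vals = []
    for _ in range(config.n_permutation_runs):
        y_perm = rng.permutation(y)
        vals.append(_cv_accuracy(X, y_perm, config, rng, reps))
    return float(np.mean(vals))


@dataclass(frozen=True)
class Contrast:
    """Two trial populations defined on a trial-table column."""
    column: str
    a: str
    b: str

    @property
    def name(self) -> str:
        return f"{self.column}:{self.a}_vs_{self.b}"


def contrast_masks(
    table: pd.DataFrame, contrast: Contrast, rt_limit_ms: float = 1200.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks for the two populations; practice trials and trials
    beyond the RT limit never enter a decoding contrast."""
    ok = (table["rt"] <= rt_limit_ms).to_numpy()
    if "practice" in table.columns:
        ok &= ~table["practice"].to_numpy(bool)
    col = table[contrast.column].astype(str).to_numpy()
    return ok & (col == str(contrast.a)), ok & (col == str(contrast.b))


def first_level(
    epochs: EpochSet,
    table: pd.DataFrame,
    contrast: Contrast,
    config: DecodingConfig,
    participant_id: str | None = None,
) -> DecodingResult | None:
    """Accuracy and empirical chance for every window of one participant.

    Returns ``None`` (with a warning) when either population cannot fill
    the folds after balancing.
    """
    tab = align(epochs, table)
    mask_a, mask_b = contrast_masks(tab, contrast)
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if min(n_a, n_b) < config.n_folds:
        warnings.warn(
            f"contrast {contrast.name}: class sizes ({n_a}, {n_b}) below "
            f"{config.n_folds}-fold requirement; skipped"
        )
        return None
    sel = mask_a | mask_b
    y = np.where(mask_a[sel], 0, 1)
    windows = make_windows(epochs.times, config)
    sub = epochs.copy(data=epochs.data[sel])
    sub.trial_ids = epochs.trial_ids[sel]
    rng = np.random.default_rng(config.seed)
    acc = np.empty(len(windows))
    cha = np.empty(len(windows))
    for w, win in enumerate(windows):
        X = build_feature_vectors(sub, win)
        acc[w] = decode_window(X, y, config, rng)
        cha[w] = empirical_chance(X, y, config, rng)
    starts = epochs.times[[w[0] for w in windows]]
    pid = participant_id or str(tab["participant_id"].iloc[0])
    return DecodingResult(pid, contrast.name, starts, acc, cha, (n_a, n_b))


# --------------------------------------------------------------------------
# RT matching
# --------------------------------------------------------------------------
def rt_match(
    table: pd.DataFrame,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    caliper_ms: float = 50.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy nearest-RT pairing without replacement between two trial
    sets; pairs farther apart than the caliper are dropped.  Returns
    boolean masks of the matched subsets."""
    rng = np.random.default_rng(seed)
    ia = np.flatnonzero(np.asarray(mask_a, bool))
    ib = np.flatnonzero(np.asarray(mask_b, bool))
    rts = table["rt"].to_numpy(float)
    order = rng.permutation(len(ia))
    used_b = np.zeros(len(ib), bool)
    keep_a, keep_b = [], []
    for j in order:
        d = np.abs(rts[ib] - rts[ia[j]])
        d[used_b] = np.inf
        k = int(np.argmin(d))
        if np.isfinite(d[k]) and d[k] <= caliper_ms:
            used_b[k] = True
            keep_a.append(ia[j])
            keep_b.append(ib[k])
    out_a = np.zeros_like(np.asarray(mask_a, bool))
    out_b = np.zeros_like(out_a)
    out_a[keep_a] = True
    out_b[keep_b] = True
    return out_a, out_b


# --------------------------------------------------------------------------
# second level
# --------------------------------------------------------------------------
def second_level(
    results: list[DecodingResult], alpha: float = 0.05
) -> pd.DataFrame:
    """Paired two-sided t tests of accuracy vs empirical chance per
    window across participants, Bonferroni-corrected over windows.

    Windows are tested on the set common to all participants (logged if
    some are missing).  Returns one row per window with group means, t,
    corrected p and the significance flag.
    """
    if len(results) < 2:
        raise ValueError("second level needs results from >= 2 participants")
    common = results[0].window_start_ms
    for r in results[1:]:
        common = np.intersect1d(common, r.window_start_ms)
    if len(common) < len(results[0].window_start_ms):
        warnings.warn("testing on the common window set only")
    acc = np.stack([
        r.accuracy[np.isin(r.window_start_ms, common)] for r in results
    ])
    cha = np.stack([
        r.chance[np.isin(r.window_start_ms, common)] for r in results
    ])
    n_win = len(common)
    diff = acc - cha
    with np.errstate(all="ignore"):
        t, p = sps.ttest_rel(acc, cha, axis=0)
    p = np.where(np.isnan(p), 1.0, p)
    p_corr = np.minimum(1.0, p * n_win)
    return pd.DataFrame({
        "window_start_ms": common,
        "mean_accuracy": acc.mean(axis=0),
        "mean_chance": cha.mean(axis=0),
        "mean_diff": diff.mean(axis=0),
        "t": t,
        "p_bonferroni": p_corr,
        "significant": p_corr < alpha,
    })


def first_significant_onset(second: pd.DataFrame) -> float:
    """Start time (ms) of the earliest significant window, or nan."""
    sig = second[second["significant"]]
    return float(sig["window_start_ms"].iloc[0]) if len(sig) else float("nan")


# --------------------------------------------------------------------------
# decoding groups (part-split scores)
# --------------------------------------------------------------------------
def decoding_group_scores(
    results_by_participant: dict[str, dict[str, DecodingResult]],
) -> pd.DataFrame:
    """Per participant x decoding group: mean over windows of
    (accuracy − chance) in percentage points.

    ``results_by_participant[pid][group]`` holds the first-level result of
    one part-pair contrast; participants missing any group are dropped
    from the comparison (logged).
    """
    groups = {f"{a}v{b}" for a, b in PART_CONTRASTS}
    rows = []
    for pid, res in results_by_participant.items():
        have = {g for g in res if res[g] is not None}
        if not groups <= have:
            warnings.warn(f"participant {pid} lacks contrasts "
                          f"{sorted(groups - have)}; dropped")
            continue
        for g in sorted(groups):
            r = res[g]
            rows.append({
                "participant": pid,
                "group": g,
                "score": 100.0 * float(np.mean(r.accuracy - r.chance)),
            })
    return pd.DataFrame(rows)


def part_contrast(a: str, b: str) -> Contrast:
    return Contrast(column="part", a=a, b=b)


def plot_decoding(second: pd.DataFrame, ax=None, title: str | None = None):
    """Accuracy vs time with the empirical-chance curve and shading over
    windows where accuracy differs significantly from chance."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    t = second["window_start_ms"]
    ax.plot(t, 100 * second["mean_accuracy"], color="k", label="accuracy")
    ax.plot(t, 100 * second["mean_chance"], color="grey", label="empirical chance")
    lo = 100 * min(second["mean_chance"].min(), second["mean_accuracy"].min()) - 2
    hi = 100 * second["mean_accuracy"].max() + 2
    for _, row in second[second["significant"]].iterrows():
        ax.axvspan(row["window_start_ms"], row["window_start_ms"] + 10,
                   color="0.85", zorder=0)
    ax.axvline(0.0, color="k", lw=0.5, ls="--")
    ax.set(xlabel="time relative to response (ms)",
           ylabel="classification accuracy (%)", ylim=(lo, hi), title=title)
    ax.legend(frameon=False, fontsize=8)
    return ax
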