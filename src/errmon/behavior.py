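"""Behavioral error-monitoring metrics from the trial table.

Response-type classification (signaled/non-signaled x correct/error),
multiple-response detection from per-key peak forces, the robust pre-post
RT difference (post-error slowing), per-cell summary statistics, the
minimum-trial inclusion rule, and the within-condition part split used by
the time-on-task decoding analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import EVAL_LIMIT_MS, FORCE_THRESHOLD_CN, RT_LIMIT_MS

RESPONSE_TYPES = ("signaled_correct", "signaled_error", "nonsignaled_error",
                  "nonsignaled_correct")
#: response types entering Table-style rate denominators (non-signaled
#: correct responses are too rare to quantify and are excluded)
INCLUDED_TYPES = ("signaled_correct", "signaled_error", "nonsignaled_error")

FORCE_COLS = [f"force_k{i}" for i in range(1, 9)]


# --------------------------------------------------------------------------
# labels
# --------------------------------------------------------------------------
def multiple_response_flag(
    forces, threshold_cn: float = FORCE_THRESHOLD_CN
) -> bool:
    """True iff force strictly exceeded the threshold on more than one key."""
    forces = np.asarray(forces, float)
    if forces.shape != (8,) or not np.all(np.isfinite(forces)):
        raise ValueError("need 8 finite per-key forces")
    n = int((forces > threshold_cn).sum())
    if n == 0:
        raise ValueError("no key exceeded the registration threshold; "
                         "trial has no registered response")
    return n >= 2


def classify_response_types(
    table: pd.DataFrame,
    rt_limit_ms: float = RT_LIMIT_MS,
    eval_limit_ms: float = EVAL_LIMIT_MS,
) -> pd.Series:
    """Response-type label per trial.

    signaled_correct  = correct response evaluated as correct
    signaled_error    = error evaluated as error
    nonsignaled_error = error evaluated as correct
    nonsignaled_correct = correct evaluated as error

    Trials outside the RT limit, practice trials, trials without an
    evaluation (no-self-evaluation condition) and evaluation timeouts are
    ``unlabeled``.  Evaluation fields on no-self-evaluation rows mark a
    malformed table.
    """
    bad = (table["condition"] == "no_self_eval") & (table["eval_response"] != "none")
    if bad.any():
        raise ValueError("evaluation responses present in no_self_eval rows; "
                         "malformed trial table")
    labels = pd.Series("unlabeled", index=table.index, dtype=object)
    practice = (
        table["practice"].astype(bool)
        if "practice" in table.columns
        else pd.Series(False, index=table.index)
    )
    ok = (
        (table["condition"] == "self_eval")
        & ~practice
        & (table["rt"] <= rt_limit_ms)
        & (table["eval_response"].isin(["correct", "error"]))
        & (table["eval_rt"] <= eval_limit_ms)
    )
    acc = table["accuracy"]
    ev = table["eval_response"]
    labels[ok & (acc == "correct") & (ev == "correct")] = "signaled_correct"
    labels[ok & (acc == "error") & (ev == "error")] = "signaled_error"
    labels[ok & (acc == "error") & (ev == "correct")] = "nonsignaled_error"
    labels[ok & (acc == "correct") & (ev == "error")] = "nonsignaled_correct"
    return labels


def add_derived_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Attach ``response_type`` and recomputed ``multiple_response``."""
    out = table.copy()
    if set(FORCE_COLS) <= set(table.columns):
        out["multiple_response"] = [
            multiple_response_flag(row) for row in table[FORCE_COLS].to_numpy()
        ]
    out["response_type"] = classify_response_types(out)
    # accuracy-level cell for the condition x accuracy analyses
    out["acc_cell"] = np.where(
        out.get("practice", False) | (out["rt"] > RT_LIMIT_MS),
        "unlabeled", out["condition"] + ":" + out["accuracy"],
    )
    return out


# --------------------------------------------------------------------------
# post-error slowing
# --------------------------------------------------------------------------
def pre_post_rt_diff(
    table: pd.DataFrame,
    target: str,
    label_column: str = "accuracy",
    rt_limit_ms: float = RT_LIMIT_MS,
) -> tuple[float, int]:
    """Robust pre-post RT difference around target trials.

    For every target trial with an immediately preceding and following
    trial in the same block (neighbors of any accuracy, but not timeouts
    — a timed-out neighbor has no comparable RT and breaks adjacency),
    compute RT_post − RT_pre; positive values mean slowing after the
    target.  Returns the mean difference and the number of contributing
    trials; an empty set returns (nan, 0) rather than 0.
    """
    diffs = []
    for (_, _), blk in table.groupby(["participant_id", "block_global"], sort=False):
        blk = blk.reset_index(drop=True)
        lab = blk[label_column].astype(str).to_numpy()
        rts = blk["rt"].to_numpy(float)
        valid = (rts <= rt_limit_ms) & ~blk.get("practice", pd.Series(False, index=blk.index)).to_numpy(bool)
        for i in range(1, len(blk) - 1):
            if lab[i] == target and valid[i] and valid[i - 1] and valid[i + 1]:
                diffs.append(rts[i + 1] - rts[i - 1])
    if not diffs:
        warnings.warn(f"no eligible {target!r} trials for pre-post RT diff")
        return float("nan"), 0
    return float(np.mean(diffs)), len(diffs)


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------
@dataclass
class BehaviorSummary:
    cell: str
    n_trials: int
    response_rate_pct: float
    multiple_responses_pct: float
    rt_ms: float
    peak_force_cn: float
    pre_post_rt_diff_ms: float
    post_response_correct_pct: float
    error_correction_pct: float
    eval_rt_ms: float
    certainty_mean: float


def post_response_correct_pct(table: pd.DataFrame, mask: np.ndarray) -> float:
    """Percentage of masked trials whose next trial (same block) is a
    correct response; last trials of a block have no successor and drop."""
    followed_correct = []
    for (_, _), blk in table.groupby(["participant_id", "block_global"], sort=False):
        idx = blk.index.to_numpy()
        acc = blk["accuracy"].to_numpy()
        for j, i in enumerate(idx[:-1]):
            if mask[i]:
                followed_correct.append(acc[j + 1] == "correct")
    if not followed_correct:
        return float("nan")
    return 100.0 * float(np.mean(followed_correct))


def error_correction_pct(
    table: pd.DataFrame, mask: np.ndarray,
    threshold_cn: float = FORCE_THRESHOLD_CN,
) -> float:
    """Percentage of masked error trials immediately followed — within the
    trial — by a press of the correct key.

    A correction is a force exceeding the registration threshold on the
    trial's target key although the registered (first) response was a
    different key.  This is what ties corrections to multiple responses.
    """
    sub = table[mask]
    sub = sub[sub["accuracy"] == "error"]
    if sub.empty or "target_key" not in sub.columns:
        return float("nan")
    forces = sub[FORCE_COLS].to_numpy(float)
    tgt = sub["target_key"].to_numpy(int) - 1
    corrected = forces[np.arange(len(sub)), tgt] > threshold_cn
    return 100.0 * float(corrected.mean())


def summarize_behavior(
    table: pd.DataFrame, label_column: str = "response_type",
    included: tuple[str, ...] = INCLUDED_TYPES,
) -> pd.DataFrame:
    """Per-cell behavioral summary in tidy long format.

    Response rates are percentages of the included cells only (the
    non-signaled correct cell is excluded from the denominator).  The
    error-correction percentage is only defined for error cells.
    """
    if label_column not in table.columns:
        table = add_derived_columns(table)
    labels = table[label_column].astype(str)
    denom = int(labels.isin(included).sum())
    rows = []
    for cell in included:
        m = (labels == cell).to_numpy()
        n = int(m.sum())
        if n == 0:
            warnings.warn(f"empty cell {cell!r}; omitted from summary")
            continue
        sub = table[m]
        ppc = post_response_correct_pct(table, m)
        err_corr = float("nan")
        if "error" in cell:
            err_corr = error_correction_pct(table, m)
        rows.append(BehaviorSummary(
            cell=cell,
            n_trials=n,
            response_rate_pct=100.0 * n / denom if denom else float("nan"),
            multiple_responses_pct=100.0 * float(sub["multiple_response"].mean()),
            rt_ms=float(sub["rt"].mean()),
            peak_force_cn=float(sub[FORCE_COLS].to_numpy().max(axis=1).mean())
            if set(FORCE_COLS) <= set(table.columns) else float("nan"),
            pre_post_rt_diff_ms=pre_post_rt_diff(table, cell, label_column)[0],
            post_response_correct_pct=ppc,
            error_correction_pct=err_corr,
            eval_rt_ms=float(sub["eval_rt"].mean()),
            certainty_mean=float(sub["certainty"].mean()),
        ))
    return pd.DataFrame([r.__dict__ for r in rows])


def minimum_trial_filter(
    counts: pd.DataFrame | pd.Series, k: int = 6
) -> pd.Series:
    """Participant inclusion flags: included iff every required cell has
    strictly more than ``k`` trials (count 7 passes, count 6 fails)."""
    if isinstance(counts, pd.Series):
        return counts > k
    return (counts > k).all(axis=1)


# --------------------------------------------------------------------------
# part split
# --------------------------------------------------------------------------
def assign_parts(table: pd.DataFrame) -> pd.Series:
    """Within-condition median split into parts 1.1/1.2 (no-self-eval)
    and 2.1/2.2 (self-eval).

    Practice trials are excluded beforehand (part ``"none"``).  Within
    each condition the non-practice trials are split at the median trial
    position; an odd count puts the extra trial in the first half.
    """
    parts = pd.Series("none", index=table.index, dtype=object)
    prefix = {"no_self_eval": "1", "self_eval": "2"}
    for cond, sub in table.groupby("condition", sort=False):
        sub = sub[~sub.get("practice", pd.Series(False, index=sub.index)).astype(bool)]
        idx = sub.index.to_numpy()
        n = len(idx)
        n_first = (n + 1) // 2
        parts.loc[idx[:n_first]] = f"{prefix[cond]}.1"
        parts.loc[idx[n_first:]] = f"{prefix[cond]}.2"
    return parts
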