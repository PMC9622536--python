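"""Hand-built trial-table fixture with fully hand-computed expectations.

Twelve self-evaluation trials in one block.  Trial 6 exceeds the 1,200-ms
response limit (unlabeled, breaks pre/post adjacency); trial 4 is a
non-signaled error with an immediate correction press of the target key;
trial 12 is a signaled error with a second press of a non-target key.
"""

import numpy as np
import pandas as pd


def _forces(**keys):
    f = {f"force_k{i}": 5.0 for i in range(1, 9)}
    for k, v in keys.items():
        f[f"force_k{k[1:]}"] = float(v)
    return f


def hand_fixture_12():
    spec = [
        # rt, accuracy, eval, eval_rt, certainty, target, response, forces
        (500, "correct", "correct", 400, 4, 1, 1, _forces(k1=80)),
        (600, "error", "error", 700, 3, 1, 2, _forces(k2=70, k1=10)),
        (700, "correct", "correct", 400, 4, 3, 3, _forces(k3=90)),
        (550, "error", "correct", 600, 2, 5, 4, _forces(k4=60, k5=45)),
        (650, "correct", "correct", 400, 4, 1, 1, _forces(k1=50)),
        (1300, "correct", "correct", 400, 4, 2, 2, _forces(k2=55)),
        (600, "correct", "correct", 400, 4, 2, 2, _forces(k2=55)),
        (640, "error", "error", 720, 3, 2, 3, _forces(k3=45, k2=40)),
        (700, "correct", "correct", 400, 4, 4, 4, _forces(k4=85)),
        (620, "correct", "error", 400, 4, 5, 5, _forces(k5=60)),
        (580, "correct", "correct", 400, 4, 5, 5, _forces(k5=75)),
        (660, "error", "error", 740, 4, 8, 6, _forces(k6=50, k7=48)),
    ]
    rows = []
    for i, (rt, acc, ev, ert, cert, tgt, resp, forces) in enumerate(spec, 1):
        rows.append({
            "trial_id": f"t{i:02d}", "participant_id": "P01",
            "condition": "self_eval", "block": 1, "block_global": 1,
            "practice": False, "accuracy": acc, "rt": float(rt),
            "timeout": rt > 1200, "multiple_response": False,
            "eval_response": ev, "eval_rt": float(ert),
            "certainty": float(cert), "stimulus_onset_ms": -float(rt),
            "target_key": tgt, "response_key": resp, **forces,
        })
    table = pd.DataFrame(rows)

    expected = {
        "labels": ["signaled_correct", "signaled_error", "signaled_correct",
                   "nonsignaled_error", "signaled_correct", "unlabeled",
                   "signaled_correct", "signaled_error", "signaled_correct",
                   "nonsignaled_correct", "signaled_correct", "signaled_error"],
        "multiple_response": [False, False, False, True, False, False,
                              False, False, False, False, False, True],
        "response_rate_pct": {"signaled_correct": 60.0, "signaled_error": 30.0,
                              "nonsignaled_error": 10.0},
        "multiple_responses_pct": {"signaled_correct": 0.0,
                                   "signaled_error": 100.0 / 3,
                                   "nonsignaled_error": 100.0},
        "rt_ms": {"signaled_correct": 3730.0 / 6,
                  "signaled_error": 1900.0 / 3, "nonsignaled_error": 550.0},
        "peak_force_cn": {"signaled_correct": 72.5, "signaled_error": 55.0,
                          "nonsignaled_error": 60.0},
        # pre/post neighbors: t2 -> +200, t8 -> +100 (t12 is last); NSE
        # t4 -> -50; correct t3 -> -50, t9 -> -20, t11 -> +40 (t5 and t7
        # lose the timed-out neighbor t6, t1 has no predecessor)
        "pre_post": {"signaled_error": (150.0, 2),
                     "nonsignaled_error": (-50.0, 1),
                     "signaled_correct": (-10.0, 3)},
        "post_response_correct_pct": {"signaled_correct": 100.0 / 3,
                                      "signaled_error": 100.0,
                                      "nonsignaled_error": 100.0},
        "error_correction_pct": {"signaled_error": 0.0,
                                 "nonsignaled_error": 100.0},
        "eval_rt_ms": {"signaled_correct": 400.0, "signaled_error": 720.0,
                       "nonsignaled_error": 600.0},
        "certainty_mean": {"signaled_correct": 4.0, "signaled_error": 10.0 / 3,
                           "nonsignaled_error": 2.0},
    }
    return table, expected


def artifact_fixture_12(rng=None):
    """12 single-channel epochs, 3 of them with planted >100 µV excursions."""
    rng = np.random.default_rng(0) if rng is None else rng
    data = rng.normal(0.0, 10.0, size=(12, 1, 40))
    np.clip(data, -95.0, 95.0, out=data)
    hot = [1, 5, 10]
    for i in hot:
        data[i, 0, 7] = 130.0
    return data, hot
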