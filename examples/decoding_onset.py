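"""Time-resolved decoding of the self-evaluation condition.

Injects a condition-specific spatial pattern starting 400 ms before the
response, decodes no-self-evaluation vs self-evaluation trials in 10-ms
windows for a small cohort, and reports where decoding first exceeds
empirical chance — which should recover the injected onset.
"""

import dataclasses
import time
import warnings

import errmon as em

warnings.filterwarnings("ignore")
t0 = time.time()

ONSET = -400.0
recovered = em.studies.onset_recovery_run(
    ONSET, base_seed=3, n_participants=8, n_scalp=8, trials_per_condition=40)

print(f"injected condition-pattern onset: {ONSET:.0f} ms")
print(f"first Bonferroni-significant decoding window starts at: "
      f"{recovered:.0f} ms")
print(f"({time.time() - t0:.0f} s; 8 synthetic participants, 60 windows of "
      "10 ms, linear SVC vs shuffled-label chance)")
print("\nagreement within one 10-ms window means the decoding pipeline "
      "dates the emergence of condition information correctly.")
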