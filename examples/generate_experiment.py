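"""Generate a synthetic 8ART session and write it to disk.

Builds one participant with the full 394 + 704 trial layout (reduced
channel set to stay light), prints the trial-table structure, and saves
the epochs (HDF5 + JSON sidecar) and trial table (TSV).
"""

import errmon as em

layout = em.ExperimentLayout.default()
layout.scalp_channels = em.synthetic._spread_subset(16)
layout.epoch_span_ms = (-1000.0, 800.0)
truth = em.GroundTruth(seed=42, noise_sd=8.0)

epochs, table = em.generate_experiment(truth, layout, participant_id="P01")
table = em.add_derived_columns(table)
table["part"] = em.assign_parts(table)

print(f"epochs: {epochs.n_trials} trials x {len(epochs.channels)} channels "
      f"x {len(epochs.times)} samples ({epochs.times[0]:.0f}..{epochs.times[-1]:.0f} ms)")
print("\ntrials per condition:")
print(table["condition"].value_counts().to_string())
print("\nresponse types (self-evaluation part):")
print(table["response_type"].value_counts().to_string())
print("\nparts (median split, practice excluded):")
print(table["part"].value_counts().to_string())

from pathlib import Path

out = Path("scratch")
out.mkdir(exist_ok=True)
epochs.save(out / "example_epochs.h5")
em.write_trial_table(table, out / "example_trials.tsv")
print("\nwrote scratch/example_epochs.h5(+.json) and scratch/example_trials.tsv")
# the response-type counts above are what drives participant inclusion:
# a participant needs >6 non-signaled errors to enter response-type analyses
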