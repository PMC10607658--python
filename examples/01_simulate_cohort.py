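"""Generate a synthetic VR-training study and write it to disk.

The cohort mirrors the study design this pipeline targets: each
participant performs two exercises (Puzzle, Shooting) under three
environments (norm, arachnophobia, acrophobia), with 21-channel 500 Hz
EEG per scene.  A planted "abnormal" subgroup reacts to the phobic
scenes.  Here we generate a small cohort (6 participants, 5 s records)
and export EDF + CSV files.
"""

import tempfile
from pathlib import Path

from vrphobia import CohortConfig, export_cohort, generate_cohort

config = CohortConfig(n_participants=6, n_abnormal=1, record_duration=5.0, seed=42)
records = generate_cohort(config)

print(f"records generated: {len(records)} "
      f"({config.n_participants} participants x {len(config.scenes)} scenes)")
first = records[0]
print(f"first record: participant {first.participant_id}, "
      f"scene {first.scene.scene_id} ({first.scene.exercise}/{first.scene.environment})")
print(f"EEG shape: {first.eeg.data.shape} channels x samples at "
      f"{first.eeg.sampling_rate:.0f} Hz")
print(f"actions in log: {first.actions.n_actions}")

out = Path(tempfile.mkdtemp(prefix="vrphobia_cohort_"))
manifest = export_cohort(records, out, config)
print(f"cohort written to {out} (manifest: {manifest.name})")
# Each EDF file is one participant x scene recording; the manifest CSV maps
# files to the study design and carries the planted ground-truth labels.
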