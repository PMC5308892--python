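"""Generate a synthetic conditioning dataset and inspect its structure.

Builds one desk-scale session (two epochs, 5 CS-alone + 15 paired trials per
epoch, short ITIs) with a 20-unit mixed ensemble, then prints the schedule
and the unit manifest.
"""

import numpy as np

from ensemblecode import synthetic

config = synthetic.GeneratorConfig(
    n_sessions=1, n_cs_alone=5, n_paired=15,
    iti_range_ms=(4000.0, 6000.0), seed=1)
ensemble_spec = synthetic.EnsembleSpec.from_mixture(
    20, np.random.default_rng(2))

trials, emg, spike_set = synthetic.generate_dataset(config, ensemble_spec)

print(trials.head(8).to_string(index=False))
print(f"\n{len(trials)} trials; epoch modalities:",
      dict(trials.groupby('epoch')['condition'].first().str[:3]))
print(f"EMG: {len(emg[0].samples)} samples at {emg[0].sample_rate:.0f} Hz")
print(spike_set.manifest().head(6).to_string(index=False))
# Each unit's class determines how its firing differentiates the four
# conditions; the schedule alternates CS modality across the two epochs with
# CS-alone trials always preceding the paired block.
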