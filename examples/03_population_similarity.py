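"""Population-vector similarity: relational vs physical condition pairs.

Builds an ensemble of relational units (paired/alone gain shared across CS
modalities, heterogeneous across units), bins rates into the 50 ms grid with
max-normalization, and tests per bin whether the ensemble is more similar
along the relational axis (ACS-US vs VCS-US) than the physical axis
(ACS-US vs ACS-alone).
"""

import numpy as np

from ensemblecode import ensemble, spikes, synthetic

rng = np.random.default_rng(42)
specs = []
for i in range(40):
    sign = -1.0 if rng.uniform() < 0.5 else 1.0
    gain = float(np.exp(sign * abs(rng.normal(1.0, 0.3))))
    specs.append(synthetic.relational_spec(
        f"r{i}", baseline_rate=float(rng.lognormal(1.5, 0.5)),
        paired_gain=gain))
ens = synthetic.EnsembleSpec(tuple(specs), {"RELATIONAL": 1.0})

config = synthetic.GeneratorConfig(n_sessions=1, n_cs_alone=10, n_paired=30,
                                   iti_range_ms=(2500.0, 3500.0), seed=5)
rng_ds = np.random.default_rng(5)
trials = synthetic.make_trial_table(config, rng_ds)
spike_set = synthetic.simulate_spike_trains(trials, ens, rng_ds)

tensor = spikes.bin_rates(spike_set, trials, normalization="MAX")
result = ensemble.similarity_difference_permtest(
    tensor, n_perm=1000, rng=np.random.default_rng(1))
print(result.table.round(3).to_string(index=False))
# delta = r(ACS-US, VCS-US) - r(ACS-US, ACS-alone). For a relational
# ensemble the shared paired/alone tuning makes delta positive and
# significant (p <= 0.005, Bonferroni over the ten bins) in most bins.
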