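import numpy as np
import pytest

from ensemblecode import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_config(**overrides) -> synthetic.GeneratorConfig:
    """Desk-scale paradigm: same trial geometry, fewer trials, short ITIs."""
    defaults = dict(n_sessions=1, n_cs_alone=5, n_paired=15,
                    iti_range_ms=(2500.0, 3500.0), seed=0)
    defaults.update(overrides)
    return synthetic.GeneratorConfig(**defaults)


def heterogeneous_ensemble(n_per_class: int, rng: np.random.Generator,
                           classes=("RELATIONAL", "PHYSICAL"),
                           **spec_kwargs) -> synthetic.EnsembleSpec:
    """Ensembles with per-unit gain variability (sign and magnitude), the
    regime in which population-vector similarity carries structure."""
    specs = []
    for klass in classes:
        for i in range(n_per_class):
            sign = -1.0 if rng.uniform() < 0.5 else 1.0
            gain = float(np.exp(sign * abs(rng.normal(1.0, 0.3))))
            base = float(rng.lognormal(1.5, 0.5))
            if klass == "RELATIONAL":
                specs.append(synthetic.relational_spec(
                    f"r{i}", baseline_rate=base, paired_gain=gain, **spec_kwargs))
            elif klass == "PHYSICAL":
                specs.append(synthetic.physical_spec(
                    f"p{i}", baseline_rate=base, preferred_gain=gain,
                    preferred_modality=("ACS", "VCS")[i % 2], **spec_kwargs))
            elif klass == "NONSELECTIVE":
                specs.append(synthetic.nonselective_spec(
                    f"n{i}", baseline_rate=base,
                    gain=float(np.exp(abs(rng.normal(0.8, 0.3)))), **spec_kwargs))
            elif klass == "UNRESPONSIVE":
                specs.append(synthetic.unresponsive_spec(
                    f"u{i}", baseline_rate=base, **spec_kwargs))
    mixture = {k: 1.0 / len(classes) for k in classes}
    return synthetic.EnsembleSpec(tuple(specs), mixture)
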