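"""Synthetic trace eyeblink conditioning datasets.

Emulates the statistical structure of a dual trace eyeblink conditioning
experiment: daily sessions of two conditioning epochs (one per CS modality),
each epoch presenting CS-alone trials followed by CS-US paired trials; an
eyelid EMG channel in which conditioned responses (CRs) appear as bursts just
before the expected US; and ensembles of prefrontal units drawn from distinct
selectivity classes (relational, physical, conjunctive, non-selective,
unresponsive) whose differential firing magnitude and trial-to-trial
consistency can be scheduled per learning stage.

The generator exists so every downstream analysis stage — CR scoring,
rate-tensor construction, population similarity, decoding, single-neuron
selectivity — can be exercised end to end without any recorded data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "GeneratorConfig",
    "NeuronSpec",
    "EnsembleSpec",
    "EmgTrace",
    "SpikeTrain",
    "SpikeTrainSet",
    "CONDITIONS",
    "make_trial_table",
    "default_cr_schedule",
    "simulate_emg",
    "simulate_spike_trains",
    "generate_dataset",
    "relational_spec",
    "physical_spec",
    "conjunctive_spec",
    "nonselective_spec",
    "unresponsive_spec",
    "DEFAULT_MIXTURE",
]

#: Canonical four-condition label set: auditory/visual CS, alone or paired.
CONDITIONS = ("ACS_ALONE", "ACS_US", "VCS_ALONE", "VCS_US")

#: Default class mixture. Relational / physical / conjunctive proportions follow
#: the observed prevalence of each selectivity class in prelimbic recordings
#: (10.5 / 13.7 / 17.6 %); responsive-but-nonselective units fill the remainder
#: of the ~65% responsive fraction, and the rest are unresponsive.
DEFAULT_MIXTURE = {
    "RELATIONAL": 0.105,
    "PHYSICAL": 0.137,
    "CONJUNCTIVE": 0.176,
    "NONSELECTIVE": 0.233,
    "UNRESPONSIVE": 0.349,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Experiment-level parameters of the simulated conditioning paradigm.

    Defaults mirror the paradigm this package analyzes: two 100-trial epochs
    per daily session (20 CS-alone then 80 CS-US paired trials each), a 100 ms
    CS, a 500 ms stimulus-free trace interval, a 100 ms US, inter-trial
    intervals of 20-40 s, and eyelid EMG sampled at 6108 Hz.
    """

    n_sessions: int = 1
    epochs_per_session: int = 2
    n_cs_alone: int = 20
    n_paired: int = 80
    cs_duration_ms: float = 100.0
    trace_interval_ms: float = 500.0
    us_duration_ms: float = 100.0
    iti_range_ms: tuple[float, float] = (20_000.0, 40_000.0)
    emg_rate_hz: float = 6108.0
    emg_noise_sd: float = 1.0
    cr_burst_amplitude: float = 8.0
    learning_midpoint: float = 5.0
    learning_slope: float = 1.0
    hyperactive_prob: float = 0.05
    modalities: tuple[str, str] = ("ACS", "VCS")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sessions", "epochs_per_session", "n_cs_alone", "n_paired"):
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be a positive count")
        for name in ("cs_duration_ms", "trace_interval_ms", "us_duration_ms",
                     "emg_rate_hz", "emg_noise_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        lo, hi = self.iti_range_ms
        if not (0 < lo <= hi):
            raise ConfigurationError("iti_range_ms must satisfy 0 < low <= high")
        if not 0.0 <= self.hyperactive_prob <= 1.0:
            raise ConfigurationError("hyperactive_prob must be in [0, 1]")

    @property
    def us_onset_offset_s(self) -> float:
        """Seconds from CS onset to US onset (CS duration + trace interval)."""
        return (self.cs_duration_ms + self.trace_interval_ms) / 1000.0

    @property
    def trial_span_s(self) -> float:
        """Seconds from CS onset to the end of the US window."""
        return (self.cs_duration_ms + self.trace_interval_ms + self.us_duration_ms) / 1000.0


# ---------------------------------------------------------------------------
# neuron and ensemble specifications


@dataclass(frozen=True)
class NeuronSpec:
    """Rate model of one unit: baseline rate plus per-condition evoked gains.

    During the CS and trace windows of a trial in condition ``c`` the firing
    rate is ``baseline_rate * g_eff(c) * eps`` where
    ``g_eff(c) = 1 + (condition_gains[c] - 1) * stage_magnitude`` and ``eps``
    is a mean-one multiplicative log-normal noise whose sigma is
    ``trial_noise_sd * stage_consistency``; outside those windows the unit
    fires at its baseline rate. Degrading consistency therefore widens the
    trial-by-trial rate distribution without moving its mean, while the
    magnitude schedule scales the differential-firing contrast itself.
    """

    neuron_id: str
    neuron_class: str
    baseline_rate: float
    condition_gains: dict[str, float]
    trial_noise_sd: float = 0.2
    stage_magnitude_schedule: dict[str, float] = field(default_factory=dict)
    stage_consistency_schedule: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ConfigurationError("baseline_rate must be >= 0")
        if any(g < 0 for g in self.condition_gains.values()):
            raise ConfigurationError("condition_gains must be >= 0")
        if self.trial_noise_sd < 0:
            raise ConfigurationError("trial_noise_sd must be >= 0")

    def effective_gain(self, condition: str, stage: str | None) -> float:
        g = self.condition_gains[condition]
        mag = self.stage_magnitude_schedule.get(stage, 1.0) if stage else 1.0
        return max(0.0, 1.0 + (g - 1.0) * mag)

    def noise_sigma(self, stage: str | None) -> float:
        cons = self.stage_consistency_schedule.get(stage, 1.0) if stage else 1.0
        return self.trial_noise_sd * cons


def relational_spec(neuron_id: str, baseline_rate: float = 5.0,
                    paired_gain: float = 3.0, alone_gain: float = 1.0,
                    modalities: tuple[str, str] = ("ACS", "VCS"),
                    **kwargs) -> NeuronSpec:
    """Unit selective for stimulus relationship (paired vs alone), CS-invariant."""
    gains = {f"{m}_ALONE": alone_gain for m in modalities}
    gains.update({f"{m}_US": paired_gain for m in modalities})
    return NeuronSpec(neuron_id, "RELATIONAL", baseline_rate, gains, **kwargs)


def physical_spec(neuron_id: str, baseline_rate: float = 5.0,
                  preferred_gain: float = 3.0, other_gain: float = 1.0,
                  preferred_modality: str = "ACS",
                  modalities: tuple[str, str] = ("ACS", "VCS"),
                  **kwargs) -> NeuronSpec:
    """Unit selective for CS modality, pairing-invariant."""
    gains = {}
    for m in modalities:
        g = preferred_gain if m == preferred_modality else other_gain
        gains[f"{m}_ALONE"] = g
        gains[f"{m}_US"] = g
    return NeuronSpec(neuron_id, "PHYSICAL", baseline_rate, gains, **kwargs)


def conjunctive_spec(neuron_id: str, baseline_rate: float = 5.0,
                     preferred_condition: str = "ACS_US", gain: float = 3.0,
                     modalities: tuple[str, str] = ("ACS", "VCS"),
                     **kwargs) -> NeuronSpec:
    """Unit whose rate in one condition differs from all other conditions."""
    gains = {}
    for m in modalities:
        for suffix in ("ALONE", "US"):
            c = f"{m}_{suffix}"
            gains[c] = gain if c == preferred_condition else 1.0
    return NeuronSpec(neuron_id, "CONJUNCTIVE", baseline_rate, gains, **kwargs)


def nonselective_spec(neuron_id: str, baseline_rate: float = 5.0,
                      gain: float = 2.0,
                      modalities: tuple[str, str] = ("ACS", "VCS"),
                      **kwargs) -> NeuronSpec:
    """Responsive unit with identical evoked gain in every condition."""
    gains = {f"{m}_{s}": gain for m in modalities for s in ("ALONE", "US")}
    return NeuronSpec(neuron_id, "NONSELECTIVE", baseline_rate, gains, **kwargs)


def unresponsive_spec(neuron_id: str, baseline_rate: float = 5.0,
                      modalities: tuple[str, str] = ("ACS", "VCS"),
                      **kwargs) -> NeuronSpec:
    """Unit that ignores the task: unit gain everywhere."""
    gains = {f"{m}_{s}": 1.0 for m in modalities for s in ("ALONE", "US")}
    return NeuronSpec(neuron_id, "UNRESPONSIVE", baseline_rate, gains, **kwargs)


_SPEC_FACTORIES = {
    "RELATIONAL": relational_spec,
    "PHYSICAL": physical_spec,
    "CONJUNCTIVE": conjunctive_spec,
    "NONSELECTIVE": nonselective_spec,
    "UNRESPONSIVE": unresponsive_spec,
}


@dataclass(frozen=True)
class EnsembleSpec:
    """A population of NeuronSpecs with a declared class mixture."""

    neurons: tuple[NeuronSpec, ...]
    mixture: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIXTURE))

    def __post_init__(self) -> None:
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"mixture proportions must sum to 1 (got {total:.12g})")

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @classmethod
    def from_mixture(cls, n_neurons: int, rng: np.random.Generator,
                     mixture: dict[str, float] | None = None,
                     baseline_mean_hz: float = 5.0,
                     modalities: tuple[str, str] = ("ACS", "VCS"),
                     stage_magnitude_schedule: dict[str, float] | None = None,
                     stage_consistency_schedule: dict[str, float] | None = None,
                     trial_noise_sd: float = 0.2) -> "EnsembleSpec":
        """Draw ``n_neurons`` specs with classes sampled from ``mixture``.

        Baseline rates are log-normal with the given mean (a right-skewed rate
        distribution is the norm for cortical units). Evoked gains are drawn
        per unit with random sign (enhanced or suppressed responses) and
        log-normal magnitude, so the population carries heterogeneous tuning
        patterns — without that heterogeneity condition-mean population
        vectors would be flat across units and carry no similarity structure.
        Preferred modalities and conjunctive conditions are randomized.
        """
        mixture = dict(mixture or DEFAULT_MIXTURE)
        classes = list(mixture)
        probs = np.array([mixture[c] for c in classes], dtype=float)
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigurationError("mixture proportions must be >= 0 and sum to 1")
        sigma = 0.5
        mu = math.log(baseline_mean_hz) - sigma**2 / 2

        def draw_gain() -> float:
            sign = -1.0 if rng.uniform() < 0.5 else 1.0
            return float(math.exp(sign * abs(rng.normal(1.0, 0.3))))

        specs = []
        for i in range(int(n_neurons)):
            klass = classes[rng.choice(len(classes), p=probs)]
            base = float(rng.lognormal(mu, sigma))
            kwargs = dict(
                baseline_rate=base, modalities=modalities,
                trial_noise_sd=trial_noise_sd,
                stage_magnitude_schedule=dict(stage_magnitude_schedule or {}),
                stage_consistency_schedule=dict(stage_consistency_schedule or {}),
            )
            if klass == "RELATIONAL":
                kwargs["paired_gain"] = draw_gain()
            elif klass == "PHYSICAL":
                kwargs["preferred_modality"] = modalities[int(rng.integers(2))]
                kwargs["preferred_gain"] = draw_gain()
            elif klass == "CONJUNCTIVE":
                conds = [f"{m}_{s}" for m in modalities for s in ("ALONE", "US")]
                kwargs["preferred_condition"] = conds[int(rng.integers(len(conds)))]
                kwargs["gain"] = draw_gain()
            elif klass == "NONSELECTIVE":
                kwargs["gain"] = float(math.exp(abs(rng.normal(0.8, 0.3))))
            specs.append(_SPEC_FACTORIES[klass](f"u{i:04d}", **kwargs))
        return cls(tuple(specs), mixture)


# ---------------------------------------------------------------------------
# data containers


@dataclass
class EmgTrace:
    """One session's continuous eyelid EMG channel."""

    session_id: int
    sample_rate: float
    t0: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be positive")
        self.samples = np.asarray(self.samples, dtype=np.float32)

    def time_slice(self, t_start: float, t_stop: float) -> np.ndarray:
        """Samples in [t_start, t_stop) (absolute seconds, half-open)."""
        i0 = int(math.ceil((t_start - self.t0) * self.sample_rate - 1e-9))
        i1 = int(math.ceil((t_stop - self.t0) * self.sample_rate - 1e-9))
        return self.samples[max(i0, 0):max(i1, 0)]

    @property
    def t_end(self) -> float:
        return self.t0 + len(self.samples) / self.sample_rate


@dataclass
class SpikeTrain:
    """Sorted spike timestamps (absolute seconds) of one isolated unit."""

    unit_id: str
    timestamps: np.ndarray
    session_id: int = 0
    rat: str = "rat1"
    tetrode: int = 0
    neuron_class: str | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)

    @property
    def n_spikes(self) -> int:
        return len(self.timestamps)


@dataclass
class SpikeTrainSet:
    """Collection of spike trains plus a manifest accessor."""

    units: list[SpikeTrain]

    def __iter__(self):
        return iter(self.units)

    def __len__(self) -> int:
        return len(self.units)

    def __getitem__(self, i):
        return self.units[i]

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"unit_id": u.unit_id, "rat": u.rat, "session_id": u.session_id,
              "tetrode": u.tetrode, "n_spikes": u.n_spikes,
              "neuron_class": u.neuron_class} for u in self.units]
        )


# ---------------------------------------------------------------------------
# trial schedule


def make_trial_table(config: GeneratorConfig, rng: np.random.Generator,
                     box_ids: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Build the event schedule for all sessions.

    Each session has ``epochs_per_session`` epochs; each epoch presents
    ``n_cs_alone`` CS-alone trials followed by ``n_paired`` CS-US paired trials
    of a single CS modality. Which modality opens the session is
    pseudorandomized per session from the generator's RNG. ITIs (CS onset to
    next CS onset) are uniform over ``iti_range_ms``.
    """
    rows = []
    lo, hi = (config.iti_range_ms[0] / 1000.0, config.iti_range_ms[1] / 1000.0)
    t = 0.0
    for s in range(config.n_sessions):
        first = int(rng.integers(2))
        order = [config.modalities[(first + e) % 2]
                 for e in range(config.epochs_per_session)]
        t += 60.0  # settling gap before each session's first trial
        for e, modality in enumerate(order, start=1):
            for k in range(config.n_cs_alone + config.n_paired):
                paired = k >= config.n_cs_alone
                condition = f"{modality}_{'US' if paired else 'ALONE'}"
                rows.append({
                    "session_id": s, "epoch": e, "trial_index": k + 1,
                    "condition": condition, "cs_onset_s": t,
                    "box_id": box_ids[s % len(box_ids)] if box_ids else "box1",
                })
                t += float(rng.uniform(lo, hi))
            t += 600.0  # inter-epoch rest
    table = pd.DataFrame(rows)
    table["paired"] = table["condition"].str.endswith("_US")
    return table


def default_cr_schedule(config: GeneratorConfig) -> dict[tuple[int, str], float]:
    """Sigmoid learning trajectory of CR probability for paired conditions.

    CR probability in paired conditions follows a logistic curve over sessions
    (floor 5%, ceiling 90%); CS-alone conditions stay at the floor, matching
    the flat CS-alone CR% seen behaviorally.
    """
    sched = {}
    for s in range(config.n_sessions):
        p_paired = 0.05 + 0.85 / (1.0 + math.exp(
            -config.learning_slope * (s - config.learning_midpoint)))
        for m in config.modalities:
            sched[(s, f"{m}_US")] = p_paired
            sched[(s, f"{m}_ALONE")] = 0.05
    return sched


# ---------------------------------------------------------------------------
# EMG simulation


def _burst(n: int, sample_rate: float, amplitude: float,
           rng: np.random.Generator, freq_hz: float = 150.0) -> np.ndarray:
    """Oscillatory EMG-like burst with a smooth on/off envelope."""
    t = np.arange(n) / sample_rate
    envelope = np.sin(np.linspace(0.0, math.pi, n)) ** 0.25  # fast rise/fall
    phase = rng.uniform(0, 2 * math.pi)
    carrier = np.sin(2 * math.pi * freq_hz * t + phase)
    jitter = rng.normal(0.0, 0.3, n)
    return amplitude * envelope * (carrier + jitter)


def simulate_emg(trial_table: pd.DataFrame,
                 cr_probability: dict[tuple[int, str], float],
                 config: GeneratorConfig,
                 rng: np.random.Generator) -> dict[int, EmgTrace]:
    """Synthesize one continuous EMG trace per session.

    Baseline is zero-mean Gaussian noise. On CR trials a burst fills the
    200 ms immediately before (expected) US onset; on hyperactive trials a
    burst occupies most of the 300 ms pre-CS window (grooming-like artifact,
    with log-normal amplitude variability); paired trials get a saturated
    100 ms US stimulation artifact.
    """
    for p in cr_probability.values():
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError("cr_probability values must be in [0, 1]")
    fs = config.emg_rate_hz
    us_off = config.us_onset_offset_s
    traces: dict[int, EmgTrace] = {}
    for session_id, sess in trial_table.groupby("session_id", sort=True):
        t0 = float(sess["cs_onset_s"].min()) - 5.0
        t_end = float(sess["cs_onset_s"].max()) + config.trial_span_s + 5.0
        n = int(math.ceil((t_end - t0) * fs))
        samples = rng.normal(0.0, config.emg_noise_sd, n).astype(np.float32)

        def put(t_start: float, t_stop: float, burst_amp: float | None,
                saturate: float | None = None) -> None:
            # same half-open index convention as EmgTrace.time_slice, so an
            # event ending at t is fully outside a window starting at t
            i0 = max(0, int(math.ceil((t_start - t0) * fs - 1e-9)))
            i1 = min(n, int(math.ceil((t_stop - t0) * fs - 1e-9)))
            if i1 <= i0:
                return
            if saturate is not None:
                square = np.sign(np.sin(2 * math.pi * 60.0
                                        * np.arange(i1 - i0) / fs) + 1e-12)
                samples[i0:i1] = saturate * square
            else:
                samples[i0:i1] += _burst(i1 - i0, fs, burst_amp, rng)

        for row in sess.itertuples():
            cs = row.cs_onset_s
            us = cs + us_off
            p_cr = cr_probability.get((row.session_id, row.condition), 0.0)
            if rng.uniform() < config.hyperactive_prob:
                amp = config.cr_burst_amplitude * float(rng.lognormal(0.0, 0.3))
                put(cs - 0.30, cs - 0.02, amp)
            if rng.uniform() < p_cr:
                put(us - 0.20, us, config.cr_burst_amplitude * config.emg_noise_sd)
            if row.paired:
                put(us, us + config.us_duration_ms / 1000.0, None,
                    saturate=40.0 * config.emg_noise_sd)
        traces[int(session_id)] = EmgTrace(int(session_id), fs, t0, samples)
    return traces


# ---------------------------------------------------------------------------
# spike-train simulation


def simulate_spike_trains(trial_table: pd.DataFrame, ensemble: EnsembleSpec,
                          rng: np.random.Generator,
                          stage_schedule: dict[int, str] | None = None,
                          rat: str = "rat1",
                          stimulus_window_s: float = 0.6) -> SpikeTrainSet:
    """Draw inhomogeneous-Poisson spike trains for every (session, unit) pair.

    Rate is ``baseline`` everywhere except during each trial's CS + trace
    window (CS onset to US onset), where it is scaled by the unit's effective
    condition gain and a per-trial multiplicative log-normal noise (mean one).
    ITI spiking is present throughout so responsiveness contrasts have a
    baseline. Every unit is instantiated independently per session, emulating
    day-to-day resampling of a stable population.
    """
    stage_schedule = stage_schedule or {}
    conds = trial_table["condition"].unique()
    for spec in ensemble.neurons:
        missing = [c for c in conds if c not in spec.condition_gains]
        if missing:
            raise ConfigurationError(
                f"neuron {spec.neuron_id} lacks gain entries for {missing}")
    units: list[SpikeTrain] = []
    for session_id, sess in trial_table.groupby("session_id", sort=True):
        stage = stage_schedule.get(int(session_id))
        t0 = float(sess["cs_onset_s"].min()) - 30.0
        t_end = float(sess["cs_onset_s"].max()) + 30.0
        cs_onsets = sess["cs_onset_s"].to_numpy()
        # gains apply over the CS + trace window (600 ms in the default
        # 100 ms CS / 500 ms trace paradigm)
        window_s = stimulus_window_s
        conditions = sess["condition"].to_numpy()
        for spec in ensemble.neurons:
            base = spec.baseline_rate
            # homogeneous baseline over the whole session
            n_base = rng.poisson(base * (t_end - t0))
            ts = rng.uniform(t0, t_end, n_base)
            # excise baseline spikes inside trial windows, replace with
            # window-specific draws at the modulated rate
            in_window = np.zeros(len(ts), dtype=bool)
            for cs in cs_onsets:
                in_window |= (ts >= cs) & (ts < cs + window_s)
            ts = ts[~in_window]
            extra = []
            sigma = spec.noise_sigma(stage)
            for cs, cond in zip(cs_onsets, conditions):
                gain = spec.effective_gain(cond, stage)
                eps = float(rng.lognormal(-sigma**2 / 2.0, sigma)) if sigma > 0 else 1.0
                lam = base * gain * eps * window_s
                k = rng.poisson(lam)
                if k:
                    extra.append(cs + rng.uniform(0.0, window_s, k))
            if extra:
                ts = np.concatenate([ts] + extra)
            ts.sort()
            units.append(SpikeTrain(
                unit_id=f"s{int(session_id)}_{spec.neuron_id}",
                timestamps=ts, session_id=int(session_id), rat=rat,
                tetrode=sum(spec.neuron_id.encode()) % 14,
                neuron_class=spec.neuron_class))
    return SpikeTrainSet(units)


def generate_dataset(config: GeneratorConfig, ensemble: EnsembleSpec,
                     stage_schedule: dict[int, str] | None = None,
                     cr_probability: dict[tuple[int, str], float] | None = None,
                     ) -> tuple[pd.DataFrame, dict[int, EmgTrace], SpikeTrainSet]:
    """Generate a complete synthetic dataset (schedule, EMG, spikes).

    All randomness derives from ``config.seed``; identical configurations
    reproduce identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    trial_table = make_trial_table(config, rng)
    cr_probability = cr_probability or default_cr_schedule(config)
    emg = simulate_emg(trial_table, cr_probability, config, rng)
    spikes = simulate_spike_trains(trial_table, ensemble, rng,
                                   stage_schedule=stage_schedule)
    return trial_table, emg, spikes
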