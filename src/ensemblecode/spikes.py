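"""Unit quality control and event-aligned binned firing-rate tensors.

Units enter the analysis only if they are plausibly single, well-isolated
neurons: fewer than 1% of inter-spike intervals inside a 2 ms refractory
period and more than 1500 spikes over the recording session.

Rates are binned on a trial-aligned grid of half-open windows relative to CS
onset (default 50 ms bins over [-400, 600) ms) and may be left raw (Hz),
max-normalized (each unit divided by its maximum condition-mean binned rate
across the four conditions), or z-scored against the 1 s pre-CS baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, CorruptInputError
from .synthetic import SpikeTrain, SpikeTrainSet

__all__ = ["UnitQcReport", "unit_qc", "qc_filter", "RateTensor", "bin_rates",
           "trial_window_rates"]


@dataclass(frozen=True)
class UnitQcReport:
    unit_id: str
    n_spikes: int
    isi_violation_fraction: float
    passed: bool
    reason: str = ""


def unit_qc(train: SpikeTrain, refractory_ms: float = 2.0,
            min_spikes: int = 1500, max_violation_fraction: float = 0.01
            ) -> UnitQcReport:
    """Single-unit inclusion check.

    Passes iff the ISI-violation fraction (ISIs shorter than the refractory
    period) is below ``max_violation_fraction`` and the unit fired strictly
    more than ``min_spikes`` spikes.
    """
    ts = train.timestamps
    if np.any(np.diff(ts) < 0):
        raise CorruptInputError(f"unit {train.unit_id}: timestamps not sorted")
    n = len(ts)
    if n < 2:
        return UnitQcReport(train.unit_id, n, 0.0, False,
                            reason=f"only {n} spikes; ISIs undefined")
    isis = np.diff(ts)
    frac = float(np.mean(isis < refractory_ms / 1000.0))
    ok_isi = frac < max_violation_fraction
    ok_count = n > min_spikes
    reason = "" if (ok_isi and ok_count) else (
        f"isi_violation_fraction={frac:.4f}" if not ok_isi
        else f"n_spikes={n} <= {min_spikes}")
    return UnitQcReport(train.unit_id, n, frac, ok_isi and ok_count, reason)


def qc_filter(spike_set: SpikeTrainSet, **kwargs) -> tuple[SpikeTrainSet, pd.DataFrame]:
    """Apply :func:`unit_qc` to every unit; return passing units and the report."""
    reports = [unit_qc(u, **kwargs) for u in spike_set]
    keep = [u for u, r in zip(spike_set, reports) if r.passed]
    report = pd.DataFrame([r.__dict__ for r in reports])
    return SpikeTrainSet(keep), report


@dataclass
class RateTensor:
    """Binned firing rates on a (unit, trial, time-bin) grid.

    ``values`` holds rates after the declared normalization; the per-unit
    normalization constants (max rate, or baseline mean/SD) are retained so
    raw rates remain recoverable.
    """

    values: np.ndarray               # (n_units, n_trials, n_bins)
    unit_ids: list[str]
    trial_table: pd.DataFrame        # rows aligned with the trial axis
    bin_edges_ms: np.ndarray         # (n_bins + 1,), relative to CS onset
    normalization: str               # RAW | MAX | ZSCORE_BASELINE
    norm_constants: dict = field(default_factory=dict)
    warnings_: list = field(default_factory=list)

    @property
    def conditions(self) -> np.ndarray:
        return self.trial_table["condition"].to_numpy()

    @property
    def bin_width_ms(self) -> float:
        return float(self.bin_edges_ms[1] - self.bin_edges_ms[0])

    def condition_mean(self, condition: str) -> np.ndarray:
        """(unit, bin) mean matrix over trials of one condition."""
        mask = self.conditions == condition
        if not mask.any():
            raise ConfigurationError(f"no trials of condition {condition!r}")
        return self.values[:, mask, :].mean(axis=1)

    def sort_order(self, condition: str = "ACS_US",
                   window_ms: tuple[float, float] = (100.0, 600.0),
                   baseline_ms: tuple[float, float] = (-400.0, 0.0)) -> np.ndarray:
        """Unit order by trace-window rate change in ``condition``, descending."""
        mat = self.condition_mean(condition)
        centers = (self.bin_edges_ms[:-1] + self.bin_edges_ms[1:]) / 2.0
        win = (centers >= window_ms[0]) & (centers < window_ms[1])
        base = (centers >= baseline_ms[0]) & (centers < baseline_ms[1])
        change = mat[:, win].mean(axis=1) - mat[:, base].mean(axis=1)
        return np.argsort(-change, kind="stable")


def _bin_counts(ts: np.ndarray, cs_onsets: np.ndarray,
                edges_s: np.ndarray) -> np.ndarray:
    """Spike counts per (trial, bin) on half-open bins; a spike at an upper
    edge belongs to the next bin."""
    abs_edges = cs_onsets[:, None] + edges_s[None, :]
    idx = np.searchsorted(ts, abs_edges, side="left")
    return np.diff(idx, axis=1).astype(float)


def bin_rates(spike_set: SpikeTrainSet, trial_table: pd.DataFrame,
              window_ms: tuple[float, float] = (-400.0, 600.0),
              bin_ms: float = 50.0, normalization: str = "RAW",
              baseline_window_ms: tuple[float, float] = (-1000.0, 0.0),
              conditions: tuple[str, ...] | None = None) -> RateTensor:
    """Build a RateTensor for all units over all trials in ``trial_table``.

    Raw rates are spike counts per bin divided by the bin width (Hz). MAX
    normalization divides each unit by the maximum of its condition-mean
    binned-rate matrices across conditions (all-zero units are emitted as
    zeros with a warning record). ZSCORE_BASELINE standardizes each unit
    against the mean/SD of its binned rates in the 1 s pre-CS baseline pooled
    across trials (zero-SD units are emitted as zeros with a warning record).
    """
    lo, hi = window_ms
    n_bins_f = (hi - lo) / bin_ms
    if abs(n_bins_f - round(n_bins_f)) > 1e-9:
        raise ConfigurationError(
            f"bin_ms={bin_ms} does not tile window {window_ms}")
    n_bins = int(round(n_bins_f))
    edges_ms = lo + bin_ms * np.arange(n_bins + 1)
    edges_s = edges_ms / 1000.0
    cs = trial_table["cs_onset_s"].to_numpy()
    values = np.empty((len(spike_set), len(cs), n_bins))
    for i, unit in enumerate(spike_set):
        values[i] = _bin_counts(unit.timestamps, cs, edges_s) / (bin_ms / 1000.0)

    tensor = RateTensor(values=values,
                        unit_ids=[u.unit_id for u in spike_set],
                        trial_table=trial_table.reset_index(drop=True),
                        bin_edges_ms=edges_ms,
                        normalization="RAW")

    norm = normalization.upper()
    if norm == "RAW":
        return tensor
    if norm == "MAX":
        conds = conditions or tuple(pd.unique(tensor.conditions))
        cond_means = np.stack([tensor.condition_mean(c) for c in conds])
        maxima = cond_means.max(axis=(0, 2))  # per unit
        out = np.zeros_like(values)
        for i, m in enumerate(maxima):
            if m > 0:
                out[i] = values[i] / m
            else:
                tensor.warnings_.append(
                    f"unit {tensor.unit_ids[i]}: zero max rate; emitted as zeros")
        tensor.values = out
        tensor.normalization = "MAX"
        tensor.norm_constants = {"max_rate_hz": maxima}
        return tensor
    if norm == "ZSCORE_BASELINE":
        blo, bhi = baseline_window_ms
        nb = (bhi - blo) / bin_ms
        if abs(nb - round(nb)) > 1e-9:
            raise ConfigurationError("bin_ms does not tile baseline window")
        bedges_s = (blo + bin_ms * np.arange(int(round(nb)) + 1)) / 1000.0
        mu = np.empty(len(spike_set))
        sd = np.empty(len(spike_set))
        out = np.zeros_like(values)
        for i, unit in enumerate(spike_set):
            base = _bin_counts(unit.timestamps, cs, bedges_s) / (bin_ms / 1000.0)
            mu[i], sd[i] = base.mean(), base.std(ddof=0)
            if sd[i] > 0:
                out[i] = (values[i] - mu[i]) / sd[i]
            else:
                tensor.warnings_.append(
                    f"unit {tensor.unit_ids[i]}: zero baseline SD; emitted as zeros")
        tensor.values = out
        tensor.normalization = "ZSCORE_BASELINE"
        tensor.norm_constants = {"baseline_mean_hz": mu, "baseline_sd_hz": sd}
        return tensor
    raise ConfigurationError(f"unknown normalization {normalization!r}")


def trial_window_rates(spike_set: SpikeTrainSet, trial_table: pd.DataFrame,
                       window_ms: tuple[float, float] = (100.0, 600.0)
                       ) -> np.ndarray:
    """(unit, trial) mean firing rates (Hz) over a single half-open window.

    The default window spans CS offset to US onset (the trace interval),
    the substrate for decoding features and single-neuron selectivity.
    """
    lo, hi = window_ms
    if hi <= lo:
        raise ConfigurationError("window_ms must satisfy start < end")
    edges_s = np.array([lo, hi]) / 1000.0
    cs = trial_table["cs_onset_s"].to_numpy()
    rates = np.empty((len(spike_set), len(cs)))
    for i, unit in enumerate(spike_set):
        rates[i] = _bin_counts(unit.timestamps, cs, edges_s)[:, 0] / ((hi - lo) / 1000.0)
    return rates
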