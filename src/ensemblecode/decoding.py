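"""Permutation-calibrated SVM decoding of condition from population firing.

The decoder asks how well trial condition can be read out from a
pseudo-population firing vector (one normalized rate per unit, default over
the first 200 ms after CS offset). One SVM run draws 20 trials per condition
without replacement, max-normalizes each unit over the 80 sampled trials,
splits 10/10 per condition into train and test, selects RBF-kernel
hyperparameters (cost, gamma) by grid search under 5-fold cross-validation on
the training half, and scores the held-out half. Runs are repeated with fresh
samplings to build a confusion matrix.

Chance is calibrated per classifier by repeating the identical procedure 50
times with condition labels randomly reassigned; each repetition yields 40
held-out readouts, giving a 2000-readout chance distribution. Raw accuracy is
significant when it falls in the upper 5% tail, and relative accuracy is raw
accuracy minus that 5% cutoff. Stage comparisons use 20 independent sets of
150 units sampled from a stage's pool; binary variants collapse the four
conditions along the relational (alone vs paired) or physical (auditory vs
visual) axis before training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .errors import ConfigurationError, InsufficientTrialsError
from .synthetic import SpikeTrainSet
from .spikes import trial_window_rates

__all__ = [
    "DEFAULT_GRID", "REDUCED_GRID", "DecodingRun", "ChanceDistribution",
    "DecodingResult", "decode_once", "decode_repeated", "chance_calibration",
    "decode_stage", "collapse_labels", "sweep_parameters",
]

#: Standard LIBSVM practice-guide log2 grid.
DEFAULT_GRID = {
    "cost": 2.0 ** np.arange(-5, 16, 2, dtype=float),
    "gamma": 2.0 ** np.arange(-15, 4, 2, dtype=float),
}
#: Coarse 3x3 subgrid for desk-scale calibration runs.
REDUCED_GRID = {
    "cost": 2.0 ** np.array([-1.0, 3.0, 7.0]),
    "gamma": 2.0 ** np.array([-7.0, -3.0, 1.0]),
}

LABELINGS = ("FOURWAY", "RELATIONAL_BINARY", "PHYSICAL_BINARY", "BOX_BINARY")


def collapse_labels(labels: np.ndarray, labeling: str) -> np.ndarray:
    """Map four-condition labels onto a binary axis (or leave them as is).

    RELATIONAL_BINARY: CS-alone vs CS-US paired, regardless of modality.
    PHYSICAL_BINARY:   auditory vs visual CS, regardless of pairing.
    BOX_BINARY:        conditioning-box identity (label suffix after 'B').
    """
    labels = np.asarray(labels)
    if labeling == "FOURWAY":
        return labels.copy()
    if labeling == "RELATIONAL_BINARY":
        return np.where(np.char.endswith(labels.astype(str), "_US"),
                        "PAIRED", "ALONE")
    if labeling == "PHYSICAL_BINARY":
        return np.array([l.split("_")[0] for l in labels.astype(str)])
    if labeling == "BOX_BINARY":
        out = []
        for l in labels.astype(str):
            tok = [t for t in l.split("_") if t.startswith("B") and t[1:].isdigit()]
            if not tok:
                raise ConfigurationError(f"label {l!r} carries no box token")
            out.append(tok[0])
        return np.array(out)
    raise ConfigurationError(f"unknown labeling {labeling!r}")


@dataclass
class DecodingRun:
    """One SVM run: sampling, normalization, model selection, held-out score."""

    trial_ids: np.ndarray
    test_ids: np.ndarray
    norm_constants: np.ndarray
    cost: float
    gamma: float
    cv_accuracy: float
    accuracy: float
    confusion: pd.DataFrame           # rows true, cols predicted (counts)
    readout_correct: np.ndarray       # per-test-trial 0/1


@dataclass
class ChanceDistribution:
    """Label-shuffled accuracy distribution for one classifier."""

    accuracies: np.ndarray            # one per shuffled repetition
    readout_correct: np.ndarray       # pooled per-readout 0/1
    n_readouts_per_rep: int

    def cutoff(self, method: str = "per_repetition", q: float = 95.0) -> float:
        """Upper-tail accuracy cutoff.

        ``per_repetition`` (default): the q-th percentile of the per-repetition
        accuracies. ``pooled``: a binomial-smoothed cutoff from the pooled
        per-readout success rate (quantile of Binomial(n_readouts, p)/n).
        """
        if method == "per_repetition":
            return float(np.percentile(self.accuracies, q))
        if method == "pooled":
            from scipy.stats import binom
            p = float(self.readout_correct.mean())
            n = self.n_readouts_per_rep
            return float(binom.ppf(q / 100.0, n, p) / n)
        raise ConfigurationError(f"unknown cutoff method {method!r}")


def _grid_search(x: np.ndarray, y: np.ndarray, grid: dict,
                 n_folds: int = 5) -> tuple[float, float, float]:
    """Stratified k-fold CV over (cost, gamma); ties break to the smallest
    cost, then the smallest gamma. Returns (cost, gamma, cv_accuracy)."""
    classes, y_idx = np.unique(y, return_inverse=True)
    folds = np.empty(len(y), dtype=int)
    for c in range(len(classes)):
        idx = np.nonzero(y_idx == c)[0]
        folds[idx] = np.arange(len(idx)) % n_folds
    best = (None, None, -1.0)
    for cost in np.sort(np.asarray(grid["cost"], dtype=float)):
        for gamma in np.sort(np.asarray(grid["gamma"], dtype=float)):
            correct = 0
            for f in range(n_folds):
                tr = folds != f
                if tr.all():      # fold empty at very small n
                    continue
                clf = SVC(C=cost, gamma=gamma, kernel="rbf")
                clf.fit(x[tr], y_idx[tr])
                correct += int((clf.predict(x[~tr]) == y_idx[~tr]).sum())
            acc = correct / len(y)
            if acc > best[2]:
                best = (cost, gamma, acc)
    return best


def decode_once(features: np.ndarray, labels: np.ndarray,
                rng: np.random.Generator, grid: dict | None = None,
                n_per_condition: int = 20, n_train_per_condition: int = 10,
                sample_labels: np.ndarray | None = None) -> DecodingRun:
    """One complete SVM run on a trial pool.

    ``features`` is (n_trials, n_units); ``labels`` the classification target.
    ``sample_labels`` (default: ``labels``) controls the stratified sampling
    of ``n_per_condition`` trials per condition, so binary collapses can keep
    sampling balanced across the original four conditions.
    """
    grid = grid or DEFAULT_GRID
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(features)):
        raise ConfigurationError("features must be finite")
    sample_labels = labels if sample_labels is None else np.asarray(sample_labels)

    sampled = []
    for cond in np.unique(sample_labels):
        idx = np.nonzero(sample_labels == cond)[0]
        if len(idx) < n_per_condition:
            raise InsufficientTrialsError(
                f"condition {cond!r} has {len(idx)} trials; "
                f"{n_per_condition} required")
        sampled.append(rng.choice(idx, size=n_per_condition, replace=False))
    sampled = np.concatenate(sampled)

    x = features[sampled]
    y = labels[sampled]
    # per-unit max normalization over the sampled trials; silent units
    # contribute zeros rather than dividing by zero
    maxima = x.max(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.where(maxima > 0, x / np.where(maxima > 0, maxima, 1.0), 0.0)

    train_mask = np.zeros(len(y), dtype=bool)
    frac = n_train_per_condition / n_per_condition
    for cond in np.unique(y):
        idx = np.nonzero(y == cond)[0]
        n_train = int(round(len(idx) * frac))
        train_mask[rng.choice(idx, size=n_train, replace=False)] = True

    cost, gamma, cv_acc = _grid_search(x[train_mask], y[train_mask], grid)
    clf = SVC(C=cost, gamma=gamma, kernel="rbf")
    clf.fit(x[train_mask], y[train_mask])
    pred = clf.predict(x[~train_mask])
    truth = y[~train_mask]
    correct = (pred == truth).astype(int)

    classes = np.unique(y)
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(truth, pred):
        conf.loc[t, p] += 1
    return DecodingRun(
        trial_ids=sampled, test_ids=sampled[~train_mask],
        norm_constants=maxima, cost=cost, gamma=gamma, cv_accuracy=cv_acc,
        accuracy=float(correct.mean()), confusion=conf,
        readout_correct=correct)


def decode_repeated(features: np.ndarray, labels: np.ndarray,
                    rng: np.random.Generator, n_repeats: int = 20,
                    **kwargs) -> tuple[list[DecodingRun], pd.DataFrame]:
    """Repeat :func:`decode_once` with fresh samplings; aggregate confusion.

    Returns the runs and the mean confusion matrix expressed as row-stochastic
    proportions (fraction of test trials of a true condition classified as
    each condition).
    """
    runs = [decode_once(features, labels, rng, **kwargs)
            for _ in range(n_repeats)]
    total = sum(r.confusion for r in runs)
    props = total.div(total.sum(axis=1), axis=0)
    return runs, props


def chance_calibration(features: np.ndarray, labels: np.ndarray,
                       rng: np.random.Generator, n_shuffles: int = 50,
                       **kwargs) -> ChanceDistribution:
    """Chance-performance distribution by label shuffling.

    The full decode procedure is repeated ``n_shuffles`` times after randomly
    reassigning a condition label to every trial; each repetition contributes
    its held-out readouts (40 with the default 10-per-condition test half of
    four conditions), pooling to a 2000-readout chance distribution at the
    defaults.
    """
    labels = np.asarray(labels)
    sample_labels = kwargs.pop("sample_labels", None)
    accs, readouts = [], []
    for _ in range(n_shuffles):
        shuffled = rng.permutation(labels)
        run = decode_once(features, shuffled, rng,
                          sample_labels=sample_labels, **kwargs)
        accs.append(run.accuracy)
        readouts.append(run.readout_correct)
    readouts = np.concatenate(readouts)
    return ChanceDistribution(np.asarray(accs), readouts,
                              n_readouts_per_rep=len(readouts) // n_shuffles)


@dataclass
class DecodingResult:
    """Stage-level decoding summary across neuron sets."""

    stage: str
    labeling: str
    n_neurons: int
    n_sets: int
    raw_accuracy: np.ndarray          # mean raw accuracy per set
    chance_cutoff: np.ndarray         # per set
    relative_accuracy: np.ndarray     # raw - cutoff, per set
    confusion_mean: pd.DataFrame
    notes: list = field(default_factory=list)

    @property
    def mean_relative(self) -> float:
        return float(self.relative_accuracy.mean())

    @property
    def sem_relative(self) -> float:
        n = len(self.relative_accuracy)
        if n < 2:
            return 0.0
        return float(self.relative_accuracy.std(ddof=1) / np.sqrt(n))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "set": np.arange(1, self.n_sets + 1),
            "raw": self.raw_accuracy,
            "chance_cutoff": self.chance_cutoff,
            "relative": self.relative_accuracy,
        })


def _pseudo_population(unit_rates: np.ndarray, labels: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Shuffle each unit's trials independently within condition.

    Units come from different sessions, so trial pairing across units is
    arbitrary; re-pairing uniformly at random discards any correlated
    activity, as a pseudo-population construction must.
    """
    out = np.empty_like(unit_rates)
    for cond in np.unique(labels):
        idx = np.nonzero(labels == cond)[0]
        for u in range(unit_rates.shape[0]):
            out[u, idx] = unit_rates[u, rng.permutation(idx)]
    return out


def decode_stage(unit_rates: np.ndarray, labels: np.ndarray, stage: str,
                 labeling: str = "FOURWAY", n_sets: int = 20,
                 n_neurons: int = 150, n_repeats: int = 20,
                 n_chance_shuffles: int = 50,
                 rng: np.random.Generator | None = None,
                 grid: dict | None = None,
                 cutoff_method: str = "per_repetition",
                 **decode_kwargs) -> DecodingResult:
    """Relative decoding accuracy for one stage and labeling.

    ``unit_rates`` is (n_units_pool, n_trials) of trace-window rates; per set,
    ``n_neurons`` units are sampled from the pool, trials re-paired at random
    within condition (pseudo-population), the decode repeated ``n_repeats``
    times, and chance calibrated by ``n_chance_shuffles`` label shuffles.
    Relative accuracy is the set's mean raw accuracy minus its 95% chance
    cutoff.
    """
    if labeling not in LABELINGS:
        raise ConfigurationError(f"unknown labeling {labeling!r}")
    rng = rng or np.random.default_rng()
    unit_rates = np.asarray(unit_rates, dtype=float)
    labels = np.asarray(labels)
    target = collapse_labels(labels, labeling)
    pool = unit_rates.shape[0]
    notes = []
    if pool < n_neurons:
        notes.append(f"pool of {pool} units < requested {n_neurons}; using {pool}")
        n_neurons = pool

    raw, cut, confs = [], [], []
    for _ in range(n_sets):
        chosen = rng.choice(pool, size=n_neurons, replace=False)
        feats = _pseudo_population(unit_rates[chosen], labels, rng).T
        runs, conf = decode_repeated(feats, target, rng, n_repeats=n_repeats,
                                     grid=grid, sample_labels=labels,
                                     **decode_kwargs)
        chance = chance_calibration(feats, target, rng,
                                    n_shuffles=n_chance_shuffles, grid=grid,
                                    sample_labels=labels, **decode_kwargs)
        raw.append(np.mean([r.accuracy for r in runs]))
        cut.append(chance.cutoff(cutoff_method))
        confs.append(conf)
    raw = np.asarray(raw)
    cut = np.asarray(cut)
    conf_mean = sum(confs) / len(confs)
    return DecodingResult(stage=stage, labeling=labeling, n_neurons=n_neurons,
                          n_sets=n_sets, raw_accuracy=raw, chance_cutoff=cut,
                          relative_accuracy=raw - cut, confusion_mean=conf_mean,
                          notes=notes)


def sweep_parameters(spike_set: SpikeTrainSet, trial_table: pd.DataFrame,
                     rng: np.random.Generator,
                     bin_sizes_ms: tuple[float, ...] = (200.0, 100.0, 50.0),
                     window_starts_ms: tuple[float, ...] = (100.0,),
                     ensemble_sizes: tuple[int, ...] | None = None,
                     n_repeats: int = 5, n_chance_shuffles: int = 20,
                     grid: dict | None = None,
                     **decode_kwargs) -> pd.DataFrame:
    """Decoding accuracy as a function of bin size, window position and
    ensemble size.

    For each (bin size, window start), features are the mean rates in
    ``[start, start + bin)`` ms from CS onset; for each ensemble size, that
    many units are sampled once from the pool. Returns a tidy table with raw
    accuracy (mean and SD over repeats) and the chance cutoff.
    """
    labels = trial_table["condition"].to_numpy()
    rows = []
    for bin_ms in bin_sizes_ms:
        for start in window_starts_ms:
            rates = trial_window_rates(spike_set, trial_table,
                                       window_ms=(start, start + bin_ms))
            sizes = ensemble_sizes or (rates.shape[0],)
            for size in sizes:
                if size > rates.shape[0]:
                    raise ConfigurationError(
                        f"ensemble size {size} exceeds pool {rates.shape[0]}")
                chosen = rng.choice(rates.shape[0], size=size, replace=False)
                feats = _pseudo_population(rates[chosen], labels, rng).T
                runs, _ = decode_repeated(feats, labels, rng,
                                          n_repeats=n_repeats, grid=grid,
                                          **decode_kwargs)
                chance = chance_calibration(feats, labels, rng,
                                            n_shuffles=n_chance_shuffles,
                                            grid=grid, **decode_kwargs)
                accs = np.array([r.accuracy for r in runs])
                rows.append({
                    "bin_ms": bin_ms, "window_start_ms": start,
                    "n_neurons": size, "raw_mean": accs.mean(),
                    "raw_sd": accs.std(ddof=1) if len(accs) > 1 else 0.0,
                    "chance_cutoff": chance.cutoff(),
                })
    return pd.DataFrame(rows)
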