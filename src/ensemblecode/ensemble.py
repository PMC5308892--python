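"""Population-vector similarity across conditions with permutation inference.

The population vector (PV) for a condition and time bin is the across-unit
vector of normalized condition-mean firing rates. Similarity between two
conditions in a bin is the Pearson correlation of their PVs. Whether the
ensemble is more similar along the relational axis (ACS-US vs VCS-US: shared
stimulus relationship) than along the physical axis (ACS-US vs ACS-alone:
shared CS modality) is tested per bin by a trial-label permutation test on
the difference of the two correlations, Bonferroni-adjusted over the ten
50 ms bins covering 0-500 ms after CS onset (alpha = 0.05/10).

Trial-by-trial dynamics are summarized by correlating each trial's PV over
the CS-offset-to-US-onset interval against a 'template' PV averaged over the
10th-80th paired trials of a reference condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, UndefinedValueError
from .spikes import RateTensor

__all__ = ["pv_similarity", "similarity_difference_permtest",
           "template_correlation", "SimilarityResult"]

RELATIONAL_PAIR = ("ACS_US", "VCS_US")
PHYSICAL_PAIR = ("ACS_US", "ACS_ALONE")


def pv_similarity(vector_a: np.ndarray, vector_b: np.ndarray) -> float:
    """Pearson correlation between two population vectors.

    Raises :class:`UndefinedValueError` when either vector has zero variance
    (correlation undefined) or fewer than three units.
    """
    a = np.asarray(vector_a, dtype=float)
    b = np.asarray(vector_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfigurationError("population vectors must be 1-D and equal-length")
    if len(a) < 3:
        raise ConfigurationError("need at least 3 units for a PV correlation")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedValueError("PV correlation undefined: zero-variance vector")
    return float(stats.pearsonr(a, b).statistic)


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r over the last axis; zero-variance rows give nan."""
    am = a - a.mean(axis=-1, keepdims=True)
    bm = b - b.mean(axis=-1, keepdims=True)
    num = (am * bm).sum(axis=-1)
    den = np.sqrt((am ** 2).sum(axis=-1) * (bm ** 2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


@dataclass
class SimilarityResult:
    """Per-bin similarity contrast between two condition pairs."""

    table: pd.DataFrame          # bin_start_ms, r_pair1, r_pair2, delta, p, significant
    pair1: tuple[str, str]
    pair2: tuple[str, str]
    n_perm: int
    alpha: float


def _pair_r_null(values: np.ndarray, conditions: np.ndarray,
                 pair: tuple[str, str], n_perm: int,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Observed per-bin r for a condition pair plus its permutation null.

    Null: trials in the pair's pool are reassigned to the two conditions with
    per-condition counts held constant; condition-mean matrices and r are
    recomputed. Returns (r_obs (n_bins,), r_null (n_perm, n_bins)).
    """
    a, b = pair
    mask_a = conditions == a
    mask_b = conditions == b
    if not mask_a.any() or not mask_b.any():
        raise ConfigurationError(f"missing trials for condition pair {pair}")
    pool = values[:, mask_a | mask_b, :]            # (U, T, B)
    n_a = int(mask_a.sum())
    n_t = pool.shape[1]
    # observed means: first n_a pool trials are condition a by construction
    # of the boolean mask only if contiguous; recompute from the masks instead
    mean_a = values[:, mask_a, :].mean(axis=1)      # (U, B)
    mean_b = values[:, mask_b, :].mean(axis=1)
    r_obs = _pearson_rows(mean_a.T, mean_b.T)       # (B,)

    # permutation assignment matrix: rows of 0/1 flags with n_a ones
    flags = np.zeros((n_perm, n_t))
    flags[:, :n_a] = 1.0
    flags = rng.permuted(flags, axis=1)
    sum_all = pool.sum(axis=1)                      # (U, B)
    sum_a = np.einsum("utb,pt->pub", pool, flags, optimize=True)
    mean_a_null = sum_a / n_a
    mean_b_null = (sum_all[None] - sum_a) / (n_t - n_a)
    r_null = _pearson_rows(np.moveaxis(mean_a_null, 1, 2),
                           np.moveaxis(mean_b_null, 1, 2))  # (P, B)
    return r_obs, r_null


def similarity_difference_permtest(tensor: RateTensor,
                                   pair1: tuple[str, str] = RELATIONAL_PAIR,
                                   pair2: tuple[str, str] = PHYSICAL_PAIR,
                                   bins_ms: tuple[float, float] = (0.0, 500.0),
                                   n_perm: int = 1000,
                                   alpha: float = 0.05 / 10,
                                   rng: np.random.Generator | None = None
                                   ) -> SimilarityResult:
    """Permutation test for r(pair1) - r(pair2), per time bin.

    Trials are shuffled between the two conditions of each pair independently
    (per-condition trial counts preserved), the pair correlations and their
    difference recomputed ``n_perm`` times, and a two-sided p-value formed
    with the (b+1)/(n+1) convention. A bin is significant when p <= alpha
    (default 0.05/10, adjusted for the ten bins examined).
    """
    if n_perm < 100:
        raise ConfigurationError(
            "n_perm < 100 gives too coarse a null for the adjusted alpha")
    rng = rng or np.random.default_rng()
    centers = (tensor.bin_edges_ms[:-1] + tensor.bin_edges_ms[1:]) / 2.0
    keep = (centers >= bins_ms[0]) & (centers < bins_ms[1])
    values = tensor.values[:, :, keep]
    conditions = tensor.conditions

    r1_obs, r1_null = _pair_r_null(values, conditions, pair1, n_perm, rng)
    r2_obs, r2_null = _pair_r_null(values, conditions, pair2, n_perm, rng)
    delta_obs = r1_obs - r2_obs
    delta_null = r1_null - r2_null                  # (P, B)

    finite = np.isfinite(delta_null)
    n_eff = finite.sum(axis=0)
    ge = np.where(finite, delta_null >= delta_obs[None, :], False).sum(axis=0)
    le = np.where(finite, delta_null <= delta_obs[None, :], False).sum(axis=0)
    p_up = (ge + 1) / (n_eff + 1)
    p_lo = (le + 1) / (n_eff + 1)
    p = np.minimum(1.0, 2.0 * np.minimum(p_up, p_lo))

    table = pd.DataFrame({
        "bin_start_ms": tensor.bin_edges_ms[:-1][keep],
        "r_pair1": r1_obs, "r_pair2": r2_obs, "delta": delta_obs,
        "p": p, "significant": p <= alpha,
    })
    return SimilarityResult(table, tuple(pair1), tuple(pair2), n_perm, alpha)


def template_correlation(trial_rates: np.ndarray, trial_table: pd.DataFrame,
                         template_condition: str = "ACS_US",
                         template_range: tuple[int, int] = (10, 80),
                         ci_method: str = "fisher",
                         leave_one_out: bool = False) -> pd.DataFrame:
    """Correlate each trial's PV with a condition template.

    ``trial_rates`` is (units, trials) over the CS-offset-to-US-onset window.
    The template is the mean PV over the ``template_range[0]``-th through
    ``template_range[1]``-th trials (1-based, inclusive) of
    ``template_condition``. By default template-member trials are included in
    the comparison series; ``leave_one_out=True`` recomputes the template
    without the trial under comparison. The confidence band is a 95% CI from
    the Fisher z transform (``ci_method='fisher'``) with n = number of units.
    """
    rates = np.asarray(trial_rates, dtype=float)
    n_units, n_trials = rates.shape
    if n_units < 4:
        raise ConfigurationError("need >= 4 units for a Fisher-z band")
    conds = trial_table["condition"].to_numpy()
    member_idx = np.nonzero(conds == template_condition)[0]
    lo, hi = template_range
    if not 1 <= lo <= hi <= len(member_idx):
        raise ConfigurationError(
            f"template_range {template_range} outside the "
            f"{len(member_idx)} trials of {template_condition!r}")
    tmpl_idx = member_idx[lo - 1:hi]
    template = rates[:, tmpl_idx].mean(axis=1)

    rs = np.empty(n_trials)
    for t in range(n_trials):
        tpl = template
        if leave_one_out and t in tmpl_idx:
            others = tmpl_idx[tmpl_idx != t]
            tpl = rates[:, others].mean(axis=1)
        r = _pearson_rows(tpl[None, :], rates[None, :, t])[0]
        rs[t] = r

    if ci_method != "fisher":
        raise ConfigurationError(f"unknown ci_method {ci_method!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.arctanh(np.clip(rs, -1 + 1e-12, 1 - 1e-12))
    half = 1.959963984540054 / np.sqrt(n_units - 3)
    out = pd.DataFrame({
        "trial": np.arange(1, n_trials + 1),
        "condition": conds,
        "r": rs,
        "ci_lo": np.tanh(z - half),
        "ci_hi": np.tanh(z + half),
    })
    out.attrs["ci_method"] = "fisher"
    out.attrs["template_condition"] = template_condition
    out.attrs["template_range"] = template_range
    return out
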