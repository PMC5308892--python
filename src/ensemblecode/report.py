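"""End-to-end pipeline orchestration from a single run configuration.

``run_pipeline`` drives the full analysis on a synthetic (or loaded) dataset:
CR scoring and stage segmentation from EMG, unit quality control,
population-similarity tests, stage-wise decoding, and single-neuron
selectivity — writing every table as CSV plus a machine-readable JSON summary
that records the seed behind every number.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, decoding, ensemble, io, selectivity, spikes, synthetic
from .errors import ConfigurationError

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("ensemblecode")


@dataclass
class RunConfig:
    """Parameters of one pipeline run.

    With ``simulate=True`` the generator supplies all inputs; otherwise
    ``trials_path``/``spikes_dir``/``emg_dir`` must point at existing data.
    Stage criteria, analysis windows, decoding sizes and permutation counts
    are all exposed so the defaults can be probed.
    """

    out_dir: str = "ensemblecode_out"
    seed: int = 0
    simulate: bool = True
    trials_path: str | None = None
    spikes_dir: str | None = None
    emg_dir: str | None = None
    # generator
    generator: dict = field(default_factory=dict)
    n_neurons: int = 40
    # analysis windows
    window_ms: tuple = (-400.0, 600.0)
    bin_ms: float = 50.0
    trace_window_ms: tuple = (100.0, 600.0)
    decode_window_ms: tuple = (100.0, 300.0)
    # stage criteria
    before_threshold: float = 30.0
    post_threshold: float = 60.0
    run_length: int = 2
    week_length: int = 7
    # permutations / decoding
    n_perm: int = 1000
    n_sets: int = 2
    n_decode_neurons: int = 30
    n_repeats: int = 5
    n_chance_shuffles: int = 20
    n_per_condition: int = 20
    n_train_per_condition: int = 10
    reduced_grid: bool = True
    labelings: tuple = ("FOURWAY", "RELATIONAL_BINARY", "PHYSICAL_BINARY")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = io.read_yaml(path)
        for key in ("window_ms", "trace_window_ms", "decode_window_ms",
                    "labelings"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if not self.simulate:
            for name in ("trials_path", "spikes_dir", "emg_dir"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ConfigurationError(
                        f"{name} must point at existing data when simulate=False")


def _load_inputs(config: RunConfig):
    if config.simulate:
        gen = synthetic.GeneratorConfig(seed=config.seed, **config.generator)
        ens = synthetic.EnsembleSpec.from_mixture(
            config.n_neurons, np.random.default_rng(config.seed + 1))
        return synthetic.generate_dataset(gen, ens)
    trials = io.read_trial_table(config.trials_path)
    spike_set = io.read_spike_set(config.spikes_dir)
    emg = {}
    for p in sorted(Path(config.emg_dir).glob("*.f32")):
        tr = io.read_emg(p)
        emg[tr.session_id] = tr
    return trials, emg, spike_set


def run_pipeline(config: RunConfig) -> dict:
    """Execute behavior -> QC -> ensemble -> decoding -> selectivity.

    Returns the JSON-serializable summary (also written to
    ``<out_dir>/summary.json``). Identical config and seed reproduce an
    identical summary.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    summary: dict = {"seed": config.seed, "config": {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in asdict(config).items()}}

    stage_name = "inputs"
    try:
        trials, emg, spike_set = _load_inputs(config)
        io.write_trial_table(trials, out / "trials.csv")

        stage_name = "behavior"
        cr_frames = [behavior.score_session(emg[s], trials)
                     for s in sorted(emg)]
        cr = pd.concat(cr_frames, ignore_index=True)
        cr.to_csv(out / "behavior.csv", index=False)
        sess = behavior.session_behavior(cr)
        sess.to_csv(out / "sessions.csv", index=False)
        paired = sess[sess["condition"].str.endswith("_US")]
        daily = paired.groupby("session_id")["cr_percent"].mean()
        stages_df = behavior.assign_stages(
            daily.to_numpy(), before_threshold=config.before_threshold,
            post_threshold=config.post_threshold,
            run_length=config.run_length, week_length=config.week_length)
        stages_df["session_id"] = daily.index.to_numpy()
        stages_df.to_csv(out / "stages.csv", index=False)
        summary["behavior"] = {
            "daily_cr_percent": daily.round(3).to_dict(),
            "stages": dict(zip(stages_df["session_id"].astype(str),
                               stages_df["stage"]))}

        stage_name = "spikes_qc"
        passed, qc_report = spikes.qc_filter(spike_set, min_spikes=0)
        qc_report.to_csv(out / "unit_qc.csv", index=False)
        summary["qc"] = {"n_units": len(spike_set),
                         "n_passed": int(qc_report["passed"].sum())}

        stage_name = "ensemble"
        tensor = spikes.bin_rates(passed, trials, window_ms=config.window_ms,
                                  bin_ms=config.bin_ms, normalization="MAX")
        sim = ensemble.similarity_difference_permtest(
            tensor, n_perm=config.n_perm, rng=rng)
        sim.table.to_csv(out / "similarity.csv", index=False)
        tr_rates = spikes.trial_window_rates(passed, trials,
                                             window_ms=config.trace_window_ms)
        n_member = int((trials["condition"] == "ACS_US").sum())
        tc = ensemble.template_correlation(
            tr_rates, trials,
            template_range=(min(10, n_member), min(80, n_member)))
        tc.to_csv(out / "template_corr.csv", index=False)
        summary["ensemble"] = {
            "n_significant_bins": int(sim.table["significant"].sum()),
            "mean_template_r": float(np.nanmean(tc["r"]))}

        stage_name = "decoding"
        grid = decoding.REDUCED_GRID if config.reduced_grid else decoding.DEFAULT_GRID
        feats = spikes.trial_window_rates(passed, trials,
                                          window_ms=config.decode_window_ms)
        labels = trials["condition"].to_numpy()
        summary["decoding"] = {}
        for labeling in config.labelings:
            res = decoding.decode_stage(
                feats, labels, stage="ALL", labeling=labeling,
                n_sets=config.n_sets, n_neurons=config.n_decode_neurons,
                n_repeats=config.n_repeats,
                n_chance_shuffles=config.n_chance_shuffles,
                n_per_condition=config.n_per_condition,
                n_train_per_condition=config.n_train_per_condition,
                rng=rng, grid=grid)
            res.to_frame().to_csv(out / f"decoding_ALL_{labeling}.csv",
                                  index=False)
            res.confusion_mean.to_csv(out / f"confusion_ALL_{labeling}.csv")
            summary["decoding"][labeling] = {
                "mean_relative": res.mean_relative,
                "sem_relative": res.sem_relative,
                "mean_raw": float(res.raw_accuracy.mean())}

        stage_name = "selectivity"
        profile = selectivity.profile_units(passed, trials, rng,
                                            window_ms=config.trace_window_ms,
                                            n_perm=config.n_perm)
        profile.to_csv(out / "selectivity.csv", index=False)
        counts = profile["category"].value_counts(dropna=False)
        summary["selectivity"] = {
            "n_responsive": int(profile["responsive"].sum()),
            "category_counts": {str(k): int(v) for k, v in counts.items()}}
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage_name!r}: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info("pipeline complete; outputs in %s", out)
    return summary
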