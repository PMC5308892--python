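# ensemblecode

Analysis pipeline for **prefrontal ensemble selectivity during dual trace
eyeblink conditioning** — for systems-neuroscience groups who score
conditioned eyelid responses from EMG, track learning across daily sessions,
and ask what feature of the task a recorded neural population encodes.

In the paradigm the package models, a rat receives daily sessions of two
conditioning epochs. Each epoch presents 20 CS-alone trials followed by 80
CS–US paired trials of one CS modality (an auditory or a visual CS, 100 ms),
with the mild eyelid-stimulation US (100 ms) arriving after a stimulus-free
500 ms **trace interval**. Conditions therefore vary along two axes:

- the **relational** axis — does the CS predict the US in this block
  (CS-alone vs CS–US paired), regardless of modality;
- the **physical** axis — which CS modality was presented, regardless of
  pairing.

The pipeline quantifies coding along both axes at the population and the
single-neuron level:

| module | what it computes |
|---|---|
| `synthetic` | trial schedules, eyelid EMG, and Poisson spike trains from neurons of declared selectivity classes (relational / physical / conjunctive / non-selective / unresponsive), with per-stage magnitude and consistency schedules |
| `behavior` | CR detection from the Hilbert envelope of EMG (Pre-Value / CR-Value / mean+2SD Threshold; hyperactive-trial rejection), per-condition CR%, and the five learning stages (Before, Learning, Post 1–3 weeks; 30% / 60% criteria) |
| `spikes` | unit QC (<1% ISIs inside 2 ms, >1500 spikes) and (unit × trial × 50 ms bin) rate tensors over −400..600 ms with raw / max / baseline z-score normalization |
| `ensemble` | Pearson similarity of condition population vectors, a trial-permutation test for r(relational pair) − r(physical pair) at α = 0.05/10 per bin, and trial-by-trial template correlation |
| `decoding` | RBF-SVM decoding of condition from trace-interval firing (20 trials/condition, 10/10 train–test, 5-fold-CV grid search), chance calibrated from 50 label-shuffled repetitions × 40 readouts; relative accuracy = raw − 95% chance cutoff |
| `selectivity` | differentiation index (Fr1−Fr2)/(Fr1+Fr2), plug-in mutual information over 10 rate bins, 1000-shuffle permutation significance, and neuron categorization |
| `report` | one-config orchestration of the full pipeline with CSV/JSON outputs |

## Worked example

`examples/04_decode_conditions.py` builds a 50-unit synthetic ensemble (half
relational, half physical units with heterogeneous gains), decodes the four
conditions from trace-interval firing, and collapses the labels onto each
axis:

```
FOURWAY            raw=0.857 chance_cutoff=0.379 relative=+0.478 ± 0.039
RELATIONAL_BINARY  raw=0.967 chance_cutoff=0.667 relative=+0.299 ± 0.001
PHYSICAL_BINARY    raw=0.920 chance_cutoff=0.637 relative=+0.283 ± 0.012
```

Raw accuracy is the held-out classification rate; the chance cutoff is the
95th percentile of the label-shuffled accuracy distribution of the same
classifier; a positive relative accuracy means the population carries
reliable information along that axis. The other examples cover dataset
simulation, behavior scoring and stage segmentation, population-vector
similarity, and single-neuron selectivity profiles.

A thin CLI mirrors the library (`ensemblecode simulate|behavior|qc|ensemble|
decode|selectivity|run-all`); see `ensemblecode --help`.

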