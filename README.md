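# xmodal

Analysis toolkit for rule-dependent neural population states in a cross-modal
sensory selection task, together with a synthetic task-and-spiking generator
that stands in for a recorded dataset.

In the task, tactile and visual stimuli are randomly interleaved while a
stimulus-response rule (respond-to-touch vs respond-to-light) alternates in
blocks of ~60 trials. The package covers the full analysis chain:

| Module | What it does |
| --- | --- |
| `xmodal.synthetic` | Session generator: block/trial schedule, a behavioral agent with a feedback-driven rule-transition lag, and inhomogeneous-Poisson spike trains whose baseline, evoked, and choice components are modulated per configured effect sizes |
| `xmodal.behavior` | Outcome scoring (hit/miss/FA/CR with grace + censor windows), performance summaries, detection sensitivity and inhibition deltas, rule-transition parsing, session QC |
| `xmodal.preprocess` | Unit QC (ISI violations, presence ratio, pass-through metrics), binned/smoothed rate tensors, soft normalization `(r - mean) / (range + 5)`, pre-stimulus-lick trial exclusion |
| `xmodal.discrim` | Ideal-observer (ROC/AUC) single-unit discriminability with Bonferroni-corrected bootstrap CIs and the consecutive-bin rule; PSTH permutation test; pre/post AUC correlation |
| `xmodal.decoding` | 10-fold cross-validated population decoding (LDA/SVM/RF) with label-shuffle controls; rule-transition classification with Kendall's tau tracking |
| `xmodal.geometry` | Trajectory PCA and tHit–tCR distances, subspace overlap via variance alignment, stimulus/choice coding dimensions and cross-rule alignment |
| `xmodal.stats` | Hierarchical bootstrap CIs, permutation tests, Bonferroni utilities |
| `xmodal.tableio` / `xmodal.cli` / `xmodal.pipeline` | CSV/JSON interchange, optional NWB-layout HDF5 ingestion, CLI, end-to-end pipeline |

## CLI

```bash
# generate 4 synthetic sessions (trials.csv + per-session spike CSVs)
xmodal simulate --sessions 4 --mice 2 --seed 1 --out data/

# behavioral analyses
xmodal score data/trials.csv
xmodal qc data/trials.csv
xmodal sensitivity data/trials.csv --modality tactile
xmodal transitions data/trials.csv

# neural analyses for one session
xmodal preprocess data/ --session s000 --out data/rates.csv
xmodal discrim data/ --session s000 --contrast tHit-vs-tCR --out data/auc.csv
xmodal decode data/ --session s000 --target rule --window pre --classifier lda

# full pipeline with a consolidated JSON report
xmodal report --seed 1 --out run/
```

Configs can be provided as YAML/JSON (`xmodal simulate --config cfg.yaml ...`);
see `xmodal.config.TaskConfig`, `AgentConfig`, and `PopulationConfig` for the
available fields. NWB-layout HDF5 files can be converted with
`xmodal ingest-nwb <file> --out <dir>` (optional feature; nothing else
depends on it).

## Layout

```
src/xmodal/        package modules (one per analysis stage)
tests/             pytest suite; tests/test_acceptance.py holds the
                   acceptance criteria (generator fidelity, oracle
                   equivalence, null calibration, parameter recovery,
                   geometry identities, transition tracking, bootstrap
                   coverage)
scripts/acceptance.py   acceptance report entry point
```
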