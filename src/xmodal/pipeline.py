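"""End-to-end orchestration: simulate -> score -> preprocess -> analyses -> report.

The pipeline is driven by a flat config dict (unknown keys rejected) and
writes per-stage CSV/JSON artifacts plus a consolidated JSON report.  Every
artifact records the package version, a config hash, and the seed so reruns
are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np

from xmodal import __version__
from xmodal.behavior import outcome_summary, parse_transitions, session_qc
from xmodal.config import AgentConfig, PopulationConfig, TaskConfig
from xmodal.decoding import decode, transition_classify, transition_tau_ci
from xmodal.discrim import evoked_discrim, prestim_discrim, significant_fraction
from xmodal.errors import ConfigError
from xmodal.geometry import (
    fit_trajectory_pca,
    prepost_overlap_correlation,
    subspace_overlap,
    trajectory_distance,
)
from xmodal.preprocess import (
    bin_rates,
    exclude_prestim_lick_trials,
    soft_normalize,
    unit_qc_filter,
)
from xmodal.synthetic import simulate_sessions
from xmodal.tableio import write_spikes_csv, write_trials_csv

log = logging.getLogger(__name__)

DEFAULT_CONFIG = dict(
    seed=0,
    n_sessions=4,
    n_mice=2,
    out_dir=None,
    stages=("simulate", "behavior", "discrim", "decode", "geometry", "transitions"),
    task={},
    agent={},
    population={},
    n_boot=200,
    n_shuffle=20,
)


def _validate_config(config: dict) -> dict:
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ConfigError(sorted(unknown)[0], "unknown pipeline config key")
    merged = {**DEFAULT_CONFIG, **config}
    return merged


def _config_hash(config: dict) -> str:
    hashable = {k: v for k, v in config.items() if k != "out_dir"}
    return hashlib.sha256(
        json.dumps(hashable, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_pipeline(config: dict) -> dict:
    """Run the configured stages on simulated sessions; return the report."""
    cfg = _validate_config(config)
    stages = set(cfg["stages"])
    seed = int(cfg["seed"])
    task = TaskConfig(**cfg["task"])
    agent = AgentConfig(**cfg["agent"])
    pop = PopulationConfig(**cfg["population"])
    out_dir = Path(cfg["out_dir"]) if cfg["out_dir"] else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = dict(
        version=__version__,
        config_hash=_config_hash(cfg),
        seed=seed,
        stages=sorted(stages),
    )

    trials, spike_sets = simulate_sessions(
        cfg["n_sessions"], task=task, agent=agent, pop=pop,
        seed=seed, n_mice=cfg["n_mice"],
        with_spikes=bool(stages - {"simulate", "behavior"}),
    )
    if out_dir:
        write_trials_csv(trials, out_dir / "trials.csv")
        for sid, spikes in spike_sets.items():
            write_spikes_csv(spikes, out_dir / f"spikes_{sid}.csv",
                             out_dir / f"units_{sid}.json")

    if "behavior" in stages:
        summary = outcome_summary(trials)
        qc = {
            sid: session_qc(sub).keep
            for sid, sub in trials.groupby("session_id")
        }
        report["behavior"] = dict(
            percent_correct=summary.percent_correct,
            per_rule={r: asdict(v) for r, v in summary.per_rule.items()},
            sessions_kept=sum(qc.values()),
            sessions_total=len(qc),
        )

    per_session = {}
    for sid, spikes in spike_sets.items():
        sess = trials[trials["session_id"] == sid]
        span = (0.0, float(sess["stim_onset"].max()) + 3.0)
        kept, _ = unit_qc_filter(spikes, span)
        stim = sess[sess["modality"].isin(("tactile", "visual"))]
        no_lick = exclude_prestim_lick_trials(stim)
        fine = bin_rates(kept, stim, window=(-0.1, 0.25), bin_size=0.01, sigma=0.05)
        coarse = bin_rates(kept, no_lick, window=(-0.1, 0.1), bin_size=0.1)
        per_session[sid] = dict(sess=sess, stim=stim, no_lick=no_lick,
                                kept=kept, fine=fine, coarse=coarse)

    if "discrim" in stages and per_session:
        fracs_evoked, fracs_rule = [], []
        for sid, d in per_session.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ev = evoked_discrim(d["fine"], d["stim"], n_boot=cfg["n_boot"], seed=seed)
                ru = prestim_discrim(d["coarse"], d["no_lick"], contrast="rule",
                                     n_boot=cfg["n_boot"], seed=seed)
            fracs_evoked.append(significant_fraction(ev))
            fracs_rule.append(significant_fraction(ru))
        report["discrim"] = dict(
            evoked_significant_fraction=float(np.mean(fracs_evoked)),
            rule_significant_fraction=float(np.mean(fracs_rule)),
        )

    if "decode" in stages and per_session:
        accs, shuffled = [], []
        for sid, d in per_session.items():
            tensor = soft_normalize(d["coarse"])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = decode(tensor, d["no_lick"], target="rule", window="pre",
                             n_shuffle=cfg["n_shuffle"], seed=seed)
            accs.append(res.accuracy)
            shuffled.append(res.accuracy_shuffled)
        report["decoding"] = dict(
            rule_pre_accuracy=float(np.mean(accs)),
            rule_pre_accuracy_shuffled=float(np.mean(shuffled)),
            n_sessions=len(accs),
        )

    if "geometry" in stages and per_session:
        overlaps, pre_overlaps, dist_peaks = [], [], []
        for sid, d in per_session.items():
            tensor = soft_normalize(d["fine"])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_trajectory_pca(tensor, d["stim"])
                _, dist = trajectory_distance(model, tensor, d["stim"])
                ov = subspace_overlap(tensor, d["stim"], seed=seed)
            dist_peaks.append(float(dist.max()))
            if ov is not None:
                overlaps.append(ov.overlap_tCR)
                pre_overlaps.append(ov.overlap_prestim_tCR)
        corr = prepost_overlap_correlation(pre_overlaps, overlaps)
        report["geometry"] = dict(
            mean_overlap_tCR=float(np.mean(overlaps)) if overlaps else None,
            mean_peak_distance=float(np.mean(dist_peaks)) if dist_peaks else None,
            prepost_r=None if corr is None else corr[0],
            n_sessions=len(overlaps),
        )

    if "transitions" in stages and per_session:
        results = {"touch->light": [], "light->touch": []}
        for sid, d in per_session.items():
            parses = parse_transitions(d["sess"])
            tensor = soft_normalize(d["coarse"])
            for direction in results:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = transition_classify(tensor, d["no_lick"], parses,
                                              direction, seed=seed)
                if res is not None:
                    results[direction].append(res)
        out = {}
        for direction, rs in results.items():
            if rs:
                ci = transition_tau_ci(rs, n_iter=cfg["n_boot"], seed=seed)
                out[direction] = dict(tau=ci.estimate, lo=ci.lo, hi=ci.hi,
                                      significant=ci.significant, n_sessions=len(rs))
        report["transitions"] = out

    if out_dir:
        (out_dir / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report
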