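"""Behavioral scoring, performance metrics, transitions, and session QC.

Outcome taxonomy: a lick to the rewarded port within the answer window on a
relevant stimulus is a *hit*; withholding on a relevant stimulus is a *miss*;
licking on an irrelevant stimulus (either port) or to the incorrect port on a
relevant stimulus is a *false alarm*; withholding on an irrelevant stimulus is
a *correct rejection*.  Licks in the grace window are ignored for scoring and
licks in the censor window mark the trial *censored* (excluded downstream).
Percent correct = 100 * (hits + correct rejections) / total trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from xmodal.config import TaskConfig
from xmodal.core import RULE_MODALITY, RULE_PORT, RULES, check_trial_table
from xmodal.errors import StructuralError
from xmodal.stats import ResampleCI, hierarchical_bootstrap


# ---------------------------------------------------------------------------
# scoring

def score_trial(rule: str, modality: str, licks, task: TaskConfig | None = None) -> str:
    """Score a single stimulus trial; raises on ``modality == 'none'``."""
    task = task or TaskConfig()
    if modality == "none":
        raise StructuralError("cannot score a trial with modality 'none' under stimulus rules")
    cen_lo, cen_hi = task.censor_window
    if any(cen_lo <= t < cen_hi for t, _ in licks):
        return "censored"
    ans_lo, ans_hi = task.answer_window
    gr_lo, gr_hi = task.grace_window
    answer = [
        (t, port)
        for t, port in sorted(licks)
        if ans_lo <= t <= ans_hi and not (gr_lo <= t < gr_hi)
    ]
    relevant = modality == RULE_MODALITY[rule]
    if not answer:
        return "miss" if relevant else "correct_rejection"
    port = answer[0][1]  # first answer-window lick determines the port
    if relevant and port == RULE_PORT[rule]:
        return "hit"
    return "false_alarm"


def score_outcomes(trials: pd.DataFrame, task: TaskConfig | None = None) -> pd.DataFrame:
    """Fill/validate the ``outcome`` column; laser-only trials stay unscored."""
    check_trial_table(trials)
    task = task or TaskConfig()
    out = trials.copy()
    outcomes = []
    for row in out.itertuples(index=False):
        if row.modality == "none":
            outcomes.append(pd.NA)
        else:
            outcomes.append(score_trial(row.block_rule, row.modality, row.licks, task))
    out["outcome"] = outcomes
    return out


def _scored_stim_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Non-censored stimulus trials (the analysis set)."""
    mask = trials["modality"].isin(("tactile", "visual")) & (trials["outcome"] != "censored")
    return trials[mask & trials["outcome"].notna()]


# ---------------------------------------------------------------------------
# summaries

@dataclass
class RuleOutcomes:
    hit_rate: float
    miss_rate: float
    fa_rate: float
    cr_rate: float
    percent_correct: float
    n_trials: int
    empty: bool = False


@dataclass
class OutcomeSummary:
    per_rule: dict[str, RuleOutcomes]
    percent_correct: float  # overall, both rules pooled
    n_trials: int


def outcome_summary(trials: pd.DataFrame) -> OutcomeSummary:
    """Outcome fractions and percent correct per rule and overall."""
    scored = _scored_stim_trials(trials)
    per_rule = {}
    for rule in RULES:
        sub = scored[scored["block_rule"] == rule]
        n = len(sub)
        if n == 0:
            per_rule[rule] = RuleOutcomes(np.nan, np.nan, np.nan, np.nan, np.nan, 0, empty=True)
            continue
        counts = sub["outcome"].value_counts()
        rates = {k: counts.get(k, 0) / n for k in
                 ("hit", "miss", "false_alarm", "correct_rejection")}
        per_rule[rule] = RuleOutcomes(
            hit_rate=rates["hit"],
            miss_rate=rates["miss"],
            fa_rate=rates["false_alarm"],
            cr_rate=rates["correct_rejection"],
            percent_correct=percent_correct(rates["hit"], rates["correct_rejection"]),
            n_trials=n,
        )
    n_all = len(scored)
    pc = (
        100.0 * scored["outcome"].isin(("hit", "correct_rejection")).mean()
        if n_all else np.nan
    )
    return OutcomeSummary(per_rule=per_rule, percent_correct=pc, n_trials=n_all)


def percent_correct(hit_fraction: float, cr_fraction: float) -> float:
    """100 * (hits + correct rejections) / total, from outcome fractions."""
    return 100.0 * (hit_fraction + cr_fraction)


# ---------------------------------------------------------------------------
# detection sensitivity

_CONDITION_TO_LASER = {
    "control": "none",
    "laser_pre": "pre",
    "laser_post": "post",
    "sham": "sham",
}


@dataclass
class SensitivityResult:
    modality: str
    condition: str
    hit_rate: float
    fa_rate: float
    sensitivity: float
    n_hit_trials: int
    n_fa_trials: int
    missing: bool = False


def _licked_port(licks, port: str, task: TaskConfig) -> bool:
    ans_lo, ans_hi = task.answer_window
    gr_lo, gr_hi = task.grace_window
    answer = [
        (t, p) for t, p in sorted(licks)
        if ans_lo <= t <= ans_hi and not (gr_lo <= t < gr_hi)
    ]
    return bool(answer) and answer[0][1] == port


def detection_sensitivity(
    trials: pd.DataFrame,
    modality: str = "tactile",
    condition: str = "control",
    task: TaskConfig | None = None,
    task_mode: str = "cross_modal",
) -> SensitivityResult:
    """Hit rate minus opposite-modality false-alarm rate within a rule's blocks.

    ``cross_modal``: tactile sensitivity = P(right lick | tactile, touch
    blocks) - P(right lick | visual, touch blocks); visual correspondingly
    with left licks in light blocks.  ``detection`` (Go/NoGo): P(lick | Go) -
    P(lick | NoGo), where NoGo trials carry modality ``none``.
    """
    task = task or TaskConfig()
    laser = _CONDITION_TO_LASER.get(condition, condition)
    sub = trials[(trials["laser"] == laser) & (trials["outcome"] != "censored")]
    if task_mode == "detection":
        go = sub[sub["modality"] == "tactile"]
        nogo = sub[sub["modality"] == "none"]
        hit_trials, fa_trials = go, nogo
        port = None
    else:
        rule = "touch" if modality == "tactile" else "light"
        port = RULE_PORT[rule]
        blocks = sub[sub["block_rule"] == rule]
        hit_trials = blocks[blocks["modality"] == RULE_MODALITY[rule]]
        other = "visual" if modality == "tactile" else "tactile"
        fa_trials = blocks[blocks["modality"] == other]
    if len(hit_trials) == 0 or len(fa_trials) == 0:
        return SensitivityResult(modality, condition, np.nan, np.nan, np.nan,
                                 len(hit_trials), len(fa_trials), missing=True)

    def _p_lick(df):
        if port is None:
            ans_lo, ans_hi = task.answer_window
            gr_lo, gr_hi = task.grace_window
            return float(np.mean([
                any(ans_lo <= t <= ans_hi and not (gr_lo <= t < gr_hi) for t, _ in lk)
                for lk in df["licks"]
            ]))
        return float(np.mean([_licked_port(lk, port, task) for lk in df["licks"]]))

    hr, fr = _p_lick(hit_trials), _p_lick(fa_trials)
    return SensitivityResult(modality, condition, hr, fr, hr - fr,
                             len(hit_trials), len(fa_trials))


def delta_sensitivity(
    trials: pd.DataFrame,
    modality: str,
    condition_a: str,
    condition_b: str,
    task: TaskConfig | None = None,
    task_mode: str = "cross_modal",
    n_iter: int = 1000,
    seed: int | None = None,
) -> ResampleCI | None:
    """Per-session sensitivity difference with a mice->sessions bootstrap CI.

    Significant when the 95% CI excludes 0.  Returns ``None`` when no session
    has both conditions populated (missing marker).
    """
    per_mouse: dict[str, list[float]] = {}
    for (mouse, _session), sub in trials.groupby(["mouse_id", "session_id"]):
        sa = detection_sensitivity(sub, modality, condition_a, task, task_mode)
        sb = detection_sensitivity(sub, modality, condition_b, task, task_mode)
        if sa.missing or sb.missing:
            continue
        per_mouse.setdefault(mouse, []).append(sa.sensitivity - sb.sensitivity)
    if not per_mouse:
        warnings.warn("delta_sensitivity: no session has both conditions; missing")
        return None
    if len(per_mouse) == 1:
        warnings.warn("single mouse: CI degenerates to a session-level bootstrap")
    data = [np.asarray(v) for v in per_mouse.values()]
    return hierarchical_bootstrap(
        data, statistic=np.mean, levels=("mice", "sessions"),
        n_iter=n_iter, seed=seed, reference=0.0,
    )


#: Laser-train durations (s) for the two laser-only conditions.
LASER_ONLY_DURATION = {"laser_only_short": 0.8, "laser_only_long": 2.0}


def laser_only_lick_change(
    trials: pd.DataFrame,
    n_iter: int = 1000,
    seed: int | None = None,
) -> ResampleCI | None:
    """Change in P(lick) between the post-laser response window and the ITI.

    Response window: 0-2 s from laser offset; ITI window: -2-0 s from laser
    onset (trial times are relative to the scheduled onset).  Per-session
    probabilities, mouse-level CI.
    """
    laser_only = trials[trials["laser"].isin(LASER_ONLY_DURATION)]
    if laser_only.empty:
        warnings.warn("no laser-only trials; missing")
        return None
    per_mouse: dict[str, list[np.ndarray]] = {}
    for (mouse, _session), sub in laser_only.groupby(["mouse_id", "session_id"]):
        diffs = []
        for row in sub.itertuples(index=False):
            offset = LASER_ONLY_DURATION[row.laser]
            resp = any(offset <= t <= offset + 2.0 for t, _ in row.licks)
            iti = any(-2.0 <= t < 0.0 for t, _ in row.licks)
            diffs.append(float(resp) - float(iti))
        per_mouse.setdefault(mouse, []).append(np.asarray(diffs))
    return hierarchical_bootstrap(
        list(per_mouse.values()), statistic=np.mean,
        levels=("mice", "sessions", "trials"),
        n_iter=n_iter, seed=seed, reference=0.0,
    )


# ---------------------------------------------------------------------------
# rule transitions

@dataclass
class TransitionParse:
    """One block switch parsed into transition periods.

    All indices are global ``trial_index`` values.  The transition period
    spans the first trial after the switch through the first hit, inclusive;
    *early* runs through the first false alarm inclusive (feedback arrives at
    that trial's outcome), *late* is the remainder.
    """

    session_id: str
    block_index: int
    direction: str
    switch_trial: int  # trial_index of the new block's first trial
    first_fa: int | None
    first_hit: int | None
    early: list[int] = field(default_factory=list)
    late: list[int] = field(default_factory=list)
    open: bool = False  # no hit in the block: open transition

    @property
    def transition_trials(self) -> list[int]:
        return self.early + self.late


def parse_transitions(trials: pd.DataFrame) -> list[TransitionParse]:
    """Parse every block switch of every session into a TransitionParse."""
    check_trial_table(trials, require=("outcome",))
    parses = []
    for session_id, sess in trials.groupby("session_id", sort=False):
        sess = sess.sort_values("trial_index")
        blocks = sess["block_index"].unique()
        for b in blocks[1:]:
            block = sess[sess["block_index"] == b]
            prev_rule = sess[sess["block_index"] == b - 1]["block_rule"].iloc[0]
            new_rule = block["block_rule"].iloc[0]
            idx = block["trial_index"].to_numpy()
            outc = block["outcome"].to_numpy(dtype=object)
            hits = idx[outc == "hit"]
            fas = idx[outc == "false_alarm"]
            parse = TransitionParse(
                session_id=str(session_id),
                block_index=int(b),
                direction=f"{prev_rule}->{new_rule}",
                switch_trial=int(idx[0]),
                first_fa=None,
                first_hit=None,
            )
            if hits.size == 0:
                parse.open = True
                parse.early = [int(i) for i in idx]
                parses.append(parse)
                continue
            first_hit = int(hits[0])
            parse.first_hit = first_hit
            period = [int(i) for i in idx if i <= first_hit]
            fas_before = fas[fas <= first_hit]
            if fas_before.size:
                first_fa = int(fas_before[0])
                parse.first_fa = first_fa
                parse.early = [i for i in period if i <= first_fa]
                parse.late = [i for i in period if i > first_fa]
            else:
                parse.early = period
            parses.append(parse)
    return parses


@dataclass
class LickCurves:
    offsets: np.ndarray  # trial offset relative to the switch (0 = first new-block trial)
    p_right: np.ndarray  # mean across mice
    p_left: np.ndarray
    p_right_ci: tuple[np.ndarray, np.ndarray]
    p_left_ci: tuple[np.ndarray, np.ndarray]
    first_hit_hist: dict[str, np.ndarray]  # direction -> first-hit trial-in-block numbers


def transition_lick_curves(
    trials: pd.DataFrame,
    direction: str | None = None,
    offsets: tuple[int, int] = (-10, 15),
    task: TaskConfig | None = None,
    n_iter: int = 200,
    seed: int | None = None,
) -> LickCurves:
    """Right/left lick probabilities around switches, averaged across mice."""
    task = task or TaskConfig()
    parses = [p for p in parse_transitions(trials)
              if direction is None or p.direction == direction]
    if not parses:
        raise StructuralError("no block switches found")
    offs = np.arange(offsets[0], offsets[1] + 1)
    lookup = trials.set_index(["session_id", "trial_index"])
    per_mouse: dict[str, list[np.ndarray]] = {}
    first_hits: dict[str, list[int]] = {}
    for p in parses:
        sess = trials[trials["session_id"] == p.session_id]
        mouse = str(sess["mouse_id"].iloc[0])
        curves = np.full((2, offs.size), np.nan)
        for j, off in enumerate(offs):
            ti = p.switch_trial + off
            try:
                row = lookup.loc[(p.session_id, ti)]
            except KeyError:
                continue
            for k, port in enumerate(("right", "left")):
                curves[k, j] = float(_licked_port(row["licks"], port, task))
        per_mouse.setdefault(mouse, []).append(curves)
        if p.first_hit is not None:
            tib = int(p.first_hit - p.switch_trial + 1)
            first_hits.setdefault(p.direction, []).append(tib)
    mouse_means = np.array([
        np.nanmean(np.stack(c), axis=0) for c in per_mouse.values()
    ])  # (mice, 2, offsets)
    mean = np.nanmean(mouse_means, axis=0)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_iter, 2, offs.size))
    for i in range(n_iter):
        pick = rng.integers(0, mouse_means.shape[0], size=mouse_means.shape[0])
        boots[i] = np.nanmean(mouse_means[pick], axis=0)
    lo, hi = np.nanpercentile(boots, [2.5, 97.5], axis=0)
    return LickCurves(
        offsets=offs,
        p_right=mean[0], p_left=mean[1],
        p_right_ci=(lo[0], hi[0]), p_left_ci=(lo[1], hi[1]),
        first_hit_hist={d: np.asarray(v) for d, v in first_hits.items()},
    )


# ---------------------------------------------------------------------------
# session QC

@dataclass
class QCVerdict:
    keep: bool
    reasons: list[str]
    trials: pd.DataFrame  # trimmed session (last 20 trials removed)


def session_qc(
    trials: pd.DataFrame,
    min_overall: float = 60.0,
    min_block: float = 55.0,
    min_hit_rate: float = 35.0,
    trim_last: int = 20,
    max_laser_catch: float = 75.0,
) -> QCVerdict:
    """Keep/drop verdict for one session.

    The last ``trim_last`` trials are removed first; thresholds are computed
    on the trimmed session, using non-laser trials when laser trials are
    present.  Drop if overall percent correct < 60, any block < 55, any
    rule's hit rate (hits / (hits + misses)) < 35%, or the laser catch rate
    exceeds 75% or the hit rate.
    """
    reasons = []
    if len(trials) <= trim_last:
        return QCVerdict(False, [f"session shorter than {trim_last + 1} trials"],
                         trials.iloc[0:0])
    trimmed = trials.sort_values("trial_index").iloc[:-trim_last] if trim_last else trials
    baseline = trimmed[trimmed["laser"] == "none"]
    scored = _scored_stim_trials(baseline)
    if scored.empty:
        return QCVerdict(False, ["no scorable non-laser trials"], trimmed)
    overall = 100.0 * scored["outcome"].isin(("hit", "correct_rejection")).mean()
    if overall < min_overall:
        reasons.append(f"overall performance {overall:.1f}% < {min_overall}%")
    for b, block in scored.groupby("block_index"):
        pc = 100.0 * block["outcome"].isin(("hit", "correct_rejection")).mean()
        if pc < min_block:
            reasons.append(f"block {b} performance {pc:.1f}% < {min_block}%")
    hit_rates = []
    for rule in RULES:
        sub = scored[(scored["block_rule"] == rule)
                     & (scored["modality"] == RULE_MODALITY[rule])]
        n_hm = int(sub["outcome"].isin(("hit", "miss")).sum())
        if n_hm:
            hr = 100.0 * (sub["outcome"] == "hit").sum() / n_hm
            hit_rates.append(hr)
            if hr < min_hit_rate:
                reasons.append(f"{rule} hit rate {hr:.1f}% < {min_hit_rate}%")
    laser_only = trimmed[trimmed["laser"].isin(LASER_ONLY_DURATION)]
    if len(laser_only):
        task = TaskConfig()
        ans_lo, ans_hi = task.answer_window
        catch = 100.0 * np.mean([
            any(ans_lo <= t <= ans_hi for t, _ in lk) for lk in laser_only["licks"]
        ])
        if catch > max_laser_catch:
            reasons.append(f"laser catch rate {catch:.1f}% > {max_laser_catch}%")
        elif hit_rates and catch > max(hit_rates):
            reasons.append(f"laser catch rate {catch:.1f}% > hit rate")
    return QCVerdict(keep=not reasons, reasons=reasons, trials=trimmed)
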