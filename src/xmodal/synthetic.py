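"""Synthetic sessions: trial schedule, behavioral agent, and Poisson spiking.

The generator produces complete sessions with the statistical structure the
downstream analyses assume: block-alternating rules, randomly interleaved
tactile/visual stimuli subject to a run-length cap, exponential inter-trial
intervals on top of a fixed interval, a switch cue on a fixed trial of each
block, an agent with a feedback-driven rule-transition lag, and
inhomogeneous-Poisson spike trains whose pre-stimulus rate tracks the agent's
*behavioral* (not nominal) rule state.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from xmodal.config import AgentConfig, PopulationConfig, TaskConfig
from xmodal.core import (
    RULE_MODALITY,
    RULE_PORT,
    RULES,
    SpikeSet,
    TRIAL_COLUMNS,
    Unit,
    check_trial_table,
    split_rng,
)
from xmodal.errors import StructuralError

# Pre-stimulus licks are placed in (-1, -0.2) s so that the pre-stimulus-lick
# exclusion sees exactly p_prestim_lick of trials while the censor window
# (default (-0.2, 0)) stays under the separate p_censor_lick knob.
_PRESTIM_LICK_WINDOW = (-1.0, -0.2)


def generate_schedule(
    cfg: TaskConfig,
    session_id: str = "s000",
    mouse_id: str = "m000",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate stimuli and timing for one session (no outcomes).

    Block lengths are drawn uniformly on ``block_len_range``; block rules
    strictly alternate from a random starting rule; modalities are drawn
    sequentially, forcing the other modality whenever the last ``max_run``
    trials share one; gaps between stimulus onsets are
    ``iti_fixed + Exponential(iti_exp_mean)``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    n_blocks = int(cfg.n_blocks) if cfg.n_blocks is not None else int(rng.integers(4, 7))
    lo, hi = cfg.block_len_range
    block_lens = rng.integers(lo, hi + 1, size=n_blocks)
    start_rule = RULES[rng.integers(0, 2)]
    rows = []
    trial_index = 0
    t = 0.0
    for b, blen in enumerate(block_lens):
        rule = RULES[(RULES.index(start_rule) + b) % 2]
        for k in range(int(blen)):
            trial_index += 1
            # run-capped sequential modality draw
            recent = [r["modality"] for r in rows[-cfg.max_run:]]
            if len(recent) == cfg.max_run and len(set(recent)) == 1 and recent[0] != "none":
                modality = "visual" if recent[0] == "tactile" else "tactile"
            else:
                modality = "tactile" if rng.random() < 0.5 else "visual"
            laser = "none"
            if cfg.laser_fracs:
                u = rng.random()
                acc = 0.0
                for cond, frac in cfg.laser_fracs.items():
                    acc += frac
                    if u < acc:
                        laser = cond
                        break
            if laser.startswith("laser_only"):
                modality = "none"
            t += cfg.iti_fixed + rng.exponential(cfg.iti_exp_mean)
            rows.append(
                dict(
                    session_id=session_id,
                    mouse_id=mouse_id,
                    block_index=b + 1,
                    block_rule=rule,
                    trial_index=trial_index,
                    trial_in_block=k + 1,
                    modality=modality,
                    stim_onset=t,
                    licks=[],
                    laser=laser,
                    cue=(k + 1 == cfg.cue_trial),
                    outcome=pd.NA,
                    believed_rule=pd.NA,
                )
            )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def simulate_agent(
    schedule: pd.DataFrame,
    agent: AgentConfig,
    task: TaskConfig | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fill licks, believed rule, and outcomes for a generated schedule.

    The agent responds according to its believed rule; a block switch is
    adopted (i) deterministically at the cue trial, or (ii) after the first
    unrewarded lick of the new block, with per-trial probability
    ``p_switch_after_feedback`` on each subsequent trial.
    """
    from xmodal.behavior import score_outcomes

    check_trial_table(schedule)
    if schedule.empty or schedule["block_index"].isna().any():
        raise StructuralError("schedule lacks block structure")
    task = task or TaskConfig()
    if rng is None:
        rng = np.random.default_rng(seed)

    trials = schedule.copy().reset_index(drop=True)
    lat_lo, lat_hi = agent.lick_latency_range
    ans_lo, ans_hi = task.answer_window
    believed = None
    feedback = False
    licks_col: list[list] = []
    believed_col: list[str] = []
    for row in trials.itertuples(index=False):
        actual = row.block_rule
        if believed is None:
            believed = actual  # trained agent: knows the first block's rule
        if row.trial_in_block == 1 and row.block_index > 1:
            feedback = False  # believed rule carries over from the old block
            if agent.instant_switch:
                believed = actual
        if believed != actual:
            if row.trial_in_block >= task.cue_trial:
                believed = actual  # cue: water at the new port forces adoption
            elif feedback and rng.random() < agent.p_switch_after_feedback:
                believed = actual
        licks = []
        if rng.random() < agent.p_prestim_lick:
            t = rng.uniform(*_PRESTIM_LICK_WINDOW)
            licks.append((t, RULE_PORT[believed]))
        if agent.p_censor_lick and rng.random() < agent.p_censor_lick:
            licks.append((rng.uniform(*task.censor_window), RULE_PORT[believed]))
        if row.modality == "none":
            if rng.random() < agent.laser_lick_prob:
                licks.append((rng.uniform(ans_lo, ans_hi), RULE_PORT[believed]))
        else:
            relevant_to_belief = row.modality == RULE_MODALITY[believed]
            p_lick = agent.p_hit if relevant_to_belief else agent.p_fa
            if row.laser in agent.laser_hit_delta and relevant_to_belief:
                p_lick = min(1.0, max(0.0, p_lick + agent.laser_hit_delta[row.laser]))
            if rng.random() < p_lick:
                latency = rng.uniform(max(lat_lo, ans_lo), min(lat_hi, ans_hi))
                port = RULE_PORT[believed]
                licks.append((latency, port))
                rewarded = (
                    row.modality == RULE_MODALITY[actual] and port == RULE_PORT[actual]
                )
                if not rewarded and believed != actual:
                    feedback = True
        licks.sort()
        licks_col.append(licks)
        believed_col.append(believed)
    trials["licks"] = licks_col
    trials["believed_rule"] = believed_col
    return score_outcomes(trials, task=task)


def _sample_halfcosine(rng, n: int, duration: float) -> np.ndarray:
    """Inverse-CDF sample of the half-cosine bump ``sin(pi t / D)`` on [0, D]."""
    u = rng.random(n)
    return duration / np.pi * np.arccos(1.0 - 2.0 * u)


def _sample_ramp(rng, n: int, width: float) -> np.ndarray:
    """Sample offsets in [0, width] with density rising linearly to the end."""
    return width * np.sqrt(rng.random(n))


def _enforce_refractory(times: np.ndarray, refractory: float) -> np.ndarray:
    """Delete spikes closer than ``refractory`` to their predecessor.

    Deletion removes a ~rate*refractory fraction of spikes, keeping counts
    Poisson to within that correction while making ISI-violation QC behave
    like it does for real (refractory) neurons.
    """
    if refractory <= 0 or times.size < 2:
        return times
    while True:
        bad = np.flatnonzero(np.diff(times) < refractory) + 1
        if bad.size == 0:
            return times
        # keep the first spike of each too-close run
        bad = bad[np.concatenate([[True], np.diff(bad) > 1])]
        times = np.delete(times, bad)


def simulate_spikes(
    trials: pd.DataFrame,
    pop: PopulationConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    stim_duration: float = 0.15,
) -> SpikeSet:
    """Inhomogeneous-Poisson spike trains realizing the configured effects.

    Per unit the rate is ``baseline * rule_gain`` (rule-modulated units in
    their preferred behavioral block) plus a half-cosine evoked bump during
    the stimulus (modality-matched units, scaled by ``relevance_gain`` when
    the stimulus is relevant under the block rule) plus a linear lick-locked
    ramp (choice units, lick trials only).  Baseline modulation follows the
    agent's *believed* rule so pre-stimulus states track behavioral
    transitions.  The three kernels are superposed exactly (each component is
    itself Poisson), so counts in any window obey the Poisson law.
    """
    check_trial_table(trials)
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else pop.seed)

    n = pop.n_units
    order = rng.permutation(n)
    n_rule = int(round(pop.frac_rule_mod * n))
    n_touch = int(round(pop.frac_touch_resp * n))
    n_light = int(round(pop.frac_light_resp * n))
    n_choice = int(round(pop.frac_choice * n))
    rule_mod = np.zeros(n, bool)
    rule_mod[order[:n_rule]] = True
    # half of rule-modulated units prefer each rule
    preferred = np.array(["touch"] * n, dtype=object)
    pref_light = order[:n_rule][1::2]
    preferred[pref_light] = "light"
    touch_resp = np.zeros(n, bool)
    touch_resp[rng.permutation(n)[:n_touch]] = True
    light_resp = np.zeros(n, bool)
    light_resp[rng.permutation(n)[:n_light]] = True
    choice_unit = np.zeros(n, bool)
    choice_unit[rng.permutation(n)[:n_choice]] = True
    baselines = rng.lognormal(pop.baseline_log_mean, pop.baseline_log_sigma, size=n)
    # per-unit evoked weight patterns; the light-block tactile pattern is the
    # touch-block pattern rotated toward an independent one by the configured
    # angle, so the evoked subspace rotates with the rule
    theta = np.deg2rad(pop.rule_rotation_deg)
    w_touch = rng.uniform(0.3, 1.7, size=n)
    w_indep = rng.uniform(0.3, 1.7, size=n)
    w_light = np.cos(theta) * w_touch + np.sin(theta) * w_indep

    onsets = trials["stim_onset"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) <= 0):
        raise StructuralError("trials must be strictly ordered by stim_onset")
    # baseline segments: midpoints between consecutive onsets; the session
    # spans from 0 to 3 s past the final onset
    mids = 0.5 * (onsets[:-1] + onsets[1:])
    seg_edges = np.concatenate([[0.0], mids, [onsets[-1] + 3.0]])
    believed = trials["believed_rule"].to_numpy(dtype=object)
    block_rule = trials["block_rule"].to_numpy(dtype=object)
    modality = trials["modality"].to_numpy(dtype=object)

    first_licks = np.full(len(trials), np.nan)
    for i, licks in enumerate(trials["licks"]):
        answer = [t for t, _ in licks if 0.1 <= t <= 2.0]
        if answer:
            first_licks[i] = min(answer)

    if pop.evoked_amp < 0 or pop.choice_amp < 0:
        warnings.warn("negative kernel amplitude clipped at 0")

    units = []
    session_id = str(trials["session_id"].iloc[0]) if len(trials) else "session"
    for u in range(n):
        spikes = []
        for i in range(len(trials)):
            a, b = seg_edges[i], seg_edges[i + 1]
            rate = baselines[u]
            if rule_mod[u] and believed[i] == preferred[u]:
                rate *= pop.rule_gain
            count = rng.poisson(max(rate, 0.0) * (b - a))
            spikes.append(rng.uniform(a, b, size=count))
            if modality[i] in ("tactile", "visual"):
                responsive = (modality[i] == "tactile" and touch_resp[u]) or (
                    modality[i] == "visual" and light_resp[u]
                )
                if responsive and pop.evoked_amp > 0:
                    amp = pop.evoked_amp
                    if modality[i] == "tactile":
                        amp *= w_touch[u] if block_rule[i] == "touch" else w_light[u]
                    if modality[i] == RULE_MODALITY[block_rule[i]]:
                        amp *= pop.relevance_gain
                    # integral of amp*sin(pi t/D) over [0, D] = amp*D*2/pi
                    mean_count = amp * stim_duration * 2.0 / np.pi
                    k = rng.poisson(mean_count)
                    spikes.append(onsets[i] + _sample_halfcosine(rng, k, stim_duration))
            if choice_unit[u] and pop.choice_amp > 0 and np.isfinite(first_licks[i]):
                k = rng.poisson(0.5 * pop.choice_amp * 0.1)
                t_lick = onsets[i] + first_licks[i]
                spikes.append(t_lick - 0.1 + _sample_ramp(rng, k, 0.1))
        times = np.sort(np.concatenate(spikes)) if spikes else np.array([])
        times = _enforce_refractory(times[times >= 0], pop.refractory_s)
        units.append(
            Unit(
                unit_id=f"{session_id}_u{u:03d}",
                area=pop.area,
                spike_times=times,
                qc=dict(
                    l_ratio=float(rng.uniform(0.0, 0.05)),
                    drift_um=float(rng.uniform(0.0, 20.0)),
                    rule_mod=bool(rule_mod[u]),
                    preferred_rule=str(preferred[u]) if rule_mod[u] else "",
                    touch_resp=bool(touch_resp[u]),
                    light_resp=bool(light_resp[u]),
                    choice_unit=bool(choice_unit[u]),
                    baseline_hz=float(baselines[u]),
                ),
            )
        )
    return SpikeSet(units=units, session_id=session_id)


def simulate_session(
    task: TaskConfig | None = None,
    agent: AgentConfig | None = None,
    pop: PopulationConfig | None = None,
    seed: int = 0,
    session_id: str = "s000",
    mouse_id: str = "m000",
) -> tuple[pd.DataFrame, SpikeSet]:
    """Generate one complete session: scored trials plus spike trains.

    A single seed is split into independent per-stage streams so that, e.g.,
    changing the population config cannot perturb the behavioral draw.
    """
    task = task or TaskConfig()
    agent = agent or AgentConfig()
    pop = pop or PopulationConfig()
    streams = split_rng(seed, "schedule", "agent", "spikes")
    schedule = generate_schedule(task, session_id=session_id, mouse_id=mouse_id,
                                 rng=streams["schedule"])
    trials = simulate_agent(schedule, agent, task=task, rng=streams["agent"])
    spikes = simulate_spikes(trials, pop, rng=streams["spikes"],
                             stim_duration=task.stim_duration)
    return trials, spikes


def simulate_sessions(
    n_sessions: int,
    task: TaskConfig | None = None,
    agent: AgentConfig | None = None,
    pop: PopulationConfig | None = None,
    seed: int = 0,
    n_mice: int = 1,
    with_spikes: bool = True,
):
    """Generate many sessions; sessions are assigned round-robin to mice.

    Returns ``(trials, spike_sets)`` where ``trials`` is the concatenated
    trial table and ``spike_sets`` maps session_id to a :class:`SpikeSet`
    (empty dict when ``with_spikes`` is False).
    """
    task = task or TaskConfig()
    agent = agent or AgentConfig()
    pop = pop or PopulationConfig()
    ss = np.random.SeedSequence(seed)
    tables, spike_sets = [], {}
    for i, child in enumerate(ss.spawn(n_sessions)):
        session_seed = int(child.generate_state(1)[0])
        sid, mid = f"s{i:03d}", f"m{i % n_mice:03d}"
        if with_spikes:
            trials, spikes = simulate_session(task, agent, pop, seed=session_seed,
                                              session_id=sid, mouse_id=mid)
            spike_sets[sid] = spikes
        else:
            streams = split_rng(session_seed, "schedule", "agent", "spikes")
            schedule = generate_schedule(task, session_id=sid, mouse_id=mid,
                                         rng=streams["schedule"])
            trials = simulate_agent(schedule, agent, task=task, rng=streams["agent"])
        tables.append(trials)
    all_trials = pd.concat(tables, ignore_index=True)
    return all_trials, spike_sets
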