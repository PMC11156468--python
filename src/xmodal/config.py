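"""Configuration objects for the synthetic task, agent, and population.

Defaults follow the task design: 4-6 rule blocks of 54-66 trials (mean 60),
tactile/visual stimuli randomly interleaved with at most 4 consecutive trials
of the same type, inter-trial intervals of 3.5 s plus an exponential component
with mean 4 s, a switch cue on the 9th trial of each block, and an agent that
performs ~75% correct with a feedback-driven rule-transition lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from xmodal.errors import ConfigError

#: Default per-area fractions for the population generator.  ``frac_rule_mod``
#: values follow the reported fractions of significantly rule-discriminating
#: units per area (S1 4.5%, S2 2.5%, MM 21.4%, ALM 10.2%); sensory/choice
#: fractions are plumbing defaults chosen so evoked analyses have signal.
AREA_PROFILES = {
    "S1-like": dict(frac_rule_mod=0.045, frac_touch_resp=0.80, frac_light_resp=0.10,
                    frac_choice=0.20),
    "S2-like": dict(frac_rule_mod=0.025, frac_touch_resp=0.70, frac_light_resp=0.15,
                    frac_choice=0.25),
    "MM-like": dict(frac_rule_mod=0.214, frac_touch_resp=0.40, frac_light_resp=0.25,
                    frac_choice=0.35),
    "ALM-like": dict(frac_rule_mod=0.102, frac_touch_resp=0.30, frac_light_resp=0.25,
                     frac_choice=0.40),
}


def _check(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(name, msg)


def _check_prob(value: float, name: str) -> None:
    _check(0.0 <= value <= 1.0, name, f"must be a probability in [0, 1], got {value}")


def _check_window(window, name: str) -> None:
    _check(
        len(window) == 2 and window[0] <= window[1],
        name,
        f"window bounds must be ordered, got {window}",
    )


@dataclass
class TaskConfig:
    """Trial-schedule parameters for one simulated session."""

    n_blocks: int | None = None  # None: drawn uniformly from [4, 6] per session
    block_len_range: tuple[int, int] = (54, 66)
    max_run: int = 4
    iti_fixed: float = 3.5
    iti_exp_mean: float = 4.0
    stim_duration: float = 0.15
    answer_window: tuple[float, float] = (0.1, 2.0)
    grace_window: tuple[float, float] = (0.0, 0.1)
    censor_window: tuple[float, float] = (-0.2, 0.0)
    cue_trial: int = 9
    laser_fracs: dict | None = None  # e.g. {"pre": .15, "post": .15, "laser_only_short": .1}
    seed: int = 0

    def __post_init__(self):
        if self.n_blocks is not None:
            _check(1 <= self.n_blocks <= 100, "n_blocks", f"must be in [1, 100], got {self.n_blocks}")
        lo, hi = self.block_len_range
        _check(1 <= lo <= hi <= 10_000, "block_len_range",
               f"must satisfy 1 <= low <= high <= 1e4, got {self.block_len_range}")
        _check(self.max_run >= 1, "max_run", f"must be >= 1, got {self.max_run}")
        _check(self.iti_fixed >= 0, "iti_fixed", "must be >= 0")
        _check(self.iti_exp_mean > 0, "iti_exp_mean", "must be > 0")
        _check(self.stim_duration > 0, "stim_duration", "must be > 0")
        _check_window(self.answer_window, "answer_window")
        _check_window(self.grace_window, "grace_window")
        _check_window(self.censor_window, "censor_window")
        _check(self.cue_trial >= 1, "cue_trial", f"must be >= 1, got {self.cue_trial}")
        if self.laser_fracs is not None:
            total = sum(self.laser_fracs.values())
            _check(0 <= total <= 1, "laser_fracs", "fractions must sum to <= 1")


@dataclass
class AgentConfig:
    """Behavioral policy of the simulated mouse.

    The agent acts according to its *believed* rule: it licks the believed
    rule's reward port with probability ``p_hit`` after the believed-relevant
    stimulus and with probability ``p_fa`` after the other stimulus.  After a
    block switch it keeps the old rule until its first unrewarded lick, then
    adopts the new rule with per-trial probability
    ``p_switch_after_feedback``, and always adopts it at the cue trial.
    """

    p_hit: float = 0.75
    p_fa: float = 0.25
    p_switch_after_feedback: float = 0.5
    instant_switch: bool = False  # adopt the new rule at the block boundary
    p_prestim_lick: float = 0.25
    p_censor_lick: float = 0.0
    lick_latency_range: tuple[float, float] = (0.15, 1.0)  # uniform, support > grace
    laser_hit_delta: dict = field(default_factory=dict)  # laser condition -> p_hit change
    laser_lick_prob: float = 0.0  # P(lick in response window) on laser-only trials

    def __post_init__(self):
        for name in ("p_hit", "p_fa", "p_switch_after_feedback", "p_prestim_lick",
                     "p_censor_lick", "laser_lick_prob"):
            _check_prob(getattr(self, name), name)
        lo, hi = self.lick_latency_range
        _check(0.1 < lo <= hi, "lick_latency_range",
               f"support must lie above 0.1 s and be ordered, got {self.lick_latency_range}")


@dataclass
class PopulationConfig:
    """Rate-model parameters for the Poisson spiking generator."""

    n_units: int = 30
    baseline_log_mean: float = 2.0  # log-normal parameters for baseline spikes/s
    baseline_log_sigma: float = 0.5
    frac_rule_mod: float | None = None  # None: taken from area_profile
    rule_gain: float = 2.5
    frac_touch_resp: float | None = None
    frac_light_resp: float | None = None
    frac_choice: float | None = None
    evoked_amp: float = 20.0
    relevance_gain: float = 1.5
    rule_rotation_deg: float = 0.0  # angle between tactile-evoked patterns across rules
    choice_amp: float = 10.0
    refractory_s: float = 0.0016  # dead time; keeps ISI-violation QC clean
    area_profile: str = "MM-like"
    seed: int = 0

    def __post_init__(self):
        _check(self.n_units >= 1, "n_units", f"must be >= 1, got {self.n_units}")
        _check(self.area_profile in AREA_PROFILES, "area_profile",
               f"must be one of {sorted(AREA_PROFILES)}, got {self.area_profile!r}")
        profile = AREA_PROFILES[self.area_profile]
        for name in ("frac_rule_mod", "frac_touch_resp", "frac_light_resp", "frac_choice"):
            if getattr(self, name) is None:
                setattr(self, name, profile[name])
            _check_prob(getattr(self, name), name)
        for name in ("rule_gain", "relevance_gain"):
            _check(getattr(self, name) >= 0, name, "must be >= 0")
        _check(0 <= self.rule_rotation_deg <= 90, "rule_rotation_deg",
               f"must be in [0, 90], got {self.rule_rotation_deg}")
        for name in ("evoked_amp", "choice_amp", "baseline_log_sigma"):
            _check(getattr(self, name) >= 0, name, "must be >= 0")

    @property
    def area(self) -> str:
        return self.area_profile.removesuffix("-like")


def config_to_dict(cfg) -> dict:
    return asdict(cfg)
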