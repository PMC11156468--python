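"""Shared domain containers: trial tables, spike sets, rate tensors.

A *trial table* is a :class:`pandas.DataFrame` with one row per trial and the
columns in :data:`TRIAL_COLUMNS`.  Licks are stored in-memory as a list of
``(time, port)`` tuples with times in seconds relative to stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RULES = ("touch", "light")
MODALITIES = ("tactile", "visual", "none")
PORTS = ("left", "right")
OUTCOMES = ("hit", "miss", "false_alarm", "correct_rejection", "censored")
LASER_CONDITIONS = ("none", "pre", "post", "laser_only_short", "laser_only_long")

#: Rewarded port under each rule.
RULE_PORT = {"touch": "right", "light": "left"}
#: Relevant stimulus modality under each rule.
RULE_MODALITY = {"touch": "tactile", "light": "visual"}

TRIAL_COLUMNS = [
    "session_id",
    "mouse_id",
    "block_index",
    "block_rule",
    "trial_index",
    "trial_in_block",
    "modality",
    "stim_onset",
    "licks",
    "laser",
    "cue",
    "outcome",
    "believed_rule",
]


def empty_trial_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in TRIAL_COLUMNS})


def check_trial_table(trials: pd.DataFrame, require: tuple[str, ...] = ()) -> None:
    """Raise :class:`~xmodal.errors.StructuralError` if columns are missing."""
    from xmodal.errors import StructuralError

    missing = [c for c in (*TRIAL_COLUMNS[:8], *require) if c not in trials.columns]
    if missing:
        raise StructuralError(f"trial table lacks columns: {missing}")


@dataclass
class Unit:
    """A single recorded or simulated unit."""

    unit_id: str
    area: str
    spike_times: np.ndarray
    qc: dict = field(default_factory=dict)

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size and np.any(np.diff(self.spike_times) < 0):
            self.spike_times = np.sort(self.spike_times)
        if self.spike_times.size and self.spike_times[0] < 0:
            raise ValueError(f"unit {self.unit_id}: negative spike time")


@dataclass
class SpikeSet:
    """Spike trains for one session's units plus per-unit metadata."""

    units: list[Unit]
    session_id: str = "session"

    def __len__(self) -> int:
        return len(self.units)

    def __iter__(self):
        return iter(self.units)

    @property
    def unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units]

    def subset(self, unit_ids) -> "SpikeSet":
        keep = set(unit_ids)
        return SpikeSet(
            units=[u for u in self.units if u.unit_id in keep],
            session_id=self.session_id,
        )


@dataclass
class RateTensor:
    """Firing rates indexed ``(unit, trial, time-bin)`` with provenance.

    ``values`` are spikes/s.  ``window`` is half-open relative to
    ``align_event``; bin *b* covers ``[window[0] + b*bin_size,
    window[0] + (b+1)*bin_size)``.
    """

    values: np.ndarray
    bin_size: float
    align_event: str
    window: tuple[float, float]
    unit_ids: list[str]
    trial_index: np.ndarray  # trial_index values of the rows in axis 1
    smoothing_sigma: float | None = None
    normalized: bool = False
    norm_mean: np.ndarray | None = None  # per-unit mean used by soft normalization
    norm_range: np.ndarray | None = None  # per-unit range used by soft normalization

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.trial_index = np.asarray(self.trial_index)
        n_bins = int(round((self.window[1] - self.window[0]) / self.bin_size))
        if self.values.shape[2] != n_bins:
            raise ValueError(
                f"bin count {self.values.shape[2]} != window/bin_size = {n_bins}"
            )

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]

    @property
    def bin_edges(self) -> np.ndarray:
        return self.window[0] + self.bin_size * np.arange(self.n_bins + 1)

    @property
    def bin_centers(self) -> np.ndarray:
        edges = self.bin_edges
        return 0.5 * (edges[:-1] + edges[1:])

    def trial_rows(self, trial_index_values) -> np.ndarray:
        """Map trial_index values to axis-1 row positions."""
        lookup = {t: i for i, t in enumerate(self.trial_index)}
        return np.array([lookup[t] for t in trial_index_values], dtype=int)

    def select_trials(self, trial_index_values) -> "RateTensor":
        rows = self.trial_rows(trial_index_values)
        return RateTensor(
            values=self.values[:, rows, :],
            bin_size=self.bin_size,
            align_event=self.align_event,
            window=self.window,
            unit_ids=list(self.unit_ids),
            trial_index=self.trial_index[rows],
            smoothing_sigma=self.smoothing_sigma,
            normalized=self.normalized,
            norm_mean=self.norm_mean,
            norm_range=self.norm_range,
        )


def split_rng(seed: int, *labels: str) -> dict[str, np.random.Generator]:
    """Derive independent, reproducible per-stage generators from one seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(labels))
    return {lab: np.random.default_rng(c) for lab, c in zip(labels, children)}
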