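import numpy as np
import pandas as pd
import pytest

from xmodal.core import TRIAL_COLUMNS
from xmodal.config import AgentConfig, PopulationConfig, TaskConfig
from xmodal.synthetic import simulate_session


def make_trials(rows, session_id="s000", mouse_id="m000", iti=8.0):
    """Build a trial table from compact row dicts.

    Each row may give: rule, modality, licks, laser, outcome, block (index);
    indices, onsets, and trial_in_block are filled automatically.
    """
    records = []
    block_counter = {}
    for i, r in enumerate(rows):
        block = r.get("block", 1)
        block_counter[block] = block_counter.get(block, 0) + 1
        records.append(dict(
            session_id=r.get("session_id", session_id),
            mouse_id=r.get("mouse_id", mouse_id),
            block_index=block,
            block_rule=r.get("rule", "touch"),
            trial_index=i + 1,
            trial_in_block=block_counter[block],
            modality=r.get("modality", "tactile"),
            stim_onset=(i + 1) * iti,
            licks=r.get("licks", []),
            laser=r.get("laser", "none"),
            cue=r.get("cue", False),
            outcome=r.get("outcome", pd.NA),
            believed_rule=r.get("believed_rule", r.get("rule", "touch")),
        ))
    return pd.DataFrame(records, columns=TRIAL_COLUMNS)


@pytest.fixture(scope="session")
def small_task():
    # short blocks keep simulated sessions cheap while preserving structure
    return TaskConfig(n_blocks=4, block_len_range=(18, 22))


@pytest.fixture(scope="session")
def default_session():
    """One full default session (trials + spikes), shared across tests."""
    return simulate_session(seed=11)


@pytest.fixture(scope="session")
def small_session(small_task):
    pop = PopulationConfig(n_units=20)
    return simulate_session(task=small_task, pop=pop, seed=7)
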