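"""Spike trains -> analysis-ready rate tensors.

Rates are computed in half-open bins ``[t, t + bin)`` relative to an
alignment event, optionally smoothed with a mass-conserving truncated
Gaussian, and soft-normalized per unit as ``(rate - mean) / (range + 5)`` so
population analyses operate on roughly unity-scaled activity while damping
low-rate units.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from xmodal.core import RateTensor, SpikeSet

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# unit QC

@dataclass
class UnitQCMetrics:
    isi_violation_rate: float  # fraction of ISIs < 1.5 ms
    presence_ratio: float  # fraction of session tenths containing >= 1 spike
    l_ratio: float | None  # supplied cluster-quality metric
    drift_um: float | None  # supplied cumulative depth drift

    def passes(
        self,
        max_isi_violation: float = 0.005,
        min_presence: float = 0.9,
        max_l_ratio: float = 0.1,
        max_drift: float = 40.0,
    ) -> bool:
        ok = (self.isi_violation_rate <= max_isi_violation
              and self.presence_ratio >= min_presence)
        if self.l_ratio is not None:
            ok = ok and self.l_ratio <= max_l_ratio
        if self.drift_um is not None:
            ok = ok and self.drift_um <= max_drift
        return ok


def compute_unit_qc(
    spike_times: np.ndarray,
    session_span: tuple[float, float],
    supplied: dict | None = None,
    n_segments: int = 10,
    isi_threshold: float = 0.0015,
) -> UnitQCMetrics:
    """ISI-violation rate and presence ratio from spike times.

    Presence ratio = fraction of ``n_segments`` equal session segments that
    contain at least one spike.  ``l_ratio`` and ``drift_um`` are taken from
    ``supplied`` metadata when present (pass-through thresholds).
    """
    supplied = supplied or {}
    t = np.asarray(spike_times, dtype=float)
    if t.size >= 2:
        isi = np.diff(t)
        viol = float(np.mean(isi < isi_threshold))
    else:
        viol = 0.0
    lo, hi = session_span
    edges = np.linspace(lo, hi, n_segments + 1)
    counts, _ = np.histogram(t, bins=edges)
    presence = float(np.mean(counts > 0)) if t.size else 0.0
    l_ratio = supplied.get("l_ratio")
    drift = supplied.get("drift_um")
    if l_ratio is None or drift is None:
        warnings.warn("missing supplied QC metric (l_ratio/drift_um); "
                      "unit judged on available metrics only")
    return UnitQCMetrics(viol, presence, l_ratio, drift)


def unit_qc_filter(
    spikes: SpikeSet,
    session_span: tuple[float, float],
    **thresholds,
) -> tuple[SpikeSet, pd.DataFrame]:
    """Return the passing units plus a per-unit QC report."""
    rows, keep = [], []
    for unit in spikes:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            qc = compute_unit_qc(unit.spike_times, session_span, supplied=unit.qc)
        ok = qc.passes(**thresholds)
        rows.append(dict(unit_id=unit.unit_id, area=unit.area,
                         isi_violation_rate=qc.isi_violation_rate,
                         presence_ratio=qc.presence_ratio,
                         l_ratio=qc.l_ratio, drift_um=qc.drift_um, kept=ok))
        if ok:
            keep.append(unit.unit_id)
    return spikes.subset(keep), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# binning and smoothing

def gaussian_smooth(values: np.ndarray, sigma_bins: float) -> np.ndarray:
    """Smooth along the last axis with a truncated (+-3 sigma) Gaussian.

    The kernel is column-normalized (each source bin's outgoing weights sum
    to one), so the total mass — and hence each trace's time-mean — is
    conserved exactly, including at the edges.
    """
    if sigma_bins <= 0:
        return values
    n = values.shape[-1]
    half = int(np.ceil(3 * sigma_bins))
    offsets = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (offsets / sigma_bins) ** 2)
    idx = np.arange(n)
    weights = np.zeros((n, n))
    for o, k in zip(offsets, kernel):
        src = idx[(idx + o >= 0) & (idx + o < n)]
        weights[src + o, src] += k
    weights /= weights.sum(axis=0, keepdims=True)
    return values @ weights.T


def bin_rates(
    spikes: SpikeSet,
    trials: pd.DataFrame,
    align_event: str = "stim_onset",
    window: tuple[float, float] = (-0.1, 0.15),
    bin_size: float = 0.01,
    sigma: float | None = None,
) -> RateTensor:
    """Per-trial spike rates in half-open bins relative to an event.

    Trials whose alignment event is missing are omitted (logged).  ``sigma``
    is the Gaussian smoothing width in seconds (``None`` = no smoothing).
    """
    n_bins = (window[1] - window[0]) / bin_size
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("window length must be divisible by bin_size")
    n_bins = int(round(n_bins))
    # smoothing uses a padded window so every kept bin sees full kernel
    # support (no edge renormalization artifacts inside the analysis window)
    pad = int(np.ceil(3 * sigma / bin_size)) if sigma else 0
    work_window = (window[0] - pad * bin_size, window[1] + pad * bin_size)
    events = trials[align_event].to_numpy(dtype=float)
    ok = np.isfinite(events)
    if not ok.all():
        log.info("bin_rates: omitting %d trials without %s", (~ok).sum(), align_event)
    events = events[ok]
    trial_index = trials["trial_index"].to_numpy()[ok]
    edges = work_window[0] + bin_size * np.arange(n_bins + 2 * pad + 1)
    values = np.empty((len(spikes), events.size, n_bins + 2 * pad))
    for ui, unit in enumerate(spikes):
        t = unit.spike_times
        for ti, ev in enumerate(events):
            rel = t[(t >= ev + work_window[0]) & (t < ev + work_window[1])] - ev
            counts, _ = np.histogram(rel, bins=edges)
            values[ui, ti] = counts / bin_size
    if sigma:
        values = gaussian_smooth(values, sigma / bin_size)
    if pad:
        values = values[:, :, pad:-pad]
    return RateTensor(
        values=values, bin_size=bin_size, align_event=align_event, window=window,
        unit_ids=spikes.unit_ids, trial_index=trial_index,
        smoothing_sigma=sigma,
    )


# ---------------------------------------------------------------------------
# normalization and trial exclusion

def soft_normalize(tensor: RateTensor, soft_factor: float = 5.0) -> RateTensor:
    """Per-unit ``(rate - mean) / (range + 5)`` over all trials and bins.

    The mean and range are stored on the result so the transform is exactly
    invertible; a constant (or silent) unit maps to all zeros (range 0,
    denominator 5).
    """
    if tensor.normalized:
        raise ValueError("tensor is already normalized")
    flat = tensor.values.reshape(tensor.n_units, -1)
    mean = flat.mean(axis=1)
    rng_ = flat.max(axis=1) - flat.min(axis=1)
    values = (tensor.values - mean[:, None, None]) / (rng_ + soft_factor)[:, None, None]
    return RateTensor(
        values=values, bin_size=tensor.bin_size, align_event=tensor.align_event,
        window=tensor.window, unit_ids=list(tensor.unit_ids),
        trial_index=tensor.trial_index.copy(),
        smoothing_sigma=tensor.smoothing_sigma,
        normalized=True, norm_mean=mean, norm_range=rng_,
    )


def undo_soft_normalize(tensor: RateTensor, soft_factor: float = 5.0) -> np.ndarray:
    """Invert :func:`soft_normalize` using the stored parameters."""
    if not tensor.normalized:
        raise ValueError("tensor is not normalized")
    return (tensor.values * (tensor.norm_range + soft_factor)[:, None, None]
            + tensor.norm_mean[:, None, None])


def exclude_prestim_lick_trials(
    trials: pd.DataFrame,
    window: tuple[float, float] = (-1.0, 0.0),
) -> pd.DataFrame:
    """Remove trials with any lick in the pre-stimulus window."""
    lo, hi = window
    keep = [
        not any(lo <= t < hi for t, _ in licks)
        for licks in trials["licks"]
    ]
    return trials[np.asarray(keep)]
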