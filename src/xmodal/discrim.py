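"""Single-unit ideal-observer (ROC) discriminability and PSTH permutation test.

The AUC for two trial classes is the Mann-Whitney statistic
``P(X_b > X_a) + 0.5 * P(X_b = X_a)``: 0.5 is chance and values above 0.5
mean higher activity in class *b*.  Bootstrap percentile CIs are
Bonferroni-corrected across comparisons; a unit discriminating an evoked
contrast is called significant when the corrected 95% CI excludes 0.5 in at
least three consecutive time bins, and for single-bin (pre-stimulus)
contrasts when the corrected CI excludes 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from xmodal.core import RateTensor
from xmodal.errors import StructuralError
from xmodal.stats import bonferroni_alpha, bonferroni_pvalues

CONTRASTS = ("tHit-vs-tCR", "rule", "stimulus")


# ---------------------------------------------------------------------------
# AUC primitives

def trial_auc(counts_a, counts_b) -> float:
    """Ideal-observer AUC between two groups of per-trial values."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("trial_auc requires non-empty groups")
    return float(_auc_columns(a[:, None], b[:, None])[0])


def _auc_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise AUC for 2-d arrays ``(trials, k)`` via midranks."""
    n_a, n_b = a.shape[0], b.shape[0]
    combined = np.concatenate([a, b], axis=0)
    ranks = sps.rankdata(combined, axis=0)  # midranks implement the tie convention
    rank_sum_b = ranks[n_a:].sum(axis=0)
    return (rank_sum_b - n_b * (n_b + 1) / 2.0) / (n_a * n_b)


def _bootstrap_auc(
    a: np.ndarray,
    b: np.ndarray,
    n_boot: int,
    alpha: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin AUC with stratified bootstrap percentile CI at level ``alpha``."""
    auc = _auc_columns(a, b)
    n_a, n_b = a.shape[0], b.shape[0]
    boot = np.empty((n_boot, a.shape[1]))
    for i in range(n_boot):
        ia = rng.integers(0, n_a, n_a)
        ib = rng.integers(0, n_b, n_b)
        boot[i] = _auc_columns(a[ia], b[ib])
    lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
    return auc, lo, hi


# ---------------------------------------------------------------------------
# trial-class selectors

def _correct(trials: pd.DataFrame) -> pd.DataFrame:
    return trials[trials["outcome"].isin(("hit", "correct_rejection"))]


def contrast_classes(trials: pd.DataFrame, contrast: str) -> tuple[np.ndarray, np.ndarray]:
    """Trial-index arrays ``(class_a, class_b)`` for a named contrast.

    ``tHit-vs-tCR``: tactile correct trials split by rule (a=tCR, b=tHit).
    ``rule``: correct trials split by block type (a=light, b=touch).
    ``stimulus``: correct trials split by modality (a=visual, b=tactile).
    """
    c = _correct(trials)
    if contrast == "tHit-vs-tCR":
        tac = c[c["modality"] == "tactile"]
        a = tac[tac["block_rule"] == "light"]  # tCR
        b = tac[tac["block_rule"] == "touch"]  # tHit
    elif contrast == "rule":
        a = c[c["block_rule"] == "light"]
        b = c[c["block_rule"] == "touch"]
    elif contrast == "stimulus":
        a = c[c["modality"] == "visual"]
        b = c[c["modality"] == "tactile"]
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    return a["trial_index"].to_numpy(), b["trial_index"].to_numpy()


def _window_bins(tensor: RateTensor, window: tuple[float, float]) -> np.ndarray:
    edges = tensor.bin_edges
    return np.where((edges[:-1] >= window[0] - 1e-9) & (edges[1:] <= window[1] + 1e-9))[0]


# ---------------------------------------------------------------------------
# results

@dataclass
class AUCResult:
    unit_id: str
    contrast: str
    auc: np.ndarray  # per analysis bin
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    significant: bool
    window: tuple[float, float]
    bin_size: float

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc))


def results_frame(results: list[AUCResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for b, (auc, lo, hi) in enumerate(zip(r.auc, r.ci_lo, r.ci_hi)):
            rows.append(dict(unit_id=r.unit_id, contrast=r.contrast, bin=b,
                             auc=auc, lo=lo, hi=hi, significant=r.significant))
    return pd.DataFrame(rows)


def _has_consecutive(mask: np.ndarray, k: int) -> bool:
    run = 0
    for m in mask:
        run = run + 1 if m else 0
        if run >= k:
            return True
    return False


def evoked_discrim(
    tensor: RateTensor,
    trials: pd.DataFrame,
    contrast: str = "tHit-vs-tCR",
    window: tuple[float, float] = (0.0, 0.15),
    n_boot: int = 1000,
    alpha: float = 0.05,
    min_consecutive: int = 3,
    n_comparisons: int | None = None,
    seed: int | None = None,
) -> list[AUCResult]:
    """Per-bin AUC over an evoked window with the consecutive-bin rule.

    The CI level is Bonferroni-corrected for ``n_comparisons`` (default:
    analysis bins x units in the tensor, i.e. the area's units).
    """
    if n_boot < 100:
        warnings.warn("n_boot < 100: CIs will be unstable")
    rng = np.random.default_rng(seed)
    bins = _window_bins(tensor, window)
    idx_a, idx_b = contrast_classes(trials, contrast)
    idx_a = np.intersect1d(idx_a, tensor.trial_index)
    idx_b = np.intersect1d(idx_b, tensor.trial_index)
    if idx_a.size < 2 or idx_b.size < 2:
        raise StructuralError("need >= 2 trials per class")
    ratio = max(idx_a.size, idx_b.size) / min(idx_a.size, idx_b.size)
    if ratio > 50:
        warnings.warn(f"class imbalance {ratio:.0f}:1")
    if n_comparisons is None:
        n_comparisons = bins.size * tensor.n_units
    level = bonferroni_alpha(alpha, n_comparisons)
    rows_a = tensor.trial_rows(idx_a)
    rows_b = tensor.trial_rows(idx_b)
    results = []
    for ui, unit_id in enumerate(tensor.unit_ids):
        a = tensor.values[ui][np.ix_(rows_a, bins)]
        b = tensor.values[ui][np.ix_(rows_b, bins)]
        auc, lo, hi = _bootstrap_auc(a, b, n_boot, level, rng)
        sig_bins = (lo > 0.5) | (hi < 0.5)
        results.append(AUCResult(
            unit_id=unit_id, contrast=contrast, auc=auc, ci_lo=lo, ci_hi=hi,
            significant=_has_consecutive(sig_bins, min_consecutive),
            window=window, bin_size=tensor.bin_size,
        ))
    return results


def prestim_discrim(
    tensor: RateTensor,
    trials: pd.DataFrame,
    contrast: str = "rule",
    window: tuple[float, float] = (-0.1, 0.0),
    n_boot: int = 1000,
    alpha: float = 0.05,
    n_comparisons: int | None = None,
    seed: int | None = None,
) -> list[AUCResult]:
    """Single-bin AUC on pre-stimulus activity (100 ms bin, no smoothing).

    Callers must pass correct-trials-compatible data with pre-stimulus-lick
    trials already excluded; the contrast selectors keep correct trials only.
    Significant iff the Bonferroni-corrected (across units) CI excludes 0.5.
    """
    bins = _window_bins(tensor, window)
    if bins.size != 1:
        raise ValueError(f"expected a single analysis bin in {window}, got {bins.size}")
    if n_comparisons is None:
        n_comparisons = tensor.n_units
    return evoked_discrim(
        tensor, trials, contrast=contrast, window=window, n_boot=n_boot,
        alpha=alpha, min_consecutive=1, n_comparisons=n_comparisons, seed=seed,
    )


def significant_fraction(results: list[AUCResult]) -> float:
    return float(np.mean([r.significant for r in results])) if results else np.nan


# ---------------------------------------------------------------------------
# PSTH permutation test

def psth_permutation_test(
    tensor: RateTensor,
    trials: pd.DataFrame,
    window: tuple[float, float] = (0.0, 0.25),
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """tHit vs tactile-false-alarm PSTH distance, per-unit permutation p.

    Statistic: Euclidean distance between the two groups' mean PSTHs over the
    window.  One-tailed p with the add-one convention; verdicts Bonferroni-
    corrected across units.
    """
    rng = np.random.default_rng(seed)
    bins = _window_bins(tensor, window)
    tac = trials[trials["modality"] == "tactile"]
    idx_hit = np.intersect1d(
        tac[tac["outcome"] == "hit"]["trial_index"].to_numpy(), tensor.trial_index)
    idx_fa = np.intersect1d(
        tac[tac["outcome"] == "false_alarm"]["trial_index"].to_numpy(), tensor.trial_index)
    if idx_hit.size == 0 or idx_fa.size == 0:
        raise StructuralError("both tHit and tactile-FA trials are required")
    low_power = min(idx_hit.size, idx_fa.size) < 5
    rows = np.concatenate([tensor.trial_rows(idx_hit), tensor.trial_rows(idx_fa)])
    n_hit = idx_hit.size
    labels = np.zeros(rows.size, dtype=bool)
    labels[:n_hit] = True
    out = []
    perms = [rng.permutation(labels) for _ in range(n_perm)]
    for ui, unit_id in enumerate(tensor.unit_ids):
        x = tensor.values[ui][np.ix_(rows, bins)]
        obs = float(np.linalg.norm(x[labels].mean(axis=0) - x[~labels].mean(axis=0)))
        null = np.array([
            np.linalg.norm(x[p].mean(axis=0) - x[~p].mean(axis=0)) for p in perms
        ])
        p = (1 + np.sum(null >= obs)) / (n_perm + 1)
        out.append(dict(unit_id=unit_id, distance=obs, p=p, low_power=low_power))
    df = pd.DataFrame(out)
    df["p_bonferroni"] = bonferroni_pvalues(df["p"].to_numpy())
    df["significant"] = df["p_bonferroni"] < alpha
    return df


# ---------------------------------------------------------------------------
# pre/post correlation

def prestim_evoked_correlation(
    rule_results: list[AUCResult],
    evoked_results: list[AUCResult],
    significant_only: bool = True,
) -> tuple[float, float, int] | None:
    """Pearson r between pre-stimulus rule AUC and evoked AUC across units.

    Restricted to units with significant pre-stimulus rule discriminability
    (when ``significant_only``); returns ``None`` with fewer than 3 units.
    """
    rule_map = {r.unit_id: r for r in rule_results}
    pairs = []
    for ev in evoked_results:
        r = rule_map.get(ev.unit_id)
        if r is None or (significant_only and not r.significant):
            continue
        pairs.append((r.mean_auc, ev.mean_auc))
    if len(pairs) < 3:
        return None
    x, y = np.array(pairs).T
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), len(pairs)
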