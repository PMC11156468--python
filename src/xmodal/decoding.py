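"""Cross-validated population decoding and rule-transition classification.

Decoders operate on one feature per unit per trial: the soft-normalized mean
rate in a pre-stimulus (-100-0 ms) or post-stimulus (0-100 ms) window.
Accuracy is stratified 10-fold cross-validation; the chance control permutes
trial labels and reruns the identical cross-validation.  For transitions, a
linear discriminant is trained on 90% of correct non-transition trials and
applied to held-out correct trials and to early/late transition-period
trials; the fraction classified respond-to-touch is rank-correlated
(Kendall's tau-b) with period order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from xmodal.behavior import TransitionParse
from xmodal.core import RateTensor
from xmodal.stats import ResampleCI, bootstrap_ci_of_groups

WINDOWS = {"pre": (-0.1, 0.0), "post": (0.0, 0.1)}

#: Ordered analysis periods for transition tracking: held-out pre-switch
#: correct trials, early transition, late transition, held-out post-first-hit
#: correct trials.
TRANSITION_PERIODS = ("pre_switch", "early", "late", "post_first_hit")


def _make_classifier(name: str, n_features: int, n_samples: int, seed: int | None):
    if name == "lda":
        # shrink toward the diagonal when the problem is ill-conditioned
        if n_features >= n_samples:
            return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        return LinearDiscriminantAnalysis()
    if name == "svm":
        return SVC(kernel="linear")
    if name == "rf":
        return RandomForestClassifier(n_estimators=500, random_state=seed)
    raise ValueError(f"unknown classifier {name!r}")


def window_features(tensor: RateTensor, window) -> np.ndarray:
    """One feature per unit: mean rate over the window bins -> (trials, units)."""
    if isinstance(window, str):
        window = WINDOWS[window]
    edges = tensor.bin_edges
    bins = np.where((edges[:-1] >= window[0] - 1e-9) & (edges[1:] <= window[1] + 1e-9))[0]
    if bins.size == 0:
        raise ValueError(f"tensor does not cover window {window}")
    return tensor.values[:, :, bins].mean(axis=2).T


@dataclass
class DecodingResult:
    session_id: str
    target: str
    window: str
    classifier: str
    accuracy: float
    accuracy_shuffled: float
    fold_accuracies: np.ndarray
    n_trials: int
    n_folds: int


def _cv_accuracy(X, y, classifier, k, seed) -> np.ndarray:
    counts = pd.Series(y).value_counts()
    folds = min(k, int(counts.min()))
    if folds < k:
        warnings.warn(f"folds reduced to {folds} (fewest class has {counts.min()} trials)")
    if folds < 2:
        raise ValueError("need at least 2 trials in the smallest class")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(X, y):
        clf = _make_classifier(classifier, X.shape[1], train.size, seed)
        clf.fit(X[train], y[train])
        accs.append(float(np.mean(clf.predict(X[test]) == y[test])))
    return np.asarray(accs)


def decode(
    tensor: RateTensor,
    trials: pd.DataFrame,
    target: str = "rule",
    window: str = "pre",
    classifier: str = "lda",
    k: int = 10,
    n_shuffle: int = 100,
    seed: int | None = None,
) -> DecodingResult:
    """Stratified k-fold decoding of rule or stimulus from population activity.

    All correct trials are used.  The shuffled control permutes the trial
    labels and reruns the identical cross-validation, averaged over
    ``n_shuffle`` permutations.
    """
    if not tensor.normalized:
        warnings.warn("decoding on an unnormalized tensor")
    correct = trials[trials["outcome"].isin(("hit", "correct_rejection"))]
    idx = np.intersect1d(correct["trial_index"].to_numpy(), tensor.trial_index)
    sub = tensor.select_trials(idx)
    lookup = correct.set_index("trial_index")
    col = "block_rule" if target == "rule" else "modality"
    y = lookup.loc[idx, col].to_numpy(dtype=object)
    if len(np.unique(y)) < 2:
        raise ValueError(f"single class for target {target!r}")
    X = window_features(sub, window)
    rng = np.random.default_rng(seed)
    fold_acc = _cv_accuracy(X, y, classifier, k, seed=int(rng.integers(2**31)))
    shuffled = []
    for _ in range(n_shuffle):
        y_perm = y[rng.permutation(y.size)]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                shuffled.append(_cv_accuracy(
                    X, y_perm, classifier, k, seed=int(rng.integers(2**31))).mean())
        except ValueError:
            continue
    session_id = str(trials["session_id"].iloc[0]) if len(trials) else ""
    return DecodingResult(
        session_id=session_id,
        target=target,
        window=window if isinstance(window, str) else str(window),
        classifier=classifier,
        accuracy=float(fold_acc.mean()),
        accuracy_shuffled=float(np.mean(shuffled)) if shuffled else np.nan,
        fold_accuracies=fold_acc,
        n_trials=int(idx.size),
        n_folds=fold_acc.size,
    )


# ---------------------------------------------------------------------------
# rule-transition classification

@dataclass
class TransitionResult:
    session_id: str
    direction: str
    fractions: dict[str, float]  # period -> fraction classified respond-to-touch
    period_counts: dict[str, int]
    tau: float
    train_trials: np.ndarray = field(default_factory=lambda: np.array([]))


def kendalls_tau(ordered_values) -> float:
    """Tie-corrected Kendall's tau-b of values against their rank order."""
    v = np.asarray(ordered_values, dtype=float)
    if v.size < 3:
        raise ValueError("kendalls_tau needs >= 3 values")
    if np.allclose(v, v[0]):
        warnings.warn("all values equal; tau = 0 by convention")
        return 0.0
    tau, _ = sps.kendalltau(v, np.arange(v.size))
    return float(tau)


def transition_classify(
    tensor: RateTensor,
    trials: pd.DataFrame,
    parses: list[TransitionParse],
    direction: str,
    window: str = "pre",
    train_frac: float = 0.9,
    seed: int | None = None,
) -> TransitionResult | None:
    """Classify transition-period trials by block type for one session.

    Training data: ``train_frac`` of the correct trials outside any
    transition period; the held-out remainder provides the pre-switch and
    post-first-hit period fractions.  Returns ``None`` when fewer than 3
    periods are populated.
    """
    rng = np.random.default_rng(seed)
    parses = [p for p in parses if p.direction == direction and not p.open]
    if not parses:
        return None
    transition_set = set()
    for p in parses:
        transition_set.update(p.transition_trials)
    correct = trials[trials["outcome"].isin(("hit", "correct_rejection"))]
    correct_idx = np.intersect1d(correct["trial_index"].to_numpy(), tensor.trial_index)
    nontrans = np.array([t for t in correct_idx if t not in transition_set])
    perm = rng.permutation(nontrans.size)
    n_train = max(2, int(round(train_frac * nontrans.size)))
    train_idx = np.sort(nontrans[perm[:n_train]])
    held_idx = np.sort(nontrans[perm[n_train:]])
    lookup = trials.set_index("trial_index")
    y_train = lookup.loc[train_idx, "block_rule"].to_numpy(dtype=object)
    if len(np.unique(y_train)) < 2:
        return None
    X_train = window_features(tensor.select_trials(train_idx), window)
    clf = _make_classifier("lda", X_train.shape[1], X_train.shape[0], seed)
    clf.fit(X_train, y_train)

    def _frac_touch(idx) -> tuple[float, int]:
        idx = np.intersect1d(np.asarray(sorted(idx), dtype=int), tensor.trial_index)
        if idx.size == 0:
            return np.nan, 0
        pred = clf.predict(window_features(tensor.select_trials(idx), window))
        return float(np.mean(pred == "touch")), int(idx.size)

    held = set(held_idx)
    pre_switch, post_hit, early, late = set(), set(), set(), set()
    for p in parses:
        for t in held:
            row = lookup.loc[t]
            if row["block_index"] == p.block_index - 1:
                pre_switch.add(t)
            elif row["block_index"] == p.block_index and p.first_hit is not None \
                    and t > p.first_hit:
                post_hit.add(t)
        early.update(p.early)
        late.update(p.late)
    fractions, counts = {}, {}
    for name, idx in zip(TRANSITION_PERIODS, (pre_switch, early, late, post_hit)):
        fractions[name], counts[name] = _frac_touch(idx)
    values = [fractions[p] for p in TRANSITION_PERIODS if counts[p] > 0]
    if len(values) < 3:
        return None
    session_id = str(trials["session_id"].iloc[0])
    return TransitionResult(
        session_id=session_id,
        direction=direction,
        fractions=fractions,
        period_counts=counts,
        tau=kendalls_tau(values),
        train_trials=train_idx,
    )


def transition_tau_ci(
    results: list[TransitionResult],
    n_iter: int = 1000,
    seed: int | None = None,
) -> ResampleCI:
    """Bootstrap CI on the mean Kendall's tau across sessions.

    Significant when the 95% CI excludes 0.
    """
    taus = [r.tau for r in results if np.isfinite(r.tau)]
    if not taus:
        raise ValueError("no finite tau values")
    return bootstrap_ci_of_groups(
        [[t] for t in taus], n_iter=n_iter, seed=seed, reference=0.0,
        levels=("sessions", "tau"),
    )
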