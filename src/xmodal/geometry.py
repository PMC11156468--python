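"""Population geometry: trajectory distances, subspace overlap, coding dimensions.

All analyses operate on soft-normalized rate tensors.  Trajectory PCA treats
time points of trial-averaged condition trajectories as observations and
units as variables; single trials are projected into the top-3 component
space.  Subspace overlap is the ratio of one condition's variance captured by
another condition's top components to the variance captured by its own.  A
coding dimension is the unit-norm population direction separating two
condition-averaged trajectories, averaged over an analysis window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from xmodal.config import TaskConfig
from xmodal.core import RateTensor
from xmodal.errors import StructuralError

# ---------------------------------------------------------------------------
# condition selectors

_CONDITION_QUERY = {
    "tHit": ("tactile", "hit"),
    "tCR": ("tactile", "correct_rejection"),
    "vHit": ("visual", "hit"),
    "vCR": ("visual", "correct_rejection"),
}


def condition_trials(trials: pd.DataFrame, name: str) -> np.ndarray:
    modality, outcome = _CONDITION_QUERY[name]
    sub = trials[(trials["modality"] == modality) & (trials["outcome"] == outcome)]
    return sub["trial_index"].to_numpy()


def trial_choice(licks, task: TaskConfig | None = None) -> str:
    """'right-lick' | 'left-lick' | 'no-lick' from the first answer-window lick."""
    task = task or TaskConfig()
    ans_lo, ans_hi = task.answer_window
    gr_lo, gr_hi = task.grace_window
    answer = [(t, p) for t, p in sorted(licks)
              if ans_lo <= t <= ans_hi and not (gr_lo <= t < gr_hi)]
    if not answer:
        return "no-lick"
    return f"{answer[0][1]}-lick"


def _window_bins(tensor: RateTensor, window: tuple[float, float]) -> np.ndarray:
    edges = tensor.bin_edges
    bins = np.where((edges[:-1] >= window[0] - 1e-9) & (edges[1:] <= window[1] + 1e-9))[0]
    if bins.size == 0:
        raise ValueError(f"tensor does not cover window {window}")
    return bins


def _trial_average(tensor: RateTensor, idx: np.ndarray, bins: np.ndarray) -> np.ndarray:
    """Trial-averaged trajectory -> (time, units)."""
    idx = np.intersect1d(idx, tensor.trial_index)
    if idx.size == 0:
        raise StructuralError("condition has no trials in the tensor")
    rows = tensor.trial_rows(idx)
    return tensor.values[:, rows][:, :, bins].mean(axis=1).T


# ---------------------------------------------------------------------------
# trajectory PCA and distances

@dataclass
class SubspaceModel:
    basis: np.ndarray  # (units, k), orthonormal columns
    center: np.ndarray  # per-unit mean over the fitted time points
    var_explained: np.ndarray  # fraction per component, nonincreasing
    source: str

    @property
    def k(self) -> int:
        return self.basis.shape[1]

    def project(self, X: np.ndarray) -> np.ndarray:
        """Project (time, units) observations into the component space."""
        return (X - self.center) @ self.basis


def _pca(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of (observations, variables): basis, center, var-explained fractions."""
    center = X.mean(axis=0)
    Xc = X - center
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    k = min(k, vt.shape[0])
    return vt[:k].T, center, frac[:k]


def fit_trajectory_pca(
    tensor: RateTensor,
    trials: pd.DataFrame,
    conditions: tuple[str, ...] = ("tHit", "tCR"),
    window: tuple[float, float] = (-0.1, 0.15),
    k: int = 3,
) -> SubspaceModel:
    """PCA on concatenated trial-averaged condition trajectories."""
    bins = _window_bins(tensor, window)
    X = np.vstack([
        _trial_average(tensor, condition_trials(trials, c), bins) for c in conditions
    ])
    if tensor.n_units < k:
        warnings.warn(f"only {tensor.n_units} units; basis truncated")
    basis, center, var = _pca(X, k)
    return SubspaceModel(basis=basis, center=center, var_explained=var,
                         source="+".join(conditions))


def trajectory_distance(
    model: SubspaceModel,
    tensor: RateTensor,
    trials: pd.DataFrame,
    conditions: tuple[str, str] = ("tHit", "tCR"),
    window: tuple[float, float] = (-0.1, 0.15),
) -> tuple[np.ndarray, np.ndarray]:
    """Mean Euclidean distance between projected single-trial trajectories.

    Distances are computed at matching time points for all cross-condition
    trial pairs and averaged; returns ``(bin_centers, distance)``.
    """
    bins = _window_bins(tensor, window)
    projections = []
    for c in conditions:
        idx = np.intersect1d(condition_trials(trials, c), tensor.trial_index)
        if idx.size == 0:
            raise StructuralError(f"condition {c} has no trials")
        rows = tensor.trial_rows(idx)
        data = tensor.values[:, rows][:, :, bins]  # (units, trials, time)
        proj = np.einsum("utb,uk->tbk", data, model.basis) \
            - (model.center @ model.basis)[None, None, :]
        projections.append(proj)  # (trials, time, k)
    a, b = projections
    diff = a[:, None, :, :] - b[None, :, :, :]  # (nA, nB, time, k)
    dist = np.linalg.norm(diff, axis=-1).mean(axis=(0, 1))
    centers = tensor.bin_centers[bins]
    return centers, dist


def split_distance_permutation(
    distances: np.ndarray,
    bin_centers: np.ndarray,
    pre_window: tuple[float, float] = (-0.1, 0.0),
    post_window: tuple[float, float] = (0.0, 0.15),
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, dict]:
    """Top- vs bottom-half (by pre-stimulus distance) permutation test.

    ``distances`` is (sessions, bins).  Sessions are ranked by mean
    pre-window distance and split at the median (an odd middle session joins
    the bottom group); the statistic is the Euclidean distance between the
    two groups' mean post-window curves; one-tailed add-one p.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.shape[0] < 4:
        raise ValueError("need >= 4 sessions")
    pre = (bin_centers >= pre_window[0]) & (bin_centers < pre_window[1])
    post = (bin_centers >= post_window[0]) & (bin_centers < post_window[1])
    order = np.argsort(distances[:, pre].mean(axis=1), kind="stable")
    n = distances.shape[0]
    n_bottom = n - n // 2  # odd middle session assigned to the bottom group
    bottom, top = order[:n_bottom], order[n_bottom:]
    post_curves = distances[:, post]

    def stat(a, b):
        return float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))

    observed = stat(post_curves[top], post_curves[bottom])
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        null[i] = stat(post_curves[perm[: top.size]], post_curves[perm[top.size:]])
    p = float((1 + np.sum(null >= observed)) / (n_perm + 1))
    return p, dict(observed=observed, null=null, top=top, bottom=bottom)


# ---------------------------------------------------------------------------
# subspace overlap

@dataclass
class OverlapResult:
    session_id: str
    overlap_tCR: float
    overlap_control_tHit: float
    overlap_prestim_tCR: float
    n_units: int


def _varexp_onto(X: np.ndarray, basis: np.ndarray) -> float:
    """Fraction of X's variance captured by the (orthonormal) basis columns."""
    Xc = X - X.mean(axis=0)
    total = float(np.sum(Xc**2))
    if total <= 0:
        return np.nan
    proj = Xc @ basis
    projc = proj - proj.mean(axis=0)
    return float(np.sum(projc**2)) / total


def _own_topk_varexp(X: np.ndarray, k: int) -> float:
    _, _, frac = _pca(X, k)
    return float(frac.sum())


def subspace_overlap(
    tensor: RateTensor,
    trials: pd.DataFrame,
    window: tuple[float, float] = (0.0, 0.15),
    prestim_window: tuple[float, float] = (-0.1, 0.0),
    k: int = 3,
    min_units: int = 10,
    seed: int | None = None,
) -> OverlapResult | None:
    """Variance-alignment overlap between tHit and tCR subspaces.

    tHit trials are split into equal-sized reference and control halves
    (single seeded split); PCA is fit on the trial-averaged reference-tHit
    activity.  Overlap = varexp(condition onto reference top-k) /
    varexp(condition onto its own top-k).  Sessions with fewer than
    ``min_units`` units return ``None`` (low-dimensionality guard).
    """
    if tensor.n_units < min_units:
        warnings.warn(f"session excluded: {tensor.n_units} < {min_units} units")
        return None
    rng = np.random.default_rng(seed)
    t_hit = np.intersect1d(condition_trials(trials, "tHit"), tensor.trial_index)
    t_cr = np.intersect1d(condition_trials(trials, "tCR"), tensor.trial_index)
    if t_hit.size < 4 or t_cr.size < 1:
        warnings.warn("too few tHit/tCR trials for the reference/control split")
        return None
    perm = rng.permutation(t_hit.size)
    half = t_hit.size // 2
    ref_idx, ctl_idx = t_hit[perm[:half]], t_hit[perm[half: 2 * half]]
    bins = _window_bins(tensor, window)
    pre_bins = _window_bins(tensor, prestim_window)
    ref = _trial_average(tensor, ref_idx, bins)
    basis, _, _ = _pca(ref, k)

    def overlap(X: np.ndarray) -> float:
        denom = _own_topk_varexp(X, k)
        num = _varexp_onto(X, basis)
        if not np.isfinite(num) or not np.isfinite(denom) or denom == 0:
            return np.nan
        return num / denom

    cr = _trial_average(tensor, t_cr, bins)
    ctl = _trial_average(tensor, ctl_idx, bins)
    cr_pre = _trial_average(tensor, t_cr, pre_bins)
    return OverlapResult(
        session_id=str(trials["session_id"].iloc[0]),
        overlap_tCR=overlap(cr),
        overlap_control_tHit=overlap(ctl),
        overlap_prestim_tCR=overlap(cr_pre),
        n_units=tensor.n_units,
    )


def prepost_overlap_correlation(pre, post) -> tuple[float, float] | None:
    """Pearson r of pre- vs post-stimulus overlap across sessions."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    ok = np.isfinite(pre) & np.isfinite(post)
    if ok.sum() < 3:
        return None
    r, p = sps.pearsonr(pre[ok], post[ok])
    return float(r), float(p)


# ---------------------------------------------------------------------------
# coding dimensions

@dataclass
class CodingDimension:
    vector: np.ndarray  # unit norm over units
    contrast: str  # stimulus | choice
    rule_context: str  # touch | light
    window: tuple[float, float]
    recipe: str
    incomplete: bool = False  # a sub-condition was empty


#: Sub-condition recipes: contrast -> rule context -> (side_a cells, side_b cells),
#: each cell a (modality, choice) pair.  Recipe "correct" matches the primary
#: analysis (hit/no-lick cells); recipe "lick" contrasts the two lick ports.
CD_RECIPES = {
    "correct": {
        "stimulus": {
            "touch": ((("tactile", "right-lick"), ("tactile", "no-lick")),
                      (("visual", "right-lick"), ("visual", "no-lick"))),
            "light": ((("tactile", "left-lick"), ("tactile", "no-lick")),
                      (("visual", "left-lick"), ("visual", "no-lick"))),
        },
        "choice": {
            "touch": ((("tactile", "right-lick"), ("visual", "right-lick")),
                      (("tactile", "no-lick"), ("visual", "no-lick"))),
            "light": ((("tactile", "left-lick"), ("visual", "left-lick")),
                      (("tactile", "no-lick"), ("visual", "no-lick"))),
        },
    },
    "lick": {
        "stimulus": {
            "touch": ((("tactile", "right-lick"), ("tactile", "left-lick")),
                      (("visual", "right-lick"), ("visual", "left-lick"))),
            "light": ((("tactile", "right-lick"), ("tactile", "left-lick")),
                      (("visual", "right-lick"), ("visual", "left-lick"))),
        },
        "choice": {
            "touch": ((("tactile", "right-lick"), ("visual", "right-lick")),
                      (("tactile", "left-lick"), ("visual", "left-lick"))),
            "light": ((("tactile", "right-lick"), ("visual", "right-lick")),
                      (("tactile", "left-lick"), ("visual", "left-lick"))),
        },
    },
}


def _with_choice(trials: pd.DataFrame, task: TaskConfig | None = None) -> pd.DataFrame:
    out = trials.copy()
    out["choice"] = [trial_choice(lk, task) for lk in out["licks"]]
    return out


def _cell_mean(tensor, df, modality, choice, bins) -> np.ndarray | None:
    idx = df[(df["modality"] == modality) & (df["choice"] == choice)]["trial_index"]
    idx = np.intersect1d(idx.to_numpy(), tensor.trial_index)
    if idx.size == 0:
        return None
    return _trial_average(tensor, idx, bins)


def coding_dimension(
    tensor: RateTensor,
    trials: pd.DataFrame,
    contrast: str = "stimulus",
    rule_context: str = "touch",
    recipe: str = "correct",
    window: tuple[float, float] = (0.0, 0.15),
    task: TaskConfig | None = None,
) -> CodingDimension | None:
    """Unit-norm direction separating two condition-averaged trajectories.

    Each side's trajectory is the unweighted average of its sub-condition
    means (e.g. tactile = (tactile-lick + tactile-no-lick) / 2); their
    time-resolved difference is averaged over the window and normalized.
    Empty sub-conditions are averaged over the available cells (flagged);
    a degenerate zero difference returns ``None``.
    """
    cells_a, cells_b = CD_RECIPES[recipe][contrast][rule_context]
    bins = _window_bins(tensor, window)
    df = _with_choice(trials[trials["block_rule"] == rule_context], task)
    incomplete = False
    sides = []
    for cells in (cells_a, cells_b):
        means = [m for m in (_cell_mean(tensor, df, mo, ch, bins) for mo, ch in cells)
                 if m is not None]
        if len(means) < len(cells):
            incomplete = True
            warnings.warn("empty CD sub-condition; averaging available cells")
        if not means:
            raise StructuralError(f"no trials for either sub-condition of {cells}")
        sides.append(np.mean(means, axis=0))  # (time, units)
    nu = (sides[0] - sides[1]).mean(axis=0)  # average difference over the window
    norm = np.linalg.norm(nu)
    if norm < 1e-12:
        warnings.warn("degenerate coding dimension (zero difference)")
        return None
    return CodingDimension(vector=nu / norm, contrast=contrast,
                           rule_context=rule_context, window=window,
                           recipe=recipe, incomplete=incomplete)


def cd_alignment(cd_a: CodingDimension | np.ndarray, cd_b: CodingDimension | np.ndarray) -> float:
    """Unsigned alignment |a . b| of two unit-norm coding dimensions."""
    a = cd_a.vector if isinstance(cd_a, CodingDimension) else np.asarray(cd_a, float)
    b = cd_b.vector if isinstance(cd_b, CodingDimension) else np.asarray(cd_b, float)
    if a.shape != b.shape:
        raise StructuralError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(abs(np.dot(a, b)))


@dataclass
class AlignmentTest:
    dot: float
    boot_ci: tuple[float, float]
    null_ci: tuple[float, float]
    null_mean: float
    significant: bool


def cd_alignment_test(
    tensor: RateTensor,
    trials: pd.DataFrame,
    contrast: str = "stimulus",
    recipe: str = "correct",
    window: tuple[float, float] = (0.0, 0.15),
    n_shuffle: int = 1000,
    n_boot: int = 1000,
    task: TaskConfig | None = None,
    seed: int | None = None,
) -> AlignmentTest | None:
    """Cross-rule CD alignment with shuffle null and trial-bootstrap CI.

    The true statistic is |dot| between the contrast's CDs estimated in
    respond-to-touch and respond-to-light blocks.  The null recomputes both
    CDs after shuffling the per-trial type labels (block rule, modality,
    choice permuted jointly across trials); significance is non-overlap of
    the two 95% percentile intervals.
    """
    rng = np.random.default_rng(seed)
    df = _with_choice(trials, task)

    def _dot(frame) -> float | None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cds = []
            for ctx in ("touch", "light"):
                sub = frame[frame["block_rule"] == ctx]
                try:
                    cd = coding_dimension(tensor, sub, contrast, ctx, recipe, window, task)
                except StructuralError:
                    return None
                if cd is None:
                    return None
                cds.append(cd)
        return cd_alignment(*cds)

    observed = _dot(df)
    if observed is None:
        return None
    labels = df[["block_rule", "modality", "choice"]].to_numpy()
    null = []
    for _ in range(n_shuffle):
        perm = rng.permutation(len(df))
        shuffled = df.copy()
        shuffled[["block_rule", "modality", "choice"]] = labels[perm]
        d = _dot(shuffled)
        if d is not None:
            null.append(d)
    boot = []
    for _ in range(n_boot):
        pick = rng.integers(0, len(df), len(df))
        d = _dot(df.iloc[pick])
        if d is not None:
            boot.append(d)
    null_ci = tuple(np.percentile(null, [2.5, 97.5])) if null else (np.nan, np.nan)
    boot_ci = tuple(np.percentile(boot, [2.5, 97.5])) if boot else (np.nan, np.nan)
    significant = bool(null and boot and (boot_ci[0] > null_ci[1] or boot_ci[1] < null_ci[0]))
    return AlignmentTest(dot=observed, boot_ci=boot_ci, null_ci=null_ci,
                         null_mean=float(np.mean(null)) if null else np.nan,
                         significant=significant)
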