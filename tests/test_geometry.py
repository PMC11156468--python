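import warnings

import numpy as np
import pytest

from xmodal.config import PopulationConfig
from xmodal.core import RateTensor
from xmodal.errors import StructuralError
from xmodal.geometry import (
    CodingDimension,
    cd_alignment,
    coding_dimension,
    fit_trajectory_pca,
    prepost_overlap_correlation,
    split_distance_permutation,
    subspace_overlap,
    trajectory_distance,
    _own_topk_varexp,
    _pca,
    _varexp_onto,
)
from xmodal.preprocess import bin_rates, exclude_prestim_lick_trials, soft_normalize
from xmodal.synthetic import simulate_session

from conftest import make_trials


def _tensor_from_trials(values, rows):
    trials = make_trials(rows)
    values = np.asarray(values, float)
    return RateTensor(values=values, bin_size=0.01, align_event="stim_onset",
                      window=(0, 0.01 * values.shape[2]),
                      unit_ids=[f"u{i}" for i in range(values.shape[0])],
                      trial_index=trials["trial_index"].to_numpy(),
                      normalized=True), trials


def _two_condition_tensor(a_trials, b_trials):
    """a = tHit trials, b = tCR trials; each item is (units, time)."""
    rows = ([dict(rule="touch", modality="tactile", outcome="hit")] * len(a_trials)
            + [dict(rule="light", modality="tactile", outcome="correct_rejection")]
            * len(b_trials))
    values = np.stack(a_trials + b_trials, axis=1)  # (units, trials, time)
    return _tensor_from_trials(values, rows)


class TestTrajectoryPCA:
    def test_planar_data_two_components(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 2 * np.pi, 25)
        plane = np.stack([np.cos(t), np.sin(t), np.zeros_like(t),
                          np.zeros_like(t)])  # (4 units, time)
        tensor, trials = _two_condition_tensor([plane] * 3, [plane * 2] * 3)
        model = fit_trajectory_pca(tensor, trials, window=tensor.window)
        assert model.var_explained[:2].sum() == pytest.approx(1.0, abs=1e-9)
        assert model.var_explained[2] == pytest.approx(0.0, abs=1e-9)

    def test_rank1_difference_aligns_pc1(self):
        rng = np.random.default_rng(1)
        direction = np.array([3.0, 0.0, 4.0, 0.0]) / 5.0
        base = np.zeros((4, 10))
        a = base + 0.0
        b = base + direction[:, None] * 5.0
        tensor, trials = _two_condition_tensor([a] * 4, [b] * 4)
        model = fit_trajectory_pca(tensor, trials, window=tensor.window)
        assert abs(np.dot(model.basis[:, 0], direction)) > 0.99

    def test_orthonormal_basis(self, small_session):
        trials, spikes = small_session
        stim = trials[trials["modality"].isin(("tactile", "visual"))]
        tensor = soft_normalize(
            bin_rates(spikes, stim, window=(-0.1, 0.15), bin_size=0.01, sigma=0.05))
        model = fit_trajectory_pca(tensor, stim)
        np.testing.assert_allclose(model.basis.T @ model.basis, np.eye(3), atol=1e-8)
        assert (np.diff(model.var_explained) <= 1e-12).all()
        assert model.var_explained.sum() <= 1 + 1e-9

    def test_few_units_truncates_with_warning(self):
        a = np.ones((2, 5))
        tensor, trials = _two_condition_tensor([a], [a * 2])
        with pytest.warns(UserWarning, match="truncated"):
            model = fit_trajectory_pca(tensor, trials, window=tensor.window)
        assert model.k <= 2


class TestTrajectoryDistance:
    def test_identical_trajectories_zero(self):
        a = np.random.default_rng(2).uniform(0, 1, (4, 8))
        tensor, trials = _two_condition_tensor([a] * 3, [a] * 3)
        model = fit_trajectory_pca(tensor, trials, window=tensor.window)
        _, dist = trajectory_distance(model, tensor, trials, window=tensor.window)
        np.testing.assert_allclose(dist, 0.0, atol=1e-9)

    def test_constant_offset_pythagorean(self):
        rng = np.random.default_rng(3)
        # base varies only in units 3/4 so base + offset spans exactly 3
        # dimensions: the top-3 projection preserves the offset norm of 5
        base = np.zeros((4, 8))
        base[2:] = rng.uniform(0, 1, (2, 8))
        offset = np.array([3.0, 4.0, 0.0, 0.0])
        a = base
        b = base + offset[:, None]
        tensor, trials = _two_condition_tensor([a] * 3, [b] * 3)
        model = fit_trajectory_pca(tensor, trials, window=tensor.window)
        _, dist = trajectory_distance(model, tensor, trials, window=tensor.window)
        np.testing.assert_allclose(dist, 5.0, atol=1e-6)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(4)
        a = [rng.uniform(0, 1, (5, 6)) for _ in range(3)]
        b = [rng.uniform(0, 1, (5, 6)) for _ in range(3)]
        tensor, trials = _two_condition_tensor(a, b)
        model = fit_trajectory_pca(tensor, trials, window=tensor.window)
        _, dist = trajectory_distance(model, tensor, trials, window=tensor.window)
        # joint rotation of all data leaves distances unchanged
        q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        rot_vals = np.einsum("ij,jtb->itb", q, tensor.values)
        tensor_rot = RateTensor(values=rot_vals, bin_size=tensor.bin_size,
                                align_event=tensor.align_event, window=tensor.window,
                                unit_ids=tensor.unit_ids,
                                trial_index=tensor.trial_index, normalized=True)
        model_rot = fit_trajectory_pca(tensor_rot, trials, window=tensor.window)
        _, dist_rot = trajectory_distance(model_rot, tensor_rot, trials,
                                          window=tensor.window)
        np.testing.assert_allclose(dist, dist_rot, atol=1e-6)

    def test_missing_condition_raises(self):
        a = np.ones((4, 5))
        rows = [dict(rule="touch", modality="tactile", outcome="hit")] * 3
        tensor, trials = _tensor_from_trials(np.stack([a] * 3, axis=1), rows)
        model_rows = fit_trajectory_pca.__defaults__  # silence lint
        with pytest.raises(StructuralError):
            fit_trajectory_pca(tensor, trials, window=tensor.window)


class TestSplitDistancePermutation:
    def test_identical_sessions_large_p(self):
        centers = np.linspace(-0.095, 0.145, 25)
        dist = np.ones((8, 25))
        p, info = split_distance_permutation(dist, centers, n_perm=200, seed=0)
        assert p > 0.5

    def test_shifted_top_group_min_p(self):
        rng = np.random.default_rng(5)
        centers = np.linspace(-0.095, 0.145, 25)
        dist = rng.uniform(0, 0.1, (12, 25))
        dist[6:] += 10.0  # strongly separated group (also higher pre-distance)
        p, info = split_distance_permutation(dist, centers, n_perm=200, seed=0)
        # only a permutation reproducing the exact split (or complement) can
        # tie the observed statistic
        assert p <= 2 / 201

    def test_null_p_uniform(self):
        rng = np.random.default_rng(6)
        centers = np.linspace(-0.095, 0.145, 25)
        ps = []
        for _ in range(100):
            dist = rng.normal(5, 1, (8, 25))
            p, _ = split_distance_permutation(dist, centers, n_perm=99,
                                              seed=int(rng.integers(2**31)))
            ps.append(p)
        from scipy import stats as sps
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_too_few_sessions(self):
        with pytest.raises(ValueError):
            split_distance_permutation(np.ones((3, 5)), np.linspace(0, 0.04, 5))


class TestSubspaceOverlap:
    def _session_tensor(self, pop=None, seed=40):
        pop = pop or PopulationConfig(n_units=20)
        trials, spikes = simulate_session(pop=pop, seed=seed)
        stim = trials[trials["modality"].isin(("tactile", "visual"))]
        tensor = soft_normalize(
            bin_rates(spikes, stim, window=(-0.1, 0.15), bin_size=0.01, sigma=0.05))
        return tensor, stim

    def test_projection_energy_optimality(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            X = rng.normal(size=(12, 6))
            own = _own_topk_varexp(X, 3)
            q, _ = np.linalg.qr(rng.normal(size=(6, 3)))
            assert own >= _varexp_onto(X, q) - 1e-10

    def test_self_overlap_is_one(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(15, 8))
        basis, _, _ = _pca(X, 3)
        assert _varexp_onto(X, basis) / _own_topk_varexp(X, 3) == pytest.approx(1.0)

    def test_orthogonal_variation_zero_overlap(self):
        # 4 units; reference varies in span(e1, e2, e3); tCR varies only along e4
        t = np.linspace(0, 1, 12)
        ref = np.stack([np.sin(2 * np.pi * t), np.cos(2 * np.pi * t), t, 0 * t])
        cr = np.stack([0 * t, 0 * t, 0 * t, t])
        basis, _, _ = _pca(ref.T, 3)
        assert _varexp_onto(cr.T, basis) == pytest.approx(0.0, abs=1e-9)

    def test_min_units_excluded(self):
        pop = PopulationConfig(n_units=6)
        tensor, stim = self._session_tensor(pop=pop, seed=41)
        with pytest.warns(UserWarning, match="excluded"):
            assert subspace_overlap(tensor, stim, seed=0) is None

    def test_rotation_increases_overlap_deficit(self):
        deficits = []
        for angle in (0.0, 45.0, 90.0):
            vals = []
            for seed in (60, 61, 62, 63):
                pop = PopulationConfig(n_units=24, rule_rotation_deg=angle,
                                       evoked_amp=40.0, frac_touch_resp=0.8,
                                       choice_amp=0.0)
                tensor, stim = self._session_tensor(pop=pop, seed=seed)
                res = subspace_overlap(tensor, stim, seed=0)
                vals.append(res.overlap_control_tHit - res.overlap_tCR)
            deficits.append(np.mean(vals))
        assert deficits[0] < deficits[-1]
        assert deficits[0] <= deficits[1] + 0.05 <= deficits[2] + 0.1

    def test_result_fields(self):
        tensor, stim = self._session_tensor(seed=45)
        res = subspace_overlap(tensor, stim, seed=0)
        assert res.n_units == 20
        assert 0 <= res.overlap_tCR
        assert 0 <= res.overlap_control_tHit


class TestPrepostCorrelation:
    def test_identical_r1(self):
        v = [0.2, 0.5, 0.8, 0.9]
        r, p = prepost_overlap_correlation(v, v)
        assert r == pytest.approx(1.0)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(9)
        r, p = prepost_overlap_correlation(rng.uniform(size=500), rng.uniform(size=500))
        assert abs(r) < 0.1

    def test_too_few_sessions_none(self):
        assert prepost_overlap_correlation([0.1, 0.2], [0.1, 0.2]) is None


def _cd_tensor(cells, n_units=2, n_time=4):
    """cells: list of (modality, licks, rule, unit_pattern)."""
    rows, values = [], []
    for modality, licks, rule, pattern in cells:
        rows.append(dict(rule=rule, modality=modality, licks=licks,
                         outcome="hit" if licks else "miss"))
        values.append(np.tile(np.asarray(pattern, float)[:, None], (1, n_time)))
    return _tensor_from_trials(np.stack(values, axis=1), rows)


class TestCodingDimension:
    def test_simple_difference(self):
        tensor, trials = _cd_tensor([
            ("tactile", [(0.5, "right")], "touch", (1.0, 0.0)),
            ("tactile", [], "touch", (1.0, 0.0)),
            ("visual", [(0.5, "right")], "touch", (0.0, 0.0)),
            ("visual", [], "touch", (0.0, 0.0)),
        ])
        cd = coding_dimension(tensor, trials, "stimulus", "touch", window=tensor.window)
        np.testing.assert_allclose(cd.vector, [1.0, 0.0], atol=1e-9)

    def test_half_weight_recipe(self):
        # tactile-right-lick (2,0), tactile-no-lick (0,0) -> x_tactile=(1,0)
        tensor, trials = _cd_tensor([
            ("tactile", [(0.5, "right")], "touch", (2.0, 0.0)),
            ("tactile", [], "touch", (0.0, 0.0)),
            ("visual", [(0.5, "right")], "touch", (0.0, 0.0)),
            ("visual", [], "touch", (0.0, 0.0)),
        ])
        cd = coding_dimension(tensor, trials, "stimulus", "touch", window=tensor.window)
        np.testing.assert_allclose(cd.vector, [1.0, 0.0], atol=1e-9)

    def test_degenerate_returns_none(self):
        tensor, trials = _cd_tensor([
            ("tactile", [(0.5, "right")], "touch", (1.0, 1.0)),
            ("tactile", [], "touch", (1.0, 1.0)),
            ("visual", [(0.5, "right")], "touch", (1.0, 1.0)),
            ("visual", [], "touch", (1.0, 1.0)),
        ])
        with pytest.warns(UserWarning, match="degenerate"):
            assert coding_dimension(tensor, trials, "stimulus", "touch",
                                    window=tensor.window) is None

    def test_missing_subcondition_flagged(self):
        tensor, trials = _cd_tensor([
            ("tactile", [(0.5, "right")], "touch", (1.0, 0.0)),
            ("visual", [], "touch", (0.0, 1.0)),
        ])
        with pytest.warns(UserWarning, match="empty CD sub-condition"):
            cd = coding_dimension(tensor, trials, "stimulus", "touch",
                                  window=tensor.window)
        assert cd.incomplete

    def test_scale_invariance(self):
        cells = [
            ("tactile", [(0.5, "right")], "touch", (3.0, 1.0)),
            ("tactile", [], "touch", (1.0, 0.5)),
            ("visual", [(0.5, "right")], "touch", (0.5, 2.0)),
            ("visual", [], "touch", (0.0, 1.0)),
        ]
        tensor, trials = _cd_tensor(cells)
        cd1 = coding_dimension(tensor, trials, "stimulus", "touch", window=tensor.window)
        scaled = RateTensor(values=tensor.values * 7.0, bin_size=tensor.bin_size,
                            align_event=tensor.align_event, window=tensor.window,
                            unit_ids=tensor.unit_ids, trial_index=tensor.trial_index,
                            normalized=True)
        cd2 = coding_dimension(scaled, trials, "stimulus", "touch", window=tensor.window)
        np.testing.assert_allclose(cd1.vector, cd2.vector, atol=1e-9)


class TestCDAlignment:
    def _cd(self, vec):
        v = np.asarray(vec, float)
        return CodingDimension(vector=v / np.linalg.norm(v), contrast="stimulus",
                               rule_context="touch", window=(0, 0.15), recipe="correct")

    def test_identical(self):
        assert cd_alignment(self._cd([1, 2, 3]), self._cd([1, 2, 3])) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert cd_alignment(self._cd([1, 0]), self._cd([0, 1])) == pytest.approx(0.0)

    def test_dimension_mismatch(self):
        with pytest.raises(StructuralError):
            cd_alignment(self._cd([1, 0]), self._cd([1, 0, 0]))

    def test_random_expectation_matches_analytic(self):
        rng = np.random.default_rng(10)
        for n in (10, 20, 50):
            dots = []
            for _ in range(2000):
                a = rng.normal(size=n)
                b = rng.normal(size=n)
                dots.append(abs(np.dot(a / np.linalg.norm(a), b / np.linalg.norm(b))))
            assert np.mean(dots) == pytest.approx(np.sqrt(2 / (np.pi * n)), rel=0.05)
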