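import dataclasses

import numpy as np
import pytest

from pincermd import (ClusterConfig, EmbedConfig, PincerSpec, cluster_frames,
                      extract_medoids, generate_pincer_trajectory,
                      interdomain_distances, map_residues,
                      select_state_representatives, smooth_normalize,
                      stack_and_project, time_lag, domain_map_for)
from pincermd.states import ResidueMapping

from conftest import make_trajectory

RNG = np.random.default_rng(5150)


class TestSmoothNormalize:
    def test_sinusoid_zero_mean_unit_sd(self):
        x = np.sin(np.linspace(0, 8 * np.pi, 400))
        y = smooth_normalize(x)
        assert abs(y.mean()) < 1e-9
        assert y.std() == pytest.approx(1.0)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            smooth_normalize(np.full(100, 2.0))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            smooth_normalize(np.arange(5.0))

    def test_step_inflection_preserved(self):
        n, step_at = 400, 200
        x = np.zeros(n)
        x[step_at:] = 5.0
        y = smooth_normalize(x)
        span = max(1, n // 10)
        inflection = int(np.argmax(np.diff(y)))
        assert abs(inflection - step_at) <= span / 10 + 1


class TestTimeLag:
    def test_self_lag_zero_correlation_one(self):
        x = smooth_normalize(np.sin(np.linspace(0, 6 * np.pi, 500)))
        lag, corr = time_lag(x, x, max_lag=50)
        assert lag == 0
        assert corr == pytest.approx(1.0, rel=1e-6)

    def test_shifted_sinusoid_recovered(self):
        t = np.arange(1000)
        a = np.sin(2 * np.pi * t / 200)
        b = np.roll(a, 50)  # b trails a by 50 frames
        lag, _ = time_lag(smooth_normalize(a), smooth_normalize(b), max_lag=90)
        assert abs(lag - 50) <= 1

    def test_antisymmetry(self):
        a = smooth_normalize(np.sin(2 * np.pi * np.arange(600) / 150))
        b = smooth_normalize(np.roll(a, 37))
        assert time_lag(a, b, 70)[0] == -time_lag(b, a, 70)[0]

    def test_noisy_shift_recovered_within_tolerance(self):
        t = np.arange(1200)
        base = np.sin(2 * np.pi * t / 300)
        errors = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            noise = base.std() / 5  # SNR 5
            a = base + rng.normal(0, noise, base.size)
            b = np.roll(base, 50) + rng.normal(0, noise, base.size)
            lag, _ = time_lag(smooth_normalize(a), smooth_normalize(b), 120)
            errors.append(abs(lag - 50))
        assert max(errors) <= 3

    def test_max_lag_must_be_smaller_than_length(self):
        x = smooth_normalize(np.sin(np.linspace(0, 10, 50)))
        with pytest.raises(ValueError):
            time_lag(x, x, max_lag=50)


class TestStateRepresentatives:
    def test_open_is_max_closed_is_min(self):
        medoids = [np.zeros((4, 3))] * 3
        open_i, closed_i = select_state_representatives(medoids, [30.0, 55.0, 41.0])
        assert (open_i, closed_i) == (1, 0)

    def test_all_equal_ties_to_first(self):
        medoids = [np.zeros((4, 3))] * 3
        assert select_state_representatives(medoids, [40.0] * 3) == (0, 0)

    def test_single_medoid_warns(self):
        with pytest.warns(UserWarning, match="single"):
            assert select_state_representatives([np.zeros((4, 3))],
                                                [10.0]) == (0, 0)

    def test_pincer_open_minus_closed_spans_twice_amplitude(self):
        # period=2 is the dwell limit: frames alternate between the closed
        # and the fully open jaw separation, a clean two-state system
        spec = PincerSpec(n_domains=4, residues_per_domain=10,
                          jaw_pair=("PAZ", "L2"), amplitude=10.0, period=2,
                          fluctuation_sigma=0.1, n_frames=300, seed=3)
        traj = generate_pincer_trajectory(spec)
        dmap = domain_map_for(spec)
        res = cluster_frames(traj, ClusterConfig(k_range=(2, 8), seed=0))
        medoids = extract_medoids(res, traj)
        jaw = interdomain_distances(traj, dmap).get("PAZ", "L2").values
        jaw_d = [jaw[i] for i in res.medoid_indices]
        open_i, closed_i = select_state_representatives(medoids, jaw_d)
        span = jaw_d[open_i] - jaw_d[closed_i]
        assert span == pytest.approx(2 * spec.amplitude, abs=2.0)
        # representatives bracket every other medoid's jaw distance
        assert all(jaw_d[closed_i] <= d <= jaw_d[open_i] for d in jaw_d)


def _two_conformer_trajectory(n_frames=80, n_atoms=12, separation=12.0,
                              noise=0.3, seed=0):
    """Frames drawn from two well-separated conformer clouds."""
    rng = np.random.default_rng(seed)
    base = rng.standard_normal((n_atoms, 3)) * 3
    shifted = base.copy()
    shifted[: n_atoms // 2] += np.array([separation, 0, 0])
    labels = np.arange(n_frames) % 2
    coords = np.empty((n_frames, n_atoms, 3))
    for f in range(n_frames):
        template = base if labels[f] == 0 else shifted
        coords[f] = template + rng.normal(0, noise, (n_atoms, 3))
    return make_trajectory(coords), labels


class TestClustering:
    def test_planted_two_conformers_recovered(self):
        traj, truth = _two_conformer_trajectory()
        res = cluster_frames(traj, ClusterConfig(k_range=(2, 6), seed=1))
        assert res.chosen_k == 2
        # labels match the generation up to cluster renaming
        agreement = max(np.mean(res.labels == truth),
                        np.mean(res.labels == 1 - truth))
        assert agreement == 1.0

    def test_medoids_inside_their_clouds(self):
        traj, truth = _two_conformer_trajectory()
        res = cluster_frames(traj, ClusterConfig(k_range=(2, 6), seed=1))
        for cluster_id, frame_idx in enumerate(res.medoid_indices):
            assert res.labels[frame_idx] == cluster_id

    def test_deterministic_under_seed(self):
        traj, _ = _two_conformer_trajectory()
        cfg = ClusterConfig(k_range=(2, 6), seed=9)
        a = cluster_frames(traj, cfg)
        b = cluster_frames(traj, cfg)
        assert np.array_equal(a.labels, b.labels)
        assert a.medoid_indices == b.medoid_indices
        assert a.chosen_k == b.chosen_k

    def test_static_trajectory_degenerates_with_warning(self):
        frame = RNG.standard_normal((8, 3))
        traj = make_trajectory(np.repeat(frame[None], 30, axis=0))
        with pytest.warns(UserWarning, match="identical"):
            res = cluster_frames(traj, ClusterConfig(k_range=(2, 5)))
        assert res.degenerate and res.chosen_k == 1
        assert res.medoid_indices == (0,)


class TestMedoids:
    def test_singleton_cluster_medoid_is_that_frame(self):
        traj, _ = _two_conformer_trajectory(n_frames=21)
        res = cluster_frames(traj, ClusterConfig(k_range=(2, 4), seed=2))
        medoids = extract_medoids(res, traj)
        for m, idx in zip(medoids, res.medoid_indices):
            assert np.array_equal(m, traj.coords[idx])

    def test_collinear_frames_medoid_is_midpoint(self):
        # three conformations on a line in shape space: a body, the same body
        # scaled x2, and their exact midpoint; the medoid must be the midpoint
        base = np.random.default_rng(3).standard_normal((6, 3)) * 3
        base -= base.mean(axis=0)
        traj = make_trajectory(np.stack([base, 1.5 * base, 2.0 * base]))
        from pincermd.states import _featurize, _medoid_index
        feats = _featurize(traj)
        assert _medoid_index(feats, np.arange(3)) == 1


class TestResidueMapping:
    def test_identical_sequences_identity_mapping(self):
        seq = "MKVLATGEWQRNDFYHIPSC"
        mapping = map_residues(seq, seq)
        assert mapping.pairs == tuple((i, i) for i in range(1, len(seq) + 1))

    def test_insertion_shifts_mapping(self):
        a = "MKVLATGEWQRNDFYHIPSC"
        b = a[:4] + "G" + a[4:]  # insert at position 5 of b
        mapping = map_residues(a, b).as_dict()
        for ra, rb in mapping.items():
            if ra <= 4:
                assert rb == ra
            else:
                assert rb == ra + 1

    def test_transpose_symmetry(self):
        a = "MKVLATGEWQRNDFYHIPSC"
        b = "MKVATGEWQRNDFWYHIPSC"
        ab = map_residues(a, b)
        ba = map_residues(b, a)
        assert ab.transpose().pairs == ba.pairs

    def test_monotonicity_enforced(self):
        with pytest.raises(ValueError, match="increasing"):
            ResidueMapping(pairs=((1, 2), (2, 2)), score=0.0)


class TestStackAndProject:
    def _medoid_inputs(self, n_medoids=3, n_res=10, planar=False, seed=0):
        rng = np.random.default_rng(seed)
        medoids = []
        for _ in range(n_medoids):
            pts = rng.standard_normal((n_res, 3)) * 5
            if planar:
                pts[:, 2] = 0.0
            medoids.append(pts)
        ca = np.arange(n_res)
        return {"P": medoids}, {"P": ca}

    def test_shape_contract(self):
        medoid_sets, ca = self._medoid_inputs()
        proj = stack_and_project(medoid_sets, ca, None, "P", EmbedConfig())
        assert proj.coords.shape == (3 * 10, 2)
        assert len(proj.rows) == 30

    def test_planar_points_recovered_by_pca(self):
        rng = np.random.default_rng(1)
        pts = rng.standard_normal((20, 3)) * 4
        pts[:, 2] = 0.0
        proj = stack_and_project({"P": [pts]}, {"P": np.arange(20)}, None,
                                 "P", EmbedConfig(method="pca"))
        emb = proj.coords
        # 2-D embedding of genuinely planar points preserves all pairwise
        # distances (rigid in-plane transform up to rotation/reflection)
        d_orig = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        d_emb = np.linalg.norm(emb[:, None] - emb[None, :], axis=2)
        np.testing.assert_allclose(d_emb, d_orig, atol=1e-8)

    def test_duplicated_medoid_rows_coincide(self):
        medoid_sets, ca = self._medoid_inputs(n_medoids=1)
        medoid_sets["P"].append(medoid_sets["P"][0].copy())
        proj = stack_and_project(medoid_sets, ca, None, "P", EmbedConfig())
        first, second = proj.coords[:10], proj.coords[10:20]
        np.testing.assert_allclose(first, second, atol=1e-8)

    def test_too_few_common_residues_rejected(self):
        medoids = {"A": [np.zeros((2, 3))], "B": [np.zeros((2, 3))]}
        ca = {"A": np.arange(2), "B": np.arange(2)}
        with pytest.raises(ValueError, match="fewer than 3"):
            stack_and_project(medoids, ca, None, "A")
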