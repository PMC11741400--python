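import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from kinetraits import kineme, synthetic
from kinetraits.io import PoseSeries

from _oracles import nnls_grid_search_2d


def _series(angles, frame_rate=10.0, video_id="v"):
    return PoseSeries(video_id=video_id, frame_rate=frame_rate, angles=angles)


class TestBuildSegmentMatrix:
    def test_window_enumeration_by_hand(self):
        # T=6 frames, ell=4, hop=2 -> windows starting at frames 0 and 2
        angles = np.arange(18, dtype=float).reshape(6, 3)
        series = _series(angles, frame_rate=2.0)  # 2 s window -> ell=4
        seg = kineme.build_segment_matrix([series], window_s=2.0, overlap_fraction=0.5)
        assert seg.ell == 4 and seg.hop == 2
        assert seg.matrix.shape == (12, 2)
        expected_first = np.concatenate(
            [angles[0:4, 0], angles[0:4, 1], angles[0:4, 2]]
        ) + seg.offset
        np.testing.assert_allclose(seg.matrix[:, 0], expected_first)
        expected_second = np.concatenate(
            [angles[2:6, 0], angles[2:6, 1], angles[2:6, 2]]
        ) + seg.offset
        np.testing.assert_allclose(seg.matrix[:, 1], expected_second)

    def test_constant_zero_angles_zero_matrix(self):
        seg = kineme.build_segment_matrix([_series(np.zeros((40, 3)))])
        assert seg.offset == 0.0
        assert not seg.matrix.any()

    def test_default_30fps_grid(self):
        # 2 s window, 50% overlap at 30 fps -> ell=60, hop=30
        seg = kineme.build_segment_matrix(
            [_series(np.zeros((120, 3)), frame_rate=30.0)]
        )
        assert seg.ell == 60
        assert seg.hop == 30

    def test_segment_count_formula(self):
        series = _series(np.zeros((95, 3)))  # ell=20, hop=10
        seg = kineme.build_segment_matrix([series])
        assert seg.counts == [(95 - 20) // 10 + 1]

    def test_short_video_skipped_with_warning(self):
        long = _series(np.zeros((40, 3)), video_id="long")
        short = _series(np.zeros((5, 3)), video_id="short")
        with pytest.warns(UserWarning, match="short"):
            seg = kineme.build_segment_matrix([long, short])
        assert seg.video_ids == ["long"]

    def test_all_videos_short_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            kineme.build_segment_matrix([_series(np.zeros((5, 3)))])

    def test_offset_makes_non_negative(self, rng):
        seg = kineme.build_segment_matrix([_series(rng.normal(0, 0.3, (60, 3)))])
        assert seg.matrix.min() >= 0
        assert seg.offset > 0


def _prototype_matrix(rng, d=24, n_protos=3, copies=20):
    protos = rng.uniform(0.1, 1.0, (d, n_protos))
    cols = np.repeat(protos, copies, axis=1)
    return protos, cols


class TestLearnVocabulary:
    def test_prototype_recovery_cosine(self, rng):
        protos, cols = _prototype_matrix(rng)
        seg = kineme.SegmentMatrix(
            matrix=cols, ell=8, hop=4, offset=0.0, video_ids=["v"], counts=[60]
        )
        vocab = kineme.learn_vocabulary(seg, rank=5, k=3, seed=0)
        # cosine similarity matrix, matched via Hungarian assignment
        K = vocab.kinemes / np.linalg.norm(vocab.kinemes, axis=0)
        P = protos / np.linalg.norm(protos, axis=0)
        sim = P.T @ K
        rows, cols_idx = linear_sum_assignment(-sim)
        assert len(set(cols_idx)) == 3
        assert (sim[rows, cols_idx] >= 0.99).all()

    def test_configured_k_respected(self, rng):
        _, cols = _prototype_matrix(rng, n_protos=4, copies=10)
        cols = cols + rng.uniform(0, 0.05, cols.shape)
        seg = kineme.SegmentMatrix(
            matrix=cols, ell=8, hop=4, offset=0.0, video_ids=["v"], counts=[40]
        )
        vocab = kineme.learn_vocabulary(seg, rank=8, k=16, seed=0)
        assert vocab.kinemes.shape[1] == 16
        assert vocab.k == 16

    def test_determinism(self, rng):
        _, cols = _prototype_matrix(rng)
        cols = cols + rng.uniform(0, 0.02, cols.shape)
        seg = kineme.SegmentMatrix(
            matrix=cols, ell=8, hop=4, offset=0.0, video_ids=["v"], counts=[60]
        )
        a = kineme.learn_vocabulary(seg, rank=5, k=3, seed=7)
        b = kineme.learn_vocabulary(seg, rank=5, k=3, seed=7)
        np.testing.assert_allclose(a.kinemes, b.kinemes, atol=1e-9)

    def test_k_exceeding_segments_errors(self, rng):
        seg = kineme.SegmentMatrix(
            matrix=rng.uniform(0, 1, (12, 5)), ell=4, hop=2, offset=0.0,
            video_ids=["v"], counts=[5],
        )
        with pytest.raises(ValueError, match="exceeds"):
            kineme.learn_vocabulary(seg, rank=4, k=6, seed=0)

    def test_mixture_weights_sum_to_one(self, small_vocab):
        assert small_vocab.mixture_weights.sum() == pytest.approx(1.0)

    def test_basis_non_negative(self, small_vocab):
        assert small_vocab.basis.min() >= 0

    def test_save_load_roundtrip(self, small_vocab, tmp_path):
        small_vocab.save(tmp_path / "vocab.npz")
        back = kineme.KinemeVocabulary.load(tmp_path / "vocab.npz")
        np.testing.assert_array_equal(back.kinemes, small_vocab.kinemes)
        assert back.ell == small_vocab.ell
        assert back.offset == small_vocab.offset


class TestProjectSegment:
    def test_exact_reconstruction(self, rng):
        basis = rng.uniform(0, 1, (30, 4))
        c0 = rng.uniform(0, 2, 4)
        c_hat = kineme.project_segment(basis @ c0, basis)
        np.testing.assert_allclose(c_hat, c0, atol=1e-6)

    def test_zero_target_zero_coefficients(self, rng):
        basis = rng.uniform(0, 1, (30, 4))
        np.testing.assert_array_equal(
            kineme.project_segment(np.zeros(30), basis), np.zeros(4)
        )

    def test_residual_no_worse_than_zero_vector(self, rng):
        basis = rng.uniform(0, 1, (30, 4))
        h = rng.uniform(0, 1, 30)
        c_hat = kineme.project_segment(h, basis)
        assert np.linalg.norm(h - basis @ c_hat) <= np.linalg.norm(h) + 1e-12

    def test_matches_brute_force_grid(self, rng):
        for _ in range(10):
            basis = rng.uniform(0.1, 1.0, (12, 2))
            h = rng.uniform(0, 3.0, 12)
            c_hat = kineme.project_segment(h, basis)
            obj_nnls = np.sum((h - basis @ c_hat) ** 2)
            _, obj_grid = nnls_grid_search_2d(basis, h)
            assert obj_nnls <= obj_grid + 1e-3
            assert abs(obj_nnls - obj_grid) <= 1e-3

    def test_dimension_mismatch_errors(self, rng):
        with pytest.raises(ValueError, match="length"):
            kineme.project_segment(np.ones(5), rng.uniform(0, 1, (6, 2)))


class TestAssignKinemes:
    def test_kineme_column_maps_to_its_label(self, small_corpus, small_vocab):
        # a window whose content equals kineme column j (minus offset) -> j
        ell = small_vocab.ell
        for j in range(small_vocab.k):
            column = small_vocab.kinemes[:, j] - small_vocab.offset
            angles = np.column_stack(
                [column[:ell], column[ell : 2 * ell], column[2 * ell :]]
            )
            series = PoseSeries(
                video_id="probe",
                frame_rate=small_corpus.config.frame_rate,
                angles=angles,
            )
            seq = kineme.assign_kinemes(series, small_vocab)
            assert seq.labels[0] == j + 1

    def test_posterior_rows_sum_to_one(self, small_vocab, rng):
        coeffs = rng.uniform(0, 1, (20, small_vocab.rank))
        posterior = small_vocab.posterior(coeffs)
        np.testing.assert_allclose(posterior.sum(axis=1), 1.0, atol=1e-9)

    def test_isotropic_equal_weight_posterior_is_nearest_mean(self, rng):
        r, k = 4, 3
        means = rng.uniform(0, 4, (k, r))
        vocab = kineme.KinemeVocabulary(
            basis=np.eye(r),
            mixture_weights=np.full(k, 1 / k),
            mixture_means=means,
            mixture_covariances=np.tile(0.25 * np.eye(r), (k, 1, 1)),
            kinemes=means.T,
            ell=1, hop=1, offset=0.0, rank=r, k=k, seed=0,
        )
        points = rng.uniform(0, 4, (50, r))
        assigned = vocab.posterior(points).argmax(axis=1)
        nearest = np.argmin(
            ((points[:, None, :] - means[None]) ** 2).sum(axis=2), axis=1
        )
        np.testing.assert_array_equal(assigned, nearest)

    def test_recovery_ari_on_synthetic(self):
        config = synthetic.SynthConfig(
            n_videos=20, duration_s=12.0, frame_rate=10.0, n_prototypes=4,
            noise_sd=synthetic.NoiseSpec(angle=0.01, au=0.2, lld=0.2, label=0.01),
            seed=21,
        )
        corpus = synthetic.generate_corpus(config)
        seg = kineme.build_segment_matrix(
            corpus.pose_series(), overlap_fraction=0.0
        )
        vocab = kineme.learn_vocabulary(seg, rank=8, k=4, seed=0)
        truth, assigned = [], []
        for video in corpus.videos:
            seq = kineme.assign_kinemes(video.pose, vocab)
            assigned.extend(seq.labels.tolist())
            truth.extend(video.true_labels[: len(seq)].tolist())
        assert adjusted_rand_score(truth, assigned) >= 0.8

    def test_offset_consistency_invariance(self, small_corpus, small_vocab):
        # shifting raw angles and the vocabulary offset together is a no-op
        video = small_corpus.videos[0]
        baseline = kineme.assign_kinemes(video.pose, small_vocab)
        shifted_vocab = kineme.KinemeVocabulary(
            **{**small_vocab.__dict__, "offset": small_vocab.offset + 0.5}
        )
        shifted_series = PoseSeries(
            video_id=video.video_id,
            frame_rate=video.pose.frame_rate,
            angles=video.pose.angles - 0.5,
        )
        shifted = kineme.assign_kinemes(shifted_series, shifted_vocab)
        np.testing.assert_array_equal(baseline.labels, shifted.labels)

    def test_too_short_series_errors(self, small_vocab):
        series = PoseSeries(video_id="s", frame_rate=10.0, angles=np.zeros((3, 3)))
        with pytest.raises(ValueError, match="shorter"):
            kineme.assign_kinemes(series, small_vocab)

    def test_sequence_csv_writer(self, small_corpus, small_vocab, tmp_path):
        import pandas as pd

        seqs = [
            kineme.assign_kinemes(v.pose, small_vocab)
            for v in small_corpus.videos[:2]
        ]
        kineme.write_sequences(tmp_path / "seq.csv", seqs)
        df = pd.read_csv(tmp_path / "seq.csv")
        assert list(df.columns) == ["video_id", "window_start_s", "label"]
        assert len(df) == sum(len(s) for s in seqs)
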