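"""Feature flattening, PCA embedding, participant means, temporal profiles."""

import numpy as np
import pytest

import discmotion as dm
from discmotion.embedding import (
    cohort_profile,
    fit_project,
    flatten_field,
    happy_sad_orderings,
    participant_emotion_means,
    session_features,
    temporal_profile,
    unflatten,
)


class TestFlattenField:
    def test_zero_field_gives_zero_vector(self, speckle_frame, analysis_grid):
        fld = dm.compute_field(speckle_frame, speckle_frame, analysis_grid)
        vec = flatten_field(fld)
        assert vec.shape == (2 * fld.u.size,)
        assert not vec.any()

    def test_one_nonzero_point_gives_two_nonzero_entries(self, speckle_frame, analysis_grid):
        fld = dm.compute_field(speckle_frame, speckle_frame, analysis_grid)
        ix, iy = np.argwhere(fld.valid)[0]
        u = fld.u.copy()
        v = fld.v.copy()
        u[ix, iy] = 1.5
        v[ix, iy] = -2.0
        object.__setattr__(fld, "u", u)
        object.__setattr__(fld, "v", v)
        vec = flatten_field(fld)
        assert np.count_nonzero(vec) == 2

    def test_unflatten_roundtrip_on_complete_lattice(self, speckle_frame, analysis_grid):
        shifted = dm.GrayFrame(np.roll(speckle_frame.pixels, 1, axis=0))
        fld = dm.compute_field(speckle_frame, shifted, analysis_grid, subpixel=True)
        u, v = unflatten(flatten_field(fld), fld)
        assert np.array_equal(u[fld.valid], fld.u[fld.valid])
        assert np.array_equal(v[fld.valid], fld.v[fld.valid])
        # invalid points were zero-imputed
        assert not u[~fld.valid].any()


class TestFitProject:
    def test_line_in_high_dimension_explains_everything(self):
        rng = np.random.default_rng(50)
        t = rng.normal(size=100)
        direction = rng.normal(size=12)
        X = np.outer(t, direction)
        emb = fit_project(X)
        assert emb.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_cloud_splits_variance_evenly(self):
        rng = np.random.default_rng(51)
        X = rng.normal(size=(2000, 10))
        emb = fit_project(X)
        ratios = emb.explained_variance_ratio
        assert ratios.sum() == pytest.approx(1.0)
        assert np.all(np.abs(ratios - 0.1) < 0.025)
        assert np.all(np.diff(ratios) <= 1e-12)  # non-increasing spectrum

    def test_zero_variance_input_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            fit_project(np.ones((10, 5)))

    def test_spectrum_invariant_to_frame_order(self):
        rng = np.random.default_rng(52)
        X = rng.normal(size=(60, 8))
        a = fit_project(X)
        b = fit_project(X[rng.permutation(60)])
        assert np.allclose(a.explained_variance_ratio, b.explained_variance_ratio)

    def test_reconstruction_from_all_components(self):
        """PCA with the full spectrum reproduces centered data."""
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(53)
        X = rng.normal(size=(40, 6))
        pca = PCA(svd_solver="full").fit(X)
        Z = pca.transform(X)
        assert np.allclose(pca.inverse_transform(Z), X, atol=1e-10)

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(54)
        X = rng.normal(size=(50, 7))
        emb = fit_project(X)
        for comp in emb.components:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_cohort_top_two_components_dominate(self, strong_sessions):
        """Two deformation modes (mouth vs brow) should leave more than half
        the pooled variance in the first two components, and happy/sad frames
        should separate along them."""
        feats = []
        for sess in strong_sessions.values():
            feats.extend(session_features(sess))
        X = np.stack([f.values for f in feats])
        labels = np.asarray([f.label for f in feats])
        emb = fit_project(X)
        assert emb.explained_variance_ratio[:2].sum() > 0.5
        happy = emb.coords[labels == "happy"].mean(axis=0)
        sad = emb.coords[labels == "sad"].mean(axis=0)
        spread = emb.coords.std(axis=0).mean()
        assert np.linalg.norm(happy - sad) > spread  # clouds separate

    def test_neutral_frames_cluster_at_zero_motion_point(self, strong_sessions):
        """Neutral frames elicit almost no movement: their projections sit
        tightly around the image of the zero-displacement state."""
        feats = []
        for sess in strong_sessions.values():
            feats.extend(session_features(sess))
        X = np.stack([f.values for f in feats])
        labels = np.asarray([f.label for f in feats])
        emb = fit_project(X)
        origin = emb.transform(np.zeros((1, X.shape[1])))[0]
        d = np.linalg.norm(emb.coords - origin, axis=1)
        assert d[labels == "neutral"].mean() < 0.25 * d[labels != "neutral"].mean()


class TestParticipantMeans:
    def test_single_frame_group_mean_is_that_projection(self):
        rng = np.random.default_rng(55)
        X = rng.normal(size=(6, 5))
        emb = fit_project(X)
        labels = ["happy", "sad", "neutral", "happy", "sad", "neutral"]
        pids = ["A", "A", "A", "B", "B", "B"]
        means = participant_emotion_means(emb, labels, pids)
        row = means[(means.participant_id == "A") & (means.label == "happy")]
        assert row.pc1.iloc[0] == pytest.approx(emb.coords[0, 0])
        assert int(row.n.iloc[0]) == 1

    def test_ordering_consistent_for_at_least_8_of_10(self, mixed_cohort):
        """With two weak responders, the happy-vs-sad mean ordering on some
        component is still consistent for at least 8 of 10 participants."""
        _, cohort = mixed_cohort
        feats = []
        for syn in cohort:
            feats.extend(session_features(syn.session))
        X = np.stack([f.values for f in feats])
        emb = fit_project(X)
        means = participant_emotion_means(
            emb, [f.label for f in feats], [f.participant_id for f in feats]
        )
        orders = happy_sad_orderings(means)
        consistency = max(
            orders["happy_gt_sad_pc1"].sum(),
            (~orders["happy_gt_sad_pc1"]).sum(),
            orders["happy_gt_sad_pc2"].sum(),
            (~orders["happy_gt_sad_pc2"]).sum(),
        )
        assert consistency >= 8


class TestTemporalProfile:
    def test_zero_fields_give_flat_zero_profile(self, speckle_frame, small_grid):
        from discmotion.session import StimulusSchedule, compute_session_fields, sample_and_label

        sched = StimulusSchedule((("neutral", 2.0), ("happy", 4.0)))
        frames = [dm.GrayFrame(speckle_frame.pixels, frame_index=i) for i in range(6)]
        sess = sample_and_label(frames, sched)
        compute_session_fields(sess, small_grid)
        prof = temporal_profile(sess, "happy")
        assert len(prof) == 4
        assert np.all(prof.mean_magnitude == 0.0)

    def test_cohort_curve_of_one_participant_is_its_own(self, strong_sessions):
        sess = next(iter(strong_sessions.values()))
        prof = temporal_profile(sess, "sad")
        cohort = cohort_profile([prof])
        assert np.allclose(cohort.mean_magnitude.values, prof.mean_magnitude.values)

    def test_ramped_generator_gives_monotone_cohort_curve(self, strong_sessions):
        from scipy.stats import spearmanr

        profs = [temporal_profile(s, "happy") for s in strong_sessions.values()]
        curve = cohort_profile(profs)
        rho = spearmanr(curve.block_time, curve.mean_magnitude).statistic
        assert rho > 0.95
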