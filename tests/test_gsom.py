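"""Growing self-organizing map: growth threshold, training, profiles."""

import math

import numpy as np
import pytest

from emovista.gsom import (GSOMConfig, GSOMMap, build_user_features,
                           derive_profiles, growth_threshold, train_gsom)


@pytest.fixture(scope="module")
def blobs():
    """Two well-separated Gaussian blobs in [0,1]^4, 200 points each."""
    rng = np.random.default_rng(42)
    X = np.clip(np.vstack([rng.normal(0.2, 0.05, (200, 4)),
                           rng.normal(0.8, 0.05, (200, 4))]), 0, 1)
    labels = np.array([0] * 200 + [1] * 200)
    return X, labels


@pytest.fixture(scope="module")
def blob_map(blobs):
    X, _ = blobs
    return train_gsom(X, GSOMConfig(seed=0))


class TestGrowthThreshold:
    @pytest.mark.parametrize("D,SF,expected", [
        (2, 0.5, 1.3863),
        (10, 0.1, 23.0259),
    ])
    def test_closed_form(self, D, SF, expected):
        assert growth_threshold(D, SF) == pytest.approx(expected, abs=5e-5)
        assert growth_threshold(D, SF) == pytest.approx(-D * math.log(SF))

    def test_vanishes_as_sf_approaches_one(self):
        assert growth_threshold(5, 1 - 1e-12) == pytest.approx(0.0, abs=1e-9)

    def test_decreasing_in_sf_linear_in_d(self):
        assert growth_threshold(4, 0.2) > growth_threshold(4, 0.6)
        assert growth_threshold(8, 0.3) == pytest.approx(
            2 * growth_threshold(4, 0.3))

    @pytest.mark.parametrize("SF", [0.0, 1.0, -0.3, 2.0])
    def test_invalid_spread_factor_rejected(self, SF):
        with pytest.raises(ValueError):
            growth_threshold(4, SF)


class TestTrainGSOM:
    def test_single_repeated_vector_is_fixed_point(self):
        v = np.array([0.3, 0.7, 0.5])
        X = np.tile(v, (50, 1))
        gmap = train_gsom(X, GSOMConfig(seed=1))
        assert np.abs(gmap.weights - v).max() < 1e-3

    def test_map_never_smaller_than_initial_grid(self, blob_map):
        assert blob_map.n_nodes >= 4

    def test_weights_stay_in_unit_hypercube(self, blob_map):
        assert blob_map.weights.min() >= 0.0
        assert blob_map.weights.max() <= 1.0

    def test_deterministic_under_seed(self, blobs):
        X, _ = blobs
        m1 = train_gsom(X[:80], GSOMConfig(seed=5, growth_epochs=10,
                                           smooth_epochs=10))
        m2 = train_gsom(X[:80], GSOMConfig(seed=5, growth_epochs=10,
                                           smooth_epochs=10))
        assert m1.coords == m2.coords
        np.testing.assert_array_equal(m1.weights, m2.weights)

    def test_blob_separation(self, blobs, blob_map):
        """Records of the two blobs map to disjoint node sets with ≥95%
        node purity."""
        X, labels = blobs
        assigned = blob_map.assign(X)
        nodes0 = set(assigned[labels == 0])
        nodes1 = set(assigned[labels == 1])
        assert nodes0.isdisjoint(nodes1)
        purity = sum(
            max((labels[assigned == n] == 0).sum(),
                (labels[assigned == n] == 1).sum())
            for n in np.unique(assigned)) / len(X)
        assert purity >= 0.95

    def test_dimension_mismatch_rejected(self, blob_map):
        with pytest.raises(ValueError):
            derive_profiles(blob_map, np.zeros((3, 7)))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            train_gsom(np.empty((0, 3)))

    def test_json_roundtrip(self, blob_map, tmp_path):
        blob_map.to_json(tmp_path / "map.json")
        loaded = GSOMMap.from_json(tmp_path / "map.json")
        assert loaded.coords == blob_map.coords
        np.testing.assert_allclose(loaded.weights, blob_map.weights)


class TestDeriveProfiles:
    def test_two_blobs_give_exactly_two_profiles(self, blobs, blob_map):
        X, labels = blobs
        profiles = derive_profiles(blob_map, X, min_hits=3)
        assert len(profiles) == 2
        for prof in profiles:
            member_labels = labels[prof.member_ids]
            assert (member_labels == member_labels[0]).all()

    def test_single_blob_gives_one_profile(self):
        rng = np.random.default_rng(0)
        X = np.clip(rng.normal(0.5, 0.05, (300, 4)), 0, 1)
        gmap = train_gsom(X, GSOMConfig(seed=0))
        assert len(derive_profiles(gmap, X, min_hits=3)) == 1

    def test_zero_hit_nodes_excluded(self, blobs, blob_map):
        X, _ = blobs
        hits = np.bincount(blob_map.assign(X), minlength=blob_map.n_nodes)
        for prof in derive_profiles(blob_map, X, min_hits=3):
            for coord in prof.node_coords:
                assert hits[blob_map.index[coord]] >= 1

    def test_unreachable_min_hits_rejected(self, blobs, blob_map):
        X, _ = blobs
        with pytest.raises(ValueError, match="min_hits"):
            derive_profiles(blob_map, X, min_hits=10_000)

    def test_labels_name_strongest_features(self, blobs, blob_map):
        X, _ = blobs
        profiles = derive_profiles(blob_map, X, min_hits=3, m=2,
                                   feature_names=["w", "x", "y", "z"])
        for prof in profiles:
            top = {["w", "x", "y", "z"][i]
                   for i in np.argsort(-prof.mean_vector)[:2]}
            assert set(prof.label.split("+")) == top


class TestUserFeatures:
    def test_blocks_normalized(self):
        users, X, names = build_user_features(
            ["u1", "u1", "u2"],
            ["work", "school", "work"],
            [{"joy": 2.0}, {"fear": 1.0}, {"joy": 0.0}],
            topic_names=["work", "school"],
            emotion_names=["joy", "fear"])
        assert users == ["u1", "u2"]
        np.testing.assert_allclose(X[0], [0.5, 0.5, 2 / 3, 1 / 3])
        # u2 has no scored emotion: topic block sums to 1, emotion block 0
        np.testing.assert_allclose(X[1], [1.0, 0.0, 0.0, 0.0])
        assert names == ["topic:work", "topic:school",
                         "emotion:joy", "emotion:fear"]
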