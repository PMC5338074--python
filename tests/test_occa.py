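import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from eeg3wd.entropy import BOUNDARY
from eeg3wd.occa import (
    Cover,
    CoverModel,
    Decision,
    cover_radius,
    decide,
    normalize_apply,
    normalize_fit,
    sphere_project,
    train,
)
from eeg3wd.synthetic import synth_feature_table


def separable_dataset(seed, n_per_class=10, dim=3, separation=8.0):
    table = synth_feature_table(n_per_class, dim, separation, seed)
    X = table.iloc[:, :dim].to_numpy()
    y = table["label"].to_numpy()
    return X, y


class TestNormalization:
    def test_min_and_range_of_a_column(self):
        mins, ranges = normalize_fit(np.array([[0.0], [5.0], [10.0]]))
        assert mins[0] == 0.0 and ranges[0] == 10.0

    def test_constant_column_maps_to_zero(self):
        mins, ranges = normalize_fit(np.array([[3.0], [3.0]]))
        assert ranges[0] == 1.0
        np.testing.assert_array_equal(
            normalize_apply(np.array([[3.0]]), mins, ranges), [[0.0]]
        )

    def test_training_rows_map_into_unit_cube(self, rng):
        X = rng.normal(5, 20, size=(30, 4))
        mins, ranges = normalize_fit(X)
        Z = normalize_apply(X, mins, ranges)
        assert Z.min() >= 0.0 and Z.max() <= 1.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            normalize_fit(np.empty((0, 3)))


class TestSphereProjection:
    def test_origin_lifts_to_the_pole(self):
        np.testing.assert_array_equal(
            sphere_project(np.zeros(3), 1.0), [0.0, 0.0, 0.0, 1.0]
        )

    def test_boundary_point_gets_zero_last_coordinate(self):
        lifted = sphere_project(np.array([3.0, 4.0]), 5.0)
        assert lifted[-1] == 0.0

    @settings(deadline=None, derandomize=True)
    @given(arrays(float, 3, elements=st.floats(-1, 1)))
    def test_lifted_norm_equals_radius(self, x):
        R = max(float(np.linalg.norm(x)), 1e-3)
        lifted = sphere_project(x, R)
        assert np.linalg.norm(lifted) == pytest.approx(R, rel=1e-9)

    def test_point_outside_sphere_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            sphere_project(np.array([2.0, 0.0]), 1.0)


class TestCoverRadius:
    def test_no_enemy_falls_back_to_farthest_friend(self):
        center = np.zeros(2)
        same = np.array([[0.0, 0.0], [0.4, 0.0]])
        assert cover_radius(center, same, np.empty((0, 2))) == pytest.approx(0.4)

    def test_midpoint_between_last_friend_and_nearest_enemy(self):
        center = np.zeros(2)
        same = np.array([[0.0, 0.0], [0.6, 0.0], [1.5, 0.0]])
        enemy = np.array([[1.0, 0.0]])
        assert cover_radius(center, same, enemy) == pytest.approx(0.8)

    def test_tight_mode_hugs_the_friends(self):
        center = np.zeros(2)
        same = np.array([[0.0, 0.0], [0.6, 0.0]])
        enemy = np.array([[1.0, 0.0]])
        assert cover_radius(center, same, enemy, mode="tight") == pytest.approx(0.6)

    def test_radius_separates_friends_from_enemies(self, rng):
        for _ in range(100):
            center = rng.normal(size=3)
            same = np.vstack([center, rng.normal(size=(5, 3))])
            enemy = rng.normal(size=(5, 3)) + 4.0
            d1 = np.linalg.norm(enemy - center, axis=1).min()
            d_same = np.linalg.norm(same - center, axis=1)
            d2 = d_same[d_same < d1].max()
            radius = cover_radius(center, same, enemy)
            assert d2 <= radius < d1

    def test_empty_same_class_rejected(self):
        with pytest.raises(ValueError, match="same-class"):
            cover_radius(np.zeros(2), np.empty((0, 2)), np.zeros((1, 2)))


class TestTraining:
    def test_two_well_separated_clusters_need_two_covers(self):
        X, y = separable_dataset(seed=1, separation=12.0)
        model = train(X, y)
        assert len(model.covers) == 2
        assert sorted(c.label for c in model.covers) == [0, 1]

    def test_single_sample_per_class_gives_half_distance_radii(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array([0, 1])
        model = train(X, y)
        lifted = [
            sphere_project(normalize_apply(x, model.feature_mins,
                                           model.feature_ranges), model.R)
            for x in X
        ]
        d1 = np.linalg.norm(lifted[0] - lifted[1])
        for cover in model.covers:
            assert cover.radius == pytest.approx(d1 / 2)
            assert cover.member_count == 1

    def test_single_class_input_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            train(np.zeros((4, 2)), np.zeros(4, dtype=int))

    def test_conflicting_duplicate_rows_warn(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        y = np.array([0, 1, 1])
        with pytest.warns(UserWarning, match="conflicting"):
            train(X, y)

    def test_model_is_deterministic_given_row_order(self):
        X, y = separable_dataset(seed=5, separation=4.0)
        m1, m2 = train(X, y), train(X, y)
        assert m1.to_json() == m2.to_json()

    def test_label_column_form_matches_split_form(self):
        table = synth_feature_table(8, 3, 6.0, seed=9)
        from_table = train(table)
        X = table.iloc[:, :3].to_numpy()
        y = table["label"].to_numpy()
        from_arrays = train(X, y)
        assert from_table.to_json() == from_arrays.to_json()


class TestStructuralInvariants:
    @pytest.mark.parametrize("seed", range(25))
    def test_covering_and_resubstitution_on_separable_data(self, seed):
        X, y = separable_dataset(seed, n_per_class=8, dim=3,
                                 separation=6.0 + (seed % 4))
        model = train(X, y)
        assert len(model.covers) <= len(X)
        lifted = np.stack([
            sphere_project(normalize_apply(x, model.feature_mins,
                                           model.feature_ranges), model.R)
            for x in X
        ])
        for i, point in enumerate(lifted):
            own = [c for c in model.covers if c.label == y[i]]
            enemy = [c for c in model.covers if c.label != y[i]]
            assert any(
                np.linalg.norm(point - c.center) <= c.radius + 1e-12
                for c in own
            )
            assert not any(
                np.linalg.norm(point - c.center) < c.radius - 1e-12
                for c in enemy
            )
            # resubstitution: every training point decided as its label
            assert decide(model, X[i]).predicted_label == y[i]


class TestDecide:
    def test_far_point_lands_in_the_boundary_region(self):
        # tight covers hug the training clusters, so a probe far from
        # both clusters (clipped to a cube corner off the cluster
        # diagonal) is claimed by neither class -> abstain
        X, y = separable_dataset(seed=2, separation=10.0)
        model = train(X, y, radius_mode="tight")
        probe = np.where(np.arange(X.shape[1]) % 2 == 0,
                         X.max(axis=0) + 100.0, X.min(axis=0) - 100.0)
        d = decide(model, probe)
        assert d.region == "BND" and d.predicted_label == BOUNDARY

    def test_point_claimed_by_both_classes_is_boundary(self):
        # contrived model with overlapping covers of both labels
        center = np.array([0.0, 0.0, 1.0])
        model = CoverModel(
            covers=[
                Cover(center=center, radius=0.5, label=0, member_count=1),
                Cover(center=center, radius=0.5, label=1, member_count=1),
            ],
            feature_mins=np.zeros(2),
            feature_ranges=np.ones(2),
            R=1.0,
        )
        d = decide(model, np.array([0.05, 0.05]))
        assert d.region == "BND"

    def test_regions_are_exhaustive_and_exclusive(self, rng):
        X, y = separable_dataset(seed=3, separation=5.0)
        model = train(X, y)
        for _ in range(200):
            d = decide(model, rng.normal(0, 3, size=X.shape[1]))
            assert d.region in ("POS", "NEG", "BND")
            expected = {"POS": 0, "NEG": 1, "BND": BOUNDARY}[d.region]
            assert d.predicted_label == expected

    def test_decisions_invariant_to_per_column_scaling(self):
        X, y = separable_dataset(seed=4, separation=6.0)
        scale = np.array([10.0, 0.5, 3.0])
        offset = np.array([-2.0, 7.0, 0.1])
        model_a = train(X, y)
        model_b = train(X * scale + offset, y)
        probes = np.vstack([X, X + 0.3])
        for p in probes:
            assert (
                decide(model_a, p).predicted_label
                == decide(model_b, p * scale + offset).predicted_label
            )

    def test_dimensionality_mismatch_rejected(self):
        X, y = separable_dataset(seed=6)
        model = train(X, y)
        with pytest.raises(ValueError, match="length"):
            decide(model, np.zeros(5))

    def test_inconsistent_decision_construction_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            Decision(region="POS", predicted_label=1)


class TestSerialization:
    def test_json_round_trip_preserves_decisions(self, rng):
        X, y = separable_dataset(seed=7, separation=5.0)
        model = train(X, y)
        restored = CoverModel.from_json(model.to_json())
        for _ in range(50):
            p = rng.normal(0, 2, size=X.shape[1])
            assert decide(model, p).region == decide(restored, p).region

    def test_unsupported_version_rejected(self):
        with pytest.raises(ValueError, match="version"):
            CoverModel.from_json('{"format_version": 99}')
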