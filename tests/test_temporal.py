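import numpy as np
import pytest

import tomoloc as tl
from tomoloc.temporal import TemporalThresholds, diana_labels


class TestStageFoldChangeFilter:
    def test_identical_profiles_fail(self):
        p = np.array([20, 20, 20, 20, 20.0])
        passed, max_fold = tl.stage_fold_change_filter(p, p)
        assert not passed and max_fold == 1.0

    def test_vegetal_shift_passes(self):
        early = np.array([20, 20, 20, 20, 20.0])
        late = np.array([10, 10, 15, 15, 50.0])
        passed, max_fold = tl.stage_fold_change_filter(early, late)
        assert passed
        assert max_fold == pytest.approx(51 / 21)

    def test_threshold_ordering(self):
        early = np.array([20, 20, 20, 20, 20.0])
        late = np.array([18, 18, 18, 14, 32.0])  # max fold = 33/21 ~ 1.57
        assert tl.stage_fold_change_filter(early, late, min_fold=1.5)[0]
        assert not tl.stage_fold_change_filter(early, late, min_fold=2.0)[0]

    def test_decrease_counts_as_change(self):
        early = np.array([50, 20, 10, 10, 10.0])
        late = np.array([20, 30, 20, 15, 15.0])
        assert tl.stage_fold_change_filter(early, late)[0]

    def test_min_fold_must_exceed_one(self):
        with pytest.raises(ValueError):
            tl.stage_fold_change_filter(np.ones(5) * 20, np.ones(5) * 20, min_fold=1.0)


class TestReproducibilityFilter:
    def test_consistent_direction_passes(self):
        early = np.array([20, 20, 20, 20, 20.0])
        late = np.array([[10, 10, 10, 20, 50.0], [12, 12, 16, 20, 40.0]])
        assert tl.replicate_reproducibility_filter(early, late)

    def test_opposite_directions_fail(self):
        early = np.array([20, 20, 20, 20, 20.0])
        late = np.array([[10, 15, 15, 20, 40.0], [30, 25, 20, 20, 5.0]])
        assert not tl.replicate_reproducibility_filter(early, late)

    def test_single_replicate_passes_with_warning(self):
        with pytest.warns(UserWarning, match="single"):
            assert tl.replicate_reproducibility_filter(
                np.full(5, 20.0), np.array([[10, 10, 10, 20, 50.0]])
            )


class TestAssignTemporalGroup:
    VEG = np.array([5, 5, 10, 30, 50.0])
    UNI = np.array([20, 20, 20, 20, 20.0])

    def _assign(self, e, l, ce, cl, passed=True):
        return tl.assign_temporal_group(e, l, ce, cl, passed)

    def test_stable_vegetal_is_early_vegetal(self):
        assert self._assign(self.VEG, self.VEG, "vegetal", "vegetal") == "early_vegetal"

    def test_uniform_to_vegetal_is_late_homogeneous(self):
        assert (
            self._assign(self.UNI, self.VEG, "undefined", "vegetal")
            == "late_vegetal_homogeneous"
        )

    def test_weak_gradient_sharpening_is_predefined(self):
        e = np.array([14, 16, 18, 24, 28.0])  # pD+pE = 52
        l = np.array([4, 6, 10, 30, 50.0])  # pD+pE = 80
        assert self._assign(e, l, "undefined", "vegetal") == "late_vegetal_predefined"

    def test_mirrored_rules_for_animal_groups(self):
        assert (
            self._assign(self.UNI, self.VEG[::-1], "undefined", "animal")
            == "late_animal_homogeneous"
        )
        e = np.array([28, 24, 18, 16, 14.0])
        l = np.array([50, 30, 10, 6, 4.0])
        assert self._assign(e, l, "undefined", "animal") == "late_animal_predefined"

    def test_bipolar_profile_is_polar(self):
        l = np.array([35, 10, 5, 10, 40.0])
        assert self._assign(self.UNI, l, "undefined", "undefined") == "polar"

    def test_failed_filters_force_other_except_early(self):
        assert (
            self._assign(self.UNI, self.VEG, "undefined", "vegetal", passed=False)
            == "other"
        )
        # early groups are exempt from the filters
        assert (
            self._assign(self.VEG, self.VEG, "vegetal", "vegetal", passed=False)
            == "early_vegetal"
        )

    def test_mirror_symmetry_of_assignment(self):
        cases = [
            (self.VEG, self.VEG, "vegetal", "vegetal"),
            (self.UNI, self.VEG, "undefined", "vegetal"),
            (np.array([14, 16, 18, 24, 28.0]), np.array([4, 6, 10, 30, 50.0]),
             "undefined", "vegetal"),
            (self.UNI, np.array([35, 10, 5, 10, 40.0]), "undefined", "undefined"),
        ]
        swap = {
            "early_vegetal": "early_animal",
            "late_vegetal_homogeneous": "late_animal_homogeneous",
            "late_vegetal_predefined": "late_animal_predefined",
            "polar": "polar",
            "other": "other",
        }
        mirror_class = {"vegetal": "animal", "undefined": "undefined"}
        for e, l, ce, cl in cases:
            fwd = self._assign(e, l, ce, cl)
            rev = self._assign(e[::-1], l[::-1], mirror_class[ce], mirror_class[cl])
            assert rev == swap[fwd]


class TestDianaClustering:
    def test_two_duplicated_archetypes_split_perfectly(self):
        X = np.array([[5, 5, 10, 30, 50.0]] * 50 + [[70, 15, 10, 3, 2.0]] * 50)
        labels, scores = tl.cluster_profiles(X, range(2, 5))
        first, second = labels[:50], labels[50:]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert first[0] != second[0]

    def test_identical_rows_return_single_cluster(self):
        with pytest.warns(UserWarning, match="identical"):
            labels, scores = tl.cluster_profiles(np.tile([20.0] * 5, (6, 1)), range(2, 4))
        assert set(labels) == {0} and scores == {}

    def test_invalid_k_range_raises(self):
        X = np.random.default_rng(0).normal(size=(5, 5))
        with pytest.raises(ValueError, match="k_range"):
            tl.cluster_profiles(X, range(2, 10))

    def test_diana_hierarchy_is_divisive(self):
        rng = np.random.default_rng(1)
        X = np.vstack(
            [rng.normal(0, 0.1, (10, 3)), rng.normal(5, 0.1, (10, 3)),
             rng.normal(10, 0.1, (10, 3))]
        )
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(X))
        l2 = diana_labels(D, 2)
        l3 = diana_labels(D, 3)
        # k=3 refines k=2: each k=3 cluster lies inside one k=2 cluster
        for c in np.unique(l3):
            assert len(np.unique(l2[l3 == c])) == 1
        assert len(np.unique(l3)) == 3
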