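import numpy as np
import pytest

import phyloquartet as pq
from phyloquartet.interpret import (
    AttributionMap,
    RelevanceProfile,
    normalize_attributions,
)
from phyloquartet.simulate import SegmentSpec


@pytest.fixture(scope="module")
def trained(study_tree, study_alignment):
    cfg = pq.LossConfig("quartet_plus_siamese", sigma=0.1)
    model, _ = pq.train(study_tree, study_alignment.sequences, cfg,
                        epochs=20, seed=0)
    return model


class TestNormalizeAttributions:
    def test_equal_outputs_score_zero(self):
        scores, undefined = normalize_attributions(np.array([[2.0, 2.0, 2.0, 2.0]]))
        assert np.allclose(scores, 0.0)
        assert not undefined[0]

    def test_single_active_base(self):
        scores, _ = normalize_attributions(np.array([[1.0, 0.0, 0.0, 0.0]]))
        assert scores[0].tolist() == [0.75, -0.25, -0.25, -0.25]

    def test_l1_arithmetic(self):
        scores, _ = normalize_attributions(np.array([[2.0, 1.0, 1.0, 0.0]]))
        assert scores[0].tolist() == [0.25, 0.0, 0.0, -0.25]

    def test_all_zero_position_flagged(self):
        scores, undefined = normalize_attributions(np.zeros((1, 4)))
        assert np.allclose(scores, 0.0)
        assert undefined[0]


class TestInSilicoMutagenesis:
    def test_map_shape_and_feature_range(self, trained, study_alignment):
        seq = next(iter(study_alignment.sequences.values()))
        amap = pq.in_silico_mutagenesis(trained, seq, feature=0)
        assert amap.scores.shape == (35, 4)
        with pytest.raises(ValueError):
            pq.in_silico_mutagenesis(trained, seq, feature=30)

    def test_position_scores_sum_to_zero(self, trained, study_alignment):
        """With nonnegative (ReLU) outputs, the four normalized scores at a
        defined position sum to sum(P)/sum|P| - 1 = 0."""
        seq = next(iter(study_alignment.sequences.values()))
        for f in range(0, 30, 7):
            amap = pq.in_silico_mutagenesis(trained, seq, feature=f)
            sums = amap.scores.sum(axis=1)
            assert np.allclose(sums[~amap.undefined], 0.0, atol=1e-12)

    def test_to_frame_columns(self, trained, study_alignment):
        seq = next(iter(study_alignment.sequences.values()))
        df = pq.in_silico_mutagenesis(trained, seq, feature=1).to_frame()
        assert list(df.columns) == ["position", "A", "C", "G", "T"]
        assert df["position"].iloc[0] == 1


class TestAverageAttribution:
    def test_single_map_identity(self, rng):
        amap = AttributionMap(0, rng.random((10, 4)))
        avg = pq.average_attribution([amap])
        assert np.array_equal(avg.scores, amap.scores)

    def test_map_plus_negation_cancels(self, rng):
        scores = rng.random((10, 4))
        avg = pq.average_attribution(
            [AttributionMap(0, scores), AttributionMap(0, -scores)]
        )
        assert np.allclose(avg.scores, 0.0)

    def test_three_maps_match_loop(self, rng):
        maps = [AttributionMap(2, rng.random((6, 4))) for _ in range(3)]
        avg = pq.average_attribution(maps)
        expected = sum(m.scores for m in maps) / 3
        assert np.allclose(avg.scores, expected)

    def test_mismatched_maps_rejected(self, rng):
        with pytest.raises(ValueError):
            pq.average_attribution(
                [AttributionMap(0, rng.random((5, 4))),
                 AttributionMap(1, rng.random((5, 4)))]
            )
        with pytest.raises(ValueError):
            pq.average_attribution([])


class TestFindRootFeatures:
    def make_F(self, tree, pattern):
        side_a, _ = tree.root_bipartition()
        V = np.zeros((tree.n_taxa, 3))
        for i, taxon in enumerate(tree.leaves):
            V[i, 0] = 1.0 if (taxon in side_a) == pattern else 0.0
            V[i, 1] = 1.0  # active everywhere
        return pq.FeatureMatrix(V, tree.leaves)

    def test_clean_separation_found(self, study_tree):
        F = self.make_F(study_tree, True)
        found = pq.find_root_features(F, study_tree)
        side_a, _ = study_tree.root_bipartition()
        assert [(f, s) for f, s in found] == [(0, side_a)]

    def test_everywhere_active_not_root_feature(self, study_tree):
        F = self.make_F(study_tree, True)
        assert all(f != 1 for f, _ in pq.find_root_features(F, study_tree))

    def test_one_leak_disqualifies(self, study_tree):
        F = self.make_F(study_tree, True)
        V = F.vectors.copy()
        side_a, side_b = study_tree.root_bipartition()
        leak = study_tree.index[sorted(side_b)[0]]
        V[leak, 0] = 0.5  # one taxon of the inactive side lights up
        assert pq.find_root_features(
            pq.FeatureMatrix(V, study_tree.leaves), study_tree
        ) == []

    def test_explicit_root_split(self, study_tree):
        side_a, _ = study_tree.root_bipartition()
        F = self.make_F(study_tree, True)
        found = pq.find_root_features(F, study_tree, root_split=sorted(side_a))
        assert found[0][0] == 0
        with pytest.raises(ValueError):
            pq.find_root_features(F, study_tree, root_split=list(study_tree.leaves))


class TestRelevanceAndDelta:
    def test_point_mass(self):
        scores = np.zeros((35, 4))
        scores[10, 2] = 0.7
        prof = pq.relative_relevance(AttributionMap(0, scores))
        assert prof.values[10] == pytest.approx(1.0)
        assert prof.values.sum() == pytest.approx(1.0)

    def test_uniform(self):
        prof = pq.relative_relevance(AttributionMap(0, np.full((35, 4), 0.1)))
        assert np.allclose(prof.values, 1 / 35)

    def test_matches_loop_oracle(self, rng):
        scores = rng.standard_normal((35, 4))
        prof = pq.relative_relevance(AttributionMap(0, scores))
        a = [sum(abs(scores[i, b]) for b in range(4)) for i in range(35)]
        expected = np.array(a) / sum(a)
        assert np.allclose(prof.values, expected)

    def test_zero_map_undefined(self):
        prof = pq.relative_relevance(AttributionMap(0, np.zeros((35, 4))))
        assert not prof.defined
        with pytest.raises(ValueError):
            pq.delta_f(prof)

    def test_delta_uniform_is_zero(self):
        prof = RelevanceProfile(0, np.full(35, 1 / 35))
        assert pq.delta_f(prof).delta == pytest.approx(0.0)

    def test_delta_single_s2_position(self):
        values = np.zeros(35)
        values[10] = 1.0  # inside S2 = positions 9..28 (1-based)
        assert pq.delta_f(RelevanceProfile(0, values)).delta == pytest.approx(1 / 20)

    def test_delta_single_s3_position(self):
        values = np.zeros(35)
        values[30] = 1.0  # inside S3 = positions 29..35 (1-based)
        assert pq.delta_f(RelevanceProfile(0, values)).delta == pytest.approx(-1 / 7)

    def test_delta_respects_custom_segments(self):
        spec = SegmentSpec(stable_len=2, evolving_len=4, random_len=2,
                           muts_per_node=1)
        values = np.zeros(8)
        values[2] = 1.0
        assert pq.delta_f(RelevanceProfile(0, values), spec).delta == pytest.approx(1 / 4)


class TestCompareDeltaDistributions:
    def test_identical_samples_near_half(self):
        u, p = pq.compare_delta_distributions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert 0.3 < p < 0.8

    def test_perfect_separation_exact_p(self):
        """3 vs 3 with complete separation: U = 9 and one-sided exact
        p = 1 / C(6,3) = 0.05."""
        u, p = pq.compare_delta_distributions([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])
        assert u == 9.0
        assert p == pytest.approx(0.05)

    def test_swapped_groups_complementary(self):
        _, p = pq.compare_delta_distributions([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])
        _, p_swapped = pq.compare_delta_distributions([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert p_swapped >= 1.0 - p

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pq.compare_delta_distributions([], [1.0])


class TestPipeline:
    def test_model_root_deltas(self, trained, study_tree, study_alignment):
        deltas = pq.model_root_deltas(trained, study_tree,
                                      study_alignment.sequences)
        assert len(deltas) >= 1
        for d in deltas:
            assert np.isfinite(d.delta)
            assert -1 / 7 - 1e-9 <= d.delta <= 1 / 20 + 1e-9

    def test_custom_attribution_backend(self, trained, study_tree,
                                        study_alignment):
        """Any backend producing an L x 4 map plugs into the same pipeline."""
        calls = []

        def backend(model, sequence, feature):
            calls.append(feature)
            scores = np.zeros((35, 4))
            scores[9, 0] = 1.0
            return AttributionMap(feature, scores)

        deltas = pq.model_root_deltas(
            trained, study_tree, study_alignment.sequences,
            attribution_backend=backend,
        )
        assert calls
        assert all(d.delta == pytest.approx(1 / 20) for d in deltas)

    def test_localization_experiment_structure(self, study_tree):
        res = pq.localization_experiment(study_tree, n_replicates=2,
                                         epochs=12, seed=5)
        assert res.deltas_correct and res.deltas_shuffled
        assert 0.0 <= res.p_value <= 1.0
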