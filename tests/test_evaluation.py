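import numpy as np
import pytest

from blnimda.data_io import AssociationMatrix, Params, ValidationError
from blnimda.evaluation import (
    kfold_cv,
    loocv,
    roc_auc,
    shuffled_label_auc,
    t_sweep,
    topk,
)
from blnimda.profile_kernels import integrated_similarities
from blnimda.scoring import score_pipeline
from blnimda.synthetic import SyntheticSpec, generate
from tests.conftest import make_inputs
from tests.reference_impl import naive_auc


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _, _ = roc_auc([0.9], [0.1])
        assert auc == 1.0

    def test_all_ties_give_half(self):
        auc, _, _ = roc_auc([0.5, 0.5], [0.5, 0.5, 0.5])
        assert auc == 0.5

    def test_pair_counting_example(self):
        auc, _, _ = roc_auc([0.8, 0.4], [0.6, 0.2])
        assert auc == 0.75

    def test_agrees_with_exhaustive_pair_count(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            pos = rng.choice([0.1, 0.3, 0.5, 0.8], size=8)
            neg = rng.choice([0.1, 0.3, 0.5, 0.8], size=13)
            auc, _, _ = roc_auc(pos, neg)
            assert auc == pytest.approx(naive_auc(pos, neg), abs=1e-12)

    def test_rank_based_equals_trapezoidal_curve_area(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            pos = rng.normal(0.6, 0.3, size=30)
            neg = rng.normal(0.4, 0.3, size=50)
            auc, fpr, tpr = roc_auc(pos, neg)
            assert auc == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-12)

    def test_empty_or_nan_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([], [0.1])
        with pytest.raises(ValidationError):
            roc_auc([0.5, np.nan], [0.1])


@pytest.fixture(scope="module")
def tiny_data():
    return generate(SyntheticSpec(n_m=10, n_d=8, n_blocks=2, seed=3))


@pytest.fixture(scope="module")
def tiny_inputs(tiny_data):
    return make_inputs(tiny_data)


class TestLoocv:
    def test_planted_signal_beats_chance(self, tiny_data, tiny_inputs):
        result = loocv(tiny_data.associations, tiny_inputs)
        assert result.auc > 0.5

    def test_low_density_instance_still_beats_chance(self):
        """A weak (15% within-block) signal is recovered above chance on
        average; individual seeds fluctuate around the mean."""
        aucs = []
        for seed in range(5):
            data = generate(SyntheticSpec(density=0.15, seed=seed))
            aucs.append(loocv(data.associations, make_inputs(data)).auc)
        assert np.mean(aucs) > 0.5

    def test_masking_defeats_a_memorizing_scorer(self, tiny_data, tiny_inputs):
        """The held-out link's own entry cannot carry its full-data score."""
        full_fms, full_fds = integrated_similarities(
            tiny_data.associations, tiny_inputs
        )
        full = score_pipeline(tiny_data.associations, full_fms, full_fds)
        result = loocv(tiny_data.associations, tiny_inputs)
        pairs = tiny_data.associations.positive_pairs()
        full_scores = full.Sf[pairs[:, 0], pairs[:, 1]]
        # full-data positive scores include the strong-branch weight e; the
        # masked rerun loses that branch, so held-out scores drop on average
        assert result.left_out_scores.mean() < full_scores.mean()

    def test_fold_kernels_reflect_the_mask(self, tiny_data, tiny_inputs):
        from blnimda.profile_kernels import gip_bandwidth

        pair = tiny_data.associations.positive_pairs()[0]
        masked = tiny_data.associations.with_masked(pair[None, :])
        full_bw = gip_bandwidth(tiny_data.associations, "mirna")
        masked_bw = gip_bandwidth(masked, "mirna")
        assert masked_bw.mean_profile_norm < full_bw.mean_profile_norm

    def test_needs_two_positives(self):
        data = generate(SyntheticSpec(n_m=4, n_d=4, n_blocks=1, density=0.0,
                                      background_density=0.0, seed=0))
        # no positives at all
        with pytest.raises(ValidationError):
            loocv(data.associations, make_inputs(data))

    def test_curve_is_monotone(self, tiny_data, tiny_inputs):
        result = loocv(tiny_data.associations, tiny_inputs)
        assert (np.diff(result.tpr) >= 0).all()
        assert (np.diff(result.fpr) >= 0).all()
        assert 0.0 <= result.auc <= 1.0


class TestKfold:
    def test_same_seed_reproduces_result(self, tiny_data, tiny_inputs):
        a = kfold_cv(tiny_data.associations, tiny_inputs, k=5, seed=7)
        b = kfold_cv(tiny_data.associations, tiny_inputs, k=5, seed=7)
        assert a.auc == b.auc
        np.testing.assert_array_equal(a.fold_assignments, b.fold_assignments)
        np.testing.assert_array_equal(a.left_out_scores, b.left_out_scores)

    def test_different_seed_changes_folds(self, tiny_data, tiny_inputs):
        a = kfold_cv(tiny_data.associations, tiny_inputs, k=5, seed=1)
        b = kfold_cv(tiny_data.associations, tiny_inputs, k=5, seed=2)
        assert not np.array_equal(a.fold_assignments, b.fold_assignments)

    def test_k_equal_positives_reproduces_loocv_scores(self, tiny_data, tiny_inputs):
        n_pos = tiny_data.associations.n_positives
        kf = kfold_cv(tiny_data.associations, tiny_inputs, k=n_pos, seed=0)
        lo = loocv(tiny_data.associations, tiny_inputs)
        np.testing.assert_array_equal(
            np.sort(kf.left_out_scores), np.sort(lo.left_out_scores)
        )
        assert kf.auc == pytest.approx(lo.auc, abs=1e-12)

    def test_mean_auc_close_to_loocv(self, tiny_data, tiny_inputs):
        kf = kfold_cv(tiny_data.associations, tiny_inputs, k=5, repeats=3, seed=0)
        lo = loocv(tiny_data.associations, tiny_inputs)
        assert kf.auc == pytest.approx(lo.auc, abs=0.1)

    def test_k_below_two_rejected(self, tiny_data, tiny_inputs):
        with pytest.raises(ValidationError):
            kfold_cv(tiny_data.associations, tiny_inputs, k=1)


class TestTSweep:
    def test_single_value_table(self, tiny_data, tiny_inputs):
        table, best = t_sweep(tiny_data.associations, tiny_inputs, [0.02], seed=0)
        assert len(table) == 1
        assert best == 0.02

    def test_grid_reports_argmax(self, tiny_data, tiny_inputs):
        table, best = t_sweep(
            tiny_data.associations, tiny_inputs, [0.0, 0.02, 0.5], seed=0
        )
        assert len(table) == 3
        assert best in {0.0, 0.02, 0.5}
        assert table.loc[table["T"] == best, "mean_auc"].iloc[0] == table["mean_auc"].max()

    def test_threshold_above_all_similarity_gives_chance(self, tiny_data, tiny_inputs):
        table, _ = t_sweep(tiny_data.associations, tiny_inputs, [2.0], seed=0)
        # T > 1 zeroes every numerator: constant scores except type weights
        assert 0.3 <= table["mean_auc"].iloc[0] <= 0.9


class TestTopK:
    @pytest.fixture()
    def bundle(self, tiny_data, tiny_inputs):
        fms, fds = integrated_similarities(tiny_data.associations, tiny_inputs)
        return score_pipeline(tiny_data.associations, fms, fds)

    def test_known_partners_excluded(self, tiny_data, bundle):
        disease = tiny_data.associations.index.disease_ids[0]
        ranking = topk(bundle, tiny_data.associations, disease, k=100)
        known = {
            tiny_data.associations.index.mirna_ids[g]
            for g in np.where(tiny_data.associations.values[:, 0] == 1)[0]
        }
        assert not (set(ranking["id"]) & known)

    def test_k_larger_than_candidates_returns_all(self, tiny_data, bundle):
        disease = tiny_data.associations.index.disease_ids[0]
        n_candidates = int((tiny_data.associations.values[:, 0] == 0).sum())
        ranking = topk(bundle, tiny_data.associations, disease, k=10_000)
        assert len(ranking) == n_candidates

    def test_scores_descend_and_ties_break_by_id(self, tiny_data, bundle):
        disease = tiny_data.associations.index.disease_ids[1]
        ranking = topk(bundle, tiny_data.associations, disease, k=50)
        scores = ranking["score"].to_numpy()
        assert (np.diff(scores) <= 1e-15).all()
        for i in range(len(ranking) - 1):
            if scores[i] == scores[i + 1]:
                assert ranking["id"].iloc[i] < ranking["id"].iloc[i + 1]

    def test_unknown_entity_rejected(self, tiny_data, bundle):
        with pytest.raises(KeyError):
            topk(bundle, tiny_data.associations, "no-such-disease", k=5)

    def test_mirna_direction(self, tiny_data, bundle):
        mirna = tiny_data.associations.index.mirna_ids[0]
        ranking = topk(
            bundle, tiny_data.associations, mirna, k=3, direction="diseases-for-mirna"
        )
        assert set(ranking["id"]) <= set(tiny_data.associations.index.disease_ids)


class TestNullCalibration:
    def test_shuffled_labels_concentrate_at_half(self, tiny_data, tiny_inputs):
        mean_auc, aucs = shuffled_label_auc(
            tiny_data.associations, tiny_inputs, n_shuffles=50, seed=0
        )
        assert len(aucs) == 50
        assert mean_auc == pytest.approx(0.5, abs=0.05)
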