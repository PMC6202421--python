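"""Cross-validation harness: AUC identities, LOOCV/k-fold behaviour."""

import numpy as np
import pytest

from cnmda import (
    ParameterError,
    Params,
    SyntheticSpec,
    generate_dataset,
    kfold_cv,
    loocv,
    new_disease_ranks,
    roc_auc,
)


def _bruteforce_auc(pos_scores, neg_scores):
    """O(n^2) pair-counting estimator: P(positive > negative) + P(tie)/2."""
    wins = ties = 0
    for p in pos_scores:
        for n in neg_scores:
            wins += p > n
            ties += p == n
    return (wins + 0.5 * ties) / (len(pos_scores) * len(neg_scores))


def _midrank(score, candidates):
    return 1.0 + sum(c > score for c in candidates) + 0.5 * sum(c == score for c in candidates)


class TestRocAuc:
    def test_perfect_ranking(self):
        auc, _ = roc_auc([1.0, 1.0, 1.0], 10)
        assert auc == 1.0

    def test_worst_ranking(self):
        auc, _ = roc_auc([11.0], 10)
        assert auc == 0.0

    def test_all_tied_scores_give_half(self):
        # a positive tied with every candidate sits at midrank (n + 2) / 2
        n = 8
        auc, _ = roc_auc([(n + 2) / 2], n)
        assert auc == pytest.approx(0.5)

    def test_hand_example_ranks_one_and_three(self):
        # positives at ranks 1 and 3 among 4 candidates; oracle by pair counts
        want = (_bruteforce_auc([10], [5, 4, 3, 2]) + _bruteforce_auc([3.5], [5, 4, 3, 2])) / 2
        auc, _ = roc_auc([1.0, 3.0], 4)
        assert auc == pytest.approx(want)

    def test_zero_positives_rejected(self):
        with pytest.raises(ParameterError):
            roc_auc([], 5)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bruteforce_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n_cand = int(rng.integers(1, 51))
        n_pos = int(rng.integers(1, 6))
        # coarse grid to force ties
        cand = rng.integers(0, 8, size=n_cand).astype(float)
        pos = rng.integers(0, 8, size=n_pos).astype(float)
        ranks = [_midrank(p, cand) for p in pos]
        auc, _ = roc_auc(ranks, n_cand)
        want = np.mean([_bruteforce_auc([p], cand) for p in pos])
        assert auc == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sklearn_on_untied_scores(self, seed):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(seed)
        cand = rng.random(40)
        pos = rng.random(3)
        ranks = [_midrank(p, cand) for p in pos]
        auc, _ = roc_auc(ranks, 40)
        want = np.mean([
            sklearn_metrics.roc_auc_score([1] + [0] * 40, np.concatenate([[p], cand]))
            for p in pos
        ])
        assert auc == pytest.approx(want, abs=1e-12)

    def test_curve_endpoints(self):
        _, curve = roc_auc([1.0, 3.0], 4)
        assert curve[0].tolist() == [0.0, 0.0] and curve[-1].tolist() == [1.0, 1.0]
        assert (np.diff(curve[:, 0]) >= 0).all() and (np.diff(curve[:, 1]) >= 0).all()


@pytest.fixture(scope="module")
def small_planted():
    ds, _ = generate_dataset(SyntheticSpec(nl=8, nd=10, nm=12, n_groups=2, seed=11))
    return ds


class TestLoocv:
    def test_planted_signal_recovered(self, small_planted):
        result = loocv(small_planted)
        assert result.auc > 0.6
        assert len(result.records) == int(small_planted.mda.values.sum())
        assert all(1 <= r.rank <= r.n_candidates + 1 for r in result.records)

    def test_fixed_kernels_close_to_recomputed(self, small_planted):
        fixed = loocv(small_planted, recompute_kernels=False)
        full = loocv(small_planted)
        assert abs(fixed.auc - full.auc) < 0.1

    def test_fold_with_only_association_runs_new_disease_mode(self):
        # d2's single association is masked in its fold: seeding falls back
        # to the lncRNA + disease blocks and the fold still completes
        from cnmda import AssociationMatrix, Dataset, EntityNamespace
        lnc = EntityNamespace("lncRNA", ("l1", "l2"))
        dis = EntityNamespace("disease", ("d1", "d2"))
        mir = EntityNamespace("miRNA", ("m1", "m2"))
        ds = Dataset(
            AssociationMatrix(dis, mir, np.array([[1, 1], [1, 0]])),
            AssociationMatrix(dis, lnc, np.array([[1, 0], [0, 1]])),
            AssociationMatrix(mir, lnc, np.array([[1, 0], [0, 1]])),
        )
        result = loocv(ds)
        assert len(result.records) == 3 and not result.failed_folds

    def test_too_few_associations_rejected(self, minimal_dataset):
        with pytest.raises(ParameterError):
            loocv(minimal_dataset)


class TestKfold:
    def test_same_seed_bit_reproducible(self, small_planted):
        a = kfold_cv(small_planted, k=5, reps=2, seed=3)
        b = kfold_cv(small_planted, k=5, reps=2, seed=3)
        assert a.rep_aucs == b.rep_aucs
        assert [(r.disease, r.mirna, r.rank) for r in a.records] == \
               [(r.disease, r.mirna, r.rank) for r in b.records]

    def test_k_equal_n_reduces_to_loocv(self, small_planted):
        n = int(small_planted.mda.values.sum())
        kf = kfold_cv(small_planted, k=n, reps=1, seed=0)
        lo = loocv(small_planted)
        kf_ranks = {(r.disease, r.mirna): r.rank for r in kf.records}
        lo_ranks = {(r.disease, r.mirna): r.rank for r in lo.records}
        assert kf_ranks == lo_ranks

    def test_kfold_close_to_loocv(self, small_planted):
        kf = kfold_cv(small_planted, k=5, reps=3, seed=1)
        lo = loocv(small_planted)
        assert abs(kf.auc - lo.auc) < 0.05
        assert kf.auc_sd is not None and kf.auc_sd_folds is not None

    def test_k_larger_than_associations_rejected(self, small_planted):
        with pytest.raises(ParameterError):
            kfold_cv(small_planted, k=10_000)


class TestNewDiseaseMode:
    def test_hidden_mirnas_rank_above_chance(self, small_planted):
        d = small_planted.diseases.ids[0]
        records = new_disease_ranks(small_planted, d)
        n_hidden = int(small_planted.mda.values[0, :].sum())
        assert len(records) == n_hidden
        median = np.median([r.rank for r in records])
        chance = (records[0].n_candidates + 1) / 2
        assert median < chance

    def test_disease_without_associations_rejected(self):
        from cnmda import AssociationMatrix, Dataset, EntityNamespace
        lnc = EntityNamespace("lncRNA", ("l1",))
        dis = EntityNamespace("disease", ("d1", "d2"))
        mir = EntityNamespace("miRNA", ("m1",))
        ds = Dataset(
            AssociationMatrix(dis, mir, np.array([[1], [0]])),
            AssociationMatrix(dis, lnc, np.array([[1], [1]])),
            AssociationMatrix(mir, lnc, np.array([[1]])),
        )
        with pytest.raises(ParameterError):
            new_disease_ranks(ds, "d2")
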