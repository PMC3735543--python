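import numpy as np
import pytest

from ervpredict import ensemble as ens
from ervpredict.io_tables import ErvInsertion
from ervpredict.mlp_core import MlpModel, TrainConfig, forward


def test_plan_study_scale_split_sizes():
    plan = ens.build_cv_plan(33, 117, permutations=1, seed=0)
    assert len(plan.splits) == 3
    for split in plan.splits:
        assert len(split["test_idx"]) == 50
        assert len(split["train_idx"]) == 100
        # stratification: 11 positives and 39 negatives per test fold
        assert np.sum(split["test_idx"] < 33) == 11
        assert np.sum(split["test_idx"] >= 33) == 39


def test_plan_minimal_classes():
    plan = ens.build_cv_plan(3, 3, permutations=1, seed=1)
    for split in plan.splits:
        assert np.sum(split["test_idx"] < 3) == 1 and np.sum(split["test_idx"] >= 3) == 1
    with pytest.raises(ValueError):
        ens.build_cv_plan(2, 10, permutations=1, seed=0)


def test_plan_remainder_distribution():
    plan = ens.build_cv_plan(34, 118, permutations=1, seed=2)
    pos_sizes = sorted(np.sum(s["test_idx"] < 34) for s in plan.splits)
    neg_sizes = sorted(np.sum(s["test_idx"] >= 34) for s in plan.splits)
    assert pos_sizes == [11, 11, 12] and neg_sizes == [39, 39, 40]
    # within a permutation, test folds are disjoint and cover everything
    all_test = np.concatenate([s["test_idx"] for s in plan.splits])
    assert len(all_test) == 152 and len(np.unique(all_test)) == 152


def test_plan_disjoint_and_complementary():
    plan = ens.build_cv_plan(33, 117, permutations=4, seed=3)
    for split in plan.splits:
        union = np.union1d(split["train_idx"], split["test_idx"])
        assert len(union) == 150
        assert len(np.intersect1d(split["train_idx"], split["test_idx"])) == 0


def test_plan_reproducible_and_digest():
    a = ens.build_cv_plan(33, 117, permutations=2, seed=5)
    b = ens.build_cv_plan(33, 117, permutations=2, seed=5)
    assert a.digest() == b.digest()
    c = ens.build_cv_plan(33, 117, permutations=2, seed=6)
    assert a.digest() != c.digest()


def test_train_ensemble_bookkeeping(encoded):
    X, t = encoded
    plan = ens.plan_from_labels(t, permutations=1, seed=0)
    model = ens.train_ensemble(plan, (X, t), n_reinits=2, cfg=TrainConfig(seed=0, max_epochs=50))
    assert model.n_members == 6
    assert sorted(set(model.split_id)) == [0, 1, 2]
    for s in range(3):
        assert np.sum(model.member_mask(s)) == 2


def test_no_leakage_between_train_and_test(small_ensemble):
    model, plan = small_ensemble
    for split in plan.splits:
        assert not np.any(np.isin(split["test_idx"], split["train_idx"]))


def test_consolidate_is_mean_of_members(small_ensemble, rng):
    model, _ = small_ensemble
    X = rng.random((5, 4))
    per_member = np.stack([forward(MlpModel.unpack(model.thetas[m]), X) for m in range(model.n_members)])
    np.testing.assert_allclose(ens.consolidate(model, X), per_member.mean(axis=0), rtol=1e-12)
    # convex hull: consolidated output between member extremes
    cons = ens.consolidate(model, X)
    assert np.all(cons >= per_member.min(axis=0)) and np.all(cons <= per_member.max(axis=0))


def test_consolidate_chunked_equals_direct(small_ensemble, rng):
    model, _ = small_ensemble
    X = rng.random((100, 4))
    np.testing.assert_allclose(
        ens.consolidate(model, X, chunk=7), ens.consolidate(model, X, chunk=10_000), atol=1e-12
    )


def test_consolidate_empty_subset_rejected(small_ensemble):
    model, _ = small_ensemble
    with pytest.raises(ValueError, match="empty"):
        ens.consolidate(model, np.zeros((1, 4)), member_mask=np.zeros(model.n_members, dtype=bool))


def _records(n=6):
    return [
        ErvInsertion(id=f"r{i}", family="IAP", orientation="sense" if i % 2 else "antisense",
                     intron_size_bp=1000 * (i + 1), exon_distance_bp=50 * i, label="unknown")
        for i in range(n)
    ]


def test_predict_threshold_extremes(small_ensemble):
    model, _ = small_ensemble
    recs = _records()
    assert (ens.predict(model, recs, tau=0.0)["call"] == "positive").all()
    assert (ens.predict(model, recs, tau=1.0 + 1e-9)["call"] == "negative").all()


def test_predict_order_equivariance(small_ensemble):
    model, _ = small_ensemble
    recs = _records()
    fwd = ens.predict(model, recs)
    rev = ens.predict(model, recs[::-1])
    np.testing.assert_allclose(fwd["likelihood"].to_numpy(), rev["likelihood"].to_numpy()[::-1])


def test_predict_per_record_error_entries(small_ensemble):
    model, _ = small_ensemble
    recs = _records(3)
    recs[1] = ErvInsertion.__new__(ErvInsertion)  # uninitialized record: encoding must fail
    recs[1].id = "broken"
    df = ens.predict(model, recs)
    assert df.loc[1, "error"] != "" and np.isnan(df.loc[1, "likelihood"])
    assert df.loc[0, "error"] == "" and df.loc[2, "error"] == ""
    assert np.isfinite(df.loc[0, "likelihood"])


def test_ensemble_training_reproducible(encoded):
    X, t = encoded
    plan = ens.plan_from_labels(t, permutations=1, seed=4)
    cfg = TrainConfig(seed=4, max_epochs=200)
    a = ens.train_ensemble(plan, (X, t), n_reinits=3, cfg=cfg)
    b = ens.train_ensemble(plan, (X, t), n_reinits=3, cfg=cfg)
    np.testing.assert_array_equal(a.thetas, b.thetas)
    np.testing.assert_array_equal(
        ens.consolidate(a, X), ens.consolidate(b, X)
    )


def test_members_trained_only_on_their_split(encoded):
    """Members of different splits differ (trained on different subsets)."""
    X, t = encoded
    plan = ens.plan_from_labels(t, permutations=1, seed=8)
    model = ens.train_ensemble(plan, (X, t), n_reinits=1, cfg=TrainConfig(seed=8, max_epochs=300))
    assert not np.array_equal(model.thetas[0], model.thetas[1])
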