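"""Randomized cross-validation ensemble of small perceptrons.

The training scheme fights two failure modes of small-sample neural-network
training. Over-fitting is handled by stratified 3-fold cross-validation:
positives and negatives are each split into three equal subgroups, one
positive and one negative subgroup form each held-out test set. Sensitivity
to the random initial weights is handled by randomization at two levels —
the class-wise permutation before subgrouping is repeated (10 times by
default, giving 30 train/test splits) and every split's network is
re-initialized and retrained (100 times by default). The final predictor
averages the outputs of all members (3000 under the defaults).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ervpredict import mlp_core
from ervpredict.features import encode_insertion
from ervpredict.io_tables import ErvInsertion, ModelArchive
from ervpredict.mlp_core import TrainConfig

SEED_MASK = 2**31 - 1


@dataclass
class CvPlan:
    """Stratified splits: ``splits[i]`` holds train/test index arrays plus provenance."""

    permutations: int
    folds: int
    splits: list  # dicts: {"permutation", "fold", "train_idx", "test_idx"}
    seed: int
    n_pos: int
    n_neg: int

    def digest(self) -> str:
        payload = [
            {"permutation": s["permutation"], "fold": s["fold"], "train_idx": s["train_idx"].tolist(), "test_idx": s["test_idx"].tolist()}
            for s in self.splits
        ]
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _subgroup(indices: np.ndarray, folds: int) -> list[np.ndarray]:
    """Partition a shuffled index pool into ``folds`` subgroups.

    When the pool size is not divisible, the remainder is distributed one
    extra member per subgroup, first subgroups first.
    """
    n = len(indices)
    base, extra = divmod(n, folds)
    sizes = [base + (1 if k < extra else 0) for k in range(folds)]
    out, pos = [], 0
    for size in sizes:
        out.append(indices[pos : pos + size])
        pos += size
    return out


def build_cv_plan(
    n_pos: int,
    n_neg: int,
    permutations: int = 10,
    seed: int = 0,
    *,
    folds: int = 3,
    pos_indices: Optional[np.ndarray] = None,
    neg_indices: Optional[np.ndarray] = None,
) -> CvPlan:
    """Build the randomized stratified cross-validation plan.

    By default positives occupy indices 0..n_pos-1 and negatives follow;
    pass explicit ``pos_indices``/``neg_indices`` for any other layout.
    Each of the ``permutations`` rounds shuffles both classes and partitions
    each into ``folds`` equal subgroups (remainders spread one per subgroup);
    fold k's test set is positive subgroup k plus negative subgroup k.
    """
    if n_pos < folds or n_neg < folds:
        raise ValueError(f"each class needs at least {folds} members (got {n_pos} positives, {n_neg} negatives)")
    pos_indices = np.arange(n_pos) if pos_indices is None else np.asarray(pos_indices)
    neg_indices = np.arange(n_pos, n_pos + n_neg) if neg_indices is None else np.asarray(neg_indices)
    if len(pos_indices) != n_pos or len(neg_indices) != n_neg:
        raise ValueError("index pools must match n_pos / n_neg")
    perm_seeds = np.random.SeedSequence(seed).spawn(permutations)
    splits = []
    for p, ss in enumerate(perm_seeds):
        rng = np.random.default_rng(ss)
        pos_sub = _subgroup(rng.permutation(pos_indices), folds)
        neg_sub = _subgroup(rng.permutation(neg_indices), folds)
        for k in range(folds):
            test = np.concatenate([pos_sub[k], neg_sub[k]])
            train = np.concatenate([pos_sub[j] for j in range(folds) if j != k] + [neg_sub[j] for j in range(folds) if j != k])
            splits.append(
                {"permutation": p, "fold": k, "train_idx": np.sort(train), "test_idx": np.sort(test)}
            )
    return CvPlan(permutations=permutations, folds=folds, splits=splits, seed=seed, n_pos=n_pos, n_neg=n_neg)


def plan_from_labels(t: np.ndarray, permutations: int = 10, seed: int = 0, folds: int = 3) -> CvPlan:
    """Convenience: stratify directly on a 0/1 target vector."""
    t = np.asarray(t)
    pos = np.flatnonzero(t == 1)
    neg = np.flatnonzero(t == 0)
    return build_cv_plan(
        len(pos), len(neg), permutations=permutations, seed=seed, folds=folds, pos_indices=pos, neg_indices=neg
    )


@dataclass
class EnsembleModel:
    """All trained members plus the cross-validation plan.

    ``thetas`` stacks every member's 19 parameters; companion arrays give
    each member's split, permutation, fold, reinit index and init seed.
    """

    thetas: np.ndarray  # (M, 19)
    split_id: np.ndarray  # (M,)
    permutation: np.ndarray
    fold: np.ndarray
    reinit: np.ndarray
    member_seed: np.ndarray
    plan: Optional[CvPlan]
    n_reinits: int
    training_config: TrainConfig = field(default_factory=TrainConfig)
    converged: Optional[np.ndarray] = None

    @property
    def n_members(self) -> int:
        return self.thetas.shape[0]

    def member_mask(self, split_id: int) -> np.ndarray:
        return self.split_id == split_id

    def stack(self, mask: Optional[np.ndarray] = None):
        thetas = self.thetas if mask is None else self.thetas[mask]
        return mlp_core._unpack_stack(thetas)


def _member_seeds(master_seed: int, n_splits: int, n_reinits: int) -> np.ndarray:
    """Seed hierarchy: master seed -> per-split sequences -> per-member init seeds."""
    split_seqs = np.random.SeedSequence(master_seed).spawn(n_splits)
    seeds = np.empty((n_splits, n_reinits), dtype=np.int64)
    for s, seq in enumerate(split_seqs):
        seeds[s] = seq.generate_state(n_reinits).astype(np.int64) & SEED_MASK
    return seeds


def train_ensemble(plan: CvPlan, data, n_reinits: int = 100, cfg: Optional[TrainConfig] = None) -> EnsembleModel:
    """Train ``n_reinits`` networks per split, each only on that split's training rows.

    ``data`` is either an (X, t) pair of arrays or a sequence of encoded
    FeatureVectors with targets. Fully reproducible from ``cfg.seed``. A
    member whose training error turns non-finite is re-seeded once; a second
    failure aborts.
    """
    cfg = cfg or TrainConfig()
    X, t = mlp_core._as_xy(data)
    n_splits = len(plan.splits)
    seeds = _member_seeds(cfg.seed, n_splits, n_reinits)
    for s, split in enumerate(plan.splits):
        if np.any(np.isin(split["test_idx"], split["train_idx"])):
            raise AssertionError(f"split {s}: test indices leak into the training set")
        if np.any(~np.isfinite(t[split["train_idx"]])):
            raise ValueError(f"split {s}: training rows must all carry targets")
    # Splits with equal training-set sizes train together in one grouped call
    # (member trajectories are independent, so grouping changes nothing).
    by_size: dict[int, list[int]] = {}
    for s, split in enumerate(plan.splits):
        by_size.setdefault(len(split["train_idx"]), []).append(s)
    thetas_by_split: dict[int, np.ndarray] = {}
    conv_by_split: dict[int, np.ndarray] = {}
    seeds_by_split: dict[int, np.ndarray] = {}
    for split_ids in by_size.values():
        group_seeds = [seeds[s] for s in split_ids]
        Xg = np.stack([X[plan.splits[s]["train_idx"]] for s in split_ids])
        tg = np.stack([t[plan.splits[s]["train_idx"]] for s in split_ids])
        thetas = np.stack([mlp_core.pack_stack(mlp_core.init_stack(ss, cfg.init_range)) for ss in group_seeds])
        try:
            thetas, _, conv, _ = mlp_core.train_grouped(thetas, Xg, tg, cfg)
        except FloatingPointError:
            # one re-seed of the whole group, then fail loudly
            group_seeds = [(ss + 1) & SEED_MASK for ss in group_seeds]
            thetas = np.stack([mlp_core.pack_stack(mlp_core.init_stack(ss, cfg.init_range)) for ss in group_seeds])
            thetas, _, conv, _ = mlp_core.train_grouped(thetas, Xg, tg, cfg)
        for g, s in enumerate(split_ids):
            thetas_by_split[s] = thetas[g]
            conv_by_split[s] = conv[g]
            seeds_by_split[s] = np.asarray(group_seeds[g])
    all_thetas, meta = [], {"split": [], "perm": [], "fold": [], "reinit": [], "seed": [], "converged": []}
    for s, split in enumerate(plan.splits):
        all_thetas.append(thetas_by_split[s])
        meta["split"].extend([s] * n_reinits)
        meta["perm"].extend([split["permutation"]] * n_reinits)
        meta["fold"].extend([split["fold"]] * n_reinits)
        meta["reinit"].extend(range(n_reinits))
        meta["seed"].extend(seeds_by_split[s].tolist())
        meta["converged"].extend(conv_by_split[s].tolist())
    return EnsembleModel(
        thetas=np.concatenate(all_thetas, axis=0),
        split_id=np.array(meta["split"]),
        permutation=np.array(meta["perm"]),
        fold=np.array(meta["fold"]),
        reinit=np.array(meta["reinit"]),
        member_seed=np.array(meta["seed"]),
        plan=plan,
        n_reinits=n_reinits,
        training_config=cfg,
        converged=np.array(meta["converged"]),
    )


def consolidate(ensemble: EnsembleModel, X, member_mask: Optional[np.ndarray] = None, chunk: int = 2048) -> np.ndarray:
    """Mean predicted likelihood over a member subset; shape (n,)."""
    if member_mask is not None and not np.any(member_mask):
        raise ValueError("cannot consolidate over an empty member subset")
    stack = ensemble.stack(member_mask)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.empty(len(X))
    for lo in range(0, len(X), chunk):
        out[lo : lo + chunk] = mlp_core.forward_stack(stack, X[lo : lo + chunk]).mean(axis=0)
    return out


def predict(ensemble: EnsembleModel, records: Sequence[ErvInsertion], tau: float = 0.5) -> pd.DataFrame:
    """Consolidated likelihood and binary call (likelihood >= tau) per record.

    A record that fails to encode yields a row with NaN likelihood and the
    error message instead of aborting the whole batch.
    """
    rows, vectors, ok_index = [], [], []
    for i, rec in enumerate(records):
        try:
            vectors.append(encode_insertion(rec).as_array())
            ok_index.append(i)
            rows.append({"id": rec.id, "likelihood": np.nan, "call": "", "error": ""})
        except Exception as exc:  # noqa: BLE001 - per-record error entry by contract
            rows.append({"id": getattr(rec, "id", f"row{i}"), "likelihood": np.nan, "call": "", "error": str(exc)})
    if vectors:
        scores = consolidate(ensemble, np.array(vectors))
        for j, i in enumerate(ok_index):
            rows[i]["likelihood"] = scores[j]
            rows[i]["call"] = "positive" if scores[j] >= tau else "negative"
    df = pd.DataFrame(rows, columns=["id", "likelihood", "call", "error"])
    df.attrs["threshold"] = tau
    return df


# ---------------------------------------------------------------------------
# Archive round-trip.
# ---------------------------------------------------------------------------


def ensemble_to_archive(ensemble: EnsembleModel) -> ModelArchive:
    members = []
    for m in range(ensemble.n_members):
        members.append(
            {
                "split": int(ensemble.split_id[m]),
                "permutation": int(ensemble.permutation[m]),
                "fold": int(ensemble.fold[m]),
                "reinit": int(ensemble.reinit[m]),
                "seed": int(ensemble.member_seed[m]),
                "theta": ensemble.thetas[m].tolist(),
            }
        )
    cfg = ensemble.training_config
    plan = ensemble.plan
    return ModelArchive(
        members=members,
        cv_plan_digest=plan.digest() if plan is not None else "",
        training_config={
            "learning_rate": cfg.learning_rate,
            "max_epochs": cfg.max_epochs,
            "stop_threshold": cfg.stop_threshold,
            "init_range": cfg.init_range,
            "n_reinits": ensemble.n_reinits,
            "plan": None
            if plan is None
            else {
                "permutations": plan.permutations,
                "folds": plan.folds,
                "seed": plan.seed,
                "n_pos": plan.n_pos,
                "n_neg": plan.n_neg,
                "splits": [
                    {
                        "permutation": s["permutation"],
                        "fold": s["fold"],
                        "train_idx": s["train_idx"].tolist(),
                        "test_idx": s["test_idx"].tolist(),
                    }
                    for s in plan.splits
                ],
            },
        },
        seeds={"master": cfg.seed},
    )


def ensemble_from_archive(archive: ModelArchive) -> EnsembleModel:
    members = archive.members
    tc = archive.training_config
    cfg = TrainConfig(
        learning_rate=tc.get("learning_rate", 0.05),
        max_epochs=tc.get("max_epochs", 100_000),
        stop_threshold=tc.get("stop_threshold", 0.01),
        init_range=tc.get("init_range", 0.5),
        seed=archive.seeds.get("master", 0),
    )
    plan = None
    plan_dict = tc.get("plan")
    if plan_dict:
        plan = CvPlan(
            permutations=plan_dict["permutations"],
            folds=plan_dict["folds"],
            splits=[
                {
                    "permutation": s["permutation"],
                    "fold": s["fold"],
                    "train_idx": np.array(s["train_idx"]),
                    "test_idx": np.array(s["test_idx"]),
                }
                for s in plan_dict["splits"]
            ],
            seed=plan_dict["seed"],
            n_pos=plan_dict["n_pos"],
            n_neg=plan_dict["n_neg"],
        )
    return EnsembleModel(
        thetas=np.array([m["theta"] for m in members], dtype=float),
        split_id=np.array([m["split"] for m in members]),
        permutation=np.array([m["permutation"] for m in members]),
        fold=np.array([m["fold"] for m in members]),
        reinit=np.array([m["reinit"] for m in members]),
        member_seed=np.array([m["seed"] for m in members]),
        plan=plan,
        n_reinits=tc.get("n_reinits", 100),
        training_config=cfg,
    )
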