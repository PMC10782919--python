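"""Attention-based multiple-instance learning for slide-level PD-L1 status.

A slide is a bag of tile feature vectors h_1..h_N with a single weak label
(TPS >= 1% or not).  The model scores each tile with a small tanh attention
network, e_k = w^T tanh(V h_k), turns the scores into a convex weighting
a = softmax(e), pools z = sum_k a_k h_k, and classifies the pooled embedding
with one logistic layer, p = sigmoid(W_c . z + b).  The attention weights
double as the explainability signal: tiles the model relies on receive more
mass.

Training minimizes binary cross-entropy one bag at a time with Adam and
early-stops on validation AUC.  Evaluation follows the weakly supervised
protocol: stratified 5-fold cross-validation (optionally grouped by patient
so no patient straddles splits), per-fold test AUC, and a deployment
ensemble that averages the five fold models' scores.

Everything is plain numpy with hand-derived gradients — the model is a few
thousand parameters and a bag is one matrix, so this is fast on a CPU and
exactly reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

__all__ = [
    "AttentionMILParams",
    "BagPrediction",
    "FoldSplit",
    "CVResult",
    "TrainConfig",
    "attention_pool",
    "predict_bag",
    "train_fold",
    "stratified_kfold",
    "cross_validate",
    "ensemble_predict",
    "auc",
    "select_explainability_model",
]


@dataclass
class AttentionMILParams:
    """Trained weights of one fold: attention (V, w) and logistic head (W_c, b).

    ``feat_mean``/``feat_std`` hold the per-dimension standardization fitted
    on the fold's training instances; they travel with the weights so that
    prediction and dense heatmap scoring apply the identical transform.
    """

    V: np.ndarray           # L x D
    w: np.ndarray           # L
    W_c: np.ndarray         # D
    b: float
    seed: int = 0
    feat_mean: np.ndarray | None = None
    feat_std: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def transform(self, features: np.ndarray) -> np.ndarray:
        if self.feat_mean is None:
            return features
        return (features - self.feat_mean) / self.feat_std

    @property
    def dim(self) -> int:
        return self.V.shape[1]

    @property
    def hidden(self) -> int:
        return self.V.shape[0]

    @classmethod
    def init(cls, dim: int, hidden: int = 128, seed: int = 0) -> "AttentionMILParams":
        """Random attention weights; zero classification head.

        Zero-initializing W_c makes the first classifier gradients follow the
        between-class difference of the pooled embeddings instead of an
        arbitrary random direction, which keeps training out of the
        bag-memorization basin that a random head can lock in when the bag
        count is small relative to the feature dimension.
        """
        rng = np.random.default_rng(seed)
        return cls(V=rng.normal(0, 1.0 / np.sqrt(dim), size=(hidden, dim)),
                   w=rng.normal(0, 1.0 / np.sqrt(hidden), size=hidden),
                   W_c=np.zeros(dim), b=0.0, seed=seed)


@dataclass
class BagPrediction:
    slide_id: str
    score: float                # P(PD-L1 high) in [0, 1]
    attention: np.ndarray       # N, nonnegative, sums to 1
    embedding: np.ndarray       # D, attention-weighted bag embedding


@dataclass
class FoldSplit:
    fold: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class CVResult:
    fold_aucs: list             # per-fold test AUC
    mean_auc: float
    sd_auc: float
    params: list                # per-fold AttentionMILParams
    oof_scores: np.ndarray      # out-of-fold score per bag
    train_aucs: list            # per-fold training AUC (for model selection)
    splits: list


@dataclass(frozen=True)
class TrainConfig:
    """MIL training hyperparameters (fixed defaults; one bag per step)."""

    hidden: int = 128
    lr: float = 1e-4
    max_epochs: int = 100
    patience: int = 10          # early stopping on validation AUC
    weight_decay: float = 0.0
    val_fraction: float = 0.2   # of the non-test portion, stratified


def _sigmoid(u: float) -> float:
    return 1.0 / (1.0 + np.exp(-u)) if u >= 0 else np.exp(u) / (1.0 + np.exp(u))


def _softmax(e: np.ndarray) -> np.ndarray:
    z = np.exp(e - e.max())
    return z / z.sum()


def attention_pool(features: np.ndarray, params: AttentionMILParams):
    """Tanh attention pooling: returns (embedding z, attention a).

    a = softmax(w^T tanh(V h_k)) over the bag; z = sum_k a_k h_k.  Permuting
    the bag permutes a identically and leaves z unchanged.
    """
    features = np.atleast_2d(features)
    if features.shape[0] == 0:
        raise ValueError("empty bag")
    if features.shape[1] != params.dim:
        raise ValueError(
            f"feature dim {features.shape[1]} does not match model dim {params.dim}")
    features = params.transform(features)
    t = np.tanh(features @ params.V.T)        # N x L
    e = t @ params.w                          # N
    a = _softmax(e)
    z = a @ features
    return z, a


def attention_logits(features: np.ndarray, params: AttentionMILParams) -> np.ndarray:
    """Raw (pre-softmax) attention scores e_k = w^T tanh(V h_k)."""
    features = params.transform(np.atleast_2d(features))
    return np.tanh(features @ params.V.T) @ params.w


def predict_bag(bag, params: AttentionMILParams) -> BagPrediction:
    """Score one bag: sigmoid classification of the attention-pooled embedding."""
    features = bag.features if hasattr(bag, "features") else np.asarray(bag)
    slide_id = getattr(bag, "slide_id", "")
    z, a = attention_pool(features, params)
    score = _sigmoid(float(params.W_c @ z + params.b))
    return BagPrediction(slide_id=slide_id, score=score, attention=a, embedding=z)


def _bag_grad(features, y, params):
    """Forward + hand-derived backward pass for BCE loss on a single bag."""
    t = np.tanh(features @ params.V.T)
    e = t @ params.w
    a = _softmax(e)
    z = a @ features
    p = _sigmoid(float(params.W_c @ z + params.b))
    du = p - y                                # dL/d(logit)
    gW_c = du * z
    gb = du
    dz = du * params.W_c                      # D
    g = features @ dz                         # N  (dL/da)
    de = a * (g - a @ g)                      # softmax backward
    gw = t.T @ de                             # L
    dt = np.outer(de, params.w) * (1.0 - t * t)   # N x L
    gV = dt.T @ features                      # L x D
    eps = 1e-12
    loss = -(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
    return loss, (gV, gw, gW_c, gb)


class _Adam:
    def __init__(self, shapes, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, grads):
        self.t += 1
        out = []
        for i, g in enumerate(grads):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            out.append(self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


def auc(scores, labels) -> float:
    """ROC AUC as pairwise concordance: P(s+ > s-) + 0.5 P(tie).

    Computed with the midrank (Mann–Whitney) formula, which equals the
    brute-force average over all positive–negative pairs exactly, ties
    counted half.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _scores_for(bags, idx, params):
    return np.array([predict_bag(bags[i], params).score for i in idx])


def train_fold(bags, labels, split: FoldSplit,
               hyper: TrainConfig = TrainConfig(), seed: int = 0) -> AttentionMILParams:
    """Train one fold's model on its train split, early-stopping on val AUC.

    Deterministic given ``seed`` (weight init and the per-epoch bag order are
    drawn from it).  Raises on a single-class training split.
    """
    labels = np.asarray(labels, dtype=int)
    tr = np.asarray(split.train_idx)
    va = np.asarray(split.val_idx)
    y_tr = labels[tr]
    if len(np.unique(y_tr)) < 2:
        raise ValueError("degenerate split: training labels are single-class")
    dim = np.atleast_2d(_features_of(bags[tr[0]])).shape[1]
    params = AttentionMILParams.init(dim, hidden=hyper.hidden, seed=seed)
    # per-dimension standardization fitted on the training instances
    train_feats = [np.atleast_2d(_features_of(bags[i])).astype(float) for i in tr]
    stacked = np.concatenate(train_feats, axis=0)
    params.feat_mean = stacked.mean(axis=0)
    params.feat_std = np.maximum(stacked.std(axis=0), 1e-8)
    train_feats = [params.transform(f) for f in train_feats]
    opt = _Adam([params.V.shape, params.w.shape, params.W_c.shape, ()], hyper.lr)
    rng = np.random.default_rng(seed + 1)

    best = ((-np.inf, -np.inf), None)
    since_best = 0
    for epoch in range(hyper.max_epochs):
        order = rng.permutation(tr.size)
        for i in order:
            feats = train_feats[i]
            _, (gV, gw, gWc, gb) = _bag_grad(feats, float(y_tr[i]), params)
            if hyper.weight_decay:
                gV = gV + hyper.weight_decay * params.V
                gw = gw + hyper.weight_decay * params.w
                gWc = gWc + hyper.weight_decay * params.W_c
            dV, dw, dWc, db = opt.step([gV, gw, gWc, gb])
            params.V -= dV
            params.w -= dw
            params.W_c -= dWc
            params.b -= db
        if va.size and len(np.unique(labels[va])) == 2:
            mon_idx, mon_y = va, labels[va]
        else:  # no usable validation split: fall back to the training bags
            mon_idx, mon_y = tr, y_tr
        mon_scores = _scores_for(bags, mon_idx, params)
        val_auc = auc(mon_scores, mon_y)
        eps = 1e-12
        val_loss = -np.mean(mon_y * np.log(mon_scores + eps) +
                            (1 - mon_y) * np.log(1 - mon_scores + eps))
        # AUC is the primary criterion; while it is saturated/tied, a still-
        # falling validation loss counts as improvement so the checkpoint
        # (and the attention weights with it) keeps maturing.
        key = (round(val_auc, 9), -val_loss)
        if best[1] is None or key > best[0]:
            best = (key, _copy_params(params))
            since_best = 0
        else:
            since_best += 1
            if since_best >= hyper.patience:
                break
    final = best[1]
    final.meta = dict(val_auc=best[0][0], epochs_run=epoch + 1, fold=split.fold)
    final.seed = seed
    return final


def _features_of(bag):
    return bag.features if hasattr(bag, "features") else np.asarray(bag)


def _copy_params(p: AttentionMILParams) -> AttentionMILParams:
    return AttentionMILParams(
        V=p.V.copy(), w=p.w.copy(), W_c=p.W_c.copy(), b=float(p.b),
        seed=p.seed, meta=dict(p.meta),
        feat_mean=None if p.feat_mean is None else p.feat_mean.copy(),
        feat_std=None if p.feat_std is None else p.feat_std.copy())


def stratified_kfold(labels, k: int = 5, seed: int = 0,
                     val_fraction: float = 0.2, groups=None) -> list:
    """Stratified k-fold splits with a stratified validation carve-out.

    Test folds partition the cohort with class proportions preserved; within
    each fold, ``val_fraction`` of the non-test bags is held out (stratified)
    for early stopping.  If ``groups`` is given (e.g. patient ids), bags of
    one group never straddle the test boundary.
    """
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2 for held-out folds")
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("labels must contain both classes")
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} members; needs >= k={k}")

    idx = np.arange(labels.size)
    if groups is not None:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = splitter.split(idx, labels, groups=np.asarray(groups))
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = splitter.split(idx, labels)

    rng = np.random.default_rng(seed)
    splits = []
    for f, (rest, test) in enumerate(folds):
        val_parts = []
        for c in classes:
            members = rest[labels[rest] == c]
            n_val = max(1, int(round(val_fraction * members.size)))
            val_parts.append(rng.choice(members, size=n_val, replace=False))
        val = np.sort(np.concatenate(val_parts))
        train = np.sort(np.setdiff1d(rest, val))
        splits.append(FoldSplit(fold=f, train_idx=train, val_idx=val,
                                test_idx=np.sort(test)))
    return splits


def cross_validate(bags, labels, k: int = 5,
                   hyper: TrainConfig = TrainConfig(), seed: int = 0,
                   groups=None) -> CVResult:
    """Stratified k-fold CV: per-fold test AUC, mean ± sd, all fold models."""
    labels = np.asarray(labels, dtype=int)
    splits = stratified_kfold(labels, k=k, seed=seed, groups=groups,
                              val_fraction=hyper.val_fraction)
    fold_aucs, train_aucs, all_params = [], [], []
    oof = np.full(labels.size, np.nan)
    for split in splits:
        params = train_fold(bags, labels, split, hyper, seed=seed + 100 + split.fold)
        test_scores = _scores_for(bags, split.test_idx, params)
        oof[split.test_idx] = test_scores
        fold_aucs.append(auc(test_scores, labels[split.test_idx]))
        train_aucs.append(auc(_scores_for(bags, split.train_idx, params),
                              labels[split.train_idx]))
        all_params.append(params)
    return CVResult(fold_aucs=fold_aucs,
                    mean_auc=float(np.mean(fold_aucs)),
                    sd_auc=float(np.std(fold_aucs)),
                    params=all_params, oof_scores=oof,
                    train_aucs=train_aucs, splits=splits)


def ensemble_predict(bags, params_list) -> np.ndarray:
    """Deployment scoring: the arithmetic mean of the fold models' scores."""
    if not params_list:
        raise ValueError("params_list must be non-empty")
    scores = np.stack([
        np.array([predict_bag(b, p).score for b in bags]) for p in params_list])
    return scores.mean(axis=0)


def select_explainability_model(cv: CVResult) -> AttentionMILParams:
    """The fold model with the best training AUC (ties -> lowest fold index)."""
    if not cv.params:
        raise ValueError("empty CV result")
    best = int(np.argmax(cv.train_aucs))   # argmax returns the first maximum
    return cv.params[best]
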