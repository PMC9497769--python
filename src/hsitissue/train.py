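"""Training protocol: weighted cross-entropy SGD under grouped 5-fold CV.

The published protocol trains the CNN with plain batch gradient descent
(no momentum) for 250 epochs at batch size 8192, learning rate 0.01 and
weight decay 0.0005, with per-sample losses weighted by inverse median
frequency class balancing.  Cross-validation is grouped by animal: images
are partitioned into 5 folds of equal size and no animal ever contributes
to both the training and the test side of a fold.

A desk-scale profile (25 epochs, batch 1024) is the default here so that a
full cross-validation run on the synthetic cohort completes in minutes on
one CPU; the full-scale profile is a config away.  Inside each SGD step
the gradient is accumulated over fixed-size micro-batches, which keeps the
working set cache-resident; the result is the exact minibatch gradient and
is bit-reproducible for a fixed configuration and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import AnnotationMask, Hypercube
from .model import Model, PredictionMap, build_model, predict_map, softmax
from .patches import (
    ClassWeights,
    PatchSet,
    compute_class_weights,
    concat_patchsets,
    extract_patches,
)

logger = logging.getLogger(__name__)

CLASSES = (1, 2)


@dataclass
class TrainConfig:
    """Hyperparameters of the training protocol.

    Full protocol values are ``epochs=250, batch_size=8192``; the defaults
    here are the desk-scale profile used for the synthetic cohort.
    """

    epochs: int = 25
    batch_size: int = 1024
    learning_rate: float = 0.01
    weight_decay: float = 0.0005
    momentum: float = 0.0        # optional; the protocol default is plain SGD
    micro_batch: int = 64        # gradient-accumulation chunk; fixed per run
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.micro_batch) < 1:
            raise ValueError("epochs, batch_size and micro_batch must be positive")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("learning_rate must be positive, weight_decay >= 0")


def full_scale_config(seed: int = 0) -> TrainConfig:
    """The full training profile (250 epochs, batch 8192)."""
    return TrainConfig(epochs=250, batch_size=8192, seed=seed)


@dataclass
class FoldPlan:
    """Animal-level fold assignment for grouped cross-validation."""

    k: int
    fold_assignment: dict[str, int]

    def fold_animals(self, fold: int) -> list[str]:
        return sorted(a for a, f in self.fold_assignment.items() if f == fold)

    def __post_init__(self) -> None:
        folds = set(self.fold_assignment.values())
        if folds != set(range(self.k)):
            raise ValueError(f"fold indices {sorted(folds)} do not cover 0..{self.k - 1}")


def make_folds(animal_ids: list[str], k: int = 5, seed: int = 0) -> FoldPlan:
    """Seeded random partition of animals into k near-equal folds.

    With 20 animals and k = 5 every fold receives exactly 4 animals.
    """
    ids = list(animal_ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({a for a in ids if ids.count(a) > 1})
        raise ValueError(f"duplicate animal ids: {dupes}")
    if len(ids) < k:
        raise ValueError(f"need at least {k} animals for {k}-fold CV, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment = {ids[int(idx)]: i % k for i, idx in enumerate(order)}
    return FoldPlan(k, assignment)


def weighted_cross_entropy(logits: np.ndarray, label_idx: np.ndarray,
                           sample_weights: np.ndarray) -> tuple[float, np.ndarray]:
    """Per-sample-weighted 2-class cross-entropy on softmax outputs.

    Returns the summed weighted loss and d(loss)/d(logits) for the sum
    (callers normalize by the minibatch size).
    """
    p = softmax(logits)
    n = len(label_idx)
    eps = 1e-12
    loss = float(np.sum(sample_weights * -np.log(p[np.arange(n), label_idx] + eps)))
    g = p
    g[np.arange(n), label_idx] -= 1.0
    g *= sample_weights[:, None]
    return loss, g.astype(np.float32)


class _SGD:
    """Plain (optionally momentum) SGD with classic coupled L2 weight decay."""

    def __init__(self, model: Model, cfg: TrainConfig):
        self.model = model
        self.cfg = cfg
        self.accum = [np.zeros_like(p) for p, _ in model.parameters()]
        self.velocity = ([np.zeros_like(p) for p, _ in model.parameters()]
                         if cfg.momentum else None)

    def zero(self) -> None:
        for a in self.accum:
            a[...] = 0.0

    def accumulate(self) -> None:
        for a, (_, g) in zip(self.accum, self.model.parameters()):
            a += g

    def step(self) -> None:
        lr, wd = self.cfg.learning_rate, self.cfg.weight_decay
        for i, (a, (p, _)) in enumerate(zip(self.accum, self.model.parameters())):
            update = a + wd * p
            if self.velocity is not None:
                v = self.velocity[i]
                v *= self.cfg.momentum
                v += update
                update = v
            p -= (lr * update).astype(np.float32)


def train(model: Model, train_patches: PatchSet, cfg: TrainConfig,
          weights: ClassWeights | None = None) -> list[float]:
    """Train in place; returns the per-epoch mean weighted loss history.

    Minibatches are drawn by seeded shuffling each epoch; the last
    incomplete minibatch is kept.  Per-sample losses are multiplied by
    their class weight (inverse median frequency by default) and L2 weight
    decay is coupled into every update.  Fully reproducible given the
    config and seed.
    """
    n = len(train_patches)
    if n == 0:
        raise ValueError("training set is empty")
    counts = train_patches.label_counts()
    if set(counts) != set(CLASSES):
        raise ValueError(
            f"training set must contain both classes, found labels {sorted(counts)}")
    if weights is None:
        weights = compute_class_weights(counts)
    w_arr = weights.as_array(CLASSES)
    label_idx = (train_patches.labels - 1).astype(np.int64)
    sample_w = w_arr[label_idx].astype(np.float64)

    rng = np.random.default_rng(cfg.seed)
    opt = _SGD(model, cfg)
    history: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            batch_idx = order[start:start + cfg.batch_size]
            m = len(batch_idx)
            opt.zero()
            for mb in range(0, m, cfg.micro_batch):
                sel = batch_idx[mb:mb + cfg.micro_batch]
                logits = model.forward_logits(train_patches.patches[sel], train=True)
                loss, g = weighted_cross_entropy(logits, label_idx[sel], sample_w[sel])
                model.backward(g / m)
                opt.accumulate()
                epoch_loss += loss
            opt.step()
        history.append(epoch_loss / n)
    return history


@dataclass
class FoldResult:
    """Artifacts of one cross-validation fold."""

    fold: int
    test_animals: list[str]
    train_animals: list[str]
    model: Model
    loss_history: list[float]
    class_weights: dict[int, float]
    predictions: list[PredictionMap] = field(default_factory=list)


@dataclass
class CVResult:
    """Cross-validation output: per-fold models and per-image predictions."""

    fold_plan: FoldPlan
    folds: list[FoldResult]
    leakage_audit: dict[int, list[str]]

    @property
    def predictions(self) -> list[PredictionMap]:
        maps = [pm for fr in self.folds for pm in fr.predictions]
        return sorted(maps, key=lambda pm: pm.animal_id)


def cross_validate(cohort: list[tuple[Hypercube, AnnotationMask]],
                   cfg: TrainConfig, k: int = 5, seed: int = 0,
                   window: int = 5) -> CVResult:
    """Grouped k-fold cross-validation over a cohort of annotated images.

    For each fold, the model trains on patches from animals outside the
    fold (class weights computed on that training split only) and predicts
    every annotated in-bounds pixel of the fold's images.  The leakage
    audit records, per fold, the intersection of training and test animal
    sets — asserted empty on every run.
    """
    if len(cohort) < k:
        raise ValueError(f"cohort of {len(cohort)} images cannot support {k} folds")
    animal_ids = [cube.animal_id for cube, _ in cohort]
    plan = make_folds(animal_ids, k, seed=seed)

    by_animal = {cube.animal_id: (cube, mask) for cube, mask in cohort}
    patch_cache = {aid: extract_patches(cube, mask, window)
                   for aid, (cube, mask) in by_animal.items()}

    seed_root = np.random.SeedSequence(seed)
    folds: list[FoldResult] = []
    audit: dict[int, list[str]] = {}
    for fold in range(k):
        test_animals = plan.fold_animals(fold)
        train_animals = sorted(a for a in animal_ids if a not in test_animals)
        leak = sorted(set(test_animals) & set(train_animals))
        audit[fold] = leak
        assert not leak, f"fold {fold}: train/test animal overlap {leak}"

        train_ps = concat_patchsets([patch_cache[a] for a in train_animals])
        weights = compute_class_weights(train_ps.label_counts())

        model_seed, train_seed = [
            int(s.generate_state(1)[0] % (2 ** 31))
            for s in np.random.SeedSequence((seed, fold)).spawn(2)]
        model = build_model(seed=model_seed)
        fold_cfg = TrainConfig(**{**cfg.__dict__, "seed": train_seed})
        history = train(model, train_ps, fold_cfg, weights)

        predictions = [predict_map(model, by_animal[a][0], support=by_animal[a][1])
                       for a in test_animals]
        folds.append(FoldResult(fold, test_animals, train_animals, model,
                                history, dict(weights.weights), predictions))
        logger.info("fold %d: trained on %d patches from %d animals, "
                    "tested on %s", fold, len(train_ps), len(train_animals),
                    test_animals)
    return CVResult(plan, folds, audit)
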