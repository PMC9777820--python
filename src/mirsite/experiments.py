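"""Reproducible end-to-end workflows on synthetic data.

These functions wire the generator, the imbalance pipeline, the scorers
and the metrics into the experiments the package is built around:
training at a given positive:negative ratio, hardness-selected +
smoothed training, and ratio-stratified evaluation of a fixed scorer.
They are used by the test suite and by ``scripts/acceptance.py``; sizes
are arguments so callers choose their own scale.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import imbalance, models
from .baselines import seed_match
from .datasets import LabeledPair, RatioDataset, assemble_ratio
from .metrics import auprc, auroc
from .synthetic import SynthSpec, gen_dataset


def _sub_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.default_rng(seed).integers(0, 2**31 - 1, n)]


def train_plain(
    spec: SynthSpec,
    k: int,
    seed: int,
    config: models.CNNConfig | None = None,
    epochs: int | None = None,
    val_set: RatioDataset | None = None,
) -> models.TrainedScorer:
    """Train a CNN on a plain ratio-1:k synthetic dataset.

    Minibatches are class-balanced (positives resampled) so the positive
    gradient signal does not shrink with k; the dataset ratio is 1:k.
    """
    ds = gen_dataset(replace(spec, rng_seed=seed), k=k)
    scorer = models.build_cnn(config or models.CNNConfig.desk(), seed=seed)
    return models.train(
        scorer, ds, val_set, seed=seed, epochs=epochs, balance_batches=True
    )


def train_hardness_smoothed(
    spec: SynthSpec,
    pool_k: int,
    target_k: int,
    seed: int,
    config: models.CNNConfig | None = None,
    committee_members: int = 3,
    committee_epochs: int = 2,
    epochs: int | None = None,
    val_set: RatioDataset | None = None,
) -> models.TrainedScorer:
    """Hardness-selected, label-smoothed training.

    Draws a deep 1:``pool_k`` negative pool, scores it with a committee
    of CNNs trained on disjoint-seed 1:1 sets, keeps the hardest
    negatives down to 1:``target_k``, smooths their labels (linear
    IH/2), and trains on the result.
    """
    s_data, s_comm, s_train = _sub_seeds(seed, 3)
    cfg = config or models.CNNConfig.desk()
    ds = gen_dataset(replace(spec, rng_seed=s_data), k=pool_k)
    committee, seen = imbalance.train_committee(
        ds.positives,
        n_members=committee_members,
        seed=s_comm,
        config=cfg,
        epochs=committee_epochs,
    )
    ih = imbalance.estimate_instance_hardness(ds.pairs, committee, seen=seen)
    smoothed_all = imbalance.smooth_labels(ds.pairs, ih)
    smoothed = imbalance.select_hard_negatives(smoothed_all, ih, target_ratio=target_k)
    scorer = models.build_cnn(cfg, seed=s_train)
    return models.train(
        scorer, smoothed, val_set, seed=s_train, epochs=epochs, balance_batches=True
    )


def evaluate_at_ratios(
    scorer,
    positives: list[LabeledPair],
    negatives: list[LabeledPair],
    ks: tuple[int, ...] = (1, 10, 100),
    seed: int = 0,
) -> dict[int, dict[str, float]]:
    """auPRC/auROC of one fixed scorer at nested negative subsamples.

    The 1:k evaluation set uses the positives plus the first
    k*|positives| negatives of a single shuffled pool, so smaller ratios
    are nested inside larger ones.
    """
    out = {}
    for k in ks:
        ds = assemble_ratio(positives, negatives, k, "test", rng_seed=seed)
        labels = np.array([1 if p.is_positive else 0 for p in ds.pairs])
        scores = scorer.predict(ds.pairs)
        out[k] = {
            "auprc": float(auprc(scores, labels)),
            "auroc": float(auroc(scores, labels)),
            "n": len(ds.pairs),
        }
    return out


def per_mechanism_recall(
    scorer, positives: list[LabeledPair], threshold: float = 0.1
) -> dict[str, float]:
    """Recall of a scorer on each planted mechanism subset of positives."""
    out = {}
    for mech in sorted({p.mechanism for p in positives if p.mechanism}):
        subset = [p for p in positives if p.mechanism == mech]
        scores = scorer.predict(subset)
        out[mech] = float(np.mean(scores >= threshold))
    return out


def seed_sensitivity(positives: list[LabeledPair]) -> float:
    """Fraction of positives the seed heuristic recovers (its recall)."""
    hits = sum(1 for p in positives if seed_match(p.mirna, p.target).match)
    return hits / len(positives)
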