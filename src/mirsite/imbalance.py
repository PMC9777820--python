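"""Instance-hardness estimation and label smoothing for skewed classes.

Under a realistic 1:100 positive:negative skew, most negatives are
trivially classifiable and teach a model little, while a small subset —
those a classifier mistakes for positives — carry the discriminative
signal.  Instance hardness (IH) quantifies this as the estimated
probability that a committee of scorers misclassifies a sample.  Two
composable steps exploit it:

* *hard-negative selection* keeps the highest-IH negatives (plus every
  positive) until a requested ratio or fraction is met, rebalancing the
  skew without discarding informative samples;
* *label smoothing* maps each selected negative's IH from [0, 1] into a
  soft label in [0, 0.5] (linear IH/2 by default), so the model is
  trained to be *unsure* about the hardest negatives rather than taught
  a flipped label.

Positives always keep their hard label 1: labels never cross 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .datasets import LabeledPair, assemble_ratio, make_negatives


@dataclass
class InstanceHardnessTable:
    """Per-sample misclassification-probability estimates.

    ``table`` columns: index (input order), pair_key, label, IH;
    ``committee_size`` is the number of scorers behind the estimates.
    """

    table: pd.DataFrame
    committee_size: int

    def __post_init__(self) -> None:
        ih = self.table["IH"].to_numpy()
        if ih.size and (ih.min() < 0 or ih.max() > 1):
            raise ValueError("IH values must lie in [0, 1]")
        if self.committee_size < 1:
            raise ValueError("committee_size must be >= 1")

    @property
    def ih(self) -> np.ndarray:
        return self.table["IH"].to_numpy()

    def to_tsv(self, path: str) -> None:
        out = self.table.copy()
        out["committee_size"] = self.committee_size
        out.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SmoothingPolicy:
    """A monotone map [0,1] -> [0,0.5] applied to negative labels.

    The default is linear, ``IH / 2``.  Any map must send 0 to 0 and 1
    to 0.5 and never exceed 0.5, so a smoothed negative can become
    maximally uncertain but never flips into a positive.
    """

    map: Callable[[float], float] = field(default=lambda ih: ih / 2.0)
    applies_to: str = "negatives"

    def __post_init__(self) -> None:
        if self.applies_to != "negatives":
            raise ValueError(
                "smoothing applies to negatives only; positives keep hard labels"
            )
        grid = np.linspace(0.0, 1.0, 101)
        vals = np.array([self.map(float(g)) for g in grid])
        if abs(vals[0]) > 1e-12 or abs(vals[-1] - 0.5) > 1e-12:
            raise ValueError("smoothing map must send 0 -> 0 and 1 -> 0.5")
        if (np.diff(vals) < -1e-12).any():
            raise ValueError("smoothing map must be non-decreasing")
        if vals.max() > 0.5 + 1e-12:
            raise ValueError("smoothing map must never exceed 0.5")


def _pair_key(p: LabeledPair) -> str:
    return f"{p.mirna.seq}:{p.target.seq}"


def estimate_instance_hardness(
    samples: Sequence[LabeledPair],
    committee: Sequence,
    seen: Sequence[set] | None = None,
) -> InstanceHardnessTable:
    """Estimate IH for every sample from a committee of scorers.

    For a negative sample IH is the committee-mean predicted
    positive-class probability (how strongly it is mistaken for a
    positive); for a positive sample it is the mean of 1 - probability.
    ``seen`` optionally gives, per committee member, the set of pair
    keys that member was trained on; members that saw a sample are
    excluded from its estimate (out-of-fold IH).  If every member saw a
    sample, all members are used and a warning is emitted.
    """
    if len(committee) == 0:
        raise ValueError("committee must be nonempty")
    samples = list(samples)
    preds = []
    for member in committee:
        s = np.asarray(member.predict(samples), dtype=np.float64)
        if s.size and (s.min() < 0 or s.max() > 1):
            raise ValueError("committee scorer produced scores outside [0, 1]")
        preds.append(s)
    P = np.stack(preds)  # (members, samples)

    labels = np.array([1.0 if p.is_positive else 0.0 for p in samples])
    miss = np.where(labels[None, :] == 1.0, 1.0 - P, P)

    if seen is not None:
        if len(seen) != len(committee):
            raise ValueError("seen must align with the committee")
        keys = [_pair_key(p) for p in samples]
        mask = np.array(
            [[keys[j] not in seen[m] for j in range(len(samples))] for m in range(len(committee))]
        )
        n_unseen = mask.sum(axis=0)
        fully_seen = n_unseen == 0
        if fully_seen.any():
            warnings.warn(
                f"{int(fully_seen.sum())} sample(s) seen by every committee "
                "member; their IH is estimated in-fold"
            )
            mask[:, fully_seen] = True
            n_unseen = mask.sum(axis=0)
        ih = (miss * mask).sum(axis=0) / n_unseen
    else:
        ih = miss.mean(axis=0)

    table = pd.DataFrame(
        {
            "index": np.arange(len(samples)),
            "pair_key": [_pair_key(p) for p in samples],
            "label": labels,
            "IH": ih,
        }
    )
    return InstanceHardnessTable(table=table, committee_size=len(committee))


def smooth_labels(
    samples: Sequence[LabeledPair],
    ih_table: InstanceHardnessTable,
    policy: SmoothingPolicy = SmoothingPolicy(),
) -> list[LabeledPair]:
    """Replace each negative's hard 0 label with policy.map(IH).

    Positives are returned unchanged; no resulting label exceeds 0.5.
    """
    samples = list(samples)
    if len(samples) != len(ih_table.table):
        raise ValueError("IH table does not cover the samples")
    ih = ih_table.ih
    out = []
    for i, p in enumerate(samples):
        if p.is_positive:
            out.append(p)
        else:
            new_label = float(np.clip(policy.map(float(ih[i])), 0.0, 0.5))
            out.append(
                LabeledPair(p.mirna, p.target, new_label, p.origin, p.mechanism)
            )
    return out


def select_hard_negatives(
    samples: Sequence[LabeledPair],
    ih_table: InstanceHardnessTable,
    keep_fraction: float | None = None,
    target_ratio: int | None = None,
) -> list[LabeledPair]:
    """Keep all positives plus the hardest negatives.

    Exactly one of ``keep_fraction`` (fraction of negatives retained) or
    ``target_ratio`` (negatives per positive, 1:k) must be given.
    Negatives are ranked by IH descending with deterministic ties broken
    by pair key ascending, then input index ascending; input order is
    preserved in the output.
    """
    if (keep_fraction is None) == (target_ratio is None):
        raise ValueError("give exactly one of keep_fraction or target_ratio")
    samples = list(samples)
    if len(samples) != len(ih_table.table):
        raise ValueError("IH table does not cover the samples")
    ih = ih_table.ih
    neg_idx = [i for i, p in enumerate(samples) if not p.is_positive]
    n_pos = len(samples) - len(neg_idx)
    if keep_fraction is not None:
        if not (0.0 <= keep_fraction <= 1.0):
            raise ValueError("keep_fraction must lie in [0, 1]")
        n_keep = int(round(keep_fraction * len(neg_idx)))
    else:
        n_keep = target_ratio * n_pos
        if n_keep > len(neg_idx):
            raise ValueError(
                f"ratio 1:{target_ratio} needs {n_keep} negatives; only "
                f"{len(neg_idx)} available"
            )
    ranked = sorted(
        neg_idx, key=lambda i: (-ih[i], _pair_key(samples[i]), i)
    )
    kept = set(ranked[:n_keep])
    return [p for i, p in enumerate(samples) if p.is_positive or i in kept]


def train_committee(
    positives: Sequence[LabeledPair],
    n_members: int = 5,
    seed: int = 0,
    config=None,
    epochs: int | None = None,
) -> tuple[list, list[set]]:
    """Train a committee of CNN scorers on disjoint-seed 1:1 datasets.

    Each member gets its own shuffled-negative draw and its own
    initialization seed.  Returns the trained members together with the
    per-member sets of training pair keys, for out-of-fold IH
    estimation via :func:`estimate_instance_hardness`.
    """
    from . import models  # deferred: keeps import graph acyclic

    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    cfg = config or models.CNNConfig.desk()
    member_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_members)
    committee, seen = [], []
    for ms in member_seeds:
        ms = int(ms)
        negs = make_negatives(list(positives), k=1, rng_seed=ms)
        ds = assemble_ratio(list(positives), negs, 1, "train", rng_seed=ms)
        scorer = models.train(
            models.build_cnn(cfg, seed=ms), ds, None, seed=ms, epochs=epochs
        )
        committee.append(scorer)
        seen.append({_pair_key(p) for p in ds.pairs})
    return committee, seen
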