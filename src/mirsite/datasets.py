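"""Labeled pair tables, shuffled negatives, ratio-controlled datasets, splits.

Positives are experimentally observed miRNA:target-site pairs; negatives
are produced by re-pairing the *same* target sequences with random miRNAs
from the same experiment's miRNA pool, excluding any pair present in the
positive set.  Re-using the real targets keeps the nucleotide composition
of the two classes identical, so a classifier cannot separate them on
sequence-content artefacts.

A :class:`RatioDataset` fixes the positive:negative ratio 1:k exactly
(k in {1, 10, 20, 100} in typical use) and records the RNG seed so any
dataset can be rebuilt byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .encoding import (
    MiRNASeq,
    SequenceError,
    TargetSeq,
    standardize_mirna,
    standardize_target,
)

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ["mirna_id", "mirna_seq", "target_id", "target_seq", "label", "origin"]


@dataclass(frozen=True)
class LabeledPair:
    """One miRNA:target pair with a hard or smoothed label.

    ``label`` is 1 for positives and lies in [0, 0.5] for (possibly
    smoothed) negatives — smoothing may make a negative uncertain but
    never flips it.  ``mechanism`` records the planted binding mechanism
    for synthetic positives (provenance only).
    """

    mirna: MiRNASeq
    target: TargetSeq
    label: float
    origin: str = "experimental"
    mechanism: str | None = None

    def __post_init__(self) -> None:
        if not (self.label == 1.0 or 0.0 <= self.label <= 0.5):
            raise ValueError(
                f"label must be 1 or in [0, 0.5], got {self.label!r}"
            )

    @property
    def is_positive(self) -> bool:
        return self.label == 1.0

    @property
    def key(self) -> tuple[str, str]:
        """Identity of the pair by exact (miRNA, target) sequence."""
        return (self.mirna.seq, self.target.seq)


@dataclass
class RatioDataset:
    """A shuffled collection of pairs at an exact 1:k positive:negative ratio."""

    pairs: list[LabeledPair]
    ratio_k: int
    rng_seed: int
    split_tag: str = "train"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_pos = sum(1 for p in self.pairs if p.is_positive)
        n_neg = len(self.pairs) - n_pos
        if n_pos and n_neg != self.ratio_k * n_pos:
            raise ValueError(
                f"declared ratio 1:{self.ratio_k} but counts are "
                f"{n_pos} positives / {n_neg} negatives"
            )

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def positives(self) -> list[LabeledPair]:
        return [p for p in self.pairs if p.is_positive]

    @property
    def negatives(self) -> list[LabeledPair]:
        return [p for p in self.pairs if not p.is_positive]

    @property
    def prevalence(self) -> float:
        return 1.0 / (1.0 + self.ratio_k)


def load_pairs(path: str) -> list[LabeledPair]:
    """Load a TSV pair table into standardized :class:`LabeledPair` records.

    Expected columns: mirna_id, mirna_seq, target_id, target_seq, and
    optionally label (default 1) and origin (default "experimental").
    Every miRNA is standardized to 20 nt; targets must already be 50 nt.
    Malformed rows are rejected together, with their line numbers.
    Duplicated (miRNA, target) pairs are retained but logged.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"mirna_id", "mirna_seq", "target_id", "target_seq"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    pairs: list[LabeledPair] = []
    bad: list[str] = []
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # 1-based, after the header line
        try:
            mirna = standardize_mirna(row["mirna_seq"], id=row["mirna_id"])
            target = standardize_target(row["target_seq"], id=row["target_id"])
            label = float(row["label"]) if "label" in df.columns and row["label"] != "" else 1.0
            origin = row["origin"] if "origin" in df.columns and row["origin"] != "" else "experimental"
            pairs.append(LabeledPair(mirna, target, label, origin))
        except (SequenceError, ValueError) as exc:
            bad.append(f"line {line_no}: {exc}")
    if bad:
        raise ValueError(f"{path}: {len(bad)} malformed row(s):\n" + "\n".join(bad))

    n_dup = len(pairs) - len({p.key for p in pairs})
    if n_dup:
        logger.warning("%s: %d duplicated (miRNA, target) pair(s) retained", path, n_dup)
    return pairs


def save_pairs(pairs: Sequence[LabeledPair], path: str) -> None:
    """Write pairs as a TSV with a fixed column order and float format."""
    rows = [
        {
            "mirna_id": p.mirna.id,
            "mirna_seq": p.mirna.seq,
            "target_id": p.target.id,
            "target_seq": p.target.seq,
            "label": f"{p.label:.6g}",
            "origin": p.origin,
        }
        for p in pairs
    ]
    pd.DataFrame(rows, columns=PAIR_COLUMNS).to_csv(path, sep="\t", index=False)


def make_negatives(
    positives: Sequence[LabeledPair],
    k: int,
    rng_seed: int,
    reject: Callable[[MiRNASeq, TargetSeq], bool] | None = None,
) -> list[LabeledPair]:
    """Generate k shuffled negatives per positive target.

    Each positive target contributes exactly k negatives, formed by pairing
    it with miRNAs drawn uniformly from the experiment's miRNA pool.  No
    emitted (miRNA, target) sequence pair occurs in the positive set.  Per
    target, miRNAs are drawn without replacement until the admissible pool
    is exhausted, then with replacement.  ``reject`` optionally vetoes
    candidate pairings (used e.g. to keep accidental seed matches out of
    synthetic negatives); a target whose admissible pool is empty is an
    error reporting the attainable maximum.
    """
    if not positives:
        raise ValueError("positives must be nonempty")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")

    pool: dict[str, MiRNASeq] = {}
    for p in positives:
        pool.setdefault(p.mirna.seq, p.mirna)
    if len(pool) < 2:
        raise ValueError(
            "miRNA pool has a single distinct sequence; no non-positive "
            "pairing exists"
        )
    pool_seqs = sorted(pool)
    positive_keys = {p.key for p in positives}

    rng = np.random.default_rng(rng_seed)
    negatives: list[LabeledPair] = []
    for t_idx, p in enumerate(positives):
        # Fast path: rejection-sample distinct admissible miRNAs directly.
        chosen: list[str] = []
        used: set[str] = set()
        attempts, budget = 0, 30 * (k + 4)
        while len(chosen) < k and attempts < budget:
            attempts += 1
            s = pool_seqs[int(rng.integers(len(pool_seqs)))]
            if s in used or (s, p.target.seq) in positive_keys:
                continue
            if reject is not None and reject(pool[s], p.target):
                continue
            used.add(s)
            chosen.append(s)
        if len(chosen) < k:
            # Slow path: enumerate the admissible pool; draw without
            # replacement until exhausted, then with replacement.
            admissible = [
                s
                for s in pool_seqs
                if (s, p.target.seq) not in positive_keys
                and not (reject is not None and reject(pool[s], p.target))
            ]
            if not admissible:
                raise ValueError(
                    f"target {p.target.id!r} admits no negative pairing; "
                    f"attainable maximum for this positive is 0 of the requested {k}"
                )
            chosen = []
            while len(chosen) < k:
                take = min(k - len(chosen), len(admissible))
                idx = rng.choice(len(admissible), size=take, replace=False)
                chosen.extend(admissible[i] for i in sorted(idx))
        for j, s in enumerate(chosen[:k]):
            negatives.append(
                LabeledPair(
                    mirna=pool[s],
                    target=replace(p.target, id=f"{p.target.id}|neg{t_idx}.{j}"),
                    label=0.0,
                    origin="shuffled",
                )
            )
    return negatives


def assemble_ratio(
    positives: Sequence[LabeledPair],
    negatives: Sequence[LabeledPair],
    k: int,
    split_tag: str = "train",
    rng_seed: int = 0,
) -> RatioDataset:
    """Combine positives with the first k*|positives| negatives, shuffled.

    The realized ratio is exact; records are shuffled deterministically
    under ``rng_seed``.
    """
    need = k * len(positives)
    if len(negatives) < need:
        raise ValueError(
            f"need {need} negatives for ratio 1:{k} with {len(positives)} "
            f"positives, got {len(negatives)}"
        )
    records = list(positives) + list(negatives)[:need]
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(records))
    return RatioDataset(
        pairs=[records[i] for i in order],
        ratio_k=k,
        rng_seed=rng_seed,
        split_tag=split_tag,
        provenance={"n_pos": len(positives), "n_neg": need},
    )


def split_pairs(
    pairs: Sequence[LabeledPair],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    rng_seed: int = 0,
    dedup_across_splits: bool = False,
) -> tuple[list[LabeledPair], list[LabeledPair], list[LabeledPair]]:
    """Partition pairs into train/validation/test, disjoint and exhaustive.

    With ``dedup_across_splits`` identical (miRNA, target) sequence pairs
    are kept within a single split (grouped assignment); otherwise the
    split is by record.  Deterministic under ``rng_seed``.
    """
    if not pairs:
        raise ValueError("cannot split an empty pair collection")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")

    rng = np.random.default_rng(rng_seed)
    if dedup_across_splits:
        groups: dict[tuple[str, str], list[int]] = {}
        for i, p in enumerate(pairs):
            groups.setdefault(p.key, []).append(i)
        units: list[list[int]] = [groups[kk] for kk in sorted(groups)]
    else:
        units = [[i] for i in range(len(pairs))]

    order = rng.permutation(len(units))
    n = len(units)
    sizes = [int(np.floor(f * n)) for f in fractions]
    for i in range(n - sum(sizes)):  # distribute the rounding remainder
        sizes[i % 3] += 1
    out: list[list[LabeledPair]] = []
    at = 0
    for size in sizes:
        chunk = [pairs[i] for u in order[at : at + size] for i in units[u]]
        out.append(chunk)
        at += size
    return out[0], out[1], out[2]


def dataset_manifest(ds: RatioDataset) -> dict:
    """Provenance manifest: ratio, seed, counts and a content checksum."""
    blob = "\n".join(
        "\t".join([p.mirna.seq, p.target.seq, f"{p.label:.6g}", p.origin])
        for p in ds.pairs
    ).encode()
    return {
        "ratio_k": ds.ratio_k,
        "rng_seed": ds.rng_seed,
        "split_tag": ds.split_tag,
        "n_pairs": len(ds.pairs),
        "n_pos": sum(1 for p in ds.pairs if p.is_positive),
        "sha256": hashlib.sha256(blob).hexdigest(),
        **ds.provenance,
    }


def save_dataset(ds: RatioDataset, path: str, manifest_path: str | None = None) -> None:
    save_pairs(ds.pairs, path)
    if manifest_path:
        with open(manifest_path, "w") as fh:
            json.dump(dataset_manifest(ds), fh, indent=2, sort_keys=True)
            fh.write("\n")


def load_dataset(path: str, ratio_k: int, rng_seed: int = 0, split_tag: str = "train") -> RatioDataset:
    return RatioDataset(load_pairs(path), ratio_k=ratio_k, rng_seed=rng_seed, split_tag=split_tag)
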