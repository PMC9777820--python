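"""Sequence standardization and binary binding-matrix encoding.

A miRNA:target-site pair is represented as a 20 x 50 grid of 0/1
indicators: entry (i, j) is 1 exactly when miRNA position i (5'->3')
and target position j (5'->3') form a Watson-Crick pair (A:U, U:A,
G:C or C:G).  The grid deliberately hides the sequences themselves
from downstream classifiers, exposing only the complementarity
pattern.  G:U wobble pairs are *not* marked, and any position holding
an ambiguous N never pairs.

miRNAs are standardized to exactly 20 nt anchored at the 5' end
(longer sequences truncated, shorter ones N-padded at the 3' end);
target sites are 50-nt windows centred on the genomic interval of
interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

MIRNA_LEN = 20
TARGET_LEN = 50

_RNA_ALPHABET = "ACGUN"
# Watson-Crick partners only; wobble (G:U) intentionally absent.
_WC_PARTNER = {"A": "U", "U": "A", "G": "C", "C": "G"}

_BASE_INDEX = {b: i for i, b in enumerate(_RNA_ALPHABET)}
_PAIR_TABLE = np.zeros((5, 5), dtype=np.uint8)
for _b, _p in _WC_PARTNER.items():
    _PAIR_TABLE[_BASE_INDEX[_b], _BASE_INDEX[_p]] = 1

_DNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


class SequenceError(ValueError):
    """Raised for sequences that violate alphabet or length contracts."""


def clean_rna(raw: str, *, context: str = "sequence") -> str:
    """Uppercase, map T->U and validate the RNA alphabet {A,C,G,U,N}.

    Raises :class:`SequenceError` naming the first offending position
    (0-based) when an illegal character is present.
    """
    seq = raw.strip().upper().replace("T", "U")
    for pos, ch in enumerate(seq):
        if ch not in _RNA_ALPHABET:
            raise SequenceError(
                f"illegal character {ch!r} at position {pos} in {context} {raw!r}"
            )
    return seq


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement on the RNA alphabet (N -> N)."""
    return clean_rna(seq).translate(_DNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MiRNASeq:
    """A standardized miRNA: exactly 20 nt, 5'-anchored, RNA alphabet."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) != MIRNA_LEN:
            raise SequenceError(
                f"miRNA {self.id!r} must be {MIRNA_LEN} nt after "
                f"standardization, got {len(self.seq)}"
            )
        clean = clean_rna(self.seq, context=f"miRNA {self.id!r}")
        if clean != self.seq:
            raise SequenceError(f"miRNA {self.id!r} not standardized: {self.seq!r}")


@dataclass(frozen=True)
class TargetSeq:
    """A standardized 50-nt target site, optionally with its source interval.

    ``interval`` is (chrom, start, end, strand) in 0-based half-open
    coordinates; it records provenance only and does not affect encoding.
    """

    id: str
    seq: str
    interval: tuple[str, int, int, str] | None = field(default=None)

    def __post_init__(self) -> None:
        if len(self.seq) != TARGET_LEN:
            raise SequenceError(
                f"target {self.id!r} must be {TARGET_LEN} nt after "
                f"windowing, got {len(self.seq)}"
            )
        clean = clean_rna(self.seq, context=f"target {self.id!r}")
        if clean != self.seq:
            raise SequenceError(f"target {self.id!r} not standardized: {self.seq!r}")


def standardize_mirna(raw: str, id: str = "mirna") -> MiRNASeq:
    """Standardize a raw miRNA sequence to 20 nt, anchored at the 5' end.

    Sequences longer than 20 nt keep their first 20 nt; shorter ones are
    padded with N at the 3' end.  T is mapped to U and case is folded.
    Sequences shorter than 6 nt are rejected — no seed region exists.
    """
    seq = clean_rna(raw, context=f"miRNA {id!r}")
    if len(seq) < 6:
        raise SequenceError(
            f"miRNA {id!r} is {len(seq)} nt; at least 6 nt are required "
            "for a seed region to exist"
        )
    if len(seq) >= MIRNA_LEN:
        seq = seq[:MIRNA_LEN]
    else:
        seq = seq + "N" * (MIRNA_LEN - len(seq))
    return MiRNASeq(id=id, seq=seq)


def standardize_target(raw: str, id: str = "target") -> TargetSeq:
    """Validate an already-windowed 50-nt target sequence."""
    seq = clean_rna(raw, context=f"target {id!r}")
    return TargetSeq(id=id, seq=seq)


def window_target(
    interval: tuple[str, int, int, str],
    genome: Mapping[str, object],
    id: str | None = None,
) -> TargetSeq:
    """Extract the 50-nt window centred on a genomic interval.

    The centre is ``c = (start + end) // 2`` and the window spans
    ``[c - 25, c + 25)`` in 0-based half-open coordinates.  Minus-strand
    intervals are reverse-complemented so the returned sequence reads
    5'->3' on the transcribed strand.  Windows truncated by a sequence
    boundary are N-padded back to 50 nt; intervals lying entirely off
    the sequence are rejected.

    ``genome`` is any mapping from chromosome name to a string-like
    sequence (a plain dict of strings or a :class:`pyfaidx.Fasta`).
    """
    chrom, start, end, strand = interval
    if chrom not in genome:
        raise SequenceError(f"unknown sequence {chrom!r}")
    ref = str(genome[chrom][:])
    if start >= len(ref) or end <= 0 or start >= end:
        raise SequenceError(f"interval {interval} lies off sequence {chrom!r}")
    if strand not in "+-":
        raise SequenceError(f"bad strand {strand!r} in interval {interval}")

    c = (start + end) // 2
    lo, hi = c - TARGET_LEN // 2, c + TARGET_LEN // 2
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(ref))
    core = ref[max(lo, 0) : min(hi, len(ref))]
    seq = "N" * left_pad + clean_rna(core, context=f"{chrom}:{lo}-{hi}") + "N" * right_pad
    if strand == "-":
        seq = reverse_complement(seq)
    return TargetSeq(
        id=id or f"{chrom}:{start}-{end}({strand})",
        seq=seq,
        interval=(chrom, start, end, strand),
    )


def _indices(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy().view(np.uint8)


_CODE = np.full(128, -1, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _CODE[ord(_b)] = _i


def encode_pair(
    mirna: MiRNASeq,
    target: TargetSeq,
    orientation: str = "mirna_rows",
) -> np.ndarray:
    """Encode one pair as its binary Watson-Crick binding matrix.

    Returns a ``uint8`` array, shape (20, 50) with rows indexed by miRNA
    position and columns by target position (both 5'->3').  Pass
    ``orientation="target_rows"`` for the transposed (50, 20) layout.
    """
    mi = _CODE[_indices(mirna.seq)]
    tj = _CODE[_indices(target.seq)]
    mat = _PAIR_TABLE[mi[:, None], tj[None, :]]
    if orientation == "target_rows":
        return mat.T.copy()
    if orientation != "mirna_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return mat


def encode_batch(
    pairs: Sequence[tuple[MiRNASeq, TargetSeq]] | Iterable[tuple[MiRNASeq, TargetSeq]],
    orientation: str = "mirna_rows",
) -> np.ndarray:
    """Encode an ordered collection of pairs; element k is encode_pair(pair k).

    Invalid pairs are rejected with their index.  An empty input yields an
    empty (0, 20, 50) array.
    """
    mats = []
    for k, pair in enumerate(pairs):
        try:
            mirna, target = pair
            mats.append(encode_pair(mirna, target, orientation=orientation))
        except (SequenceError, ValueError, TypeError, AttributeError) as exc:
            raise SequenceError(f"pair {k} cannot be encoded: {exc}") from exc
    if not mats:
        shape = (0, TARGET_LEN, MIRNA_LEN) if orientation == "target_rows" else (0, MIRNA_LEN, TARGET_LEN)
        return np.empty(shape, dtype=np.uint8)
    return np.stack(mats)


def read_bed(path: str) -> list[tuple[str, int, int, str]]:
    """Read a BED file (>= 3 columns, 0-based half-open; strand from col 6)."""
    intervals: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
            strand = parts[5] if len(parts) >= 6 else "+"
            intervals.append((parts[0], int(parts[1]), int(parts[2]), strand))
    return intervals
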