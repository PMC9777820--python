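"""Seed-match heuristic and free-energy score handling.

The canonical seed heuristic calls a pair "bound" when the reverse
complement of the miRNA seed hexamer (positions 2-7, 1-based from the
5' end) occurs as a perfect contiguous Watson-Crick match anywhere in
the 50-nt target.  It is a binary decision — no score, hence no area
under any curve.

Free-energy scorers (hybridization / co-folding tools) report minimum
free energies in kcal/mol; these are min-max normalized to [0, 1] with
1 for the most favourable (most negative) energy so they can be
compared on the same curves as probabilistic scorers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datasets import LabeledPair
from .encoding import MiRNASeq, TargetSeq, reverse_complement

SEED_START, SEED_END = 1, 7  # python slice for 1-based positions 2-7


@dataclass(frozen=True)
class SeedCall:
    """Outcome of the seed scan: binary match plus all match offsets."""

    match: bool
    match_offsets: tuple[int, ...] = ()
    warning: str | None = None

    def __post_init__(self) -> None:
        if self.match != bool(self.match_offsets):
            raise ValueError("match flag inconsistent with offsets")


def seed_hexamer(mirna: MiRNASeq) -> str:
    """The miRNA seed: nucleotides 2-7 (1-based, 5'-anchored)."""
    return mirna.seq[SEED_START:SEED_END]


def seed_match(mirna: MiRNASeq, target: TargetSeq) -> SeedCall:
    """Scan the target for a perfect complement of the seed hexamer.

    Returns every 0-based target offset at which the reverse complement
    of the seed occurs (overlaps included).  A seed containing N cannot
    be matched; the call is negative and carries a warning flag.
    """
    seed = seed_hexamer(mirna)
    if "N" in seed:
        return SeedCall(False, (), warning="seed region contains N")
    needle = reverse_complement(seed)
    offsets = []
    at = target.seq.find(needle)
    while at != -1:
        offsets.append(at)
        at = target.seq.find(needle, at + 1)
    return SeedCall(bool(offsets), tuple(offsets))


class SeedScorer:
    """Binary scorer over pairs: 1.0 on a seed match, else 0.0."""

    name = "seed"

    def predict(self, pairs: Sequence[LabeledPair]) -> np.ndarray:
        return np.array(
            [1.0 if seed_match(p.mirna, p.target).match else 0.0 for p in pairs],
            dtype=np.float64,
        )


@dataclass
class NormalizedScoreTable:
    """Per-pair raw energies/scores and their min-max normalized values."""

    table: pd.DataFrame  # columns: pair_id, raw, score
    degenerate: bool = False

    @property
    def scores(self) -> np.ndarray:
        return self.table["score"].to_numpy()


def normalize_energies(
    raw: Iterable[float], pair_ids: Sequence[str] | None = None
) -> NormalizedScoreTable:
    """Min-max normalize free energies so 1 is the strongest binding.

    ``score = (max_raw - raw) / (max_raw - min_raw)``: the most negative
    energy maps to 1, the least negative to 0.  If all energies are equal
    the range is degenerate; every score is defined as 0.5 and a warning
    is emitted.
    """
    values = np.asarray(list(raw), dtype=np.float64)
    if values.size == 0:
        raise ValueError("no energies to normalize")
    if not np.all(np.isfinite(values)):
        raise ValueError("energies must be finite")
    lo, hi = values.min(), values.max()
    degenerate = hi == lo
    if degenerate:
        warnings.warn("degenerate energy range: all values equal; scores set to 0.5")
        scores = np.full_like(values, 0.5)
    else:
        scores = (hi - values) / (hi - lo)
    ids = list(pair_ids) if pair_ids is not None else [str(i) for i in range(values.size)]
    if len(ids) != values.size:
        raise ValueError("pair_ids length mismatch")
    return NormalizedScoreTable(
        pd.DataFrame({"pair_id": ids, "raw": values, "score": scores}),
        degenerate=degenerate,
    )


def import_external_scores(
    tool_tsv: str,
    pair_ids: Sequence[str],
    kind: str = "energy",
) -> NormalizedScoreTable:
    """Adapt an external tool's per-pair score table to normalized scores.

    ``tool_tsv`` has columns (pair_id, value); pairs missing from the
    table are taken as "no interaction reported" and receive the worst
    score, 0.  ``kind`` selects the raw-value semantics: "energy"
    (kcal/mol, lower is better) or "rna22_pvalue" (converted to
    1 - p before min-max normalization, so small p is better).
    Unparseable rows are rejected with their line numbers.
    """
    df = pd.read_csv(tool_tsv, sep="\t", dtype=str, keep_default_na=False)
    if not {"pair_id", "value"} <= set(df.columns):
        raise ValueError(f"{tool_tsv}: expected columns pair_id, value")
    raw: dict[str, float] = {}
    bad = []
    for idx, row in df.iterrows():
        line_no = int(idx) + 2
        try:
            raw[row["pair_id"]] = float(row["value"])
        except ValueError:
            bad.append(f"line {line_no}: unparseable value {row['value']!r}")
    if bad:
        raise ValueError(f"{tool_tsv}: " + "; ".join(bad))

    reported = [pid for pid in pair_ids if pid in raw]
    if not reported:
        scores = pd.DataFrame(
            {"pair_id": list(pair_ids), "raw": np.nan, "score": 0.0}
        )
        return NormalizedScoreTable(scores)

    values = np.array([raw[pid] for pid in reported])
    if kind == "rna22_pvalue":
        values = 1.0 - values  # higher is better after conversion
        norm = normalize_energies(-values, pair_ids=reported)  # reuse: lower=-value is better
    elif kind == "energy":
        norm = normalize_energies(values, pair_ids=reported)
    else:
        raise ValueError(f"unknown score kind {kind!r}")

    by_id = dict(zip(norm.table["pair_id"], norm.table["score"]))
    raw_by_id = dict(zip(reported, values))
    rows = [
        {
            "pair_id": pid,
            "raw": raw_by_id.get(pid, np.nan),
            "score": by_id.get(pid, 0.0),
        }
        for pid in pair_ids
    ]
    return NormalizedScoreTable(pd.DataFrame(rows), degenerate=norm.degenerate)
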