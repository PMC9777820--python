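"""Synthetic miRNA:target pairs with planted binding mechanisms.

The generator emulates the composition of unbiased chimeric-read
(CLASH-style) interaction data: by default ~40% of positives carry a
canonical seed site (a perfect complement of miRNA nucleotides 2-7
embedded in the target), 18% bind only through the miRNA 3' end (a
perfect complement of nucleotides 13-20, with *no* seed complement
anywhere in the target), and the remainder are "non-canonical" —
modeled here as an imperfect extended duplex: a complement of miRNA
nucleotides 3-9 carrying one forced internal mismatch.  Negatives are
random miRNA:target re-pairings that never reproduce a positive pair
and never contain an accidental seed complement (rejection sampling).

The planted mechanism of every positive is recorded in its provenance
so per-mechanism recall is computable for any scorer.  The generator
makes no claim of thermodynamic realism; flanking sequence is i.i.d.
at a configurable GC content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .baselines import seed_match
from .datasets import LabeledPair, RatioDataset, assemble_ratio, make_negatives
from .encoding import MIRNA_LEN, TARGET_LEN, MiRNASeq, TargetSeq, reverse_complement

MECHANISMS = ("canonical", "three_prime", "noncanonical")


class SiteConflictError(RuntimeError):
    """Raised when a seed-free site cannot be built for a given miRNA."""

_BASES = "ACGU"


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for one synthetic dataset."""

    n_pos: int = 1000
    canonical_fraction: float = 0.40
    three_prime_fraction: float = 0.18
    mutation_rate: float = 0.0
    rng_seed: int = 0
    gc_content: float = 0.5

    def __post_init__(self) -> None:
        if self.n_pos < 1:
            raise ValueError("n_pos must be >= 1")
        if self.canonical_fraction < 0 or self.three_prime_fraction < 0:
            raise ValueError("mechanism fractions must be non-negative")
        if self.canonical_fraction + self.three_prime_fraction > 1 + 1e-9:
            raise ValueError(
                "canonical_fraction + three_prime_fraction must not exceed 1"
            )
        if not (0.0 <= self.mutation_rate < 1.0):
            raise ValueError("mutation_rate must lie in [0, 1)")
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must lie in (0, 1)")

    @property
    def noncanonical_fraction(self) -> float:
        return 1.0 - self.canonical_fraction - self.three_prime_fraction


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G U


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    idx = rng.choice(4, size=n, p=_base_probs(gc))
    return "".join(_BASES[i] for i in idx)


def gen_mirnas(
    n: int, length: int = MIRNA_LEN, seed: int = 0, gc_content: float = 0.5
) -> list[MiRNASeq]:
    """Draw n i.i.d. miRNA sequences at the requested composition."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        seq = _random_seq(rng, length, gc_content)
        if length < MIRNA_LEN:
            seq = seq + "N" * (MIRNA_LEN - length)
        out.append(MiRNASeq(id=f"syn-mir-{i:05d}", seq=seq[:MIRNA_LEN]))
    return out


def _mutate(rng: np.random.Generator, elem: str, rate: float) -> str:
    if rate == 0.0:
        return elem
    chars = list(elem)
    for i, ch in enumerate(chars):
        if ch in _BASES and rng.random() < rate:
            chars[i] = rng.choice([b for b in _BASES if b != ch])
    return "".join(chars)


def plant_site(
    mirna: MiRNASeq,
    mechanism: str,
    mutation_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    gc_content: float = 0.5,
    id: str | None = None,
) -> TargetSeq:
    """Build a 50-nt target carrying the requested binding element.

    The element sits at a uniform random offset with i.i.d. flanks.
    Mechanisms:

    * ``canonical`` — reverse complement of miRNA 2-7 (the seed hexamer);
      with ``mutation_rate`` 0 the seed heuristic always fires.
    * ``three_prime`` — reverse complement of miRNA 13-20; the finished
      target is resampled until it contains no seed complement.
    * ``noncanonical`` — reverse complement of miRNA 3-9 with one forced
      internal mismatch; also guaranteed free of seed complements.

    ``mutation_rate`` applies per element position on top of any forced
    mismatch.
    """
    if mechanism not in MECHANISMS:
        raise ValueError(f"unknown mechanism {mechanism!r}; expected {MECHANISMS}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # A miRNA whose 3' element itself embeds the seed complement can never
    # yield a seed-free target by flank resampling; fail fast so callers
    # can substitute another miRNA.
    if mechanism == "three_prime" and mutation_rate == 0.0:
        elem0 = reverse_complement(mirna.seq[12:20])
        if reverse_complement(mirna.seq[1:7]) in elem0:
            raise SiteConflictError(
                f"3' element of {mirna.id} contains its own seed complement"
            )

    for _attempt in range(200):
        if mechanism == "canonical":
            elem = reverse_complement(mirna.seq[1:7])
        elif mechanism == "three_prime":
            elem = reverse_complement(mirna.seq[12:20])
        else:
            elem = list(reverse_complement(mirna.seq[2:9]))
            at = int(rng.integers(1, len(elem) - 1))  # internal position
            elem[at] = rng.choice([b for b in _BASES if b != elem[at]])
            elem = "".join(elem)
        elem = _mutate(rng, elem, mutation_rate)
        offset = int(rng.integers(0, TARGET_LEN - len(elem) + 1))
        flank_l = _random_seq(rng, offset, gc_content)
        flank_r = _random_seq(rng, TARGET_LEN - offset - len(elem), gc_content)
        target = TargetSeq(
            id=id or f"{mirna.id}:{mechanism}", seq=flank_l + elem + flank_r
        )
        if mechanism == "canonical":
            return target
        # seed-free mechanisms: reject accidental canonical complements
        if not seed_match(mirna, target).match:
            return target
    raise SiteConflictError(
        f"could not build a seed-free {mechanism} target for {mirna.id} "
        "within 200 attempts"
    )


def gen_positives(spec: SynthSpec) -> list[LabeledPair]:
    """Generate the positive class: one fresh miRNA per positive, with the
    mechanism mixture given by the SynthSpec (counts rounded, remainder
    non-canonical)."""
    rng = np.random.default_rng(spec.rng_seed)
    mirnas = gen_mirnas(spec.n_pos, seed=int(rng.integers(2**31)), gc_content=spec.gc_content)
    n_canon = int(round(spec.canonical_fraction * spec.n_pos))
    n_3p = int(round(spec.three_prime_fraction * spec.n_pos))
    n_3p = min(n_3p, spec.n_pos - n_canon)
    mech = (
        ["canonical"] * n_canon
        + ["three_prime"] * n_3p
        + ["noncanonical"] * (spec.n_pos - n_canon - n_3p)
    )
    site_rng = np.random.default_rng(int(rng.integers(2**31)))
    positives = []
    for i, (m, mirna) in enumerate(zip(mech, mirnas)):
        for _retry in range(100):
            try:
                target = plant_site(
                    mirna,
                    m,
                    mutation_rate=spec.mutation_rate,
                    seed=site_rng,
                    gc_content=spec.gc_content,
                    id=f"syn-tgt-{i:05d}",
                )
                break
            except SiteConflictError:
                # substitute a fresh miRNA for which the site is constructible
                mirna = MiRNASeq(
                    id=f"syn-mir-r{i:05d}.{_retry}",
                    seq=_random_seq(site_rng, MIRNA_LEN, spec.gc_content),
                )
        else:
            raise SiteConflictError(f"no constructible {m} site after 100 miRNAs")
        positives.append(
            LabeledPair(mirna, target, label=1.0, origin="synthetic", mechanism=m)
        )
    return positives


def gen_dataset(spec: SynthSpec, k: int = 1, split_tag: str = "train") -> RatioDataset:
    """A full ratio-1:k dataset: planted positives plus shuffled negatives.

    Negatives are drawn by re-pairing positive targets with random
    miRNAs from the generated pool, excluding the positive pairs and any
    pairing that would create an accidental seed complement.
    """
    positives = gen_positives(spec)
    rng = np.random.default_rng(spec.rng_seed)
    _ = rng.integers(2**31), rng.integers(2**31)  # consumed by gen_positives
    neg_seed = int(rng.integers(2**31))
    negatives = make_negatives(
        positives,
        k=k,
        rng_seed=neg_seed,
        reject=lambda m, t: seed_match(m, t).match,
    )
    ds = assemble_ratio(positives, negatives, k, split_tag, rng_seed=neg_seed)
    ds.rng_seed = spec.rng_seed
    ds.provenance.update(
        {
            "generator": "synthetic",
            "spec": {
                "n_pos": spec.n_pos,
                "canonical_fraction": spec.canonical_fraction,
                "three_prime_fraction": spec.three_prime_fraction,
                "mutation_rate": spec.mutation_rate,
                "rng_seed": spec.rng_seed,
                "gc_content": spec.gc_content,
            },
        }
    )
    return ds


def mechanism_of(pair: LabeledPair) -> str | None:
    return pair.mechanism


def save_fasta(pairs, path: str) -> None:
    """Export pairs as interleaved FASTA (miRNA record then target record)."""
    with open(path, "w") as fh:
        for i, p in enumerate(pairs):
            fh.write(f">{p.mirna.id}|pair{i}\n{p.mirna.seq}\n")
            fh.write(f">{p.target.id}|pair{i}\n{p.target.seq}\n")
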