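"""Pair tables, shuffled negatives, ratio assembly and splits."""

import logging

import numpy as np
import pytest

from mirsite.datasets import (
    LabeledPair,
    RatioDataset,
    assemble_ratio,
    dataset_manifest,
    load_pairs,
    make_negatives,
    save_pairs,
    split_pairs,
)
from mirsite.encoding import standardize_mirna, standardize_target


def make_positives(rng, n, n_mirnas=None):
    n_mirnas = n_mirnas or n
    mirnas = [
        standardize_mirna("".join(rng.choice(list("ACGU"), size=20)), id=f"m{i}")
        for i in range(n_mirnas)
    ]
    out = []
    for i in range(n):
        tgt = standardize_target("".join(rng.choice(list("ACGU"), size=50)), id=f"t{i}")
        out.append(LabeledPair(mirnas[i % n_mirnas], tgt, 1.0))
    return out


class TestLabeledPair:
    @pytest.mark.parametrize("label", [1.0, 0.0, 0.25, 0.5])
    def test_valid_labels(self, rng, label):
        p = make_positives(rng, 1)[0]
        LabeledPair(p.mirna, p.target, label)

    @pytest.mark.parametrize("label", [0.75, 1.5, -0.1])
    def test_invalid_labels_rejected(self, rng, label):
        p = make_positives(rng, 1)[0]
        with pytest.raises(ValueError):
            LabeledPair(p.mirna, p.target, label)


class TestLoadPairs:
    def _write(self, path, rows, header="mirna_id\tmirna_seq\ttarget_id\ttarget_seq"):
        path.write_text("\n".join([header] + rows) + "\n")

    def test_valid_table(self, tmp_path, rng):
        pos = make_positives(rng, 3)
        path = tmp_path / "pairs.tsv"
        self._write(path, [f"{p.mirna.id}\t{p.mirna.seq}\t{p.target.id}\t{p.target.seq}" for p in pos])
        pairs = load_pairs(str(path))
        assert len(pairs) == 3
        assert all(p.label == 1.0 for p in pairs)

    def test_short_target_rejected_with_line_number(self, tmp_path, rng):
        pos = make_positives(rng, 2)
        rows = [
            f"{pos[0].mirna.id}\t{pos[0].mirna.seq}\t{pos[0].target.id}\t{pos[0].target.seq}",
            f"{pos[1].mirna.id}\t{pos[1].mirna.seq}\tbad\t{'ACGUA' * 3 + 'ACGU'}",  # 19 nt
        ]
        path = tmp_path / "pairs.tsv"
        self._write(path, rows)
        with pytest.raises(ValueError, match="line 3"):
            load_pairs(str(path))

    def test_duplicates_retained_and_logged(self, tmp_path, rng, caplog):
        p = make_positives(rng, 1)[0]
        row = f"{p.mirna.id}\t{p.mirna.seq}\t{p.target.id}\t{p.target.seq}"
        path = tmp_path / "pairs.tsv"
        self._write(path, [row, row])
        with caplog.at_level(logging.WARNING):
            pairs = load_pairs(str(path))
        assert len(pairs) == 2
        assert "1 duplicated" in caplog.text

    def test_round_trip(self, tmp_path, rng):
        pos = make_positives(rng, 5)
        path = tmp_path / "pairs.tsv"
        save_pairs(pos, str(path))
        back = load_pairs(str(path))
        assert [(p.mirna.seq, p.target.seq, p.label) for p in back] == [
            (p.mirna.seq, p.target.seq, p.label) for p in pos
        ]


class TestMakeNegatives:
    def test_counts_and_exclusion(self, rng):
        pos = make_positives(rng, 100)
        negs = make_negatives(pos, k=10, rng_seed=1)
        assert len(negs) == 1000
        pos_keys = {p.key for p in pos}
        assert all(n.key not in pos_keys for n in negs)
        assert all(n.label == 0.0 and n.origin == "shuffled" for n in negs)

    def test_degenerate_pool_rejected(self, rng):
        pos = make_positives(rng, 5, n_mirnas=1)
        with pytest.raises(ValueError, match="single distinct"):
            make_negatives(pos, k=1, rng_seed=0)

    def test_determinism_and_seed_sensitivity(self, rng):
        pos = make_positives(rng, 50)
        a = make_negatives(pos, k=2, rng_seed=7)
        b = make_negatives(pos, k=2, rng_seed=7)
        c = make_negatives(pos, k=2, rng_seed=8)
        assert [n.key for n in a] == [n.key for n in b]
        assert [n.key for n in a] != [n.key for n in c]
        # different seeds still deliver identical label/ratio statistics
        assert len(c) == len(a) and all(n.label == 0.0 for n in c)

    def test_without_replacement_until_pool_exhausted(self, rng):
        pos = make_positives(rng, 10)
        negs = make_negatives(pos, k=5, rng_seed=3)
        for t in {n.target.seq for n in negs}:
            mirnas = [n.mirna.seq for n in negs if n.target.seq == t]
            assert len(set(mirnas)) == len(mirnas)  # k=5 < pool size: all distinct


class TestAssembleRatio:
    @pytest.mark.parametrize("k", [1, 10, 20, 100])
    def test_exact_prevalence(self, rng, k):
        pos = make_positives(rng, 20)
        negs = make_negatives(pos, k=k, rng_seed=0)
        ds = assemble_ratio(pos, negs, k, rng_seed=0)
        n_pos = sum(1 for p in ds.pairs if p.is_positive)
        assert n_pos == 20
        assert len(ds) == 20 * (1 + k)
        assert ds.prevalence == pytest.approx(1 / (1 + k))

    def test_insufficient_negatives_rejected(self, rng):
        pos = make_positives(rng, 10)
        negs = make_negatives(pos, k=1, rng_seed=0)
        with pytest.raises(ValueError, match="need 20"):
            assemble_ratio(pos, negs, 2, rng_seed=0)

    def test_shuffle_is_deterministic(self, rng):
        pos = make_positives(rng, 10)
        negs = make_negatives(pos, k=1, rng_seed=0)
        a = assemble_ratio(pos, negs, 1, rng_seed=5)
        b = assemble_ratio(pos, negs, 1, rng_seed=5)
        assert [p.key for p in a.pairs] == [p.key for p in b.pairs]


class TestSplitPairs:
    def test_80_10_10(self, rng):
        pos = make_positives(rng, 100)
        tr, va, te = split_pairs(pos, (0.8, 0.1, 0.1), rng_seed=0)
        assert (len(tr), len(va), len(te)) == (80, 10, 10)

    def test_partition_is_exhaustive_multiset(self, rng):
        pos = make_positives(rng, 37)
        tr, va, te = split_pairs(pos, (0.5, 0.25, 0.25), rng_seed=1)
        assert sorted(id(p) for p in tr + va + te) == sorted(id(p) for p in pos)

    def test_dedup_keeps_identical_pairs_together(self, rng):
        pos = make_positives(rng, 30)
        dup = pos + pos[:10]
        tr, va, te = split_pairs(dup, (0.6, 0.2, 0.2), rng_seed=2, dedup_across_splits=True)
        keysets = [{p.key for p in chunk} for chunk in (tr, va, te)]
        assert not (keysets[0] & keysets[1])
        assert not (keysets[0] & keysets[2])
        assert not (keysets[1] & keysets[2])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            split_pairs([], (0.8, 0.1, 0.1))


class TestByteDeterminism:
    def test_same_seed_gives_byte_identical_files(self, tmp_path, rng):
        pos = make_positives(rng, 20)
        files = []
        for name in ("a.tsv", "b.tsv"):
            negs = make_negatives(pos, k=3, rng_seed=11)
            ds = assemble_ratio(pos, negs, 3, rng_seed=11)
            path = tmp_path / name
            save_pairs(ds.pairs, str(path))
            files.append(path.read_bytes())
        assert files[0] == files[1]

    def test_manifest_checksum_tracks_content(self, rng):
        pos = make_positives(rng, 10)
        negs = make_negatives(pos, k=1, rng_seed=0)
        a = dataset_manifest(assemble_ratio(pos, negs, 1, rng_seed=1))
        b = dataset_manifest(assemble_ratio(pos, negs, 1, rng_seed=1))
        c = dataset_manifest(assemble_ratio(pos, negs, 1, rng_seed=2))
        assert a["sha256"] == b["sha256"] != c["sha256"]
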