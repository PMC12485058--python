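"""Canonical k-mer counting against a brute-force oracle, plus histogram I/O."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hapqc.kmer import (
    HistoParseError,
    KmerDatabase,
    KmerSpectrum,
    canonical_kmer,
    count_kmers,
    read_histo,
    reverse_complement,
    spectrum,
    write_histo,
)

# ---------------------------------------------------------------- oracle


def naive_counts(seqs, k):
    """Brute-force canonical counter: dict of window tallies."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    counts = {}
    skipped = 0
    for seq in seqs:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            win = seq[i : i + k]
            if any(c not in "ACGT" for c in win):
                skipped += 1
                continue
            rc = "".join(comp[c] for c in reversed(win))
            canon = min(win, rc)
            counts[canon] = counts.get(canon, 0) + 1
    return counts, skipped


dna = st.text(alphabet="ACGT", min_size=0, max_size=200)
dna_with_n = st.text(alphabet="ACGTN", min_size=0, max_size=200)


# ---------------------------------------------------------------- canonical


@pytest.mark.parametrize(
    "kmer,expected",
    [
        ("ACGT", "ACGT"),  # reverse-complement palindrome
        ("TTTT", "AAAA"),
        ("AACG", "AACG"),  # revcomp CGTT is larger
        ("acgt", "ACGT"),  # case-insensitive
    ],
)
def test_canonical_kmer_examples(kmer, expected):
    assert canonical_kmer(kmer) == expected


def test_canonical_kmer_rejects_ambiguity_codes():
    with pytest.raises(ValueError):
        canonical_kmer("ACNG")


@given(dna.filter(lambda s: len(s) >= 1))
def test_canonical_kmer_is_involution_and_strand_free(s):
    c = canonical_kmer(s)
    assert canonical_kmer(c) == c
    assert canonical_kmer(reverse_complement(s)) == c
    assert c <= reverse_complement(c)


# ---------------------------------------------------------------- counting


@pytest.mark.parametrize(
    "seqs,k,expected,positions,skipped",
    [
        (["AAAAA"], 3, {"AAA": 3}, 3, 0),
        (["ACGTACGT"], 4, {"ACGT": 2, "CGTA": 2, "GTAC": 1}, 5, 0),
        (["ACNGT"], 2, {"AC": 2}, 2, 2),
        ([], 3, {}, 0, 0),
        (["AC"], 3, {}, 0, 0),  # k longer than every sequence
    ],
)
def test_count_kmers_examples(seqs, k, expected, positions, skipped):
    db = count_kmers(seqs, k)
    assert dict(db.counts) == expected
    assert db.total_positions == positions
    assert db.skipped_windows == skipped


@given(st.lists(dna_with_n, max_size=5), st.integers(min_value=1, max_value=7))
def test_count_kmers_matches_brute_force(seqs, k):
    db = count_kmers(seqs, k)
    expected, skipped = naive_counts(seqs, k)
    assert dict(db.counts) == expected
    assert db.total_positions == sum(expected.values())
    assert db.skipped_windows == skipped


@given(st.lists(dna, max_size=5), st.integers(min_value=1, max_value=7))
def test_counting_is_strand_invariant(seqs, k):
    fwd = count_kmers(seqs, k)
    rev = count_kmers([reverse_complement(s) for s in seqs], k)
    assert dict(fwd.counts) == dict(rev.counts)
    assert fwd.total_positions == rev.total_positions


def test_count_kmers_rejects_bad_k():
    with pytest.raises(ValueError):
        count_kmers(["ACGT"], 0)


def test_database_invariants_on_random_input():
    rng = np.random.default_rng(7)
    seqs = ["".join(rng.choice(list("ACGT"), size=200)) for _ in range(5)]
    db = count_kmers(seqs, 5)
    # every key canonical, correct length; multiplicities conserve positions
    for kmer in db.counts:
        assert len(kmer) == 5
        assert kmer == canonical_kmer(kmer)
    assert sum(db.counts.values()) == db.total_positions
    assert db.get_count(reverse_complement(seqs[0][:5])) == db.get_count(seqs[0][:5])


# ---------------------------------------------------------------- spectrum


@pytest.mark.parametrize(
    "counts,k,expected",
    [
        ({"ACGT": 2, "CGTA": 2, "GTAC": 1}, 4, {1: 1, 2: 2}),
        ({}, 4, {}),
        ({"AAA": 3}, 3, {3: 1}),
    ],
)
def test_spectrum_examples(counts, k, expected):
    db = KmerDatabase.from_counts(k, counts)
    assert spectrum(db).histogram == expected


@given(st.lists(dna, max_size=4), st.integers(min_value=1, max_value=6))
def test_spectrum_conservation(seqs, k):
    db = count_kmers(seqs, k)
    spec = spectrum(db)
    assert spec.total_positions == db.total_positions
    assert spec.n_distinct == db.n_distinct


# ---------------------------------------------------------------- histo I/O


def test_read_histo_direct_parse(tmp_path):
    p = tmp_path / "a.histo"
    p.write_text("1 10\n2 5\n")
    spec = read_histo(p, k=21)
    assert spec.histogram == {1: 10, 2: 5}
    assert spec.k == 21


def test_histo_round_trip(tmp_path):
    p = tmp_path / "rt.histo"
    write_histo(KmerSpectrum(21, {1: 1, 2: 2}), p)
    assert read_histo(p, 21).histogram == {1: 1, 2: 2}


@pytest.mark.parametrize(
    "content,fragment",
    [
        ("1 x\n", "line 1"),
        ("1 10\n1 4\n", "line 2"),  # duplicate multiplicity
        ("2 5\n1 9\n", "line 2"),  # decreasing multiplicity
        ("1 2 3\n", "line 1"),  # too many fields
    ],
)
def test_read_histo_errors_name_line(tmp_path, content, fragment):
    p = tmp_path / "bad.histo"
    p.write_text(content)
    with pytest.raises(HistoParseError, match=fragment):
        read_histo(p, 21)


def test_dump_is_lexicographically_sorted(tmp_path):
    db = count_kmers(["ACGTACGTTT"], 3)
    p = tmp_path / "dump.tsv"
    db.dump(p)
    kmers = [line.split("\t")[0] for line in p.read_text().splitlines()]
    assert kmers == sorted(kmers)
    assert all(len(km) == 3 for km in kmers)
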