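"""Canonical k-mer counting, spectra, and Jellyfish-style histogram I/O.

K-mers are counted canonically: each window of length *k* over {A,C,G,T} is
collapsed with its reverse complement to the lexicographically smaller of the
two, so counts are independent of which strand a read or contig happens to
represent. Windows containing any other character (N, IUPAC ambiguity codes,
gap symbols) are skipped and tallied separately.

Internally k-mers are 2-bit packed (A=0, C=1, G=2, T=3) into int64 codes and
held in sorted numpy arrays; this encoding preserves lexicographic order for
fixed k, so numeric code order is string order. The mapping contract
(canonical k-mer string -> multiplicity) is exposed through
:attr:`KmerDatabase.counts`, a lazy read-only view that decodes on access.
"""

from __future__ import annotations

import gzip
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

__all__ = [
    "KmerDatabase",
    "KmerSpectrum",
    "HistoParseError",
    "canonical_kmer",
    "reverse_complement",
    "count_kmers",
    "spectrum",
    "read_histo",
    "write_histo",
]

DEFAULT_K = 21

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# byte -> 2-bit code; 4 marks a non-ACGT base, 5 is reserved for the
# between-sequence separator inserted during batch encoding.
_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i
_SEP = np.array([5], dtype=np.uint8)


class HistoParseError(ValueError):
    """Raised when a .histo file cannot be parsed; message names the line."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per base)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    """Return the canonical form: min(kmer, revcomp(kmer)), uppercased.

    Raises ``ValueError`` on any character outside {A,C,G,T} (case
    insensitive); callers counting over raw sequence skip such windows
    instead of aborting.
    """
    s = kmer.upper()
    if not s or any(c not in "ACGT" for c in s):
        raise ValueError(f"k-mer contains non-ACGT characters: {kmer!r}")
    return min(s, reverse_complement(s))


def _encode_kmer(kmer: str) -> int:
    code = 0
    for c in kmer:
        code = (code << 2) | "ACGT".index(c)
    return code


def _decode_kmer(code: int, k: int) -> str:
    chars = []
    for _ in range(k):
        chars.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(chars))


def _encode_sequences(sequences: list[str]) -> np.ndarray:
    """Concatenate sequences into one code buffer with separators (code 5)."""
    parts: list[np.ndarray] = []
    for s in sequences:
        raw = np.frombuffer(s.encode("ascii", "replace"), dtype=np.uint8)
        parts.append(_LUT[raw])
        parts.append(_SEP)
    if not parts:
        return np.empty(0, dtype=np.uint8)
    return np.concatenate(parts[:-1])


@njit(cache=True)
def _scan_kernel(enc: np.ndarray, k: int, out: np.ndarray):  # pragma: no cover
    """Rolling 2-bit scan emitting canonical codes of all valid windows.

    ``enc`` holds 0..3 for A,C,G,T, 4 for a non-ACGT base, 5 for the
    between-sequence separator. Returns (number of codes written, number of
    skipped windows), where a skipped window lies within one sequence but
    contains a non-ACGT base; windows spanning a separator are dropped
    without being tallied.
    """
    mask = (np.int64(1) << (2 * k)) - 1
    rc_shift = 2 * (k - 1)
    fwd = np.int64(0)
    rc = np.int64(0)
    big = np.int64(1) << 40
    since_bad = big  # valid bases since the last non-ACGT character
    since_sep = big  # valid-or-bad bases since the last separator
    m = 0
    skipped = 0
    for i in range(enc.size):
        b = enc[i]
        if b < 4:
            fwd = ((fwd << 2) | np.int64(b)) & mask
            rc = (rc >> 2) | (np.int64(3 - b) << rc_shift)
            since_bad += 1
            since_sep += 1
        elif b == 4:
            since_bad = 0
            since_sep += 1
        else:
            since_sep = 0
            since_bad += 1
        if i >= k - 1:
            if since_bad >= k and since_sep >= k:
                out[m] = fwd if fwd < rc else rc
                m += 1
            elif since_bad < k <= since_sep:
                skipped += 1
    return m, skipped


def _canonical_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, int]:
    """All canonical k-mer codes for valid windows of the encoded buffer.

    Returns (codes, skipped); see :func:`_scan_kernel` for the skip rules.
    2-bit packed codes fit int64 for k <= 31.
    """
    n = enc.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), 0
    if k > 31:
        raise ValueError("k must be <= 31 for packed counting")
    out = np.empty(n, dtype=np.int64)
    m, skipped = _scan_kernel(enc, k, out)
    return out[:m], skipped


class _KmerCounts(Mapping):
    """Read-only mapping view (canonical k-mer string -> multiplicity)."""

    def __init__(self, db: "KmerDatabase"):
        self._db = db

    def __getitem__(self, kmer: str) -> int:
        db = self._db
        if len(kmer) != db.k:
            raise KeyError(kmer)
        code = _encode_kmer(kmer.upper()) if set(kmer.upper()) <= set("ACGT") else None
        if code is None:
            raise KeyError(kmer)
        i = int(np.searchsorted(db._codes, code))
        if i < db._codes.size and int(db._codes[i]) == code:
            return int(db._mults[i])
        raise KeyError(kmer)

    def __iter__(self) -> Iterator[str]:
        k = self._db.k
        for code in self._db._codes:
            yield _decode_kmer(int(code), k)

    def __len__(self) -> int:
        return int(self._db._codes.size)


@dataclass
class KmerSpectrum:
    """Multiplicity histogram: m -> number of distinct canonical k-mers."""

    k: int
    histogram: dict[int, int] = field(default_factory=dict)

    @property
    def total_positions(self) -> int:
        return sum(m * c for m, c in self.histogram.items())

    @property
    def n_distinct(self) -> int:
        return sum(self.histogram.values())

    @property
    def max_multiplicity(self) -> int:
        return max(self.histogram) if self.histogram else 0

    def dense_counts(self) -> np.ndarray:
        """Counts as an array indexed by multiplicity (index 0 unused)."""
        out = np.zeros(self.max_multiplicity + 1, dtype=np.int64)
        for m, c in self.histogram.items():
            out[m] = c
        return out


class KmerDatabase:
    """Canonical k-mer -> multiplicity map for one sequence collection.

    Construct via :func:`count_kmers` (bulk) or :meth:`from_counts` (tests,
    small hand-built inputs).
    """

    def __init__(
        self,
        k: int,
        codes: np.ndarray,
        multiplicities: np.ndarray,
        skipped_windows: int = 0,
    ):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = int(k)
        self._codes = np.asarray(codes, dtype=np.int64)
        self._mults = np.asarray(multiplicities, dtype=np.int64)
        self.skipped_windows = int(skipped_windows)

    @classmethod
    def from_counts(cls, k: int, counts: Mapping[str, int]) -> "KmerDatabase":
        items = []
        for kmer, mult in counts.items():
            canon = canonical_kmer(kmer)
            if canon != kmer.upper():
                raise ValueError(f"{kmer!r} is not in canonical form")
            if len(kmer) != k:
                raise ValueError(f"{kmer!r} does not have length k={k}")
            if mult <= 0:
                raise ValueError("multiplicities must be positive")
            items.append((_encode_kmer(canon), int(mult)))
        items.sort()
        codes = np.array([c for c, _ in items], dtype=np.int64)
        mults = np.array([m for _, m in items], dtype=np.int64)
        return cls(k, codes, mults)

    @property
    def counts(self) -> Mapping[str, int]:
        return _KmerCounts(self)

    @property
    def total_positions(self) -> int:
        return int(self._mults.sum())

    @property
    def n_distinct(self) -> int:
        return int(self._codes.size)

    def __len__(self) -> int:
        return self.n_distinct

    def __contains__(self, kmer: str) -> bool:
        try:
            self.get_count(kmer)
        except (ValueError, KeyError):
            return False
        return True

    def get_count(self, kmer: str) -> int:
        """Multiplicity of a k-mer, canonicalizing first; 0 if absent."""
        canon = canonical_kmer(kmer)
        try:
            return self.counts[canon]
        except KeyError:
            return 0

    def spectrum(self) -> KmerSpectrum:
        return spectrum(self)

    def dump(self, path: str | Path) -> None:
        """Write 'kmer<TAB>count' lines in lexicographic k-mer order."""
        with open(path, "w") as fh:
            for code, mult in zip(self._codes, self._mults):
                fh.write(f"{_decode_kmer(int(code), self.k)}\t{int(mult)}\n")

    # sorted-array views used by assembly evaluation
    @property
    def codes(self) -> np.ndarray:
        return self._codes

    @property
    def multiplicities(self) -> np.ndarray:
        return self._mults


def count_kmers(sequences: Iterable[str], k: int = DEFAULT_K) -> KmerDatabase:
    """Count canonical k-mers over all length-k windows of the sequences.

    Windows containing non-ACGT characters are skipped (tallied in
    ``skipped_windows``); sequences shorter than k contribute nothing.
    Empty input yields an empty database.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seqs = [s for s in sequences if s]
    enc = _encode_sequences(seqs)
    canon, skipped = _canonical_codes(enc, k)
    if canon.size == 0:
        return KmerDatabase(k, np.empty(0, np.int64), np.empty(0, np.int64), skipped)
    codes, mults = np.unique(canon, return_counts=True)
    return KmerDatabase(k, codes, mults.astype(np.int64), skipped)


def spectrum(db: KmerDatabase) -> KmerSpectrum:
    """Multiplicity histogram of a database (m -> distinct k-mers at m)."""
    if db.n_distinct == 0:
        return KmerSpectrum(db.k, {})
    ms, cs = np.unique(db.multiplicities, return_counts=True)
    return KmerSpectrum(db.k, {int(m): int(c) for m, c in zip(ms, cs)})


def read_histo(path: str | Path, k: int = DEFAULT_K) -> KmerSpectrum:
    """Parse a Jellyfish-style histogram: 'multiplicity count' per line.

    The format does not carry k, so the caller supplies it. Multiplicities
    must be strictly increasing; malformed lines raise
    :class:`HistoParseError` naming the line number.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    histogram: dict[int, int] = {}
    last = 0
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 2:
                raise HistoParseError(
                    f"{path}: line {lineno}: expected 2 fields, got {len(fields)}"
                )
            try:
                m, c = int(fields[0]), int(fields[1])
            except ValueError:
                raise HistoParseError(
                    f"{path}: line {lineno}: non-integer field in {line.strip()!r}"
                ) from None
            if m <= last:
                raise HistoParseError(
                    f"{path}: line {lineno}: multiplicity {m} not strictly "
                    f"increasing (previous {last})"
                )
            if c < 0:
                raise HistoParseError(f"{path}: line {lineno}: negative count")
            last = m
            if c:
                histogram[m] = c
    return KmerSpectrum(k, histogram)


def write_histo(spec: KmerSpectrum, path: str | Path) -> None:
    """Write 'multiplicity count' lines in increasing multiplicity order."""
    with open(path, "w") as fh:
        for m in sorted(spec.histogram):
            fh.write(f"{m} {spec.histogram[m]}\n")
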