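"""Merqury-style assembly evaluation: k-mer completeness, consensus QV,
and basic assembly statistics.

The two k-mer measures are deliberately asymmetric, mirroring the Merqury
tool family:

* completeness asks how many *distinct reliable read* k-mers (multiplicity
  above the error cutoff) the assembly contains;
* consensus QV asks how many *positional assembly* k-mers (counted with
  multiplicity) are supported by the reads at all (multiplicity ≥ 1), and
  converts the unsupported fraction into a per-base Phred error estimate via
  P_base = (shared/total)^(1/k), E = 1 − P_base, QV = −10·log10(E).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kmer import KmerDatabase

__all__ = [
    "QVReport",
    "AssemblyStats",
    "kmer_completeness",
    "qv_estimate",
    "qv_from_counts",
    "error_rate_from_qv",
    "assembly_stats",
]


@dataclass
class QVReport:
    k: int
    total_assembly_kmers: int
    shared_kmers: int
    error_rate_E: float
    qv: float
    capped: bool = False


@dataclass
class AssemblyStats:
    total_length_bp: int
    gc_fraction: float
    n_sequences: int
    n50_bp: int
    n90_bp: int


def _membership(queries: np.ndarray, sorted_codes: np.ndarray) -> np.ndarray:
    """Boolean mask: which query codes occur in the sorted unique code array."""
    if sorted_codes.size == 0:
        return np.zeros(queries.shape, dtype=bool)
    idx = np.searchsorted(sorted_codes, queries)
    idx_clipped = np.minimum(idx, sorted_codes.size - 1)
    return (idx < sorted_codes.size) & (sorted_codes[idx_clipped] == queries)


def kmer_completeness(
    assembly_db: KmerDatabase, read_db: KmerDatabase, reliable_cutoff: int = 1
) -> float:
    """Fraction of distinct reliable read k-mers present in the assembly.

    Reliable read k-mers are those with multiplicity ≥ ``reliable_cutoff``;
    in the standard pipeline the cutoff passed here is one above the error
    cutoff found on the read spectrum, so that error k-mers do not deflate
    completeness.
    """
    if assembly_db.k != read_db.k:
        raise ValueError("assembly and read databases use different k")
    reliable = read_db.codes[read_db.multiplicities >= reliable_cutoff]
    if reliable.size == 0:
        raise ValueError("no reliable read k-mers at this cutoff; completeness undefined")
    found = _membership(reliable, assembly_db.codes)
    return float(np.count_nonzero(found)) / float(reliable.size)


def qv_from_counts(shared: int, total: int, k: int, cap: float = 99.0) -> QVReport:
    """Phred consensus QV from shared/total positional assembly k-mer counts."""
    if total <= 0:
        raise ValueError("total assembly k-mers must be positive")
    if shared > total or shared < 0:
        raise ValueError("shared k-mers must lie in [0, total]")
    if shared == total:
        return QVReport(k, total, shared, 0.0, cap, capped=True)
    # E = 1 - (shared/total)^(1/k), evaluated in log space for tiny E
    error = -math.expm1(math.log(shared / total) / k) if shared else 1.0
    return QVReport(k, total, shared, error, -10.0 * math.log10(error))


def qv_estimate(assembly_db: KmerDatabase, read_db: KmerDatabase, cap: float = 99.0) -> QVReport:
    """Consensus QV of an assembly against a read k-mer database.

    Assembly k-mer positions are counted with multiplicity; a position is
    "shared" when its canonical k-mer occurs in the reads at any
    multiplicity. A perfect assembly (no assembly-only k-mers) is reported
    at the configurable QV cap with ``capped=True``.
    """
    if assembly_db.k != read_db.k:
        raise ValueError("assembly and read databases use different k")
    total = assembly_db.total_positions
    if total == 0:
        raise ValueError("empty assembly database")
    present = _membership(assembly_db.codes, read_db.codes)
    shared = int(assembly_db.multiplicities[present].sum())
    return qv_from_counts(shared, total, assembly_db.k, cap=cap)


def _round_sig(x: float, digits: int = 3) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)


def error_rate_from_qv(qv: float) -> tuple[float, int]:
    """Convert a Phred QV to (error rate, "one error in N bases").

    N is the reciprocal error rate rounded to 3 significant figures, e.g.
    QV 33.47 → (4.498e-4, 2220).
    """
    if qv < 0:
        raise ValueError("qv must be >= 0")
    error_rate = 10.0 ** (-qv / 10.0)
    return error_rate, int(_round_sig(1.0 / error_rate, 3))


def assembly_stats(sequences) -> AssemblyStats:
    """Total length, GC fraction (over unambiguous bases), N50 and N90.

    N50 is the length L such that sequences of length ≥ L sum to at least
    half the assembly (descending sort, cumulate, first length reaching the
    threshold); N90 analogously at 90%.
    """
    lengths: list[int] = []
    gc = at = 0
    for seq in sequences:
        if not seq:
            continue
        lengths.append(len(seq))
        s = seq.upper()
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    if not lengths:
        raise ValueError("no non-empty sequences")
    lengths.sort(reverse=True)
    total = sum(lengths)
    cum = np.cumsum(lengths)
    n50 = lengths[int(np.searchsorted(cum, 0.5 * total))]
    n90 = lengths[int(np.searchsorted(cum, 0.9 * total))]
    denom = gc + at
    return AssemblyStats(
        total_length_bp=total,
        gc_fraction=gc / denom if denom else 0.0,
        n_sequences=len(lengths),
        n50_bp=n50,
        n90_bp=n90,
    )
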