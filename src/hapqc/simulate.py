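"""Synthetic diploid genomes, shotgun reads, and purged/unpurged fixtures.

The simulator realises exactly the model under which the pseudo-haplotype
completeness ceiling 1/(2−(1−r)^k) is derived: i.i.d. base composition with
a target GC fraction (no repeats), SNP-only heterozygosity planted
independently per base at rate r, and uniform substitution-error shotgun
reads drawn from both haplotypes and both strands. Every generator is
deterministic given its seed (numpy PCG64 via ``default_rng``).

What this deliberately does NOT emulate: repetitive sequence, indel or
structural heterozygosity, linked SNP clusters, coverage bias, and ONT-like
indel-rich error profiles. Passing tests on these fixtures therefore
validate the arithmetic of the model and its estimators — not their
behaviour on repeat-rich real genomes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kmer import reverse_complement
from .seqio import write_fasta, write_fastq

__all__ = [
    "DiploidTruth",
    "simulate_haploid",
    "mutate_haplotype",
    "simulate_reads",
    "simulate_diploid",
    "make_fixtures",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_LUT = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_LUT[ord(_b)] = _i


@dataclass
class DiploidTruth:
    """Ground-truth record for one simulated diploid scenario."""

    seed: int
    length_bp: int
    gc_target: float
    heterozygosity_r: float
    haplotype_a: str
    haplotype_b: str
    snp_positions: np.ndarray
    read_coverage: float
    read_length: int
    read_error_rate: float
    reads: list[str] = field(default_factory=list, repr=False)

    def metadata(self) -> dict:
        return {
            "seed": self.seed,
            "length_bp": self.length_bp,
            "gc_target": self.gc_target,
            "heterozygosity_r": self.heterozygosity_r,
            "n_snps": int(self.snp_positions.size),
            "read_coverage": self.read_coverage,
            "read_length": self.read_length,
            "read_error_rate": self.read_error_rate,
            "n_reads": len(self.reads),
        }


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def simulate_haploid(length_bp: int, gc_target: float = 0.37, seed=0) -> str:
    """I.i.d. random genome with P(G)+P(C) = gc_target; deterministic per seed."""
    if not 0.0 < gc_target < 1.0:
        raise ValueError("gc_target must be in (0, 1)")
    if length_bp < 1:
        raise ValueError("length_bp must be positive")
    rng = _rng(seed)
    p = np.array(
        [(1 - gc_target) / 2, gc_target / 2, gc_target / 2, (1 - gc_target) / 2]
    )
    codes = rng.choice(4, size=length_bp, p=p).astype(np.uint8)
    return _to_str(codes)


def mutate_haplotype(sequence: str, r: float, seed=0) -> tuple[str, np.ndarray]:
    """Second haplotype: each base substituted independently with probability r.

    A substitution always changes the base (uniform over the 3 alternatives).
    Returns (mutated sequence, sorted array of 0-based SNP positions).
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must be in [0, 1]")
    rng = _rng(seed)
    codes = _BASE_LUT[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)].copy()
    hit = np.flatnonzero(rng.random(codes.size) < r)
    if hit.size:
        shift = rng.integers(1, 4, size=hit.size).astype(np.uint8)
        codes[hit] = (codes[hit] + shift) % 4
    return _to_str(codes), hit


def simulate_reads(
    haplotypes,
    coverage: float,
    read_length: int = 150,
    error_rate: float = 0.0,
    seed=0,
) -> list[str]:
    """Uniform shotgun reads until total bases ≥ coverage × Σ haplotype lengths.

    Each read picks a haplotype, a start, and a strand uniformly at random;
    substitution errors are planted per base at ``error_rate``. Reads are
    returned as plain sequence strings, deterministic given the seed.
    """
    haplotypes = list(haplotypes)
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if any(read_length > len(h) for h in haplotypes):
        raise ValueError("read_length exceeds a haplotype length")
    rng = _rng(seed)
    genome_len = sum(len(h) for h in haplotypes)
    n_reads = math.ceil(coverage * genome_len / read_length)
    hap_idx = rng.integers(0, len(haplotypes), size=n_reads)
    starts = rng.integers(0, np.array([len(haplotypes[i]) for i in hap_idx]) - read_length + 1)
    flip = rng.integers(0, 2, size=n_reads).astype(bool)
    n_errors = (
        rng.binomial(read_length, error_rate, size=n_reads)
        if error_rate > 0
        else np.zeros(n_reads, dtype=int)
    )
    reads: list[str] = []
    for i in range(n_reads):
        seq = haplotypes[hap_idx[i]][starts[i] : starts[i] + read_length]
        if flip[i]:
            seq = reverse_complement(seq)
        if n_errors[i]:
            codes = _BASE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()
            pos = rng.choice(read_length, size=n_errors[i], replace=False)
            codes[pos] = (codes[pos] + rng.integers(1, 4, size=pos.size)) % 4
            seq = _to_str(codes)
        reads.append(seq)
    return reads


def simulate_diploid(
    length_bp: int,
    heterozygosity_r: float,
    gc_target: float = 0.37,
    read_coverage: float = 30.0,
    read_length: int = 150,
    read_error_rate: float = 0.0,
    seed: int = 0,
) -> DiploidTruth:
    """Full scenario: diploid genome plus shotgun reads from both haplotypes.

    ``read_coverage`` is per-haplotype depth; total read bases are
    ≥ coverage × 2 × length_bp (diploid length), matching sequencing a
    diploid sample at that overall depth per haplotype.
    """
    rng = np.random.default_rng(seed)
    hap_a = simulate_haploid(length_bp, gc_target, rng)
    hap_b, snps = mutate_haplotype(hap_a, heterozygosity_r, rng)
    reads = simulate_reads(
        [hap_a, hap_b], read_coverage, read_length, read_error_rate, rng
    )
    return DiploidTruth(
        seed=seed,
        length_bp=length_bp,
        gc_target=gc_target,
        heterozygosity_r=heterozygosity_r,
        haplotype_a=hap_a,
        haplotype_b=hap_b,
        snp_positions=snps,
        read_coverage=read_coverage,
        read_length=read_length,
        read_error_rate=read_error_rate,
        reads=reads,
    )


def make_fixtures(truth: DiploidTruth, outdir: str | Path) -> dict[str, Path]:
    """Write purged/unpurged assemblies, reads, and the truth record.

    The "purged" assembly is haplotype A alone (a correct pseudo-haplotype);
    the "unpurged" assembly concatenates both haplotypes, emulating a
    diploid assembly whose haplotigs were never removed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "purged_assembly": outdir / "purged.fasta",
        "unpurged_assembly": outdir / "unpurged.fasta",
        "reads": outdir / "reads.fastq",
        "truth_record": outdir / "truth.json",
    }
    write_fasta([("hapA", truth.haplotype_a)], paths["purged_assembly"])
    write_fasta(
        [("hapA", truth.haplotype_a), ("hapB", truth.haplotype_b)],
        paths["unpurged_assembly"],
    )
    write_fastq(
        ((f"read{i+1}", seq) for i, seq in enumerate(truth.reads)), paths["reads"]
    )
    paths["truth_record"].write_text(json.dumps(truth.metadata(), indent=2) + "\n")
    return paths
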