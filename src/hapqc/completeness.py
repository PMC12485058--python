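"""Theoretical pseudo-haplotype completeness model and purging verdicts.

A pseudo-haplotype assembly of a diploid genome deliberately carries only one
allele at each heterozygous locus, so it can never contain all distinct
k-mers seen in diploid sequencing reads. With per-base heterozygosity r and
k-mer size k, a window is allele-identical on both haplotypes with
probability (1−r)^k. The diploid read set then holds ≈ G·(2 − (1−r)^k)
distinct k-mers against the single haplotype's ≈ G, giving the ceiling

    maximum completeness = 1 / (2 − (1−r)^k),

which lies in (0.5, 1] and decreases with both r and k. Because the assembly
may miss some k-mers even before purging, the ceiling is scaled by the
pre-purge completeness s:  expected = s · maximum.

Comparing an assembly's observed completeness with this expectation (plus,
optionally, its size against the haploid genome size) diagnoses the purging
step: observed far above expectation means retained haplotigs
(INCOMPLETE_PURGING, classically corroborated by an assembly ~twice the
haploid size); observed far below means genuine sequence was discarded
(OVER_PURGED).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

__all__ = [
    "CompletenessInputs",
    "CompletenessReport",
    "CONSISTENT",
    "INCOMPLETE_PURGING",
    "OVER_PURGED",
    "DEFAULT_TOLERANCE_PP",
    "DEFAULT_SIZE_BAND",
    "max_pseudohaplotype_completeness",
    "expected_pseudohaplotype_completeness",
    "het_kmer_fraction",
    "purging_verdict",
]

CONSISTENT = "CONSISTENT"
INCOMPLETE_PURGING = "INCOMPLETE_PURGING"
OVER_PURGED = "OVER_PURGED"

DEFAULT_TOLERANCE_PP = 5.0
DEFAULT_SIZE_BAND = (0.8, 1.25)


def _check_rk(r: float, k: int) -> None:
    if not 0.0 <= r < 1.0:
        raise ValueError(f"heterozygosity r must be in [0, 1), got {r}")
    if int(k) != k or k < 1:
        raise ValueError(f"k must be a positive integer, got {k}")


def max_pseudohaplotype_completeness(r: float, k: int = 21) -> float:
    """Theoretical ceiling 1/(2 − (1−r)^k) on pseudo-haplotype completeness.

    Strictly decreasing in r (fixed k) and in k (fixed r > 0); range (0.5, 1].
    """
    _check_rk(r, k)
    return 1.0 / (2.0 - (1.0 - r) ** k)


def expected_pseudohaplotype_completeness(s: float, r: float, k: int = 21) -> float:
    """Ceiling scaled by the pre-purge capture rate s: s·maximum."""
    if not 0.0 < s <= 1.0:
        raise ValueError(f"pre-purge completeness s must be in (0, 1], got {s}")
    return s * max_pseudohaplotype_completeness(r, k)


def het_kmer_fraction(r: float, k: int = 21) -> float:
    """Probability 1 − (1−r)^k that a k-mer window spans ≥1 heterozygous site."""
    _check_rk(r, k)
    return 1.0 - (1.0 - r) ** k


@dataclass
class CompletenessInputs:
    """Per-genome inputs to the purging diagnosis (all rates as fractions)."""

    heterozygosity_r: float
    prepurge_completeness_s: float
    observed_completeness: Optional[float] = None
    k: int = 21
    assembly_size_bp: Optional[float] = None
    haploid_size_bp: Optional[float] = None


@dataclass
class CompletenessReport:
    """One diagnosis row: model values, deviation, and verdict."""

    inputs: CompletenessInputs
    maximum: float
    expected: float
    deviation_pp: float
    size_ratio: Optional[float]
    verdict: str
    size_corroborated: bool = False


def purging_verdict(
    inputs: CompletenessInputs,
    tolerance_pp: float = DEFAULT_TOLERANCE_PP,
    size_band: tuple[float, float] = DEFAULT_SIZE_BAND,
) -> CompletenessReport:
    """Judge whether purging of an assembly was consistent with theory.

    ``deviation = (observed − expected) · 100`` percentage points. Deviation
    above ``tolerance_pp`` (or an assembly/haploid size ratio above the band)
    flags INCOMPLETE_PURGING; deviation below ``−tolerance_pp`` (or a size
    ratio below the band) flags OVER_PURGED; otherwise CONSISTENT. When both
    the deviation and the size ratio point at incomplete purging the report
    is marked ``size_corroborated``.
    """
    if inputs.observed_completeness is None:
        raise ValueError("observed_completeness is required for a verdict")
    if not 0.0 <= inputs.observed_completeness <= 1.0:
        raise ValueError("observed_completeness must be in [0, 1]")
    maximum = max_pseudohaplotype_completeness(inputs.heterozygosity_r, inputs.k)
    expected = expected_pseudohaplotype_completeness(
        inputs.prepurge_completeness_s, inputs.heterozygosity_r, inputs.k
    )
    deviation = (inputs.observed_completeness - expected) * 100.0

    size_ratio: Optional[float] = None
    if inputs.assembly_size_bp is not None and inputs.haploid_size_bp is not None:
        if inputs.haploid_size_bp <= 0:
            raise ValueError("haploid_size_bp must be positive")
        if inputs.assembly_size_bp <= 0:
            raise ValueError("assembly_size_bp must be positive")
        size_ratio = inputs.assembly_size_bp / inputs.haploid_size_bp

    low, high = size_band
    oversized = size_ratio is not None and size_ratio > high
    undersized = size_ratio is not None and size_ratio < low
    if deviation > tolerance_pp or oversized:
        verdict = INCOMPLETE_PURGING
    elif deviation < -tolerance_pp or undersized:
        verdict = OVER_PURGED
    else:
        verdict = CONSISTENT
    corroborated = verdict == INCOMPLETE_PURGING and deviation > tolerance_pp and oversized
    return CompletenessReport(
        inputs=inputs,
        maximum=maximum,
        expected=expected,
        deviation_pp=deviation,
        size_ratio=size_ratio,
        verdict=verdict,
        size_corroborated=corroborated,
    )
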