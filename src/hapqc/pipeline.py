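"""End-to-end analysis: reads → spectrum → profile → completeness → verdict.

This is the programmatic equivalent of running the CLI stages in order with
one k throughout: count read k-mers, find the error cutoff, profile the
genome, measure assembly completeness/QV against the reads, and judge the
purging of a candidate assembly against the model expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .completeness import (
    DEFAULT_SIZE_BAND,
    DEFAULT_TOLERANCE_PP,
    CompletenessInputs,
    CompletenessReport,
    purging_verdict,
)
from .evaluate import QVReport, kmer_completeness, qv_estimate
from .kmer import DEFAULT_K, KmerDatabase, count_kmers
from .profile import GenomeProfile, find_error_cutoff, fit_profile

__all__ = ["AssemblyAssessment", "build_read_db", "assess_assembly"]


@dataclass
class AssemblyAssessment:
    """Everything the pipeline derives for one candidate assembly."""

    profile: GenomeProfile
    reliable_cutoff: int
    prepurge_completeness_s: float
    observed_completeness: float
    qv: QVReport
    report: CompletenessReport


def build_read_db(reads, k: int = DEFAULT_K) -> KmerDatabase:
    return count_kmers(reads, k)


def assess_assembly(
    candidate_seqs,
    prepurge_seqs,
    read_db: KmerDatabase,
    k: int = DEFAULT_K,
    tolerance_pp: float = DEFAULT_TOLERANCE_PP,
    size_band: tuple[float, float] = DEFAULT_SIZE_BAND,
    profile: Optional[GenomeProfile] = None,
) -> AssemblyAssessment:
    """Assess a candidate (purged) assembly against reads and the model.

    ``prepurge_seqs`` is the assembly before haplotig removal; its
    completeness provides the scaling factor s. Heterozygosity and haploid
    size come from the read-spectrum profile (or a caller-supplied one).
    Reliable read k-mers are those strictly above the error cutoff.
    """
    candidate = list(candidate_seqs)
    prepurge = list(prepurge_seqs)
    spec = read_db.spectrum()
    if profile is None:
        profile = fit_profile(spec, k)
    cutoff = find_error_cutoff(spec)
    reliable_cutoff = cutoff + 1

    candidate_db = count_kmers(candidate, k)
    prepurge_db = count_kmers(prepurge, k)
    s = kmer_completeness(prepurge_db, read_db, reliable_cutoff)
    observed = kmer_completeness(candidate_db, read_db, reliable_cutoff)
    qv = qv_estimate(candidate_db, read_db)

    inputs = CompletenessInputs(
        heterozygosity_r=profile.heterozygosity_r,
        prepurge_completeness_s=s,
        observed_completeness=observed,
        k=k,
        assembly_size_bp=sum(len(c) for c in candidate),
        haploid_size_bp=profile.haploid_size_G,
    )
    report = purging_verdict(inputs, tolerance_pp=tolerance_pp, size_band=size_band)
    return AssemblyAssessment(
        profile=profile,
        reliable_cutoff=reliable_cutoff,
        prepurge_completeness_s=s,
        observed_completeness=observed,
        qv=qv,
        report=report,
    )
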