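"""Shared fixtures: hypothesis settings and the simulated diploid grid.

The grid fixture runs the full pipeline (simulate → count → profile →
completeness → verdict) for r ∈ {0.5%, 1.5%, 4.5%} × seeds 1..10 on 1 Mb
genomes with 30x error-free reads per haplotype, and caches only scalar
summaries. It is session-scoped because the read k-mer counting dominates
the suite's runtime.
"""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

GRID_R = (0.005, 0.015, 0.045)
GRID_SEEDS = tuple(range(1, 11))
GRID_LENGTH = 1_000_000


@pytest.fixture(scope="session")
def sim_grid():
    """Scalar pipeline results for every (r, seed) simulation cell."""
    from hapqc.completeness import max_pseudohaplotype_completeness
    from hapqc.evaluate import kmer_completeness
    from hapqc.kmer import count_kmers
    from hapqc.pipeline import assess_assembly
    from hapqc.profile import find_error_cutoff, fit_profile
    from hapqc.simulate import simulate_diploid

    records = []
    scenario_reports = {}
    for r in GRID_R:
        for seed in GRID_SEEDS:
            truth = simulate_diploid(GRID_LENGTH, r, seed=seed)
            read_db = count_kmers(truth.reads, 21)
            spec = read_db.spectrum()
            cutoff = find_error_cutoff(spec)
            prof = fit_profile(spec, 21)
            hap_a_db = count_kmers([truth.haplotype_a], 21)
            union_db = count_kmers([truth.haplotype_a, truth.haplotype_b], 21)
            obs_hap_a = kmer_completeness(hap_a_db, read_db, cutoff + 1)
            obs_union = kmer_completeness(union_db, read_db, cutoff + 1)
            records.append(
                {
                    "r": r,
                    "seed": seed,
                    "model_max": max_pseudohaplotype_completeness(r, 21),
                    "obs_hap_a": obs_hap_a,
                    "obs_union": obs_union,
                    "r_hat": prof.heterozygosity_r,
                    "g_hat": prof.haploid_size_G,
                    "length": GRID_LENGTH,
                }
            )
            if seed == 1 and r in (0.015, 0.045):
                both = [truth.haplotype_a, truth.haplotype_b]
                scenario_reports[r] = {
                    "purged": assess_assembly([truth.haplotype_a], both, read_db),
                    "unpurged": assess_assembly(both, both, read_db),
                }
    return {"records": records, "scenarios": scenario_reports}
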