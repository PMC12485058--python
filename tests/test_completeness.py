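"""Closed-form completeness model, verdicts, and the combinatorial oracle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hapqc.completeness import (
    CONSISTENT,
    INCOMPLETE_PURGING,
    OVER_PURGED,
    CompletenessInputs,
    expected_pseudohaplotype_completeness,
    het_kmer_fraction,
    max_pseudohaplotype_completeness,
    purging_verdict,
)
from hapqc.datasets import load_manihot_survey
from hapqc.kmer import count_kmers
from hapqc.simulate import mutate_haplotype, simulate_haploid

# ---------------------------------------------------------------- formulas


@pytest.mark.parametrize(
    "r,k,expected,places",
    [
        (0.0125, 21, 0.8116, 4),  # printed survey value
        (0.0, 21, 1.0, 12),
        (0.020, 21, 0.743, 3),  # low end of the published theoretical range
        (0.0151, 21, 0.7852, 4),  # printed survey value
    ],
)
def test_maximum_completeness_examples(r, k, expected, places):
    assert max_pseudohaplotype_completeness(r, k) == pytest.approx(
        expected, abs=0.5 * 10**-places
    )


@pytest.mark.parametrize(
    "s,r,expected",
    [
        (0.940100, 0.0125, 0.7630),
        (1.0, 0.0, 1.0),
        (0.940525, 0.0151, 0.7385),
    ],
)
def test_expected_completeness_examples(s, r, expected):
    assert expected_pseudohaplotype_completeness(s, r, 21) == pytest.approx(
        expected, abs=5e-5
    )


def test_het_kmer_fraction_values():
    assert het_kmer_fraction(0.0, 21) == 0.0
    assert het_kmer_fraction(0.015, 21) == pytest.approx(0.27195, abs=5e-6)
    # algebraic inverse round trip
    frac = het_kmer_fraction(0.03, 21)
    assert 1 - (1 - frac) ** (1 / 21) == pytest.approx(0.03, abs=1e-12)


@pytest.mark.parametrize(
    "fn,kwargs",
    [
        (max_pseudohaplotype_completeness, {"r": -0.1, "k": 21}),
        (max_pseudohaplotype_completeness, {"r": 1.0, "k": 21}),
        (max_pseudohaplotype_completeness, {"r": 0.01, "k": 0}),
        (expected_pseudohaplotype_completeness, {"s": 0.0, "r": 0.01, "k": 21}),
        (expected_pseudohaplotype_completeness, {"s": 1.2, "r": 0.01, "k": 21}),
    ],
)
def test_domain_errors(fn, kwargs):
    with pytest.raises(ValueError):
        fn(**kwargs)


def test_monotonicity_grid():
    rs = np.arange(0.0, 0.0501, 0.001)
    for k in (15, 21, 31):
        vals = [max_pseudohaplotype_completeness(r, k) for r in rs]
        assert all(a > b for a, b in zip(vals, vals[1:]))
    for r in rs[1:]:
        by_k = [max_pseudohaplotype_completeness(r, k) for k in (15, 21, 31)]
        assert by_k[0] > by_k[1] > by_k[2]


@given(
    st.floats(min_value=0.0, max_value=0.5),
    st.floats(min_value=1e-6, max_value=1.0),
    st.integers(min_value=1, max_value=31),
)
def test_bounds_properties(r, s, k):
    maximum = max_pseudohaplotype_completeness(r, k)
    assert 0.5 < maximum <= 1.0
    assert expected_pseudohaplotype_completeness(s, r, k) <= maximum + 1e-15


# ---------------------------------------------------------------- verdicts


def test_verdict_wildtype_row_is_incomplete_and_size_corroborated():
    inputs = CompletenessInputs(
        heterozygosity_r=0.0456,
        prepurge_completeness_s=0.963812,
        observed_completeness=0.897580,
        assembly_size_bp=1299.6e6,
        haploid_size_bp=659e6,
    )
    rep = purging_verdict(inputs)
    assert rep.verdict == INCOMPLETE_PURGING
    assert rep.size_corroborated
    assert rep.deviation_pp == pytest.approx(30.4, abs=0.2)
    assert rep.size_ratio == pytest.approx(1.97, abs=0.01)


def test_verdict_consistent_and_overpurged_cases():
    expected = expected_pseudohaplotype_completeness(0.94, 0.015, 21)
    base = dict(heterozygosity_r=0.015, prepurge_completeness_s=0.94)
    ok = purging_verdict(
        CompletenessInputs(
            observed_completeness=expected,
            assembly_size_bp=1e6,
            haploid_size_bp=1e6,
            **base,
        )
    )
    assert ok.verdict == CONSISTENT and ok.deviation_pp == pytest.approx(0.0)
    low = purging_verdict(
        CompletenessInputs(observed_completeness=expected - 0.10, **base)
    )
    assert low.verdict == OVER_PURGED
    shrunk = purging_verdict(
        CompletenessInputs(
            observed_completeness=expected,
            assembly_size_bp=0.7e6,
            haploid_size_bp=1e6,
            **base,
        )
    )
    assert shrunk.verdict == OVER_PURGED


def test_verdict_requires_observed_and_valid_sizes():
    base = dict(heterozygosity_r=0.01, prepurge_completeness_s=0.95)
    with pytest.raises(ValueError):
        purging_verdict(CompletenessInputs(**base))
    with pytest.raises(ValueError):
        purging_verdict(
            CompletenessInputs(
                observed_completeness=0.8,
                assembly_size_bp=1e6,
                haploid_size_bp=0.0,
                **base,
            )
        )


# ------------------------------------------------- combinatorial oracle


def test_distinct_kmer_ratio_matches_ceiling_on_tiny_diploids():
    """On 10 kb SNP-mutated diploids, |hapA k-mers| / |union k-mers| equals
    1/(2-(1-r)^k) within 1.5 pp averaged over seeds 1-10."""
    k, r = 21, 0.015
    deviations = []
    for seed in range(1, 11):
        hap_a = simulate_haploid(10_000, 0.37, seed=seed)
        hap_b, _ = mutate_haplotype(hap_a, r, seed=seed + 100)
        a = count_kmers([hap_a], k)
        union = count_kmers([hap_a, hap_b], k)
        ratio = a.n_distinct / union.n_distinct
        deviations.append(ratio - max_pseudohaplotype_completeness(r, k))
    assert abs(np.mean(deviations)) < 0.015


# ---------------------------------------------- printed survey agreement


def test_survey_maxima_within_rounding_of_formula():
    """Recomputed model columns agree with the published ones to 0.15 pp;
    the residual traces to the printed r being rounded to 2 d.p."""
    df = load_manihot_survey()
    for _, row in df.iterrows():
        maximum = 100 * max_pseudohaplotype_completeness(float(row.r_percent) / 100, 21)
        expected = float(row.s_percent) / 100 * maximum
        assert maximum == pytest.approx(float(row.reported_maximum_percent), abs=0.15)
        assert expected == pytest.approx(float(row.reported_expected_percent), abs=0.15)
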