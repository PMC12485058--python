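"""Bundled example data.

The package ships the published 21-mer completeness survey of ten *Manihot*
(cassava) pseudo-haplotype assemblies: per-genotype heterozygosity r,
pre-purge completeness s, observed post-purge completeness, assembly sizes,
and — for the one genotype whose haploid genome size is reported alongside
(the highly heterozygous *M. glaziovii* WildType) — the haploid size
estimate. The ``reported_maximum_percent``/``reported_expected_percent``
columns carry the survey's own model values for cross-checking; the model
columns this package computes are derived fresh from r and s.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_manihot_survey"]


def load_manihot_survey() -> pd.DataFrame:
    """The ten-genome *Manihot* k=21 completeness survey as a DataFrame."""
    path = resources.files("hapqc").joinpath("data/manihot_k21_survey.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", dtype=str)
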