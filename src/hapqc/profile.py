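"""Genome profiling from a read k-mer spectrum.

A whole-genome read set from a diploid sample produces a k-mer multiplicity
histogram with (up to) three components: a low-multiplicity spike of
sequencing-error k-mers, a peak near the haploid k-mer coverage λ made of
k-mers overlapping a heterozygous site (present on one haplotype only), and a
peak near 2λ of homozygous k-mers present on both haplotypes. From the
positions and distinct-k-mer masses of these components this module estimates

* the haploid genome size  G = Σ_{m > cutoff} m·hist[m] / (hom coverage),
* the per-base heterozygosity r from the het/hom distinct-k-mer mass ratio
  ρ = D_het / D_hom.  Under independent per-base heterozygosity a k-mer
  window is homozygous with probability q = (1−r)^k, giving D_hom ≈ G·q and
  D_het ≈ 2·G·(1−q), hence ρ = 2(1−q)/q and r = 1 − (2/(ρ+2))^(1/k).

This is a modal-peak simplification of full spectrum-mixture fitters such as
GenomeScope2: no negative-binomial mixture, no duplication terms, diploid
only. It is intended for desk-scale validation work, not for publication
figures on real sequencing data.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from .kmer import KmerSpectrum

__all__ = [
    "GenomeProfile",
    "UnfittableSpectrumError",
    "find_error_cutoff",
    "fit_profile",
    "het_hom_ratio",
    "heterozygosity_from_ratio",
]


class UnfittableSpectrumError(ValueError):
    """Raised when no genomic peak can be located in a spectrum."""


@dataclass
class GenomeProfile:
    """Estimated genome characteristics from a read k-mer spectrum.

    ``het_coverage_lambda`` and ``hom_coverage`` are the (refined) positions
    of the 1-copy and 2-copy peaks in multiplicity units; ``error_cutoff`` is
    the multiplicity at/below which k-mers are treated as sequencing-error
    artifacts. Rates are fractions; formatting as percent happens only at the
    reporting boundary.
    """

    k: int
    haploid_size_G: float
    heterozygosity_r: float
    het_coverage_lambda: float
    hom_coverage: float
    error_cutoff: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def het_hom_ratio(r: float, k: int) -> float:
    """ρ = D_het/D_hom = 2((1−r)^(−k) − 1) implied by heterozygosity r."""
    if not 0 <= r < 1:
        raise ValueError("r must be in [0, 1)")
    return 2.0 * ((1.0 - r) ** (-k) - 1.0)

def heterozygosity_from_ratio(rho: float, k: int) -> float:
    """Inverse of :func:`het_hom_ratio`: r = 1 − (2/(ρ+2))^(1/k)."""
    if rho < 0:
        raise ValueError("rho must be >= 0")
    return 1.0 - (2.0 / (rho + 2.0)) ** (1.0 / k)


def find_error_cutoff(spec: KmerSpectrum) -> int:
    """Multiplicity of the first local minimum scanning up from m=1.

    Separates the sequencing-error spike from genomic k-mers. If counts never
    fall then rise again before the global maximum (e.g. error-free reads),
    returns the fallback cutoff 2.
    """
    if not spec.histogram or spec.n_distinct == 0:
        raise UnfittableSpectrumError("empty spectrum")
    c = spec.dense_counts()
    m0 = int(np.nonzero(c)[0][0])
    # an error spike means counts *descend* from the lowest multiplicity;
    # a spectrum that rises from the start has no spike to cut away
    if m0 + 1 >= c.size or c[m0 + 1] >= c[m0]:
        return 2
    for m in range(m0 + 1, c.size - 1):
        if c[m - 1] > c[m] and c[m] <= c[m + 1] and c[m + 1 :].max() > c[m]:
            return m
    return 2


def _local_peak(smooth: np.ndarray, lo: int, hi: int, min_height: float) -> int | None:
    """Strict interior local maximum of smooth within [lo, hi], or None."""
    lo = max(lo, 1)
    hi = min(hi, smooth.size - 2)
    if hi <= lo:
        return None
    window = smooth[lo : hi + 1]
    i = lo + int(np.argmax(window))
    if smooth[i] < min_height or i in (lo, hi):
        return None
    if smooth[i] < smooth[i - 1] or smooth[i] < smooth[i + 1]:
        return None
    return i


def _centroid(c: np.ndarray, lo: int, hi: int) -> float:
    """Count-weighted mean multiplicity over [lo, hi)."""
    m = np.arange(lo, min(hi, c.size))
    w = c[lo : min(hi, c.size)]
    total = w.sum()
    if total == 0:
        return float("nan")
    return float((m * w).sum() / total)


def fit_profile(spec: KmerSpectrum, k: int | None = None) -> GenomeProfile:
    """Fit a diploid genome profile to a read k-mer spectrum.

    Locates the genomic peak(s) by smoothed argmax (moving average, window
    3) above the error cutoff, pairs the het peak λ with the hom peak near
    2λ, and refines each to the count-weighted mean within its window. The
    het/hom split point is the equal-density point of two Poisson-shaped
    peaks, √(λ·2λ). A single-peaked spectrum is treated as effectively
    homozygous (r = 0), with the peak read as the 2-copy peak. Repeat k-mers
    above 1.5·hom contribute to the size numerator but not to the
    heterozygosity ratio.
    """
    if k is None:
        k = spec.k
    cutoff = find_error_cutoff(spec)
    c = spec.dense_counts().astype(float)
    if c.size <= cutoff + 1 or c[cutoff + 1 :].sum() == 0:
        raise UnfittableSpectrumError("no genomic k-mers above the error cutoff")

    smooth = np.convolve(c, np.ones(3) / 3.0, mode="same")
    genomic = smooth.copy()
    genomic[: cutoff + 1] = 0.0
    p = int(np.argmax(genomic))
    if genomic[p] <= 0:
        raise UnfittableSpectrumError("no genomic peak above the error cutoff")

    min_h = 0.02 * smooth[p]
    upper = _local_peak(smooth, round(1.6 * p), round(2.6 * p), min_h)
    lower = _local_peak(smooth, max(cutoff + 1, round(0.4 * p)), round(0.65 * p), min_h)

    raw = spec.dense_counts().astype(float)
    if upper is not None:
        lam_bin, hom_bin = p, upper
    elif lower is not None:
        lam_bin, hom_bin = lower, p
    else:
        lam_bin, hom_bin = None, p  # single peak: homozygous 2-copy peak

    if lam_bin is None:
        hom_lo = max(cutoff + 1, round(0.5 * hom_bin))
        hom_hi = round(1.5 * hom_bin)
        hom = _centroid(raw, hom_lo, hom_hi)
        lam = hom / 2.0
        r = 0.0
    else:
        split = round(math.sqrt(lam_bin * hom_bin))
        het_lo = max(cutoff + 1, round(0.5 * lam_bin))
        hom_hi = round(1.5 * hom_bin)
        d_het = float(raw[het_lo:split].sum())
        d_hom = float(raw[split : min(hom_hi, raw.size)].sum())
        if d_hom == 0:
            raise UnfittableSpectrumError("empty homozygous peak window")
        lam = _centroid(raw, het_lo, split)
        hom = _centroid(raw, split, hom_hi)
        r = heterozygosity_from_ratio(d_het / d_hom, k)

    mass = float(sum(m * cnt for m, cnt in spec.histogram.items() if m > cutoff))
    return GenomeProfile(
        k=k,
        haploid_size_G=mass / hom,
        heterozygosity_r=r,
        het_coverage_lambda=lam,
        hom_coverage=hom,
        error_cutoff=cutoff,
    )
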