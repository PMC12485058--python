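# Methods

## Scope and model

`hapqc` quantifies how complete a purged (pseudo-haplotype) assembly of a
diploid genome *should* be, measures how complete it *is*, and judges the
difference. All quantities are k-mer based; k defaults to 21 everywhere and
must be identical across the stages of one analysis (2-bit packed counting
supports k ≤ 31).

The core model assumes independent per-base heterozygosity: each site
differs between the two haplotypes with probability r, independently of its
neighbours, and the genome is effectively repeat-free at the k-mer level
(every genomic k-mer is unique). Under these assumptions a k-base window is
haplotype-identical with probability q = (1−r)^k, the diploid read set
contains ≈ G·(2−q) distinct k-mers for haploid size G, one haplotype
contains ≈ G of them, and the completeness ceiling of a perfect
pseudo-haplotype is 1/(2−q). Indel heterozygosity, linked SNP clusters and
repeat-induced k-mer sharing are deliberately outside the model; on real
genomes they make the ceiling an approximation, which is why the verdict
uses a tolerance band rather than an equality test.

## Canonical k-mer counting

Counting is canonical (lexicographic min of a window and its reverse
complement, the Jellyfish convention) so results are strand-independent and
histograms are comparable to Jellyfish `-C` output. Windows containing any
non-ACGT character are skipped silently and tallied in `skipped_windows`;
input is uppercased, so soft-masked FASTA is handled. Counting is in-memory
(sorted int64 code arrays), sized for desk-scale work — up to tens of
megabases of simulated or bacterial-scale sequence — not for disk-backed
counting of real HiFi/Illumina runs. The scan itself is a numba-compiled
rolling 2-bit hash: O(1) work per position, with invalid-character and
sequence-boundary state tracked in the same pass.

## Spectrum profiling

The read spectrum is modelled as an error component at low multiplicity
plus two Poisson-shaped genomic peaks: haplotype-specific k-mers near the
per-haplotype k-mer coverage λ and homozygous k-mers near 2λ.

**Error cutoff.** The cutoff is the first local minimum of the histogram
scanning upward — but only when counts *descend* from the lowest occupied
multiplicity, i.e. when an error spike actually exists. Otherwise (e.g.
error-free simulations) the fallback cutoff is 2. Without the descent
guard, a clean two-peak spectrum would hand back the between-peaks valley
and swallow the het peak.

**Peak pairing.** The global smoothed maximum (moving average, window 3)
above the cutoff is taken as one genomic peak; a companion is sought as a
strict interior local maximum in [1.6p, 2.6p] (upper) or [0.4p, 0.65p]
(lower) with height ≥ 2% of the main peak. Whichever companion exists
fixes the (λ, 2λ) pairing. A single-peaked spectrum is read as effectively
homozygous: the peak is the 2-copy peak, r = 0, λ = peak/2. (Treating a
lone peak as the 1-copy peak would halve the size estimate for
homozygous samples.)

**Peak refinement.** Each peak position is refined from the modal bin to
the count-weighted mean multiplicity within its window. The raw integer
mode of a Poisson-shaped peak ties between ⌊λ⌋ and λ, which alone would
inject ~1/λ (~2% at 30x) of noise into the size estimate; the centroid
removes that without fitting a mixture.

**Het/hom windows.** Distinct-k-mer masses D_het and D_hom are summed over
non-overlapping windows split at the equal-density point of the two
Poisson peaks, √(λ·2λ) (outer bounds 0.5λ and 1.5·hom). Overlapping
per-peak windows of the form [0.5p, 1.5p) would double-count the region
between λ and 1.5λ and bias r̂ low by >20% at r = 1.5%. K-mers above
1.5·hom (repeats) are excluded from the ratio but kept in the size
numerator, where they belong.

**Estimates.** Ĝ = Σ_{m>cutoff} m·hist[m] / hom; ρ = D_het/D_hom;
r̂ = 1 − (2/(ρ+2))^(1/k), the exact inverse of ρ(r) = 2((1−r)^(−k) − 1)
implied by the window model. This is a deliberately light replacement for
negative-binomial mixture fitters (GenomeScope2): no overdispersion, no
duplication terms, diploid only, no confidence intervals. On the
simulations it recovers r within ~10% relative error and G within ~3%;
it is not expected to reproduce published estimates on real read sets.

## Completeness, QV and the verdict

Completeness and QV follow the Merqury conventions, including their
asymmetry: completeness is the fraction of *distinct reliable read* k-mers
(multiplicity strictly above the error cutoff) found in the assembly; QV
counts *positional* assembly k-mers (with multiplicity) and calls one
supported if it occurs in the reads at all. The per-base accuracy is
P = (shared/total)^(1/k), E = 1 − P (evaluated via expm1/log for tiny E),
QV = −10·log10(E), capped at 99 with an explicit flag when no
assembly-only k-mers exist. "One error in N bases" reports 1/E rounded to
3 significant figures. N50/N90 use the descending-cumulative "sum ≥
threshold" convention; GC excludes ambiguous bases from the denominator.

The verdict compares observed with expected completeness:
deviation = (observed − expected)·100 pp. Defaults: tolerance 5 pp, size
band 0.8–1.25 on assembly/haploid size. Deviation above tolerance (or an
oversized assembly) ⇒ INCOMPLETE_PURGING, marked `size_corroborated` when
both signals agree; deviation below −tolerance (or an undersized assembly)
⇒ OVER_PURGED; otherwise CONSISTENT. The thresholds are package-defined
defaults — the phenomenon they detect (a near-complete, near-double-size
"purged" assembly) sits an order of magnitude beyond them — and are
configurable everywhere they appear.

## Simulator

The generators realise the model's assumptions exactly: i.i.d. bases at a
target GC (default 0.37, a typical euphorbia-family composition), SNP-only
mutation at rate r with uniform choice among the three alternative bases,
and uniform-coverage substitution-error reads (default 150 bp, 30x per
haplotype, error-free) drawn from both haplotypes and strands until
coverage × diploid length bases are emitted. Everything is deterministic
given a seed (numpy PCG64). Fixture sets pair a "purged" assembly
(haplotype A) with an "unpurged" one (both haplotypes) so the verdict
machinery can be exercised with known truth.

Because the simulator omits repeats, indels, coverage bias and realistic
error profiles, green tests demonstrate the correctness of the arithmetic
and the estimators under the model — not performance on repeat-rich real
data, where spectrum fitting is genuinely harder.

## Numerical and design notes

- Rates are fractions internally; percent formatting (2 d.p. for model
  columns, input precision echoed for observed values) happens only at the
  reporting boundary.
- The bundled ten-genome cassava survey carries a haploid size only for
  the wild genotype, the one genome whose haploid estimate is reported
  alongside its assembly size; the other rows are judged on deviation
  alone.
- Recomputing the survey's model columns from its printed (2 d.p.) r
  values reproduces the printed maxima/expectations within 0.15 pp; the
  residual is rounding of r upstream of the published table, not a model
  difference.
- Validation problem sizes: 1 Mb genomes × seeds 1–10 × r ∈ {0.5%, 1.5%,
  4.5%} at 30x per haplotype for model and estimator recovery; 10 kb
  genomes for the combinatorial ceiling oracle; k ≤ 7 against a
  brute-force counter. These sizes give three-sigma statistical headroom
  on every asserted tolerance while keeping the suite desk-scale.
- CLI exit codes: 0 success, 2 usage error, 1 runtime error.

## Known limitations

Diploid only; SNP-only heterozygosity model; in-memory counting; no
negative-binomial spectrum fitting or confidence intervals; no trio/hap-mer
phasing analysis; no per-window QV tracks.
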