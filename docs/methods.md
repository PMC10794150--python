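# Methods

## Scoring model

Scoring operates on per-sample variant frequencies, `f = c / N`, where `N` is
the sample's observed total count. The analysis assumes a single selection
round with one positive, one negative and one input condition, each in one or
more sequencing replicates; rounds of an iterative campaign are scored
independently.

**Replicate merging.** Only variants observed in *every* positive replicate
are scored (AND merge). The rationale is asymmetric coverage: a real signal
must reproduce across positive replicates, whereas a highly enriched variant
may legitimately be missing from the negative or input pools. Retained
variants missing from a negative or input replicate therefore receive a
placeholder of 0.95 counts in that replicate (OR merge). The placeholder is
applied in count space and divided by the replicate's *observed* total — it
is not added to the total, which would shift every other frequency in the
sample. The input condition receives placeholders on the same footing as the
negative condition. With 0 < 0.95 < 1, a placeholder is always "worse than
seen once, better than impossible": selectivity computed from a placeholder
strictly exceeds the selectivity that an observed count of 1 would give, and
it decreases monotonically as observed negative counts grow.

**Scores.** Enrichment and negative enrichment are quotients of mean
frequencies (mean-then-quotient, not the mean of per-replicate quotients):
`E = mean(f⁺)/mean(f⁰)`, `E⁻ = mean(f⁻)/mean(f⁰)`. Selectivity is
`S = mean(f⁺)/mean(f⁻)`, which equals `E/E⁻` identically — the input
frequency cancels, and the test suite asserts the identity to 1e-12 relative.
The dispersion error is the coefficient of variation of the positive-replicate
frequencies with the sample (n−1) standard deviation; it quantifies replicate
irreproducibility. With a single positive replicate the dispersion is
undefined: it is reported as 0, flagged `dispersion_defined = False`, and the
dispersion filter is bypassed with a warning.

**Hit calling.** Hits satisfy `E ≥ 5` and `S ≥ 10` with inclusive bounds, and
`D ≤ dispersion_max`. The enrichment and selectivity thresholds follow the
characterisation cut-off used in practice for these selections; the
dispersion ceiling is an empirical choice with no canonical value, so it
defaults to 1.0 (replicate scatter as large as the mean) and is exposed as
configuration. Variants whose key contains `*` (an amber codon inside an NNK
scheme) are scored like any other variant but excluded from hit lists by
default. Hits are ranked by selectivity, ties broken by enrichment and then
lexically by key, so output order is fully deterministic.

`ln(E + 2)` is the transform used when relating enrichment to downstream
activity; it is strictly monotone and keeps zero-enrichment variants finite.
The regression helper fits activity (y) on `ln(E + 2)` (x); r² is invariant
to which variable is regressed on which.

## Library model and read processing

A library design is a reference ORF plus ordered 1-based residue positions,
one IUPAC degenerate codon per position, and an amplicon interval with
constant anchor flanks (default 12 nt) on either side of the variable region.
Residue p occupies nucleotides 3(p−1)+1..3p; variant identity is the
translated amino-acid string over the library positions, pooling synonymous
codons (a codon-level mode exists for diagnostics).

Read pairs are merged by exhaustive overlap search: the reverse read is
reverse-complemented and scored at every shift as (matches − mismatches) over
the overlap, subject to a minimum overlap (default 20 nt) and a maximum
mismatch fraction (default 0.1). At disagreeing positions the base with the
higher Phred quality wins; equal qualities keep the forward base; agreeing
positions take the larger quality. A tie between two admissible best shifts
is a rejection (`ambiguous-overlap`) rather than an arbitrary choice.

Extraction is anchored and ungapped: the left anchor is located by minimum
mismatches (at most `max_anchor_mismatches`, default 1, per flank; the
smallest offset wins ties), the right anchor is verified at its implied
position, and the library codons are read out at fixed offsets. This trades
indel sensitivity for determinism — the amplicon is fixed-length and reads
carrying indels fall out via anchor mismatch, which the QC report tallies.
Reads with ambiguous bases inside a library codon are rejected; no other
quality filtering is applied, since Phred scores already arbitrate merge
conflicts. The QC invariant `pairs seen = extracted + Σ rejections` is
asserted in tests.

Both stages run vectorised over whole samples (uint8 matrices, one array
comparison per candidate shift/offset), so a few hundred thousand pairs take
seconds on one core.

## Synthetic selection rounds

The simulator emulates the statistical structure of an acylation-based
pulldown. Each variant v has an input abundance p_v (log-normal with
sigma = 1.0 by default, normalised), a cognate activity a_v in [0, 1] and a
background activity b_v in [0, 1]. Sampling weights per condition are
p_v·(a_v + ε) (positive), p_v·(b_v + ε) (negative) and p_v (input), with
ε = 0.01 the non-specific capture probability. The additive ε reflects that
bead carry-over is never exactly zero — pulldowns recover measurable material
even without the monomer — and guarantees well-defined negative samples.
Counts are multinomial at the planned depth (default 200,000 reads/sample,
a typical mid-size amplicon sequencing allocation; real depths vary and the
value is configurable). Replicate noise is purely multinomial by default; an
optional per-variant, per-replicate log-normal capture jitter models
biological replicate variance so the dispersion filter has something to
reject.

Default truth parameters: 1,000 variants drawn uniquely from the design's
codon space, 5% cognate-active with a_v ~ Beta(2, 2) (activities spread over
the unit interval, mass away from the extremes), an independent 1%
promiscuous with b_v ~ Beta(2, 8) (background activity small relative to
cognate activity).

FASTQ generation covers the amplicon with a forward prefix read and a reverse
suffix read (reverse-complemented), applies independent per-base substitution
errors at the planned rate, writes constant Phred+33 qualities, and records
the true variant of every read pair in a manifest for round-trip testing.
Indels, PCR bias, chimeras and instrument-specific quality profiles are not
modelled: the generator's purpose is to give the scoring chain data whose
ground truth is exactly known, not to imitate an instrument. Consequently,
passing round-trip and recovery tests demonstrates correctness of the
counting and scoring arithmetic, not robustness to artefacts the generator
does not produce.

Seeding: every sample's generator derives deterministically from the master
seed as `SeedSequence([master_seed, sample_index, stream])` (stream 0 for
count draws, stream 1 for reads/errors), so identical seeds give
byte-identical FASTQ and any sample can be regenerated in isolation.

## qPCR quantification

Standard curves are ordinary least squares of Cq on log10(copies) over a
serial dilution (the conventional five-step fivefold design is provided as a
helper). Efficiency is `10^(−1/slope) − 1`; a slope of −1/log10(2) ≈
−3.321928 (template doubling each cycle) corresponds to 100%. Replicate Cq
values are combined by arithmetic mean of Cq before inversion — the dominant
qPCR convention; the alternative (geometric mean of per-replicate copy
estimates) differs only at second order in the Cq scatter. Recovery is
reported as percent of input, `100·after/input`.

## Numerical and degenerate-input choices

* Frequencies, means and quotients are plain double arithmetic; the scoring
  chain is verified against an exact rational-arithmetic transcription of the
  formulas to 1e-12 relative.
* Curve fitting and regression use `scipy.stats.linregress`; a constant
  predictor raises; a constant response reports slope 0 and r² = 0 with a
  warning rather than 0/0.
* A fitted standard curve with non-negative slope is rejected outright.
* Empty FASTQ files yield empty counts with zeroed QC; a zero-total count
  sample and an empty AND-merge result are hard errors naming the culprit.
* All stochastic entry points require a seed; there is no global RNG state.

## Problem sizes in the test and acceptance runs

The packaged checks use a compact two-position NNK design (36-nt amplicon)
for read-level round trips at 9 × 50,000 pairs, and the default three-position
design at 1,000 variants × 200,000 reads for ground-truth recovery over five
seeds — sizes chosen so the full suite exercises every code path at realistic
depth while remaining quick on a single core.

## Known limitations

* Rank-correlation recovery metrics computed over *all* AND-surviving
  variants are bounded well below 1 on this simulation design: with ε > 0 and
  typical depths, essentially all zero-activity variants survive the AND
  merge, and a survivor set that is ~95% exact ties at a_v = 0 caps Spearman's
  rho near 0.38 regardless of how well enrichment orders the variants (the
  bound depends only on the tied fraction). The implementation sits at that
  ceiling — enrichment places every active variant above the inactive block —
  and rank correlation restricted to active variants is ~0.97–0.99. Recovery
  should therefore be judged by the active-only correlation and by hit
  precision, both reported by `scripts/acceptance.py`.
* Sequencing errors inside library codons create spurious low-count variant
  keys that can pass the AND merge at high depth; they scatter near the
  origin of the spindle plot and do not reach the hit thresholds, but they
  inflate the scored-variant count.
* The pipeline does not demultiplex, trim adapters, or align with indel
  tolerance; equivalence with read-level filtering of general-purpose
  pairing/alignment tools is not claimed.
* No significance testing is attached to enrichment or selectivity; the
  dispersion filter is the only replicate-consistency control, mirroring how
  these selections are analysed in practice.
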