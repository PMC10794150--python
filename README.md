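# trnadisplay

Selection analysis for tRNA-display directed evolution of aminoacyl-tRNA
synthetases. The package turns paired-end amplicon sequencing of a selection
round — samples grown **with** the non-canonical monomer (positive), **without**
it (negative), and the unselected **input** library — into per-variant
enrichment, selectivity and dispersion scores, ranked hit lists and spindle
plots. It also ships a synthetic selection-round simulator with full ground
truth, and the qPCR standard-curve arithmetic used to quantify pulldown
recovery.

It is written for protein engineers running degenerate-codon (e.g. NNK)
active-site libraries of PylRS-type synthetases, but nothing in the scoring
is specific to that scaffold: any fixed-length amplicon with mutated codons at
known positions works.

## The statistics

For each sample, a variant's frequency is its read count divided by the
sample's total count, `f = c / N`. Replicate tables are merged in two steps:

* variants must be present in **every positive replicate** (AND merge);
* each retained variant missing from a negative or input replicate receives a
  placeholder of **0.95 counts**, i.e. frequency `0.95 / N` for that
  replicate's observed total (OR merge) — highly enriched variants may
  legitimately be absent from the unselected or negative pools.

With mean frequencies over replicates (`f̄⁺`, `f̄⁻`, `f̄⁰` for positive,
negative, input):

| score | definition | meaning |
|---|---|---|
| enrichment `E` | `f̄⁺ / f̄⁰` | amplification over the input library |
| negative enrichment `E⁻` | `f̄⁻ / f̄⁰` | amplification without the monomer |
| selectivity `S` | `f̄⁺ / f̄⁻` (= `E / E⁻`) | monomer dependence |
| dispersion `D` | `sd(f⁺) / mean(f⁺)` | replicate irreproducibility (CV) |

Hits satisfy `E ≥ 5`, `S ≥ 10` (inclusive) and `D ≤` a configurable ceiling
(default 1.0), ranked by selectivity. `ln(E + 2)` is the transform used when
regressing enrichment against downstream activity measurements (e.g. GFP
amber-suppression fluorescence).

## Worked example

The default configuration simulates one selection round — 1,000 variants over
3 NNK positions, 5% of variants cognate-active, triplicate conditions at
200,000 reads per sample, 0.1% per-base sequencing error — then merges read
pairs, counts variants, scores and plots:

```sh
trnadisplay run-all --seed 3 --outdir demo
```

```
... INFO simulated 1000 variants, 9 samples x 200000 reads
... INFO run complete: 1199 variants scored, 38 hits
```

`demo/hits.csv` starts:

```
variant,...,enrichment,...,selectivity,dispersion,...
FLR,...,29.999888292038282,...,35.32204851611141,0.002141600089871084,...
FCI,...,26.23041636096652,...,31.742284584471022,0.01911746554799358,...
```

Reading: variant `FLR` (the amino acids at the three library positions) is
30-fold enriched over the input library, 35-fold more abundant with the
monomer than without, and its positive-replicate frequencies agree to 0.2% —
a clean, selective hit. More variants are scored (1,199) than simulated
(1,000) because sequencing errors inside library codons create low-count
spurious keys; these fall far below the hit thresholds. The per-sample QC in
`demo/run_summary.json` accounts for every read pair (e.g. 200,000 seen,
199,980 extracted, 20 anchor-mismatch rejections).

Each stage is also available separately (`trnadisplay simulate / count /
score / plot / quant`) and as library functions:

```python
import trnadisplay as td

design = td.make_library_design(orf, positions=[306, 309, 346], schemes=["NNK"] * 3)
counts, qc = td.count_sample("R1.fastq", "R2.fastq", design, spec)
scores = td.score_counts(count_table, sample_specs)
hits = td.call_hits(scores)       # E >= 5, S >= 10, D <= 1
```

qPCR quantification of pulldown recovery:

```python
curve = td.fit_standard_curve([(copies, cq), ...])   # five-step fivefold dilution
curve.efficiency                                     # 1.0 == 100%
n = td.copies_from_cq(curve, [cq1, cq2, cq3])        # mean-Cq inversion
td.percent_input(n_after, n_input)                   # 100 * after / input
```

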