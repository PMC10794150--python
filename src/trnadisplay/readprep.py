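"""Paired FASTQ to per-sample variant counts.

The stage replaces generic read pairing and alignment tools with two
special-purpose steps that exploit the fixed-length amplicon:

1. **Overlap merging** — the reverse read is reverse-complemented and slid
   against the forward read; the best shift maximises (matches - mismatches)
   over all shifts with overlap >= ``min_overlap`` and mismatch fraction <=
   ``max_mismatch_frac``.  At disagreeing positions the base with the higher
   Phred quality wins (ties keep the forward base); agreeing positions get the
   larger of the two qualities.  A tie between two best shifts is a rejection
   (``ambiguous-overlap``), as is an empty admissible set (``no-overlap``).

2. **Anchored extraction** — the merged read is located against the reference
   amplicon by matching the constant flanks on either side of the variable
   region (at most ``max_anchor_mismatches`` mismatches per flank); the
   library codons are then read out at fixed offsets, unaligned and ungapped,
   and translated to the variant key.  Reads carrying indels fall out through
   anchor mismatches; reads with ambiguous bases inside a library codon are
   rejected (``ambiguous-base``), reads too short to span the variable region
   are rejected (``length``).

Counting is at the amino-acid level, pooling synonymous codons; pass
``codon_level=True`` to retain nucleotide-level keys for diagnostics.

All heavy paths operate on uint8 matrices over whole samples, so counting a
few hundred thousand read pairs takes seconds.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from .errors import FastqFormatError
from .variant_model import CountTable, LibraryDesign, SampleSpec, VariantKey, translate_codons

REJECT_REASONS = ("no-overlap", "ambiguous-overlap", "anchor-mismatch", "ambiguous-base", "length")

_COMPLEMENT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTNacgtn", b"TGCANTGCAN"):
    _COMPLEMENT[_a] = _b
_IS_DNA = np.zeros(256, dtype=bool)
for _a in b"ACGT":
    _IS_DNA[_a] = True


@dataclass
class MergedRead:
    """A consensus sequence assembled from one read pair."""

    sequence: str
    qualities: np.ndarray  # integer Phred scores, same length as sequence
    provenance: str = ""

    def __post_init__(self):
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.qualities) != len(self.sequence):
            raise ValueError("qualities and sequence lengths differ")


@dataclass
class Rejection:
    """A read pair that failed merging or extraction, with the reason."""

    reason: str
    provenance: str = ""

    def __post_init__(self):
        if self.reason not in REJECT_REASONS:
            raise ValueError(f"unknown rejection reason {self.reason!r}")


@dataclass
class ReadPrepParams:
    """Tunable thresholds of the merge/extract stage."""

    min_overlap: int = 20
    max_mismatch_frac: float = 0.1
    max_anchor_mismatches: int = 1


@dataclass
class QCReport:
    """Per-sample accounting: pairs seen = extracted + sum of rejections."""

    pairs_seen: int = 0
    merged: int = 0
    extracted: int = 0
    rejections: dict[str, int] = field(default_factory=lambda: {r: 0 for r in REJECT_REASONS})

    def consistent(self) -> bool:
        return self.pairs_seen == self.extracted + sum(self.rejections.values())

    def as_dict(self) -> dict:
        return {
            "pairs_seen": self.pairs_seen,
            "merged": self.merged,
            "extracted": self.extracted,
            "rejections": dict(self.rejections),
        }


def _encode(seqs: list[str]) -> np.ndarray:
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), len(seqs[0]))


def _encode_quals(quals: list[str]) -> np.ndarray:
    return _encode(quals).astype(np.int16) - 33


def merge_pairs_batch(
    fwd_seq: np.ndarray,
    fwd_qual: np.ndarray,
    rev_seq: np.ndarray,
    rev_qual: np.ndarray,
    params: ReadPrepParams,
) -> tuple[np.ndarray, np.ndarray, list[tuple[np.ndarray, np.ndarray]]]:
    """Merge a batch of equal-length read pairs.

    ``rev_seq``/``rev_qual`` are the raw reverse reads; reverse complementing
    happens here.  Returns ``(status, shift, merged)`` where status is 0 for
    merged, 1 for no-overlap, 2 for ambiguous-overlap; ``merged`` maps each
    row to its (sequence codes, qualities) or ``(None, None)`` when rejected.
    """
    n, lf = fwd_seq.shape
    lr = rev_seq.shape[1]
    rc_seq = _COMPLEMENT[rev_seq[:, ::-1]]
    rc_qual = rev_qual[:, ::-1]

    none_score = np.iinfo(np.int32).min
    best_score = np.full(n, none_score, dtype=np.int64)
    best_shift = np.zeros(n, dtype=np.int64)
    n_best = np.zeros(n, dtype=np.int64)

    # shift s: reverse-complement read starts at forward coordinate s
    for s in range(-(lr - params.min_overlap), lf - params.min_overlap + 1):
        a0, a1 = max(0, s), min(lf, s + lr)
        ov = a1 - a0
        if ov < params.min_overlap:
            continue
        mm = np.count_nonzero(fwd_seq[:, a0:a1] != rc_seq[:, a0 - s : a1 - s], axis=1)
        score = ov - 2 * mm
        admissible = mm <= params.max_mismatch_frac * ov
        tie = admissible & (score == best_score)
        n_best[tie] += 1
        better = admissible & (score > best_score)
        best_score[better] = score[better]
        best_shift[better] = s
        n_best[better] = 1

    status = np.zeros(n, dtype=np.int8)
    status[best_score == none_score] = 1
    status[(best_score != none_score) & (n_best > 1)] = 2

    merged: list[tuple[np.ndarray | None, np.ndarray | None]] = [(None, None)] * n
    for s in np.unique(best_shift[status == 0]):
        rows = np.flatnonzero((status == 0) & (best_shift == s))
        lo, hi = min(0, s), max(lf, s + lr)
        length = hi - lo
        coords = np.arange(lo, hi)
        f_cov = (coords >= 0) & (coords < lf)
        r_cov = (coords >= s) & (coords < s + lr)

        seq = np.zeros((len(rows), length), dtype=np.uint8)
        qual = np.zeros((len(rows), length), dtype=np.int16)
        fs = fwd_seq[rows][:, coords[f_cov]]
        fq = fwd_qual[rows][:, coords[f_cov]]
        rs = rc_seq[rows][:, coords[r_cov] - s]
        rq = rc_qual[rows][:, coords[r_cov] - s]

        seq[:, f_cov] = fs
        qual[:, f_cov] = fq
        only_r = r_cov & ~f_cov
        seq[:, only_r] = rc_seq[rows][:, coords[only_r] - s]
        qual[:, only_r] = rc_qual[rows][:, coords[only_r] - s]

        both = f_cov & r_cov
        fb = seq[:, both]
        fqb = qual[:, both]
        rb = rc_seq[rows][:, coords[both] - s]
        rqb = rc_qual[rows][:, coords[both] - s]
        agree = fb == rb
        use_rev = ~agree & (rqb > fqb)  # quality tie keeps the forward base
        out_seq = np.where(use_rev, rb, fb)
        out_qual = np.where(agree, np.maximum(fqb, rqb), np.where(use_rev, rqb, fqb))
        seq[:, both] = out_seq
        qual[:, both] = out_qual

        for i, r in enumerate(rows):
            merged[r] = (seq[i], qual[i])
    return status, best_shift, merged


def merge_pair(
    forward_seq: str,
    forward_qual: str,
    reverse_seq: str,
    reverse_qual: str,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
    provenance: str = "",
) -> MergedRead | Rejection:
    """Merge one read pair; see the module docstring for the rules."""
    params = ReadPrepParams(min_overlap=min_overlap, max_mismatch_frac=max_mismatch_frac)
    status, _, merged = merge_pairs_batch(
        _encode([forward_seq.upper()]),
        _encode_quals([forward_qual]),
        _encode([reverse_seq.upper()]),
        _encode_quals([reverse_qual]),
        params,
    )
    if status[0] == 1:
        return Rejection("no-overlap", provenance)
    if status[0] == 2:
        return Rejection("ambiguous-overlap", provenance)
    seq, qual = merged[0]
    return MergedRead(bytes(seq).decode(), qual, provenance)


def _anchor_layout(design: LibraryDesign):
    """Precompute anchor byte arrays and codon offsets relative to the left anchor."""
    left = np.frombuffer(design.left_anchor.encode(), dtype=np.uint8)
    right = np.frombuffer(design.right_anchor.encode(), dtype=np.uint8)
    la = design.left_anchor_offset_in_amplicon()
    codon_rel = [off - la for off in design.codon_offsets_in_amplicon()]
    right_rel = design.right_anchor_offset_in_amplicon() - la
    return left, right, codon_rel, right_rel


def extract_variants_batch(
    merged_seq: np.ndarray,
    design: LibraryDesign,
    max_anchor_mismatches: int = 1,
    codon_level: bool = False,
) -> tuple[list[VariantKey | None], np.ndarray]:
    """Extract variant keys from equal-length merged reads.

    Returns one key (or ``None``) per row plus a status array: 0 extracted,
    3 anchor-mismatch, 4 ambiguous-base, 5 length.
    """
    n, length = merged_seq.shape
    left, right, codon_rel, right_rel = _anchor_layout(design)
    al = len(left)
    status = np.zeros(n, dtype=np.int8)
    keys: list[VariantKey | None] = [None] * n
    if length < al:
        status[:] = 5
        return keys, status

    best_mm = np.full(n, al + 1, dtype=np.int64)
    best_off = np.full(n, -1, dtype=np.int64)
    for o in range(0, length - al + 1):
        mm = np.count_nonzero(merged_seq[:, o : o + al] != left, axis=1)
        better = mm < best_mm  # first best offset wins ties
        best_mm[better] = mm[better]
        best_off[better] = o
    found = best_mm <= max_anchor_mismatches
    status[~found] = 3

    span = right_rel + len(right)  # nt needed downstream of the left anchor start
    for o in np.unique(best_off[found]):
        rows = np.flatnonzero(found & (best_off == o))
        if o + span > length:
            status[rows] = 5
            continue
        sub = merged_seq[rows]
        right_mm = np.count_nonzero(sub[:, o + right_rel : o + right_rel + len(right)] != right, axis=1)
        bad_right = right_mm > max_anchor_mismatches
        status[rows[bad_right]] = 3
        ok = rows[~bad_right]
        if not len(ok):
            continue
        codon_cols = np.concatenate([np.arange(o + r, o + r + 3) for r in codon_rel])
        codon_mat = merged_seq[ok][:, codon_cols]
        ambiguous = ~_IS_DNA[codon_mat].all(axis=1)
        status[ok[ambiguous]] = 4
        good = ok[~ambiguous]
        if not len(good):
            continue
        uniq, inverse = np.unique(codon_mat[~ambiguous], axis=0, return_inverse=True)
        uniq_keys = []
        for row in uniq:
            nts = bytes(row).decode()
            codons = [nts[i : i + 3] for i in range(0, len(nts), 3)]
            uniq_keys.append("|".join(codons) if codon_level else translate_codons(codons))
        for i, r in enumerate(good):
            keys[r] = uniq_keys[inverse[i]]
    return keys, status


def extract_variant(
    merged: MergedRead,
    design: LibraryDesign,
    max_anchor_mismatches: int = 1,
    codon_level: bool = False,
) -> VariantKey | Rejection:
    """Extract the variant key from one merged read."""
    seq = np.frombuffer(merged.sequence.upper().encode(), dtype=np.uint8).reshape(1, -1)
    keys, status = extract_variants_batch(seq, design, max_anchor_mismatches, codon_level)
    if status[0] == 0:
        return keys[0]
    reason = {3: "anchor-mismatch", 4: "ambiguous-base", 5: "length"}[int(status[0])]
    return Rejection(reason, merged.provenance)


def _open_text(path: str | Path):
    path = str(path)
    return gzip.open(path, "rt") if path.endswith(".gz") else open(path, "rt")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (read id, sequence, quality string) from a Phred+33 FASTQ file.

    Raises :class:`FastqFormatError` naming the 0-based record index on any
    structural problem.
    """
    with _open_text(path) as fh:
        record = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise FastqFormatError(f"malformed FASTQ record {record} in {path}")
            if len(seq) != len(qual) or not seq:
                raise FastqFormatError(
                    f"record {record} in {path}: sequence and quality lengths differ or empty"
                )
            yield header[1:].strip().split()[0], seq.upper(), qual
            record += 1


def count_sample(
    fastq1: str | Path,
    fastq2: str | Path,
    design: LibraryDesign,
    spec: SampleSpec,
    params: ReadPrepParams | None = None,
    codon_level: bool = False,
) -> tuple[dict[VariantKey, int], QCReport]:
    """Count library variants in one paired-FASTQ sample.

    Pairs are matched positionally between the two files (the usual R1/R2
    convention).  Returns the variant counts and a :class:`QCReport` whose
    rejection tallies account for every non-extracted pair.
    """
    params = params or ReadPrepParams()
    qc = QCReport()
    counts: dict[str, int] = {}

    reads1 = list(read_fastq(fastq1))
    reads2 = list(read_fastq(fastq2))
    if len(reads1) != len(reads2):
        raise FastqFormatError(
            f"paired files have different record counts ({len(reads1)} vs {len(reads2)})"
        )
    qc.pairs_seen = len(reads1)
    if not reads1:
        return counts, qc

    # batch pairs by read-length combination so each batch is rectangular
    by_len: dict[tuple[int, int], list[int]] = {}
    for i, ((_, s1, _), (_, s2, _)) in enumerate(zip(reads1, reads2)):
        by_len.setdefault((len(s1), len(s2)), []).append(i)

    for rows in by_len.values():
        f_seq = _encode([reads1[i][1] for i in rows])
        f_qual = _encode_quals([reads1[i][2] for i in rows])
        r_seq = _encode([reads2[i][1] for i in rows])
        r_qual = _encode_quals([reads2[i][2] for i in rows])
        status, shift, merged = merge_pairs_batch(f_seq, f_qual, r_seq, r_qual, params)
        qc.rejections["no-overlap"] += int((status == 1).sum())
        qc.rejections["ambiguous-overlap"] += int((status == 2).sum())
        ok = np.flatnonzero(status == 0)
        qc.merged += len(ok)
        if not len(ok):
            continue
        # merged reads of equal shift have equal length; group again
        by_mlen: dict[int, list[int]] = {}
        for i in ok:
            by_mlen.setdefault(len(merged[i][0]), []).append(i)
        for mlen, midx in by_mlen.items():
            mat = np.vstack([merged[i][0] for i in midx])
            keys, xstatus = extract_variants_batch(
                mat, design, params.max_anchor_mismatches, codon_level
            )
            qc.rejections["anchor-mismatch"] += int((xstatus == 3).sum())
            qc.rejections["ambiguous-base"] += int((xstatus == 4).sum())
            qc.rejections["length"] += int((xstatus == 5).sum())
            for key in keys:
                if key is not None:
                    counts[key] = counts.get(key, 0) + 1
    qc.extracted = sum(counts.values())
    return counts, qc


def count_samples(
    sample_fastqs: dict[str, tuple[str, str]],
    design: LibraryDesign,
    specs: list[SampleSpec],
    params: ReadPrepParams | None = None,
    codon_level: bool = False,
) -> tuple[CountTable, dict[str, QCReport]]:
    """Run :func:`count_sample` over an experiment's sample sheet."""
    table = CountTable()
    reports: dict[str, QCReport] = {}
    spec_by_id = {s.sample_id: s for s in specs}
    for sample_id, (fq1, fq2) in sample_fastqs.items():
        counts, qc = count_sample(fq1, fq2, design, spec_by_id[sample_id], params, codon_level)
        table.add_sample(sample_id, counts)
        reports[sample_id] = qc
    return table, reports
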