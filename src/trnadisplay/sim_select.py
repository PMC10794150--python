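"""Synthetic selection-round generator.

Emulates one round of an acylation-based pulldown selection.  Each library
variant ``v`` has an input abundance ``p_v`` (log-normal, normalised), a
cognate activity ``a_v`` in [0, 1] (acylation with the monomer present) and a
background activity ``b_v`` (acylation from canonical substrates, which drives
signal in the negative condition).  A sample's variant sampling weights are

* positive:  ``p_v * (a_v + eps)``
* negative:  ``p_v * (b_v + eps)``
* input:     ``p_v``

where ``eps`` is the non-specific capture probability that keeps every weight
positive (bead carry-over is never exactly zero in a pulldown).  Read counts
are drawn multinomially per sample; replicate noise is purely multinomial by
default, with an optional per-replicate log-normal capture jitter to give the
dispersion filter biological variance to reject.

Seeds: every sample's generator is derived deterministically from the master
seed as ``SeedSequence([master_seed, sample_index, stream])`` with stream 0
for count sampling and stream 1 for read/error generation, so any sample can
be regenerated in isolation.
"""

from __future__ import annotations

import gzip
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SimulationError
from .variant_model import (
    CountTable,
    LibraryDesign,
    SampleSpec,
    VariantKey,
    expand_degenerate_codon,
    translate_codons,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT[_a] = _b

_SENSE_CODONS = tuple(
    c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
    if translate_codons([c]) != "*"
)


def random_orf(n_codons: int, seed: int, include_stop: bool = False) -> str:
    """Seeded random ORF: ATG start, sense codons, optional terminal stop."""
    if n_codons < 2:
        raise SimulationError("random ORF needs at least 2 codons")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 904]))
    body = rng.choice(len(_SENSE_CODONS), size=n_codons - (2 if include_stop else 1))
    codons = ["ATG"] + [_SENSE_CODONS[i] for i in body]
    if include_stop:
        codons.append("TAA")
    return "".join(codons)


@dataclass
class SelectionTruth:
    """Ground truth of a simulated selection library."""

    keys: list[VariantKey]
    codons: list[tuple[str, ...]]
    p: np.ndarray          # input abundance, sums to 1
    a: np.ndarray          # cognate activity in [0, 1]
    b: np.ndarray          # background activity in [0, 1]
    epsilon: float = 0.01  # non-specific capture probability

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        n = len(self.keys)
        if not (len(self.codons) == len(self.p) == len(self.a) == len(self.b) == n):
            raise SimulationError("truth arrays must all have one entry per variant")
        if n == 0:
            raise SimulationError("empty variant library")
        if abs(self.p.sum() - 1.0) > 1e-9 or (self.p < 0).any():
            raise SimulationError("input abundances must be non-negative and sum to 1")
        for arr, name in ((self.a, "cognate"), (self.b, "background")):
            if ((arr < 0) | (arr > 1)).any():
                raise SimulationError(f"{name} activities must lie in [0, 1]")
        if not 0 < self.epsilon <= 1:
            raise SimulationError("epsilon must lie in (0, 1]")

    @property
    def n_variants(self) -> int:
        return len(self.keys)

    def condition_weights(self, condition: str) -> np.ndarray:
        """Unnormalised sampling weights for one condition."""
        if condition == "positive":
            return self.p * (self.a + self.epsilon)
        if condition == "negative":
            return self.p * (self.b + self.epsilon)
        if condition == "input":
            return self.p.copy()
        raise SimulationError(f"unknown condition {condition!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant": self.keys,
                "codons": ["|".join(c) for c in self.codons],
                "input_abundance": self.p,
                "cognate_activity": self.a,
                "background_activity": self.b,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class SimPlan:
    """Sizes, noise levels and seed of one simulated selection round."""

    seed: int
    replicates: int = 3
    input_replicates: int | None = None  # defaults to `replicates`
    reads_per_sample: int = 200_000
    error_rate: float = 0.0
    read_length: int | None = None       # None -> full amplicon length
    capture_jitter_sigma: float = 0.0
    quality_char: str = "F"              # Phred+33 Q37 for every base
    monomer_label: str = "ncM"

    def __post_init__(self):
        if self.reads_per_sample < 1:
            raise SimulationError("reads_per_sample must be >= 1")
        if not 0 <= self.error_rate < 1:
            raise SimulationError("error_rate must lie in [0, 1)")
        if self.replicates < 1 or (self.input_replicates is not None and self.input_replicates < 1):
            raise SimulationError("replicate counts must be >= 1")
        if self.seed is None:
            raise SimulationError("a seed is mandatory")

    @property
    def n_input(self) -> int:
        return self.replicates if self.input_replicates is None else self.input_replicates

    def sample_specs(self) -> list[SampleSpec]:
        """Canonical sample ordering: positive, negative, then input replicates."""
        specs = []
        for cond, short, n in (
            ("positive", "pos", self.replicates),
            ("negative", "neg", self.replicates),
            ("input", "in", self.n_input),
        ):
            for r in range(1, n + 1):
                specs.append(
                    SampleSpec(
                        sample_id=f"{short}{r}",
                        condition=cond,
                        replicate=r,
                        monomer_label=None if cond == "input" else self.monomer_label,
                    )
                )
        return specs

    def sample_rng(self, sample_index: int, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), int(sample_index), int(stream)])
        )


def simulate_truth(
    design: LibraryDesign,
    n_variants: int = 1000,
    frac_active: float = 0.05,
    frac_promiscuous: float = 0.01,
    activity_beta: tuple[float, float] = (2.0, 2.0),
    background_beta: tuple[float, float] = (2.0, 8.0),
    abundance_sigma: float = 1.0,
    epsilon: float = 0.01,
    seed: int = 0,
) -> SelectionTruth:
    """Draw a ground-truth library for one selection round.

    ``n_variants`` distinct protein-level variants are sampled uniformly from
    the design's degenerate codon space.  Abundances are log-normal (sigma =
    ``abundance_sigma``) and normalised; a fraction ``frac_active`` of
    variants receives cognate activity from Beta(``activity_beta``), the rest
    a_v = 0; an independent fraction ``frac_promiscuous`` is promiscuous with
    background activity from Beta(``background_beta``).
    """
    if not 0 <= frac_active <= 1 or not 0 <= frac_promiscuous <= 1:
        raise SimulationError("activity fractions must lie in [0, 1]")
    space = design.variant_space_size()
    if n_variants > space:
        raise SimulationError(f"n_variants={n_variants} exceeds the variant space ({space})")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    codon_choices = [expand_degenerate_codon(s) for s in design.schemes]

    keys: list[str] = []
    codons: list[tuple[str, ...]] = []
    seen: set[str] = set()
    while len(keys) < n_variants:
        batch = max(64, 2 * (n_variants - len(keys)))
        draws = [rng.integers(0, len(ch), size=batch) for ch in codon_choices]
        for row in range(batch):
            cods = tuple(ch[d[row]] for ch, d in zip(codon_choices, draws))
            key = translate_codons(cods)
            if key not in seen:
                seen.add(key)
                keys.append(key)
                codons.append(cods)
                if len(keys) == n_variants:
                    break

    p = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=n_variants)
    p /= p.sum()

    a = np.zeros(n_variants)
    n_active = int(round(frac_active * n_variants))
    if n_active:
        idx = rng.choice(n_variants, size=n_active, replace=False)
        a[idx] = rng.beta(*activity_beta, size=n_active)

    b = np.zeros(n_variants)
    n_prom = int(round(frac_promiscuous * n_variants))
    if n_prom:
        idx = rng.choice(n_variants, size=n_prom, replace=False)
        b[idx] = rng.beta(*background_beta, size=n_prom)

    return SelectionTruth(keys=keys, codons=codons, p=p, a=a, b=b, epsilon=epsilon)


def simulate_counts(truth: SelectionTruth, plan: SimPlan) -> tuple[CountTable, list[SampleSpec]]:
    """Draw multinomial per-sample counts for every sample in the plan."""
    specs = plan.sample_specs()
    table = CountTable()
    for k, spec in enumerate(specs):
        rng = plan.sample_rng(k, stream=0)
        w = truth.condition_weights(spec.condition)
        if plan.capture_jitter_sigma > 0 and spec.condition in ("positive", "negative"):
            w = w * rng.lognormal(0.0, plan.capture_jitter_sigma, size=truth.n_variants)
        total = w.sum()
        if total <= 0:
            raise SimulationError(f"all sampling weights zero for sample {spec.sample_id!r}")
        counts = rng.multinomial(plan.reads_per_sample, w / total)
        table.add_sample(
            spec.sample_id,
            {truth.keys[i]: int(c) for i, c in enumerate(counts) if c > 0},
        )
    return table, specs


def _apply_errors(reads: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute bases in a (n_reads, length) uint8 matrix at a uniform rate."""
    if rate <= 0:
        return reads
    base_index = np.full(256, 255, dtype=np.uint8)
    for i, code in enumerate(_BASES):
        base_index[code] = i
    mask = rng.random(reads.shape) < rate
    n_err = int(mask.sum())
    if n_err:
        old = base_index[reads[mask]]
        new = (old + rng.integers(1, 4, size=n_err)) % 4
        reads = reads.copy()
        reads[mask] = _BASES[new]
    return reads


def _revcomp_matrix(m: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[m[:, ::-1]]


def simulate_fastq(
    counts: CountTable,
    truth: SelectionTruth,
    design: LibraryDesign,
    plan: SimPlan,
    outdir: str | Path,
    gzip_output: bool = False,
) -> dict[str, dict[str, str]]:
    """Write paired FASTQ (Phred+33) plus a per-read variant manifest.

    Each read pair covers the amplicon: the forward read is the first
    ``read_length`` nt of the variant amplicon, the reverse read the
    reverse complement of the last ``read_length`` nt, so the pair overlaps by
    ``2*read_length - amplicon_length`` nt.  Substitution errors are applied
    independently per read at ``plan.error_rate``.  Returns, per sample, the
    paths of the two FASTQ files and the manifest TSV.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    amplicon_len = len(design.amplicon)
    read_len = plan.read_length or amplicon_len
    if read_len > amplicon_len:
        raise SimulationError(f"read_length {read_len} exceeds amplicon length {amplicon_len}")
    if 2 * read_len < amplicon_len:
        raise SimulationError(
            f"2x{read_len} nt reads cannot span the {amplicon_len}-nt amplicon "
            "(the variable region would be uncovered)"
        )

    key_to_row = {k: i for i, k in enumerate(truth.keys)}
    amp_matrix = np.frombuffer(
        "".join(design.amplicon_for(c) for c in truth.codons).encode(), dtype=np.uint8
    ).reshape(truth.n_variants, amplicon_len)

    specs = plan.sample_specs()
    qual_line = plan.quality_char * read_len
    suffix = ".fastq.gz" if gzip_output else ".fastq"
    paths: dict[str, dict[str, str]] = {}

    for k, spec in enumerate(specs):
        sample_counts = counts.counts.get(spec.sample_id, {})
        rng = plan.sample_rng(k, stream=1)
        variant_rows = np.concatenate(
            [np.full(c, key_to_row[v], dtype=np.int64) for v, c in sorted(sample_counts.items())]
        ) if sample_counts else np.empty(0, dtype=np.int64)
        order = rng.permutation(len(variant_rows))
        variant_rows = variant_rows[order]

        amps = amp_matrix[variant_rows]
        fwd = _apply_errors(amps[:, :read_len], plan.error_rate, rng)
        rev = _apply_errors(_revcomp_matrix(amps[:, amplicon_len - read_len :]),
                            plan.error_rate, rng)

        fq1 = outdir / f"{spec.sample_id}_R1{suffix}"
        fq2 = outdir / f"{spec.sample_id}_R2{suffix}"
        manifest = outdir / f"{spec.sample_id}_manifest.tsv"
        opener = gzip.open if gzip_output else open
        with opener(fq1, "wt") as f1, opener(fq2, "wt") as f2, open(manifest, "w") as fm:
            fm.write("read_id\tvariant\n")
            for i in range(len(variant_rows)):
                rid = f"{spec.sample_id}:{i}"
                f1.write(f"@{rid}/1\n{bytes(fwd[i]).decode()}\n+\n{qual_line}\n")
                f2.write(f"@{rid}/2\n{bytes(rev[i]).decode()}\n+\n{qual_line}\n")
                fm.write(f"{rid}\t{truth.keys[variant_rows[i]]}\n")
        paths[spec.sample_id] = {"fastq1": str(fq1), "fastq2": str(fq2), "manifest": str(manifest)}

    with open(outdir / "fastq_manifest.json", "w") as fh:
        json.dump(paths, fh, indent=2)
    return paths


def manifest_tally(manifest_path: str | Path) -> dict[str, int]:
    """Aggregate a per-read manifest into variant counts (round-trip oracle)."""
    # keep_default_na: amino-acid keys like "NA" must stay strings
    frame = pd.read_csv(manifest_path, sep="\t", dtype=str, keep_default_na=False)
    return frame["variant"].value_counts().to_dict()
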