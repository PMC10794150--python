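"""Domain types shared by every stage of the selection analysis.

A directed-evolution selection library is described by a :class:`LibraryDesign`:
a reference ORF, an ordered set of mutated codon positions (1-based residue
numbers, e.g. the classical PylRS active-site positions 306/309/346), one IUPAC
degenerate codon scheme per position (typically NNK), and the sequenced amplicon
with its constant anchor flanks.  A library member is identified by its
:data:`VariantKey`: the amino acids read out at the library positions, one
symbol per position, with ``*`` marking an amber codon (NNK encodes 20 amino
acids plus the amber stop in 32 codons).

Per-sample observations live in a :class:`CountTable` keyed by sample id, with
sample metadata (condition, replicate, monomer) in :class:`SampleSpec`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Data.IUPACData import ambiguous_dna_values

from .errors import (
    DesignError,
    EmptySampleError,
    InvalidSchemeError,
    SampleSheetError,
    UntranslatableCodonError,
)

#: A library member's identity: one amino-acid symbol per library position,
#: ``*`` allowed (amber codon inside NNK-style schemes).
VariantKey = str

CONDITIONS = ("positive", "negative", "input")

_STANDARD_TABLE = unambiguous_dna_by_id[1]
#: codon -> amino acid under the standard genetic code, stops mapped to '*'.
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
CODON_TO_AA.update({c: "*" for c in _STANDARD_TABLE.stop_codons})

_DNA = set("ACGT")
# Biopython's table also carries the non-IUPAC alias 'X'; restrict to IUPAC.
_IUPAC_DNA = {s: v for s, v in ambiguous_dna_values.items() if s in set("ACGTRYSWKMBDHVN")}


def expand_degenerate_codon(scheme: str) -> tuple[str, ...]:
    """Expand an IUPAC degenerate codon into its concrete DNA codons.

    Returns the Cartesian product of the per-position symbol expansions in
    deterministic, lexicographically sorted order.  ``"NNK"`` expands to 32
    codons; a plain codon expands to itself.

    Raises
    ------
    InvalidSchemeError
        If ``scheme`` is not exactly three IUPAC DNA symbols.
    """
    if len(scheme) != 3:
        raise InvalidSchemeError(f"degenerate codon must have 3 symbols, got {scheme!r}")
    choices = []
    for sym in scheme.upper():
        try:
            choices.append(sorted(_IUPAC_DNA[sym]))
        except KeyError:
            raise InvalidSchemeError(f"{sym!r} is not an IUPAC DNA symbol (in {scheme!r})") from None
    return tuple("".join(bases) for bases in itertools.product(*choices))


def translate_codons(codons: Iterable[str]) -> str:
    """Translate unambiguous DNA codons under the standard genetic code.

    Stop codons translate to ``'*'``.  Any codon containing a base outside
    A/C/G/T raises :class:`UntranslatableCodonError` — degenerate schemes must
    be expanded first, and reads with ambiguous bases are rejected upstream.
    """
    out = []
    for codon in codons:
        codon = codon.upper()
        if len(codon) != 3 or not set(codon) <= _DNA:
            raise UntranslatableCodonError(f"cannot translate ambiguous or malformed codon {codon!r}")
        out.append(CODON_TO_AA[codon])
    return "".join(out)


def scheme_amino_acids(scheme: str) -> tuple[str, ...]:
    """Sorted distinct amino-acid symbols encoded by a degenerate codon."""
    return tuple(sorted({translate_codons([c]) for c in expand_degenerate_codon(scheme)}))


def contains_stop(key: VariantKey) -> bool:
    """True if the variant carries an amber/stop symbol at any library position."""
    return "*" in key


@dataclass(frozen=True)
class LibraryDesign:
    """A degenerate-codon library on a reference ORF.

    Parameters
    ----------
    reference_orf
        The wild-type ORF (DNA, length divisible by 3).
    library_positions
        Ordered 1-based residue numbers of the mutated codons.
    schemes
        One IUPAC degenerate codon per library position (e.g. ``"NNK"``).
    anchor_length
        Number of constant nucleotides flanking the variable region on each
        side, used to anchor reads during extraction.
    amplicon_bounds
        1-based inclusive nucleotide interval of the sequenced amplicon within
        the ORF.  Must contain every library codon plus both anchors.
    """

    reference_orf: str
    library_positions: tuple[int, ...]
    schemes: tuple[str, ...]
    anchor_length: int = 12
    amplicon_bounds: tuple[int, int] = (0, 0)  # (0, 0) sentinel -> full ORF

    def __post_init__(self):
        orf = self.reference_orf.upper()
        object.__setattr__(self, "reference_orf", orf)
        object.__setattr__(self, "library_positions", tuple(int(p) for p in self.library_positions))
        object.__setattr__(self, "schemes", tuple(s.upper() for s in self.schemes))
        if len(orf) == 0 or len(orf) % 3 != 0:
            raise DesignError(f"reference ORF length {len(orf)} is not a positive multiple of 3")
        if not set(orf) <= _DNA:
            raise DesignError("reference ORF contains non-ACGT characters")
        n_res = len(orf) // 3
        if not self.library_positions:
            raise DesignError("at least one library position is required")
        if len(self.schemes) != len(self.library_positions):
            raise DesignError("one degenerate scheme is required per library position")
        if list(self.library_positions) != sorted(set(self.library_positions)):
            raise DesignError("library positions must be strictly increasing")
        for p in self.library_positions:
            if not 1 <= p <= n_res:
                raise DesignError(f"library position {p} outside 1..{n_res}")
        for s in self.schemes:
            expand_degenerate_codon(s)  # validates
        if self.anchor_length < 1:
            raise DesignError("anchor_length must be >= 1")
        if self.amplicon_bounds == (0, 0):
            object.__setattr__(self, "amplicon_bounds", (1, len(orf)))
        b0, b1 = self.amplicon_bounds
        if not (1 <= b0 <= b1 <= len(orf)):
            raise DesignError(f"amplicon bounds {self.amplicon_bounds} outside ORF 1..{len(orf)}")
        first_start, _ = self.codon_interval(self.library_positions[0])
        _, last_end = self.codon_interval(self.library_positions[-1])
        if first_start - self.anchor_length < b0 or last_end + self.anchor_length > b1:
            raise DesignError(
                "anchors extend outside the amplicon: variable region "
                f"{first_start}-{last_end} with {self.anchor_length}-nt anchors "
                f"does not fit in amplicon {b0}-{b1}"
            )

    # -- coordinates ------------------------------------------------------

    @staticmethod
    def codon_interval(position: int) -> tuple[int, int]:
        """1-based inclusive nucleotide interval of a residue's codon."""
        return 3 * (position - 1) + 1, 3 * position

    @staticmethod
    def residue_of_nucleotide(nt: int) -> int:
        """Residue number containing a 1-based nucleotide coordinate."""
        return (nt - 1) // 3 + 1

    @property
    def n_positions(self) -> int:
        return len(self.library_positions)

    @property
    def amplicon(self) -> str:
        """The reference amplicon sequence."""
        b0, b1 = self.amplicon_bounds
        return self.reference_orf[b0 - 1 : b1]

    def codon_offsets_in_amplicon(self) -> tuple[int, ...]:
        """0-based start offset of each library codon within the amplicon."""
        b0 = self.amplicon_bounds[0]
        return tuple(self.codon_interval(p)[0] - b0 for p in self.library_positions)

    @property
    def left_anchor(self) -> str:
        """Constant sequence immediately 5' of the first library codon."""
        start, _ = self.codon_interval(self.library_positions[0])
        return self.reference_orf[start - 1 - self.anchor_length : start - 1]

    @property
    def right_anchor(self) -> str:
        """Constant sequence immediately 3' of the last library codon."""
        _, end = self.codon_interval(self.library_positions[-1])
        return self.reference_orf[end : end + self.anchor_length]

    def left_anchor_offset_in_amplicon(self) -> int:
        start, _ = self.codon_interval(self.library_positions[0])
        return start - 1 - self.anchor_length - (self.amplicon_bounds[0] - 1)

    def right_anchor_offset_in_amplicon(self) -> int:
        _, end = self.codon_interval(self.library_positions[-1])
        return end - (self.amplicon_bounds[0] - 1)

    # -- variants ---------------------------------------------------------

    def reference_codons(self) -> tuple[str, ...]:
        """Wild-type codons at the library positions."""
        out = []
        for p in self.library_positions:
            s, e = self.codon_interval(p)
            out.append(self.reference_orf[s - 1 : e])
        return tuple(out)

    @property
    def wildtype_key(self) -> VariantKey:
        return translate_codons(self.reference_codons())

    def variant_space_size(self) -> int:
        """Number of distinct protein-level variants the schemes encode."""
        n = 1
        for s in self.schemes:
            n *= len(scheme_amino_acids(s))
        return n

    def amplicon_for(self, codons: Iterable[str]) -> str:
        """Amplicon sequence with the library codons replaced by ``codons``."""
        amp = list(self.amplicon)
        for off, codon in zip(self.codon_offsets_in_amplicon(), codons, strict=True):
            if len(codon) != 3 or not set(codon.upper()) <= _DNA:
                raise DesignError(f"invalid replacement codon {codon!r}")
            amp[off : off + 3] = codon.upper()
        return "".join(amp)

    # -- serialization ----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "reference": self.reference_orf,
            "positions": list(self.library_positions),
            "schemes": list(self.schemes),
            "anchor_length": self.anchor_length,
            "amplicon_bounds": list(self.amplicon_bounds),
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LibraryDesign":
        doc = yaml.safe_load(Path(path).read_text())
        return design_from_config(doc, base_dir=Path(path).parent)


def design_from_config(doc: Mapping, base_dir: str | Path = ".") -> LibraryDesign:
    """Build a :class:`LibraryDesign` from a parsed config mapping.

    ``reference`` may be a literal DNA sequence or a path to a FASTA file
    (resolved relative to ``base_dir``); the first record is used.
    """
    try:
        ref = doc["reference"]
        positions = doc["positions"]
        schemes = doc["schemes"]
    except (KeyError, TypeError) as exc:
        raise DesignError(f"design config missing required key: {exc}") from None
    if not set(str(ref).upper()) <= _DNA:
        fasta = Path(base_dir) / str(ref)
        if not fasta.exists():
            raise DesignError(f"reference {ref!r} is neither a DNA sequence nor an existing FASTA path")
        records = list(SeqIO.parse(str(fasta), "fasta"))
        if not records:
            raise DesignError(f"no FASTA records in {fasta}")
        ref = str(records[0].seq)
    bounds = doc.get("amplicon_bounds")
    return make_library_design(
        reference_orf=str(ref),
        positions=positions,
        schemes=schemes,
        anchor_length=int(doc.get("anchor_length", 12)),
        amplicon_bounds=tuple(bounds) if bounds else None,
    )


def make_library_design(
    reference_orf: str,
    positions: Iterable[int],
    schemes: Iterable[str],
    anchor_length: int = 12,
    amplicon_bounds: tuple[int, int] | None = None,
) -> LibraryDesign:
    """Validate and construct a :class:`LibraryDesign`.

    When ``amplicon_bounds`` is ``None`` the amplicon defaults to the minimal
    codon-aligned region covering all library codons plus both anchors.
    """
    positions = tuple(int(p) for p in positions)
    schemes = tuple(schemes)
    if amplicon_bounds is None:
        if not positions:
            raise DesignError("at least one library position is required")
        lo = 3 * (min(positions) - 1) + 1 - anchor_length
        hi = 3 * max(positions) + anchor_length
        amplicon_bounds = (max(1, lo), min(len(reference_orf), hi))
    return LibraryDesign(
        reference_orf=reference_orf,
        library_positions=positions,
        schemes=schemes,
        anchor_length=anchor_length,
        amplicon_bounds=tuple(amplicon_bounds),
    )


@dataclass(frozen=True)
class SampleSpec:
    """Metadata for one sequenced selection sample.

    ``condition`` is ``positive`` (grown with the non-canonical monomer),
    ``negative`` (grown without it) or ``input`` (the unselected/naive
    library).  Input samples carry no monomer requirement.
    """

    sample_id: str
    condition: str
    replicate: int = 1
    monomer_label: str | None = None

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise SampleSheetError(
                f"sample {self.sample_id!r}: condition {self.condition!r} not in {CONDITIONS}"
            )
        if self.replicate < 1:
            raise SampleSheetError(f"sample {self.sample_id!r}: replicate must be >= 1")


def validate_specs(specs: Iterable[SampleSpec]) -> None:
    """Check (condition, replicate, monomer) uniqueness across an experiment."""
    seen = set()
    for s in specs:
        k = (s.condition, s.replicate, s.monomer_label if s.condition != "input" else None)
        if k in seen:
            raise SampleSheetError(f"duplicate sample role {k}")
        seen.add(k)


@dataclass
class CountTable:
    """Per-sample variant counts: ``sample_id -> {VariantKey: count}``."""

    counts: dict[str, dict[VariantKey, int]] = field(default_factory=dict)

    def add_sample(self, sample_id: str, variant_counts: Mapping[VariantKey, int]) -> None:
        clean = {}
        for v, c in variant_counts.items():
            c = int(c)
            if c < 0:
                raise ValueError(f"negative count for {v!r} in sample {sample_id!r}")
            if c > 0:
                clean[str(v)] = c
        self.counts[sample_id] = clean

    def total(self, sample_id: str) -> int:
        return sum(self.counts[sample_id].values())

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.counts)

    def variants(self) -> tuple[VariantKey, ...]:
        seen: set[str] = set()
        for d in self.counts.values():
            seen.update(d)
        return tuple(sorted(seen))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": s, "variant": v, "count": c}
            for s, d in self.counts.items()
            for v, c in sorted(d.items())
        ]
        return pd.DataFrame(rows, columns=["sample_id", "variant", "count"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountTable":
        table = cls()
        for sample_id, grp in frame.groupby("sample_id", sort=False):
            table.add_sample(str(sample_id), dict(zip(grp["variant"], grp["count"])))
        return table

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        # keep_default_na: amino-acid keys like "NA" must stay strings
        frame = pd.read_csv(path, sep="\t", dtype={"variant": str}, keep_default_na=False)
        missing = {"sample_id", "variant", "count"} - set(frame.columns)
        if missing:
            raise EmptySampleError(f"count table {path} missing columns {sorted(missing)}")
        return cls.from_frame(frame)


def read_sample_sheet(path: str | Path) -> tuple[list[SampleSpec], dict[str, dict[str, str]]]:
    """Read a TSV sample sheet.

    Required columns: sample_id, condition, replicate.  Optional:
    monomer_label, fastq1, fastq2 (returned verbatim in the extras mapping).
    """
    frame = pd.read_csv(path, sep="\t")
    required = {"sample_id", "condition", "replicate"}
    if not required <= set(frame.columns):
        raise SampleSheetError(f"sample sheet {path} must have columns {sorted(required)}")
    specs, extras = [], {}
    for _, row in frame.iterrows():
        monomer = row.get("monomer_label")
        if pd.isna(monomer):
            monomer = None
        spec = SampleSpec(
            sample_id=str(row["sample_id"]),
            condition=str(row["condition"]),
            replicate=int(row["replicate"]),
            monomer_label=monomer,
        )
        specs.append(spec)
        extras[spec.sample_id] = {
            k: str(row[k]) for k in ("fastq1", "fastq2") if k in frame.columns and not pd.isna(row[k])
        }
    validate_specs(specs)
    return specs, extras


def write_sample_sheet(specs: Iterable[SampleSpec], path: str | Path,
                       fastq_paths: Mapping[str, tuple[str, str]] | None = None) -> None:
    rows = []
    for s in specs:
        row = {
            "sample_id": s.sample_id,
            "condition": s.condition,
            "replicate": s.replicate,
            "monomer_label": s.monomer_label or "",
        }
        if fastq_paths and s.sample_id in fastq_paths:
            row["fastq1"], row["fastq2"] = (str(p) for p in fastq_paths[s.sample_id])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
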