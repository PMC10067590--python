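"""Sequence record types and readers/writers for the external file formats.

The package moves data around as plain text: FASTA for sequences, TSV for the
primer and restriction-enzyme tables, and TSV/JSON for reports.  This module
owns the core record types (:class:`GenomeRecord`, :class:`PrimerSet`,
:class:`EnzymeSpec`) and all parsing/validation, so the analysis modules never
touch files directly.

Conventions
-----------
* Sequences are uppercased on input and ``U`` is converted to ``T`` (primers
  and templates are handled as DNA).
* Genome topology (linear vs circular) is carried as the word ``circular`` in
  the FASTA description; the default is linear.
* IUPAC one-letter ambiguity codes are allowed in genome sequences and enzyme
  recognition sites; primers must be unambiguous A/C/G/T.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# IUPAC nucleotide codes, shared by the PCR and restriction scanners.
# Each code maps to a 4-bit set over (A=1, C=2, G=4, T=8).

IUPAC_BITS: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 1 | 2 | 4 | 8,
}

IUPAC_ALPHABET = frozenset(IUPAC_BITS)

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string, IUPAC codes included."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert U->T; no validation."""
    return seq.upper().replace("U", "T")


class FormatError(ValueError):
    """Raised for malformed input files; message names the offending line."""


# --------------------------------------------------------------------------
# Record types


class Topology(str, enum.Enum):
    LINEAR = "linear"
    CIRCULAR = "circular"


class PrimerRole(str, enum.Enum):
    AMPLIFICATION = "amplification"
    SEQUENCING_INTERNAL = "sequencing_internal"


@dataclass(frozen=True)
class GenomeRecord:
    """One DNA sequence with an identity and a topology."""

    id: str
    sequence: str
    description: str = ""
    topology: Topology = Topology.LINEAR

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("GenomeRecord id must be nonempty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.id}: sequence must be nonempty")
        bad = set(self.sequence) - IUPAC_ALPHABET
        if bad:
            raise ValueError(
                f"{self.id}: illegal sequence character(s) {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology is Topology.CIRCULAR


@dataclass(frozen=True)
class PrimerSet:
    """A locus's forward/reverse primer pair.

    ``role`` separates the amplification pairs from internal sequencing
    primers; ``fwd_in_intron``/``rev_in_intron`` flag primers that bind near a
    terminus but *within* the target intron rather than in the flanking exon.
    """

    locus: str
    forward: str
    reverse: str
    role: PrimerRole = PrimerRole.AMPLIFICATION
    fwd_in_intron: bool = False
    rev_in_intron: bool = False

    def __post_init__(self) -> None:
        if not self.locus:
            raise ValueError("primer locus must be nonempty")
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if not 15 <= len(p) <= 30:
                raise ValueError(
                    f"{self.locus} {name} primer length {len(p)} outside 15-30"
                )
            bad = set(p) - set("ACGT")
            if bad:
                raise ValueError(
                    f"{self.locus} {name} primer has non-ACGT character(s) "
                    f"{sorted(bad)!r}"
                )


@dataclass(frozen=True)
class EnzymeSpec:
    """A Type II restriction enzyme: IUPAC recognition site and cut offsets.

    ``cut_top``/``cut_bottom`` are offsets from the site start (top-strand
    coordinates) at which the top and bottom strands are cut.
    """

    name: str
    site: str
    cut_top: int
    cut_bottom: int

    def __post_init__(self) -> None:
        if len(self.site) < 4:
            raise ValueError(f"{self.name}: site shorter than 4 nt")
        bad = set(self.site) - IUPAC_ALPHABET
        if bad:
            raise ValueError(
                f"{self.name}: illegal IUPAC code(s) {sorted(bad)!r} in site"
            )
        for label, cut in (("cut_top", self.cut_top), ("cut_bottom", self.cut_bottom)):
            if not 0 <= cut <= len(self.site):
                raise ValueError(
                    f"{self.name}: {label}={cut} outside recognition site"
                )

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.site) == self.site


# --------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a (multi-)FASTA file into :class:`GenomeRecord` objects.

    Sequences are uppercased and U->T normalized.  Topology defaults to
    linear; a record whose header contains the word ``circular`` is circular.
    Illegal characters raise :class:`FormatError` naming the line number.
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id == "" or rec.id == "<unknown id>":
            raise FormatError(f"{path}: malformed FASTA header for a record")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = normalize_sequence(str(rec.seq))
        bad = set(seq) - IUPAC_ALPHABET
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} has illegal character(s) "
                f"{sorted(bad)!r} near line {_find_bad_line(path, bad)}"
            )
        tokens = rec.description.split()
        topology = Topology.CIRCULAR if "circular" in tokens[1:] else Topology.LINEAR
        description = " ".join(tokens[1:])
        records.append(
            GenomeRecord(id=rec.id, sequence=seq, description=description,
                         topology=topology)
        )
    return records


def _find_bad_line(path: Path, bad_chars: set[str]) -> int:
    """Locate the first line containing an illegal sequence character."""
    upper_bad = {c.upper() for c in bad_chars}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            if set(normalize_sequence(line.strip())) & upper_bad:
                return lineno
    return 0


def write_fasta(records: Iterable[GenomeRecord], path: str | Path) -> None:
    """Write records as FASTA, 60-column wrapped; topology in the header."""
    seqrecords = []
    for rec in records:
        desc = rec.description
        if rec.is_circular and "circular" not in desc.split():
            desc = (desc + " circular").strip()
        seqrecords.append(SeqRecord(Seq(rec.sequence), id=rec.id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqrecords)


# --------------------------------------------------------------------------
# Primer and enzyme tables

_PRIMER_COLUMNS = ["locus", "forward", "reverse", "role", "binds_within_intron"]


def read_primer_table(path: str | Path) -> list[PrimerSet]:
    """Read a primer TSV (locus, forward, reverse, role, binds_within_intron).

    ``binds_within_intron`` is one of none/forward/reverse/both and may be
    omitted (default none).  An empty file yields an empty list with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("primer table %s is empty", path)
        return []
    missing = {"locus", "forward", "reverse", "role"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    primers: list[PrimerSet] = []
    for i, row in df.iterrows():
        where = str(row.get("binds_within_intron", "none") or "none").lower()
        if where not in {"none", "forward", "reverse", "both"}:
            raise FormatError(
                f"{path} row {i + 2}: bad binds_within_intron value {where!r}"
            )
        try:
            primers.append(
                PrimerSet(
                    locus=str(row["locus"]),
                    forward=normalize_sequence(str(row["forward"])),
                    reverse=normalize_sequence(str(row["reverse"])),
                    role=PrimerRole(str(row["role"])),
                    fwd_in_intron=where in {"forward", "both"},
                    rev_in_intron=where in {"reverse", "both"},
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path} row {i + 2}: {exc}") from exc
    return primers


def write_primer_table(primers: Sequence[PrimerSet], path: str | Path) -> None:
    rows = []
    for p in primers:
        where = {
            (False, False): "none", (True, False): "forward",
            (False, True): "reverse", (True, True): "both",
        }[(p.fwd_in_intron, p.rev_in_intron)]
        rows.append([p.locus, p.forward, p.reverse, p.role.value, where])
    pd.DataFrame(rows, columns=_PRIMER_COLUMNS).to_csv(path, sep="\t", index=False)


def read_enzyme_table(path: str | Path) -> list[EnzymeSpec]:
    """Read an enzyme TSV (name, site, cut_top, cut_bottom)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("enzyme table %s is empty", path)
        return []
    missing = {"name", "site", "cut_top", "cut_bottom"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    enzymes: list[EnzymeSpec] = []
    for i, row in df.iterrows():
        try:
            enzymes.append(
                EnzymeSpec(
                    name=str(row["name"]),
                    site=normalize_sequence(str(row["site"])),
                    cut_top=int(row["cut_top"]),
                    cut_bottom=int(row["cut_bottom"]),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path} row {i + 2}: {exc}") from exc
    return enzymes


# --------------------------------------------------------------------------
# Bundled reference tables


def _data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def load_bundled_primers() -> list[PrimerSet]:
    """The 14 published mitochondrial-intron primer pairs (11 amplification +
    3 internal sequencing pairs) for introns of nad1, nad2, nad4, nad5, nad7
    and ccmFc."""
    return read_primer_table(_data_path("mt_intron_primers.tsv"))


def load_bundled_enzymes() -> list[EnzymeSpec]:
    """A bundled table of common Type IIP restriction enzymes.

    This is a convenience set of widely used enzymes, not any vendor's full
    catalogue; CAPS reports always carry the number of enzymes actually
    tested so results from different tables remain comparable.
    """
    return read_enzyme_table(_data_path("type2_enzymes.tsv"))
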