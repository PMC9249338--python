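"""Sequences, transcript models, coordinate conversion and translation.

Everything downstream (variant application, NMD classification, pseudogene
translation) works in 1-based inclusive *transcript* coordinates, the frame
of reference of HGVS ``c.`` notation: position ``c.1`` is the A of the
initiator ATG.  Genomic coordinates are deliberately absent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "Sequence",
    "TranscriptModel",
    "GeneticCode",
    "STANDARD_CODE",
    "read_fasta",
    "write_fasta",
    "load_transcript",
    "coding_to_transcript",
    "transcript_to_coding",
    "translate_cds",
]

DNA_ALPHABET = set("ACGTN")
RNA_ALPHABET = set("ACGUN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY" + "X*")


class SequenceError(ValueError):
    """Raised for malformed sequences or sequence files."""


@dataclass(frozen=True)
class Sequence:
    """A named sequence over a declared alphabet.

    ``residues`` is upper-case; RNA input is accepted for the DNA alphabet and
    silently mapped U->T on construction (mRNA and cDNA vocabulary are used
    interchangeably by variant databases).
    """

    id: str
    residues: str
    alphabet: str = "DNA"  # DNA | RNA | PROTEIN

    def __post_init__(self) -> None:
        residues = self.residues.upper()
        if self.alphabet == "DNA":
            residues = residues.replace("U", "T")
        object.__setattr__(self, "residues", residues)
        if not residues:
            raise SequenceError(f"sequence {self.id!r} is empty")
        allowed = {
            "DNA": DNA_ALPHABET,
            "RNA": RNA_ALPHABET,
            "PROTEIN": PROTEIN_ALPHABET,
        }[self.alphabet]
        for i, ch in enumerate(residues, start=1):
            if ch not in allowed:
                raise SequenceError(
                    f"sequence {self.id!r}: invalid {self.alphabet} character "
                    f"{ch!r} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneticCode:
    """Codon translation table (standard nuclear code by default)."""

    table: dict[str, str]
    stop_codons: frozenset[str]

    @classmethod
    def standard(cls) -> "GeneticCode":
        ncbi = CodonTable.unambiguous_dna_by_id[1]
        table = dict(ncbi.forward_table)
        stops = frozenset(ncbi.stop_codons)
        for codon in stops:
            table[codon] = "*"
        assert len(table) == 64 and len(stops) == 3
        return cls(table=table, stop_codons=stops)


STANDARD_CODE = GeneticCode.standard()


@dataclass
class TranscriptModel:
    """A processed transcript: cDNA, exon intervals, CDS bounds.

    Exons are (start, end) 1-based inclusive in transcript coordinates,
    contiguous, starting at 1 and ending at the cDNA length.  cds_start /
    cds_end bound the coding sequence (ATG .. stop) on the transcript.
    """

    id: str
    cdna: Sequence
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    warnings_: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.cdna)
        if not self.exons:
            raise ValueError(f"transcript {self.id!r}: no exons")
        if self.exons[0][0] != 1:
            raise ValueError(f"transcript {self.id!r}: exon 1 must start at 1")
        prev_end = 0
        for i, (start, end) in enumerate(self.exons, start=1):
            if start > end:
                raise ValueError(
                    f"transcript {self.id!r}: exon {i} has start > end"
                )
            if start != prev_end + 1:
                kind = "gap" if start > prev_end + 1 else "overlap"
                raise ValueError(
                    f"transcript {self.id!r}: {kind} after exon {i - 1}"
                )
            prev_end = end
        if prev_end != n:
            raise ValueError(
                f"transcript {self.id!r}: exons cover 1..{prev_end} "
                f"but cDNA has length {n}"
            )
        if not (1 <= self.cds_start <= self.cds_end <= n):
            raise ValueError(
                f"transcript {self.id!r}: CDS {self.cds_start}..{self.cds_end} "
                f"outside transcript of length {n}"
            )
        # Soft checks: unusual but biologically possible annotations.
        cds = self.cds
        if len(cds) % 3 != 0:
            self._warn("CDS length not divisible by 3")
        if not cds.startswith("ATG"):
            self._warn("CDS does not begin with ATG")
        if len(cds) % 3 == 0 and cds[-3:] not in STANDARD_CODE.stop_codons:
            self._warn("CDS does not end with a stop codon")

    def _warn(self, msg: str) -> None:
        full = f"transcript {self.id!r}: {msg}"
        self.warnings_.append(full)
        warnings.warn(full, stacklevel=3)

    @property
    def cds(self) -> str:
        return self.cdna.residues[self.cds_start - 1 : self.cds_end]

    @property
    def cds_len(self) -> int:
        return self.cds_end - self.cds_start + 1

    @property
    def junctions(self) -> list[int]:
        """Transcript positions of exon-exon junctions: ends of exons 1..n-1."""
        return [end for (_, end) in self.exons[:-1]]


def read_fasta(path: str | Path, alphabet: str = "DNA") -> list[Sequence]:
    """Read a FASTA file into validated :class:`Sequence` records.

    The header token before the first whitespace becomes the id; residues are
    case-normalized to upper (and U->T under the DNA alphabet).
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    return [Sequence(rec.id, str(rec.seq), alphabet) for rec in records]


def write_fasta(sequences: list[Sequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


def load_transcript(
    cdna: Sequence,
    exon_table_path: str | Path,
    cds_start: int,
    cds_end: int,
) -> TranscriptModel:
    """Build a validated TranscriptModel from a cDNA and an exon TSV.

    The TSV must have a header row with columns exon_index, start, end
    (1-based inclusive transcript coordinates).
    """
    table = pd.read_csv(exon_table_path, sep="\t")
    required = {"exon_index", "start", "end"}
    if not required.issubset(table.columns):
        raise ValueError(
            f"exon table {exon_table_path}: needs columns {sorted(required)}"
        )
    table = table.sort_values("exon_index")
    exons = [(int(r.start), int(r.end)) for r in table.itertuples()]
    return TranscriptModel(cdna.id, cdna, exons, cds_start, cds_end)


def coding_to_transcript(model: TranscriptModel, c_pos: int) -> int:
    """Map an HGVS coding position (c.) to a transcript position."""
    if not 1 <= c_pos <= model.cds_len:
        raise ValueError(
            f"c.{c_pos} outside CDS of length {model.cds_len}"
        )
    return model.cds_start + c_pos - 1


def transcript_to_coding(model: TranscriptModel, t_pos: int) -> int:
    """Inverse of :func:`coding_to_transcript`."""
    c_pos = t_pos - model.cds_start + 1
    if not 1 <= c_pos <= model.cds_len:
        raise ValueError(f"transcript position {t_pos} outside CDS")
    return c_pos


def translate_cds(
    dna: str,
    code: GeneticCode = STANDARD_CODE,
    stop_at_first_stop: bool = True,
) -> tuple[str, bool]:
    """Translate a DNA string codon by codon from position 1.

    Trailing 1-2 bases are ignored.  A codon containing an ambiguity code
    translates to 'X'.  Returns (protein, stopped); with stop_at_first_stop
    the protein ends before the first stop codon, otherwise stops render '*'.
    """
    if len(dna) < 3:
        raise ValueError("need at least one full codon")
    dna = dna.upper().replace("U", "T")
    out: list[str] = []
    stopped = False
    for i in range(0, len(dna) - len(dna) % 3, 3):
        codon = dna[i : i + 3]
        aa = code.table.get(codon, "X")
        if aa == "*":
            stopped = True
            if stop_at_first_stop:
                break
        out.append(aa)
    if stop_at_first_stop and stopped:
        return "".join(out), True
    return "".join(out), stopped
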