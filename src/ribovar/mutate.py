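"""HGVS c.-notation parsing, variant application and consequence prediction.

Supported grammar (coding DNA positions only):

    c.76A>C            substitution
    c.331del / c.331delC
    c.25_42del / c.25_42delAC...
    c.53_54insAGA      insertion between positions 53 and 54
    c.76dup / c.76dupA / c.76_78dup
    c.76_78delinsTT    deletion-insertion

Intronic positions (c.N+M / c.N-M) are rejected with
:class:`IntronicVariantError` so callers can route splice-site variants to
their own category; protein-level (p.) and genomic (g.) notation are out of
scope.  Duplications are treated as insertions of the duplicated span
immediately after it.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import pandas as pd

from .genemodel import (
    STANDARD_CODE,
    TranscriptModel,
    coding_to_transcript,
    translate_cds,
)

__all__ = [
    "VariantKind",
    "ConsequenceClass",
    "HgvsVariant",
    "ProteinConsequence",
    "HgvsParseError",
    "IntronicVariantError",
    "RefMismatchError",
    "parse_hgvs_c",
    "apply_variant",
    "predict_consequence",
    "summarize_consequences",
    "read_variant_table",
    "write_consequence_table",
]


class VariantKind(str, Enum):
    SUB = "SUB"
    DEL = "DEL"
    INS = "INS"
    DUP = "DUP"
    DELINS = "DELINS"


class ConsequenceClass(str, Enum):
    SYNONYMOUS = "SYNONYMOUS"
    MISSENSE = "MISSENSE"
    NONSENSE = "NONSENSE"
    INFRAME_DEL = "INFRAME_DEL"
    INFRAME_INS = "INFRAME_INS"
    FRAMESHIFT = "FRAMESHIFT"
    START_LOSS = "START_LOSS"
    STOP_LOSS = "STOP_LOSS"


class HgvsParseError(ValueError):
    pass


class IntronicVariantError(HgvsParseError):
    """Intronic (c.N+M / c.N-M) positions: valid HGVS, outside this grammar."""


class RefMismatchError(ValueError):
    pass


@dataclass(frozen=True)
class HgvsVariant:
    raw: str
    kind: VariantKind
    c_start: int
    c_end: int
    ref_allele: str = ""
    alt_allele: str = ""

    def __post_init__(self) -> None:
        if self.c_start > self.c_end:
            raise HgvsParseError(
                f"{self.raw!r}: reversed range {self.c_start}_{self.c_end}"
            )
        if self.kind is VariantKind.INS:
            if self.c_end != self.c_start + 1:
                raise HgvsParseError(
                    f"{self.raw!r}: insertion must be between adjacent positions"
                )
            if not self.alt_allele:
                raise HgvsParseError(f"{self.raw!r}: insertion without sequence")
        if self.kind is VariantKind.SUB and (
            len(self.ref_allele) != 1 or len(self.alt_allele) != 1
        ):
            raise HgvsParseError(f"{self.raw!r}: substitution must be 1 nt")


@dataclass(frozen=True)
class ProteinConsequence:
    variant: HgvsVariant
    klass: ConsequenceClass
    mutant_protein: str
    mutant_length: int
    ptc_c_pos: int | None  # coding position (mutant coords) of PTC first base
    length_delta_nt: int
    no_stop: bool = False  # translation ran off the transcript end


_INTRONIC = re.compile(r"^c\.\d+[+-]\d+")
_SUB = re.compile(r"^c\.(\d+)([ACGTU])>([ACGTU])$")
_DEL = re.compile(r"^c\.(\d+)(?:_(\d+))?del([ACGTU]*)$")
_INS = re.compile(r"^c\.(\d+)_(\d+)ins([ACGTU]+)$")
_DUP = re.compile(r"^c\.(\d+)(?:_(\d+))?dup([ACGTU]*)$")
_DELINS = re.compile(r"^c\.(\d+)(?:_(\d+))?delins([ACGTU]+)$")


def parse_hgvs_c(text: str) -> HgvsVariant:
    """Parse a coding-DNA HGVS string into an :class:`HgvsVariant`."""
    s = text.strip()
    if not s.startswith("c."):
        raise HgvsParseError(f"{text!r}: HGVS coding variant must start with 'c.'")
    if _INTRONIC.match(s):
        raise IntronicVariantError(
            f"{text!r}: intronic position; splice-site variants are not "
            "representable on the transcript"
        )
    def _nt(allele: str) -> str:
        # mRNA-style alleles: U -> T
        return allele.upper().replace("U", "T")

    if m := _SUB.match(s):
        pos = int(m.group(1))
        return HgvsVariant(
            text, VariantKind.SUB, pos, pos, _nt(m.group(2)), _nt(m.group(3))
        )
    if m := _DELINS.match(s):
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        return HgvsVariant(text, VariantKind.DELINS, start, end, "", _nt(m.group(3)))
    if m := _DEL.match(s):
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        return HgvsVariant(text, VariantKind.DEL, start, end, _nt(m.group(3)), "")
    if m := _INS.match(s):
        return HgvsVariant(
            text, VariantKind.INS, int(m.group(1)), int(m.group(2)), "", _nt(m.group(3))
        )
    if m := _DUP.match(s):
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        return HgvsVariant(text, VariantKind.DUP, start, end, _nt(m.group(3)), "")
    raise HgvsParseError(f"{text!r}: unsupported or malformed HGVS string")


def apply_variant(model: TranscriptModel, v: HgvsVariant) -> tuple[str, int]:
    """Apply a variant to the transcript's cDNA.

    Returns (mutant cDNA, net nucleotide change).  Coordinates must lie in
    the CDS; a stated reference allele is checked against the transcript.
    """
    t_start = coding_to_transcript(model, v.c_start)
    t_end = coding_to_transcript(model, v.c_end)
    cdna = model.cdna.residues
    found = cdna[t_start - 1 : t_end]

    if v.kind in (VariantKind.SUB, VariantKind.DEL, VariantKind.DUP):
        if v.ref_allele and found != v.ref_allele:
            raise RefMismatchError(
                f"{v.raw!r}: expected {v.ref_allele!r} at c.{v.c_start}"
                f"{'_' + str(v.c_end) if v.c_end != v.c_start else ''}, "
                f"found {found!r}"
            )

    if v.kind is VariantKind.SUB:
        mutant = cdna[: t_start - 1] + v.alt_allele + cdna[t_start:]
        delta = 0
    elif v.kind is VariantKind.DEL:
        mutant = cdna[: t_start - 1] + cdna[t_end:]
        delta = -(t_end - t_start + 1)
    elif v.kind is VariantKind.INS:
        # inserted between c_start and c_end = c_start + 1
        mutant = cdna[:t_start] + v.alt_allele + cdna[t_start:]
        delta = len(v.alt_allele)
    elif v.kind is VariantKind.DUP:
        mutant = cdna[:t_end] + found + cdna[t_end:]
        delta = len(found)
    elif v.kind is VariantKind.DELINS:
        mutant = cdna[: t_start - 1] + v.alt_allele + cdna[t_end:]
        delta = len(v.alt_allele) - (t_end - t_start + 1)
    else:  # pragma: no cover
        raise AssertionError(v.kind)
    return mutant, delta


def _edit_site_t_pos(model: TranscriptModel, v: HgvsVariant) -> int:
    """First transcript position at/after which coordinates can shift."""
    return coding_to_transcript(model, v.c_start)


def predict_consequence(model: TranscriptModel, v: HgvsVariant) -> ProteinConsequence:
    """Translate the mutant transcript and classify the protein consequence.

    Translation starts at the original cds_start and, for frameshifts,
    continues into the 3' UTR until a stop codon or the transcript end.
    """
    mutant_cdna, delta = apply_variant(model, v)
    cds_len = model.cds_len

    # START_LOSS: the initiator codon itself is disrupted.
    if mutant_cdna[model.cds_start - 1 : model.cds_start + 2] != "ATG":
        return ProteinConsequence(v, ConsequenceClass.START_LOSS, "", 0, None, delta)

    # Translate from cds_start through the end of the mutant transcript.
    tail = mutant_cdna[model.cds_start - 1 :]
    protein, stopped = translate_cds(tail, STANDARD_CODE, stop_at_first_stop=True)
    no_stop = not stopped

    # Position (mutant coding coords, 1-based) of the first base of the stop
    # codon actually used, and of where the natural stop now sits.
    stop_c_pos = 3 * len(protein) + 1 if stopped else None
    natural_stop_c_pos = cds_len - 2 + (delta if v.c_start <= cds_len - 3 else 0)

    premature = stopped and stop_c_pos < natural_stop_c_pos
    ptc_c_pos = stop_c_pos if premature else None

    wt_protein, _ = translate_cds(model.cds, STANDARD_CODE, stop_at_first_stop=True)

    natural_stop_hit = v.c_start <= cds_len and v.c_end >= cds_len - 2
    if v.kind is VariantKind.SUB:
        if natural_stop_hit:
            klass = (
                ConsequenceClass.SYNONYMOUS
                if stopped and stop_c_pos == natural_stop_c_pos
                else ConsequenceClass.STOP_LOSS
            )
        elif premature:
            klass = ConsequenceClass.NONSENSE
        elif protein == wt_protein:
            klass = ConsequenceClass.SYNONYMOUS
        else:
            klass = ConsequenceClass.MISSENSE
    elif delta % 3 != 0:
        klass = ConsequenceClass.FRAMESHIFT
    elif natural_stop_hit and v.kind in (VariantKind.DEL, VariantKind.DELINS) and (
        not stopped or stop_c_pos > natural_stop_c_pos
    ):
        klass = ConsequenceClass.STOP_LOSS
    elif delta < 0:
        klass = ConsequenceClass.INFRAME_DEL
    elif delta > 0:
        klass = ConsequenceClass.INFRAME_INS
    elif premature:  # net-0 delins creating a premature stop
        klass = ConsequenceClass.NONSENSE
    else:  # in-frame delins, net 0
        klass = (
            ConsequenceClass.SYNONYMOUS
            if protein == wt_protein
            else ConsequenceClass.MISSENSE
        )

    return ProteinConsequence(
        variant=v,
        klass=klass,
        mutant_protein=protein,
        mutant_length=len(protein),
        ptc_c_pos=ptc_c_pos,
        length_delta_nt=delta,
        no_stop=no_stop,
    )


def summarize_consequences(consequences: list[ProteinConsequence]) -> pd.DataFrame:
    """Count and percentage per consequence class (the cohort distribution)."""
    if not consequences:
        raise ValueError("no consequences to summarize")
    counts = Counter(c.klass.value for c in consequences)
    total = sum(counts.values())
    rows = [
        {"klass": k, "count": n, "percent": 100.0 * n / total}
        for k, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows)


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read a variant TSV with columns variant_id, hgvs_c ('#' comments allowed)."""
    table = pd.read_csv(path, sep="\t", comment="#")
    if not {"variant_id", "hgvs_c"}.issubset(table.columns):
        raise ValueError(f"{path}: needs columns variant_id, hgvs_c")
    return table


def write_consequence_table(
    consequences: list[tuple[str, ProteinConsequence]], path: str | Path
) -> None:
    rows = [
        {
            "variant_id": vid,
            "hgvs_c": c.variant.raw,
            "klass": c.klass.value,
            "mutant_length": c.mutant_length,
            "ptc_c_pos": c.ptc_c_pos if c.ptc_c_pos is not None else "",
            "length_delta_nt": c.length_delta_nt,
        }
        for vid, c in consequences
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
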