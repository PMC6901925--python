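"""Sequence records and alphabet handling shared across the pipeline.

All nucleotide sequences are normalized to uppercase RNA (T -> U) on ingest;
protein sequences to the 20-letter alphabet plus X. Ambiguity codes are
rejected with a clear error rather than silently scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


class Region(str, Enum):
    UTR3 = "UTR3"
    CDS = "CDS"
    TRANSCRIPT = "transcript"
    PROTEIN = "protein"


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains characters outside its alphabet."""


def normalize_rna(seq: str, *, context: str = "") -> str:
    """Uppercase, T->U, and validate against the unambiguous RNA alphabet."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        where = f" in {context}" if context else ""
        raise InvalidSequenceError(
            f"non-ACGU characters {sorted(bad)}{where}; ambiguity codes are not supported"
        )
    return s


def normalize_protein(seq: str, *, context: str = "") -> str:
    s = seq.upper()
    bad = set(s) - PROTEIN_ALPHABET
    if bad:
        where = f" in {context}" if context else ""
        raise InvalidSequenceError(f"non-amino-acid characters {sorted(bad)}{where}")
    return s


def revcomp_rna(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA, 5'->3', RNA alphabet."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence, context=self.id))
        if len(self.sequence) < 15:
            raise InvalidSequenceError(f"miRNA {self.id} shorter than 15 nt")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript-level sequence with region metadata."""

    id: str
    sequence: str
    gene_id: str = ""
    region: Region = Region.TRANSCRIPT

    def __post_init__(self) -> None:
        gene = self.gene_id or self.id
        object.__setattr__(self, "gene_id", gene)
        if self.region is Region.PROTEIN:
            seq = normalize_protein(self.sequence, context=self.id)
        else:
            seq = normalize_rna(self.sequence, context=self.id)
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


def read_mirna_fasta(path: str | Path) -> list[MiRNA]:
    return [MiRNA(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_transcript_fasta(
    path: str | Path, region: Region = Region.TRANSCRIPT
) -> list[TranscriptRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = rec.id
        # honor a "gene=XXX" tag in the description when present
        for tok in rec.description.split():
            if tok.startswith("gene="):
                gene = tok[5:]
        out.append(TranscriptRecord(rec.id, str(rec.seq), gene_id=gene, region=region))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    """Write (id, sequence) pairs; deterministic plain-text output."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def translate_cds(cds_rna: str) -> str:
    """Translate an RNA CDS, trimming any trailing partial codon."""
    usable = len(cds_rna) - len(cds_rna) % 3
    return str(Seq(cds_rna[:usable].replace("U", "T")).translate())
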