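"""Sequence records and file round-trips.

A :class:`ProteinRecord` is the unit that flows through screening,
annotation and clustering: one translated gene with its identifiers and
whatever sample metadata (depth, taxon label) travelled with it.
FASTA handling is delegated to Biopython; tables are pandas DataFrames
written as plain TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA20 = set("ACDEFGHIKLMNPQRSTVWY")
#: standard residues plus X for assembly ambiguity
AA_ALPHABET = AA20 | {"X"}
NT_ALPHABET = set("ACGTUN")


@dataclass
class ProteinRecord:
    """One protein sequence with its provenance.

    ``depth_m`` and ``taxon`` are carried as metadata only; nothing in the
    screen or annotation stages reads them.
    """

    id: str
    aa_sequence: str
    nt_sequence: Optional[str] = None
    sample_id: str = ""
    depth_m: Optional[float] = None
    taxon: Optional[str] = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        self.aa_sequence = self.aa_sequence.upper()
        if not self.aa_sequence:
            raise ValueError(f"{self.id}: empty amino-acid sequence")
        for i, c in enumerate(self.aa_sequence):
            if c not in AA_ALPHABET:
                raise ValueError(
                    f"{self.id}: non-amino-acid character {c!r} at position {i + 1}"
                )
        if self.nt_sequence is not None:
            self.nt_sequence = self.nt_sequence.upper()
            n, m = len(self.nt_sequence), len(self.aa_sequence)
            # 3L without stop codon, 3(L+1) with it
            if n not in (3 * m, 3 * (m + 1)):
                raise ValueError(
                    f"{self.id}: nucleotide length {n} does not match "
                    f"protein length {m} (expected {3 * m} or {3 * (m + 1)})"
                )
        if self.depth_m is not None and self.depth_m < 0:
            raise ValueError(f"{self.id}: negative depth {self.depth_m}")

    @property
    def x_fraction(self) -> float:
        return self.aa_sequence.count("X") / len(self.aa_sequence)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA (wrapped or unwrapped) into records.

    Raises on duplicate identifiers (all listed) and on non-amino-acid
    characters (position named).
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seen[rec.id] = seen.get(rec.id, 0) + 1
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(ProteinRecord(id=rec.id, aa_sequence=str(rec.seq), description=desc))
    dupes = sorted(i for i, n in seen.items() if n > 1)
    if dupes:
        raise ValueError(f"{path}: duplicate record ids: {', '.join(dupes)}")
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqrecs = [
        SeqRecord(Seq(r.aa_sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqrecs, fh, "fasta")


def read_tsv(path: str | Path) -> pd.DataFrame:
    """Read a header-bearing TSV; CRLF and LF line endings are equivalent."""
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV deterministically (fixed float format, LF endings)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")
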