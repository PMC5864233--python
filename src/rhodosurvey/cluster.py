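"""Greedy identity-threshold dereplication (CD-HIT style).

Sequences are sorted longest first and each joins the first existing
cluster whose representative it matches at or above the identity
threshold, else founds its own cluster. Identity is computed from the
optimal global alignment; by default the denominator is the shorter
sequence length, a dereplication convention tolerant of gene fragments
(a perfect fragment of a representative clusters with it). An
alignment-length denominator is available instead, and only with that
denominator can the length-ratio shortcut soundly skip pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

from .align import AlignParams, global_align
from .records import ProteinRecord

LEVELS = ("amino_acid", "nucleotide")

#: scoring per level (protein: BLAST defaults; nucleotide: +5/-4, 10/1)
LEVEL_PARAMS = {
    "amino_acid": AlignParams(matrix="BLOSUM62", gap_open=11.0, gap_extend=1.0),
    "nucleotide": AlignParams(matrix="simple_nt", gap_open=10.0, gap_extend=1.0),
}


@dataclass
class Cluster:
    representative_id: str
    member_ids: list[str]
    threshold: float
    level: str
    #: identity of each member to the representative, parallel to member_ids
    identities: list[float] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_ids)


def _as_pairs(records: Sequence[Union[ProteinRecord, tuple[str, str]]], level: str):
    pairs = []
    for rec in records:
        if isinstance(rec, ProteinRecord):
            seq = rec.nt_sequence if level == "nucleotide" else rec.aa_sequence
            if seq is None:
                raise ValueError(f"{rec.id}: no nucleotide sequence for nt-level clustering")
            pairs.append((rec.id, seq))
        else:
            pairs.append(tuple(rec))
    return pairs


def pairwise_identity(
    a: str,
    b: str,
    level: str = "amino_acid",
    denominator: str = "shorter",
) -> float:
    """Identity of the optimal global alignment of two sequences.

    ``denominator='shorter'`` divides identical columns by the shorter
    sequence length (symmetric, fragment-tolerant); ``'alignment'``
    divides by the number of alignment columns.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    if not a or not b:
        raise ValueError("cannot compute identity of empty sequences")
    amap = global_align(a, b, LEVEL_PARAMS[level])
    matches = sum(1 for qp, rp in amap.pairs if a[qp].upper() == b[rp].upper())
    if denominator == "shorter":
        return matches / min(len(a), len(b))
    if denominator == "alignment":
        # columns = aligned pairs + residues left unpaired in either sequence
        columns = len(a) + len(b) - len(amap.pairs)
        return matches / columns
    raise ValueError(f"unknown denominator {denominator!r}")


def greedy_cluster(
    records: Sequence[Union[ProteinRecord, tuple[str, str]]],
    threshold: float = 0.95,
    level: str = "amino_acid",
    denominator: str = "shorter",
) -> list[Cluster]:
    """Dereplicate records at an identity threshold.

    Longest-first, first-fit: the output is a partition in which every
    member matches its representative at >= threshold and every
    representative matches all earlier (longer) representatives at
    < threshold. Ties in length are broken by lexicographic id, which
    together with the deterministic aligner makes output order stable.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    pairs = _as_pairs(records, level)
    if not pairs:
        raise ValueError("no records to cluster")
    ids = [p[0] for p in pairs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    order = sorted(pairs, key=lambda p: (-len(p[1]), p[0]))
    clusters: list[Cluster] = []
    reps: list[tuple[str, str]] = []
    for rec_id, seq in order:
        placed = False
        for k, (rep_id, rep_seq) in enumerate(reps):
            if denominator == "alignment":
                ratio = min(len(seq), len(rep_seq)) / max(len(seq), len(rep_seq))
                if ratio < threshold:  # identity can never reach threshold
                    continue
            ident = pairwise_identity(seq, rep_seq, level, denominator)
            if ident >= threshold:
                clusters[k].member_ids.append(rec_id)
                clusters[k].identities.append(ident)
                placed = True
                break
        if not placed:
            clusters.append(
                Cluster(
                    representative_id=rec_id,
                    member_ids=[rec_id],
                    threshold=threshold,
                    level=level,
                    identities=[1.0],
                )
            )
            reps.append((rec_id, seq))
    return clusters
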