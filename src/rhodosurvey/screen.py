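"""Opsin candidate validation.

A candidate passes when it (i) has exactly seven called transmembrane
segments, (ii) carries a lysine at the query position homologous to the
reference retinal-binding lysine, and (iii) that lysine lies within the
seventh (last) called segment. Failures are enumerated, never
short-circuited, so a decoy failing two ways reports both reasons.

The retinal lysine is located by global alignment to the reference
frame rather than by scanning TM7 for any lysine: homology, not
composition, is the criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .align import MISSING, AlignParams, DEFAULT_ALIGN, global_align, map_position
from .hydropathy import DEFAULT_TOPOLOGY, TopologyParams, call_topology
from .records import ProteinRecord
from .reference import ReferenceFrame

#: fraction of X residues above which a sequence is deemed ambiguous
MAX_X_FRACTION = 0.2
#: slack around the called seventh segment when testing lysine membership;
#: window smoothing blurs segment edges by a couple of residues
TM7_TOLERANCE = 2


@dataclass
class ScreenResult:
    record_id: str
    passed: bool
    tm_count: int
    retinal_lysine_position: Optional[int]  # 0-based query index, None if absent
    fail_reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.passed == (not self.fail_reasons)


def screen_opsin(
    record: ProteinRecord,
    reference: ReferenceFrame,
    topology_params: TopologyParams = DEFAULT_TOPOLOGY,
    align_params: AlignParams = DEFAULT_ALIGN,
    tm7_tolerance: int = TM7_TOLERANCE,
    max_x_fraction: float = MAX_X_FRACTION,
) -> ScreenResult:
    """Apply the seven-TM + retinal-lysine exclusion rule to one record."""
    seq = record.aa_sequence
    reasons: list[str] = []

    if len(seq) < topology_params.window:
        return ScreenResult(
            record_id=record.id,
            passed=False,
            tm_count=0,
            retinal_lysine_position=None,
            fail_reasons=["ambiguous_sequence"],
        )
    if record.x_fraction > max_x_fraction:
        reasons.append("ambiguous_sequence")

    topo = call_topology(seq, topology_params)
    if topo.tm_count != 7:
        reasons.append("tm_count_not_7")

    amap = global_align(
        seq, reference.aa_sequence, align_params,
        query_id=record.id, ref_name=reference.name,
    )
    qpos = map_position(amap, reference.retinal_lysine_pr)
    lys_pos: Optional[int] = None
    if qpos is MISSING or seq[qpos] != "K":
        reasons.append("no_retinal_lysine")
    else:
        lys_pos = qpos
        if topo.segments:
            start, end = topo.segments[-1]
            in_tm7 = start - tm7_tolerance <= lys_pos < end + tm7_tolerance
        else:
            in_tm7 = False
        if not in_tm7:
            reasons.append("lysine_outside_tm7")

    return ScreenResult(
        record_id=record.id,
        passed=not reasons,
        tm_count=topo.tm_count,
        retinal_lysine_position=lys_pos,
        fail_reasons=reasons,
    )


def read_hmm_hits(
    path: str | Path,
    evalue_max: float = 1e-5,
    dialect: str = "auto",
) -> set[str]:
    """Target ids from a HMMER3 ``--tblout``/``--domtblout`` file.

    Keeps targets whose full-sequence E-value is ``<= evalue_max``;
    ``dialect='auto'`` distinguishes the two layouts by column count.
    Malformed lines raise with the line number.
    """
    if dialect not in ("auto", "tblout", "domtblout"):
        raise ValueError(f"unknown HMMER dialect {dialect!r}")
    path = Path(path)
    hits: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            this_dialect = dialect
            if this_dialect == "auto":
                this_dialect = "domtblout" if len(fields) >= 23 else "tblout"
            evalue_col = 6 if this_dialect == "domtblout" else 4
            if len(fields) <= evalue_col:
                raise ValueError(
                    f"{path}:{lineno}: malformed HMMER {this_dialect} line "
                    f"({len(fields)} fields)"
                )
            try:
                evalue = float(fields[evalue_col])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric E-value {fields[evalue_col]!r}"
                ) from None
            if evalue <= evalue_max:
                hits.add(fields[0])
    return hits
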