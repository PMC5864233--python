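"""Motif extraction and functional classification.

Each validated opsin is aligned to the reference frame and its residues
at proteorhodopsin positions 97, 101, 105 and 108 are read off. Sites
97/101/108 form the ion-pumping motif (DTE and DTD: proton pumps; NDQ:
sodium pump; NTQ: chloride pump); site 105 is the spectral-tuning
residue (Q: blue-absorbing; L, M, I: green-absorbing; T and everything
else: unknown absorption — T is abundant in deep-water sequences but its
spectral role has not been established, and motifs such as DTT and DTQ
have no confirmed pump assignment). Variants are reported with the
combined "PUMP-TUNING" shorthand, e.g. "DTE-Q" or "DTT-T".

Partial sequences missing any of the four sites are flagged incomplete
and excluded from motif summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .align import AlignParams, DEFAULT_ALIGN, MISSING, global_align, map_position
from .records import ProteinRecord
from .reference import ReferenceFrame

#: placeholder used in tables for an unreadable site
MISSING_CHAR = "-"

PUMP_CLASSES = ("proton_pump", "sodium_pump", "chloride_pump", "unknown")
TUNING_CLASSES = ("blue", "green", "unknown")

#: ion-pumping rule table over residues (97, 101, 108); user-extensible
PUMP_RULES: dict[str, str] = {
    "DTE": "proton_pump",
    "DTD": "proton_pump",
    "NDQ": "sodium_pump",
    "NTQ": "chloride_pump",
}

#: spectral-tuning rule table over residue 105
TUNING_RULES: dict[str, str] = {
    "Q": "blue",
    "L": "green",
    "M": "green",
    "I": "green",
    # "T" deliberately absent: unknown absorption
}

#: alignments below this identity are refused as unalignable
DEFAULT_MIN_IDENTITY = 0.25


class UnalignableError(ValueError):
    """Query/reference identity below the transfer floor."""


@dataclass
class MotifCall:
    """The four extracted residues plus their functional read-out."""

    record_id: str
    residue_97: Optional[str]
    residue_101: Optional[str]
    residue_105: Optional[str]
    residue_108: Optional[str]
    alignment_identity: float = float("nan")

    @property
    def complete(self) -> bool:
        return None not in (
            self.residue_97, self.residue_101, self.residue_105, self.residue_108
        )

    @property
    def pump_motif(self) -> str:
        return "".join(
            r if r is not None else MISSING_CHAR
            for r in (self.residue_97, self.residue_101, self.residue_108)
        )

    @property
    def combined_label(self) -> str:
        tuning = self.residue_105 if self.residue_105 is not None else MISSING_CHAR
        return f"{self.pump_motif}-{tuning}"

    @property
    def pump_class(self) -> str:
        return classify_pump(self.residue_97, self.residue_101, self.residue_108)

    @property
    def tuning_class(self) -> str:
        return classify_tuning(self.residue_105)


def classify_pump(
    r97: Optional[str],
    r101: Optional[str],
    r108: Optional[str],
    rules: Mapping[str, str] = PUMP_RULES,
) -> str:
    """Pump class of an ion-pumping motif; total and case-insensitive."""
    if None in (r97, r101, r108):
        return "unknown"
    return rules.get((r97 + r101 + r108).upper(), "unknown")


def classify_tuning(r105: Optional[str], rules: Mapping[str, str] = TUNING_RULES) -> str:
    """Spectral class of the tuning residue; total and case-insensitive."""
    if r105 is None:
        return "unknown"
    return rules.get(r105.upper(), "unknown")


def extract_motif(
    record: ProteinRecord,
    reference: ReferenceFrame,
    align_params: AlignParams = DEFAULT_ALIGN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> MotifCall:
    """Read the four motif residues of one record via the reference frame.

    Raises :class:`UnalignableError` when the global-alignment identity
    falls below ``min_identity`` (position transfer between
    non-homologues is meaningless).
    """
    amap = global_align(
        record.aa_sequence, reference.aa_sequence, align_params,
        query_id=record.id, ref_name=reference.name,
    )
    if amap.identity < min_identity:
        raise UnalignableError(
            f"{record.id}: identity {amap.identity:.3f} to {reference.name} "
            f"below floor {min_identity}"
        )
    residues: list[Optional[str]] = []
    for ref_pos in reference.motif_positions_pr:
        qpos = map_position(amap, ref_pos)
        residues.append(record.aa_sequence[qpos] if qpos is not MISSING else None)
    return MotifCall(
        record_id=record.id,
        residue_97=residues[0],
        residue_101=residues[1],
        residue_105=residues[2],
        residue_108=residues[3],
        alignment_identity=amap.identity,
    )
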