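"""The residue-numbering reference frame.

All motif positions in this package are quoted in the proteorhodopsin
frame of the canonical green-absorbing proteorhodopsin eBAC31A08
(bundled): spectral-tuning site 105 and ion-pumping sites 97/101/108,
with the retinal-binding lysine at 231. The classical bacteriorhodopsin
frame differs by a constant offset of 12 at these sites (97→85, 101→89,
105→93, 108→96) and is provided for reporting only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

from .hydropathy import DEFAULT_TOPOLOGY, TopologyParams, call_topology

#: constant PR→BR numbering offset at the motif sites
PR_BR_OFFSET = 12


@dataclass
class ReferenceFrame:
    """A reference sequence plus the 1-based positions read from it."""

    name: str
    aa_sequence: str
    motif_positions_pr: tuple[int, int, int, int] = (97, 101, 105, 108)
    motif_positions_br: tuple[int, int, int, int] = (85, 89, 93, 96)
    retinal_lysine_pr: int = 231
    tm_segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.aa_sequence[self.retinal_lysine_pr - 1] != "K":
            raise ValueError(
                f"{self.name}: residue at {self.retinal_lysine_pr} is "
                f"{self.aa_sequence[self.retinal_lysine_pr - 1]}, expected K"
            )
        offsets = {
            pr - br
            for pr, br in zip(self.motif_positions_pr, self.motif_positions_br)
        }
        if offsets != {PR_BR_OFFSET}:
            raise ValueError(f"{self.name}: PR/BR offset not constant: {offsets}")

    @property
    def native_motif(self) -> tuple[str, str, str, str]:
        """The reference's own residues at the four motif sites."""
        return tuple(self.aa_sequence[p - 1] for p in self.motif_positions_pr)


def br_numbering(pr_pos: int) -> tuple[int, bool]:
    """Bacteriorhodopsin-frame position for a proteorhodopsin position.

    The −12 offset is established at the four motif sites; for any other
    position the converted value is returned with ``canonical=False``.
    """
    canonical = pr_pos in (97, 101, 105, 108)
    return pr_pos - PR_BR_OFFSET, canonical


def load_reference(
    name: str = "eBAC31A08",
    topology_params: TopologyParams = DEFAULT_TOPOLOGY,
) -> ReferenceFrame:
    """Load a bundled reference frame; TM segments are called on load."""
    pkg = resources.files("rhodosurvey.data")
    meta = json.loads((pkg / f"{name}.json").read_text())
    fasta_text = (pkg / f"{name}.fasta").read_text()
    seq = "".join(
        line.strip() for line in fasta_text.splitlines() if not line.startswith(">")
    )
    frame = ReferenceFrame(
        name=meta["name"],
        aa_sequence=seq,
        motif_positions_pr=tuple(meta["motif_positions_pr"]),
        motif_positions_br=tuple(meta["motif_positions_br"]),
        retinal_lysine_pr=meta["retinal_lysine_pr"],
    )
    frame.tm_segments = call_topology(seq, topology_params).segments
    return frame
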