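"""Global pairwise alignment and reference-position transfer.

Residue-level annotation (the 97/101/105/108 motif read-out, the retinal
lysine check) is done by aligning each query to a fixed reference frame
and transferring 1-based reference positions through the alignment. The
aligner is a full Needleman–Wunsch/Gotoh with affine gaps: a gap of
length k costs ``gap_open + (k - 1) * gap_extend``, and end gaps are
penalised (true global alignment).

Determinism contract: among co-optimal moves the traceback prefers
diagonal, then up (gap in the query), then left (gap in the reference);
inside a gap state, opening beats extending. Outputs are therefore
byte-stable across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence, Union

from Bio.Align import substitution_matrices

#: sentinel for "this reference column is gapped in the query"
MISSING = None

NEG_INF = float("-inf")


@dataclass(frozen=True)
class AlignParams:
    """Scoring scheme for protein alignments (BLAST-style defaults)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0


DEFAULT_ALIGN = AlignParams()

#: simple nucleotide scheme: +5 match / -4 mismatch, N neutral
_NT_ALPHABET = "ACGTUN"


@lru_cache(maxsize=8)
def _load_matrix(name: str) -> tuple[str, tuple[tuple[float, ...], ...]]:
    """Return (alphabet, dense score table) for a named scheme."""
    if name == "simple_nt":
        alphabet = _NT_ALPHABET
        rows = []
        for a in alphabet:
            row = []
            for b in alphabet:
                if a == "N" or b == "N":
                    row.append(0.0)
                elif a == b or {a, b} == {"T", "U"}:
                    row.append(5.0)
                else:
                    row.append(-4.0)
            rows.append(tuple(row))
        return alphabet, tuple(rows)
    mat = substitution_matrices.load(name)
    alphabet = str(mat.alphabet)
    rows = tuple(
        tuple(float(mat[a][b]) for b in alphabet) for a in alphabet
    )
    return alphabet, rows


def _encode(seq: str, alphabet: str, matrix_name: str) -> list[int]:
    index = {c: i for i, c in enumerate(alphabet)}
    out = []
    for c in seq:
        try:
            out.append(index[c])
        except KeyError:
            raise ValueError(
                f"residue {c!r} absent from substitution matrix {matrix_name}"
            ) from None
    return out


@dataclass
class AlignmentMap:
    """Colinear query↔reference position map from one global alignment.

    ``pairs`` lists all aligned (non-gap/non-gap) columns as 0-based
    ``(query_pos, ref_pos)``, strictly increasing in both coordinates.
    ``identity`` is identical columns divided by the shorter sequence
    length.
    """

    query_id: str
    ref_name: str
    pairs: list[tuple[int, int]]
    score: float
    identity: float
    query_length: int
    ref_length: int

    def __post_init__(self) -> None:
        self._by_ref = {r: q for q, r in self.pairs}


# traceback byte layout: bits 0-1 = H choice (0 diag, 1 up, 2 left),
# bit 2 = up-gap opened from H, bit 3 = left-gap opened from H
_DIAG, _UP, _LEFT = 0, 1, 2


def global_align(
    query: str,
    reference: str,
    params: AlignParams = DEFAULT_ALIGN,
    query_id: str = "query",
    ref_name: str = "reference",
) -> AlignmentMap:
    """Optimal global alignment of ``query`` against ``reference``.

    Raises ``ValueError`` for empty input or residues missing from the
    substitution matrix.
    """
    if not query or not reference:
        raise ValueError("cannot align empty sequences")
    alphabet, table = _load_matrix(params.matrix)
    q = _encode(query.upper(), alphabet, params.matrix)
    r = _encode(reference.upper(), alphabet, params.matrix)
    open_, ext = params.gap_open, params.gap_extend
    n, m = len(r), len(q)  # rows over reference, cols over query

    # H = best score ending at (i, j); F = gap in query (vertical),
    # E = gap in reference (horizontal)
    H_prev = [0.0] * (m + 1)
    F_prev = [NEG_INF] * (m + 1)
    ptr = [bytearray(m + 1) for _ in range(n + 1)]
    row0 = ptr[0]
    for j in range(1, m + 1):
        H_prev[j] = -open_ - (j - 1) * ext
        row0[j] = _LEFT | (8 if j == 1 else 0)
    for i in range(1, n + 1):
        ri = r[i - 1]
        srow = table[ri]
        H = [0.0] * (m + 1)
        F = [0.0] * (m + 1)
        H[0] = -open_ - (i - 1) * ext
        F[0] = H[0]
        prow = ptr[i]
        prow[0] = _UP | (4 if i == 1 else 0)
        E = NEG_INF
        hp, fp = H_prev, F_prev
        for j in range(1, m + 1):
            diag = hp[j - 1] + srow[q[j - 1]]
            # vertical gap: consumes reference, gap in query
            f_open = hp[j] - open_
            f_ext = fp[j] - ext
            if f_open >= f_ext:
                f, fbit = f_open, 4
            else:
                f, fbit = f_ext, 0
            # horizontal gap: consumes query, gap in reference
            e_open = H[j - 1] - open_
            e_ext = E - ext
            if e_open >= e_ext:
                E, ebit = e_open, 8
            else:
                E, ebit = e_ext, 0
            # tie-break: diagonal, then up (gap in query), then left
            if diag >= f and diag >= E:
                h, choice = diag, _DIAG
            elif f >= E:
                h, choice = f, _UP
            else:
                h, choice = E, _LEFT
            H[j] = h
            F[j] = f
            prow[j] = choice | fbit | ebit
        H_prev, F_prev = H, F

    score = H_prev[m]
    # traceback
    pairs: list[tuple[int, int]] = []
    i, j, state = n, m, "H"
    while i > 0 or j > 0:
        b = ptr[i][j]
        if state == "H":
            choice = b & 3
            if choice == _DIAG:
                pairs.append((j - 1, i - 1))
                i -= 1
                j -= 1
            elif choice == _UP:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            state = "H" if b & 4 else "F"
            i -= 1
        else:
            state = "H" if b & 8 else "E"
            j -= 1
    pairs.reverse()
    matches = sum(1 for qp, rp in pairs if query[qp] == reference[rp])
    identity = matches / min(m, n)
    return AlignmentMap(
        query_id=query_id,
        ref_name=ref_name,
        pairs=pairs,
        score=score,
        identity=identity,
        query_length=m,
        ref_length=n,
    )


def map_position(alignmap: AlignmentMap, ref_pos_1based: int) -> Optional[int]:
    """0-based query position aligned to a 1-based reference position.

    Returns :data:`MISSING` (``None``) when that reference column is
    gapped in the query; raises for positions outside the reference.
    """
    if not 1 <= ref_pos_1based <= alignmap.ref_length:
        raise ValueError(
            f"reference position {ref_pos_1based} outside 1..{alignmap.ref_length}"
        )
    return alignmap._by_ref.get(ref_pos_1based - 1, MISSING)
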