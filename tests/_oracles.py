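"""Independent oracles used only by the test suite.

The alignment oracle is a memoised recursive Gotoh, written separately
from the package's iterative matrix implementation. It shares the
package's documented scoring contract (gap of length k costs
open + (k-1)*extend; co-optimal moves resolved diagonal > up > left,
gap-open > gap-extend) but none of its code.
"""

from __future__ import annotations

from functools import lru_cache

NEG = float("-inf")


def oracle_align(query: str, reference: str, score, gap_open: float, gap_extend: float):
    """Optimal global alignment by recursion with memoisation.

    ``score`` is a callable (ref_char, query_char) -> float. Returns
    ``(best_score, pairs)`` with pairs as 0-based (query_pos, ref_pos).
    """
    r, q = reference, query
    n, m = len(r), len(q)

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        # best score of aligning r[:i] with q[:j], last column of type
        # `state`: 'D' match/mismatch, 'U' gap in query (consumes r),
        # 'L' gap in reference (consumes q); 'H' = unconstrained
        if state == "H":
            if i == 0 and j == 0:
                return 0.0
            return max(best(i, j, s) for s in "DUL")
        if state == "D":
            if i == 0 or j == 0:
                return NEG
            return best(i - 1, j - 1, "H") + score(r[i - 1], q[j - 1])
        if state == "U":
            if i == 0:
                return NEG
            # opening from 'H' vs extending a gap whose previous column
            # was also 'U'
            open_from = best(i - 1, j, "H") - gap_open
            ext_from = best(i - 1, j, "U") - gap_extend
            return max(open_from, ext_from)
        # state == "L"
        if j == 0:
            return NEG
        return max(best(i, j - 1, "H") - gap_open, best(i, j - 1, "L") - gap_extend)

    # NB: a run of k gap columns scores -(open + (k-1)*ext) because the
    # first column opens from 'H' and the rest extend.
    total = best(n, m, "H")

    pairs = []
    i, j = n, m
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            h = best(i, j, "H")
            # documented preference: diagonal, then up, then left
            for s in "DUL":
                if best(i, j, s) == h:
                    state = s
                    break
        elif state == "D":
            pairs.append((j - 1, i - 1))
            i, j = i - 1, j - 1
            state = "H"
        elif state == "U":
            # prefer closing the gap (opened here) over extending
            if best(i - 1, j, "H") - gap_open == best(i, j, "U"):
                state_next = "H"
            else:
                state_next = "U"
            i -= 1
            state = state_next
        else:  # "L"
            if best(i, j - 1, "H") - gap_open == best(i, j, "L"):
                state_next = "H"
            else:
                state_next = "L"
            j -= 1
            state = state_next
    pairs.reverse()
    return total, pairs


def oracle_identity(a: str, b: str, score, gap_open: float, gap_extend: float) -> float:
    """Identity (identical columns / shorter length) of the oracle alignment."""
    _, pairs = oracle_align(a, b, score, gap_open, gap_extend)
    matches = sum(1 for qp, rp in pairs if a[qp] == b[rp])
    return matches / min(len(a), len(b))


def components_partition(records, threshold: float, identity) -> list[set[str]]:
    """Partition by connected components of the >= threshold identity graph.

    On well-separated instances (within-band far above, between-band far
    below the threshold) this equals the planted grouping and is an
    algorithm-independent clustering oracle.
    """
    ids = [i for i, _ in records]
    seqs = dict(records)
    adj = {i: set() for i in ids}
    for x in range(len(ids)):
        for y in range(x + 1, len(ids)):
            a, b = ids[x], ids[y]
            if identity(seqs[a], seqs[b]) >= threshold:
                adj[a].add(b)
                adj[b].add(a)
    seen: set[str] = set()
    parts: list[set[str]] = []
    for start in ids:
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            node = stack.pop()
            for nxt in adj[node]:
                if nxt not in comp:
                    comp.add(nxt)
                    stack.append(nxt)
        seen |= comp
        parts.append(comp)
    return parts
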