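"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementations they validate: the string
distance oracle enumerates explicit edit scripts with a left-to-right cursor
(depth-first with cost pruning) instead of filling a dynamic-programming
table.
"""

from __future__ import annotations


def osa_oracle(a: str, b: str) -> int:
    """Exhaustive edit-script search for the optimal string alignment cost.

    Scripts transform ``a`` into ``b`` left to right with a cursor that never
    revisits produced output, which enforces the "no substring edited twice"
    restriction; all operation choices (copy, substitute, delete, insert,
    adjacent transposition) are explored at every position.
    """
    best = [len(a) + len(b)]

    def rec(i: int, j: int, cost: int) -> None:
        if cost >= best[0]:
            return
        if i == len(a):
            best[0] = min(best[0], cost + (len(b) - j))
            return
        if j == len(b):
            best[0] = min(best[0], cost + (len(a) - i))
            return
        if a[i] == b[j]:
            rec(i + 1, j + 1, cost)  # copy
        if i + 1 < len(a) and j + 1 < len(b) and a[i] == b[j + 1] and a[i + 1] == b[j]:
            rec(i + 2, j + 2, cost + 1)  # adjacent transposition
        rec(i + 1, j + 1, cost + 1)  # substitution
        rec(i + 1, j, cost + 1)  # deletion
        rec(i, j + 1, cost + 1)  # insertion

    rec(0, 0, 0)
    return best[0]


def all_strings(alphabet: str, max_len: int):
    """Every string over ``alphabet`` of length 0..max_len."""
    out = [""]
    frontier = [""]
    for _ in range(max_len):
        frontier = [s + c for s in frontier for c in alphabet]
        out.extend(frontier)
    return out
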