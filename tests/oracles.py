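"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: the alignment oracle is a
plain-Python full-DP Needleman-Wunsch, the chimera oracle an exhaustive scan
over parent pairs and crossovers.
"""

MATCH, MISMATCH, GAP = 1, -1, -2


def nw_identity_oracle(a: str, b: str) -> float:
    """Full-DP global alignment identity, terminal-gap columns excluded.

    Scoring +1/-1/-2; traceback prefers diagonal, then a gap in ``b`` (up),
    then a gap in ``a`` (left).
    """
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        H[i][0] = GAP * i
    for j in range(1, m + 1):
        H[0][j] = GAP * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            H[i][j] = max(H[i - 1][j - 1] + s, H[i - 1][j] + GAP, H[i][j - 1] + GAP)
    cols = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and H[i][j] == H[i - 1][j - 1] + (
            MATCH if a[i - 1] == b[j - 1] else MISMATCH
        ):
            cols.append((a[i - 1], b[j - 1]))
            i, j = i - 1, j - 1
        elif i > 0 and H[i][j] == H[i - 1][j] + GAP:
            cols.append((a[i - 1], "-"))
            i -= 1
        else:
            cols.append(("-", b[j - 1]))
            j -= 1
    cols.reverse()
    while cols and "-" in cols[0]:
        cols.pop(0)
    while cols and "-" in cols[-1]:
        cols.pop()
    if not cols:
        return 0.0
    matches = sum(1 for x, y in cols if x == y)
    return matches / len(cols)


def chimera_oracle(query: str, parents: list[str], min_div: int, min_score_gain: int) -> bool:
    """Exhaustive scan: is the query flagged under the two-parent model?

    All ordered parent pairs and all interior crossovers are enumerated;
    prefix/suffix mismatches are counted position-wise (equal lengths only).
    """
    L = len(query)
    cands = [p for p in parents if len(p) == L]
    if len(cands) < 2:
        return False
    best_single = min(sum(q != p for q, p in zip(query, c)) for c in cands)
    for A in cands:
        for B in cands:
            if A == B:
                continue
            for c in range(1, L):
                chim = sum(query[k] != A[k] for k in range(c)) + sum(
                    query[k] != B[k] for k in range(c, L)
                )
                if best_single - chim < min_score_gain:
                    continue
                div_a = sum(
                    1 for k in range(c) if A[k] != B[k] and query[k] == A[k]
                )
                div_b = sum(
                    1 for k in range(c, L) if A[k] != B[k] and query[k] == B[k]
                )
                if div_a >= min_div and div_b >= min_div:
                    return True
    return False
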