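"""Affine-gap semi-global alignment for segment assignment.

The query (a germline segment) must be aligned end-to-end; the target (a read)
is free at both ends, i.e. the segment is located as an "infix" of the read.
A length-k gap costs ``gap_open + (k-1) * gap_extend``.  'N' in either string
never matches.  The traceback projects query coordinates (anchor codons) onto
the read.

This is deliberately a small, self-contained dynamic program: segment
assignment against a handful of germline candidates is the contract here, and
an independently written brute-force aligner cross-checks it in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

NEG_INF = float("-inf")


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1

    def pair(self, a: str, b: str) -> int:
        if a == b and a != "N":
            return self.match
        return self.mismatch


@dataclass
class Alignment:
    score: float
    target_start: int
    target_end: int  # half-open
    projection: list[int | None]  # query index -> target index (None if gapped)


# traceback state codes
_M, _D, _I, _START = 0, 1, 2, 3


def semiglobal(query: str, target: str, scoring: Scoring = Scoring()) -> Alignment:
    """Best alignment of the whole ``query`` within ``target``."""
    m, n = len(query), len(target)
    if m == 0:
        return Alignment(0.0, 0, 0, [])
    go, ge = scoring.gap_open, scoring.gap_extend

    # state matrices and tracebacks, (m+1) x (n+1)
    M = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    D = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    I = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    ptrM = [[_START] * (n + 1) for _ in range(m + 1)]
    ptrD = [[_START] * (n + 1) for _ in range(m + 1)]
    ptrI = [[_START] * (n + 1) for _ in range(m + 1)]

    for i in range(1, m + 1):
        qc = query[i - 1]
        Mi, Di, Ii = M[i], D[i], I[i]
        Mp, Dp, Ip = M[i - 1], D[i - 1], I[i - 1]
        pM, pD, pI = ptrM[i], ptrD[i], ptrI[i]
        for j in range(0, n + 1):
            # D: query char deleted (no target consumed)
            best, arg = Mp[j] + go, _M
            if Dp[j] + ge > best:
                best, arg = Dp[j] + ge, _D
            if Ip[j] + go > best:
                best, arg = Ip[j] + go, _I
            if i == 1 and go > best:  # alignment may open with a deletion
                best, arg = go, _START
            Di[j], pD[j] = best, arg
            if j == 0:
                continue
            # M: query char aligned to target char
            s = scoring.pair(qc, target[j - 1])
            best, arg = Mp[j - 1], _M
            if Dp[j - 1] > best:
                best, arg = Dp[j - 1], _D
            if Ip[j - 1] > best:
                best, arg = Ip[j - 1], _I
            if i == 1 and 0.0 >= best:  # free target prefix
                best, arg = 0.0, _START
            Mi[j], pM[j] = best + s, arg
            # I: target char consumed against a gap (internal only)
            best, arg = Mi[j - 1] + go, _M
            if Ii[j - 1] + ge > best:
                best, arg = Ii[j - 1] + ge, _I
            if Di[j - 1] + go > best:
                best, arg = Di[j - 1] + go, _D
            Ii[j], pI[j] = best, arg

    # free target suffix: best over final query row, not ending in I
    score, end_j, state = NEG_INF, 0, _M
    for j in range(0, n + 1):
        if M[m][j] > score:
            score, end_j, state = M[m][j], j, _M
        if D[m][j] > score:
            score, end_j, state = D[m][j], j, _D

    # traceback
    projection: list[int | None] = [None] * m
    i, j, st = m, end_j, state
    start_j = end_j
    while i > 0:
        if st == _M:
            projection[i - 1] = j - 1
            st = ptrM[i][j]
            i, j = i - 1, j - 1
        elif st == _D:
            st = ptrD[i][j]
            i = i - 1
        elif st == _I:
            st = ptrI[i][j]
            j = j - 1
        else:  # START
            break
        start_j = j
    return Alignment(score, start_j, end_j, projection)


def anchored_extend(query: str, target: str, scoring: Scoring = Scoring()) -> float:
    """Score of aligning the whole ``query`` from the start of ``target``.

    The target end is free (trailing target is ignored); used to extend an
    exact core match across the variable, junction-trimmed remainder of a
    segment.  Returns 0 for an empty query.
    """
    m, n = len(query), len(target)
    if m == 0:
        return 0.0
    go, ge = scoring.gap_open, scoring.gap_extend
    M = [NEG_INF] * (n + 1)
    D = [NEG_INF] * (n + 1)
    I = [NEG_INF] * (n + 1)
    # i = 0 row
    M[0] = 0.0
    for j in range(1, n + 1):
        I[j] = go + (j - 1) * ge
    for i in range(1, m + 1):
        qc = query[i - 1]
        nM = [NEG_INF] * (n + 1)
        nD = [NEG_INF] * (n + 1)
        nI = [NEG_INF] * (n + 1)
        nD[0] = max(M[0] + go, D[0] + ge)
        nM[0] = NEG_INF
        for j in range(1, n + 1):
            s = scoring.pair(qc, target[j - 1])
            nM[j] = max(M[j - 1], D[j - 1], I[j - 1]) + s
            nD[j] = max(M[j] + go, D[j] + ge, I[j] + go)
            nI[j] = max(nM[j - 1] + go, nI[j - 1] + ge, nD[j - 1] + go)
        M, D, I = nM, nD, nI
    return max(max(M), max(D))
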