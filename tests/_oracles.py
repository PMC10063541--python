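"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

NEG_INF = float("-inf")


def gotoh_score(
    read: str,
    ref: str,
    match: int = 2,
    mismatch: int = -4,
    gap_open: int = -10,
    gap_extend: int = -1,
) -> float:
    """Full-matrix affine-gap global alignment score (three-state Gotoh).

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``; end gaps are
    penalized.  Pure-Python O(n*m) reference, independent of the package's
    alignment path.
    """
    n, m = len(read), len(ref)
    # state M: read[i-1] aligned to ref[j-1]; Ix: gap in ref (insertion,
    # read consumed); Iy: gap in read (deletion, ref consumed)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Iy[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if read[i - 1] == ref[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s
            Ix[i][j] = max(
                M[i - 1][j] + gap_open,
                Ix[i - 1][j] + gap_extend,
                Iy[i - 1][j] + gap_open,
            )
            Iy[i][j] = max(
                M[i][j - 1] + gap_open,
                Iy[i][j - 1] + gap_extend,
                Ix[i][j - 1] + gap_open,
            )
    return max(M[n][m], Ix[n][m], Iy[n][m])
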