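"""Independent pure-Python oracles used only by the test suite."""

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def sw_score_oracle(a: str, b: str, gap_open: int = 11,
                    gap_extend: int = 1) -> float:
    """Affine-gap Smith-Waterman best local score, full three-matrix DP.

    Gap of length k costs gap_open + k * gap_extend (same convention as
    the package). Substitution scores come from Biopython's BLOSUM62, an
    independent source from the implementation's matrix.
    """
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] - gap_extend,
                          H[i][j - 1] - gap_open - gap_extend)
            F[i][j] = max(F[i - 1][j] - gap_extend,
                          H[i - 1][j] - gap_open - gap_extend)
            sub = _BLOSUM62[a[i - 1]][b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def largest_terminal_repeat(seq: str) -> int:
    """Largest L <= floor(n/2) with prefix(L) == suffix(L), by upward scan."""
    best = 0
    for length in range(1, len(seq) // 2 + 1):
        if seq[:length] == seq[-length:]:
            best = length
    return best
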