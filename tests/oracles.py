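"""Independent brute-force oracles used by the test suite.

These are deliberately naive textbook implementations, kept free of any
code from the package's alignment kernels, so that agreement between the
two routes is meaningful.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def sw_score(q: str, s: str, gap_open: int = -11, gap_extend: int = -1,
             stop_score=None) -> int:
    """Plain-Python affine-gap Smith-Waterman score (first gapped residue
    costs gap_open, further ones gap_extend). ``stop_score`` overrides the
    substitution score against '*' when given."""
    m, n = len(q), len(s)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i - 1][j] + gap_open, E[i - 1][j] + gap_extend)
            F[i][j] = max(H[i][j - 1] + gap_open, F[i][j - 1] + gap_extend)
            a, b = q[i - 1], s[j - 1]
            if stop_score is not None and (a == "*" or b == "*"):
                sub = stop_score
            else:
                sub = _BLOSUM62[a][b]
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


def greedy_cluster_ids(records, threshold, identity_fn) -> list[str]:
    """Exhaustive reference clustering: precompute the full pairwise
    identity matrix, then apply the longest-first greedy rule."""
    ordered = sorted(records, key=lambda r: (-len(r.residues), r.id))
    ident = {}
    for a in ordered:
        for b in ordered:
            if a.id != b.id:
                ident[(a.id, b.id)] = identity_fn(a.residues, b.residues)
    reps = []
    for rec in ordered:
        if not any(ident[(rec.id, rep.id)] >= threshold for rep in reps):
            reps.append(rec)
    return [r.id for r in reps]
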