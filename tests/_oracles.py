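"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's alignment/scan code paths: a Gotoh
affine-gap dynamic program over (score, identities), a sliding-window PAM
scanner, and a from-scratch greedy clustering over a precomputed identity
matrix.
"""

from __future__ import annotations

NEG = float("-inf")

MATCH, MISMATCH, GAP_OPEN, GAP_EXT = 1, 0, -5, -1

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(dna: str) -> str:
    return dna.translate(_COMP)[::-1]


def _lex_best(*cands):
    best = (NEG, NEG)
    for c in cands:
        if c[0] > best[0] or (c[0] == best[0] and c[1] > best[1]):
            best = c
    return best


def _gotoh(a: str, b: str, ident_sign: int):
    """Max alignment score; among co-optimal alignments, the extreme
    (max for ident_sign=+1, min for -1) identity count."""
    n, m = len(a), len(b)
    M = [[(NEG, 0)] * (m + 1) for _ in range(n + 1)]
    X = [[(NEG, 0)] * (m + 1) for _ in range(n + 1)]
    Y = [[(NEG, 0)] * (m + 1) for _ in range(n + 1)]
    M[0][0] = (0, 0)
    for i in range(1, n + 1):
        X[i][0] = (GAP_OPEN + (i - 1) * GAP_EXT, 0)
    for j in range(1, m + 1):
        Y[0][j] = (GAP_OPEN + (j - 1) * GAP_EXT, 0)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            hit = ai == b[j - 1]
            s = MATCH if hit else MISMATCH
            d = (1 if hit else 0) * ident_sign
            pm = _lex_best(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = (pm[0] + s, pm[1] + d)
            xo = _lex_best(M[i - 1][j], Y[i - 1][j])
            X[i][j] = _lex_best(
                (xo[0] + GAP_OPEN, xo[1]),
                (X[i - 1][j][0] + GAP_EXT, X[i - 1][j][1]),
            )
            yo = _lex_best(M[i][j - 1], X[i][j - 1])
            Y[i][j] = _lex_best(
                (yo[0] + GAP_OPEN, yo[1]),
                (Y[i][j - 1][0] + GAP_EXT, Y[i][j - 1][1]),
            )
    score, ident = _lex_best(M[n][m], X[n][m], Y[n][m])
    return score, ident * ident_sign


def align_oracle(a: str, b: str) -> tuple[float, int, int]:
    """(optimal score, min identities, max identities) over all co-optimal
    global alignments under the package's fixed scoring."""
    score, max_ident = _gotoh(a, b, +1)
    _, min_ident = _gotoh(a, b, -1)
    return score, min_ident, max_ident


def pam_scan_oracle(seq: str) -> list[tuple[int, str]]:
    """All (cut boundary, strand) SpCas9 sites in a raw sequence: 20-nt
    protospacer + NGG forward, CCN + 20 nt reverse; cut 3 nt 5' of the PAM
    on the protospacer strand."""
    out = []
    for i in range(len(seq)):
        if seq[i + 21 : i + 23] == "GG" and i + 23 <= len(seq):
            out.append((i + 17, "+"))
        if seq[i : i + 2] == "CC" and i + 23 <= len(seq):
            out.append((i + 6, "-"))
    return out


def greedy_cluster_oracle(
    ids: list[str], lengths: dict[str, int], ident, threshold: float
) -> list[list[str]]:
    """Re-run the stated greedy rule from scratch over a precomputed identity
    lookup ``ident(a, b)`` (canonical order: length desc, id asc)."""
    order = sorted(ids, key=lambda g: (-lengths[g], g))
    clusters: list[list[str]] = []
    for g in order:
        for c in clusters:
            if ident(g, c[0]) > threshold:
                c.append(g)
                break
        else:
            clusters.append([g])
    return clusters
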