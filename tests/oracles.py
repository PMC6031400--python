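"""Independent reference implementations used only for checking.

Each oracle is deliberately written as plain, exhaustive computation
(recursive enumeration, quadratic DP, direct Monte-Carlo) so it shares
no code path with the package.
"""

from __future__ import annotations

import itertools

import numpy as np

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def expand_recursive(pattern: str) -> set[str]:
    """All concrete expansions of an IUPAC pattern, by recursion."""
    if not pattern:
        return {""}
    rest = expand_recursive(pattern[1:])
    return {b + r for b in IUPAC[pattern[0]] for r in rest}


NEG = float("-inf")


def global_alignment_identity(a: str, b: str, match: float = 1.0,
                              mismatch: float = -1.0, gap_open: float = -2.0,
                              gap_extend: float = -1.0) -> float:
    """Percent identity from an exhaustive global Gotoh DP.

    ``gap_open`` is the score of the first base of a gap, ``gap_extend``
    of each subsequent base; terminal gaps are penalized like any other.
    Identity = matched columns / columns, with terminal-gap columns
    trimmed from the traced path, x 100.
    """
    la, lb = len(a), len(b)
    M = [[NEG] * (lb + 1) for _ in range(la + 1)]
    X = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in b (consume a)
    Y = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, la + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, lb + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    # traceback from the corner, recording the column sequence
    i, j = la, lb
    state = max(("M", "X", "Y"), key=lambda st: {"M": M, "X": X, "Y": Y}[st][i][j])
    columns = []  # (is_gap, is_match)
    while i > 0 or j > 0:
        if state == "M":
            s = match if a[i - 1] == b[j - 1] else mismatch
            columns.append((False, a[i - 1] == b[j - 1]))
            prev = M[i][j] - s
            i, j = i - 1, j - 1
            for st, mat in (("M", M), ("X", X), ("Y", Y)):
                if abs(mat[i][j] - prev) < 1e-9:
                    state = st
                    break
        elif state == "X":
            columns.append((True, False))
            cur = X[i][j]
            i -= 1
            if abs(M[i][j] + gap_open - cur) < 1e-9:
                state = "M"
            elif abs(Y[i][j] + gap_open - cur) < 1e-9 and j > 0:
                state = "Y"
            else:
                state = "X"
        else:
            columns.append((True, False))
            cur = Y[i][j]
            j -= 1
            if abs(M[i][j] + gap_open - cur) < 1e-9:
                state = "M"
            elif abs(X[i][j] + gap_open - cur) < 1e-9 and i > 0:
                state = "X"
            else:
                state = "Y"
    columns.reverse()
    lo, hi = 0, len(columns)
    while lo < hi and columns[lo][0]:
        lo += 1
    while hi > lo and columns[hi - 1][0]:
        hi -= 1
    trimmed = columns[lo:hi]
    if not trimmed:
        raise ValueError("empty alignment after trimming")
    matches = sum(m for _, m in trimmed)
    return 100.0 * matches / len(trimmed)


def greedy_replay(sequences: list[str], threshold: float) -> list[list[int]]:
    """Replay the greedy best-hit centroid rule with the DP oracle.

    ``sequences`` come pre-ordered (abundance order); returns clusters
    as lists of input indices, in founding order.
    """
    reps: list[str] = []
    clusters: list[list[int]] = []
    for idx, seq in enumerate(sequences):
        best_i, best_id = -1, -1.0
        for i, rep in enumerate(reps):
            ident = global_alignment_identity(seq, rep)
            if ident >= threshold and ident > best_id:
                best_i, best_id = i, ident
        if best_i >= 0:
            clusters[best_i].append(idx)
        else:
            reps.append(seq)
            clusters.append([idx])
    return clusters


def ols_normal_equations(x, y) -> tuple[float, float]:
    """Slope and intercept by explicitly solving the normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    A = np.array([[len(x), x.sum()], [x.sum(), (x * x).sum()]])
    b = np.array([y.sum(), (x * y).sum()])
    intercept, slope = np.linalg.solve(A, b)
    return slope, intercept


def pearson_formula(x, y) -> float:
    """Pearson r straight from the covariance formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum()))


def rarefaction_subsampling(counts, depth: int, n_draws: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Richness of ``n_draws`` random subsamples at ``depth`` reads."""
    counts = np.asarray(counts, int)
    labels = np.repeat(np.arange(len(counts)), counts)
    n = len(labels)
    richness = np.empty(n_draws)
    for k in range(n_draws):
        pick = labels[rng.permutation(n)[:depth]]
        richness[k] = len(np.unique(pick))
    return richness
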