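"""Independent brute-force oracles used to check the aligner's kernels.

These are deliberately simple, obviously-correct implementations (full DP
matrices, quadratic enumeration, exhaustive search); they share no code
with the package.
"""

from __future__ import annotations

import itertools

NEG = float("-inf")


def _sub(a: str, b: str, match: int, mismatch: int) -> float:
    if a == b and a in "ACGT":
        return match
    return mismatch


def local_score(read: str, ref: str, match=1, mismatch=-3, open_=-5, ext=-2):
    """Gotoh local alignment score; a gap of length L costs open + L*ext."""
    n, m = len(read), len(ref)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    I = [[NEG] * (m + 1) for _ in range(n + 1)]  # read base vs gap
    D = [[NEG] * (m + 1) for _ in range(n + 1)]  # ref base vs gap
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            I[i][j] = max(H[i - 1][j] + open_ + ext, I[i - 1][j] + ext)
            D[i][j] = max(H[i][j - 1] + open_ + ext, D[i][j - 1] + ext)
            H[i][j] = max(
                0.0,
                H[i - 1][j - 1] + _sub(read[i - 1], ref[j - 1], match, mismatch),
                I[i][j],
                D[i][j],
            )
            if H[i][j] > best:
                best = H[i][j]
    return best


def semiglobal_score(read: str, ref: str, match=1, mismatch=-3, open_=-5, ext=-2):
    """Whole read aligned; gaps at the reference ends are free."""
    n, m = len(read), len(ref)
    S = [[NEG] * (m + 1) for _ in range(n + 1)]
    I = [[NEG] * (m + 1) for _ in range(n + 1)]
    D = [[NEG] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        S[0][j] = 0.0  # free leading reference gap
    for i in range(1, n + 1):
        for j in range(m + 1):
            I[i][j] = max(S[i - 1][j] + open_ + ext, I[i - 1][j] + ext)
            best = I[i][j]
            if j >= 1:
                D[i][j] = max(S[i][j - 1] + open_ + ext, D[i][j - 1] + ext)
                diag = S[i - 1][j - 1] + _sub(
                    read[i - 1], ref[j - 1], match, mismatch
                )
                best = max(best, D[i][j], diag)
            S[i][j] = best
    return max(S[n])  # free trailing reference gap


def count_occurrences(pattern: str, text: str) -> int:
    """Overlapping exact occurrences by naive scan (N never matches)."""
    if any(c not in "ACGT" for c in pattern):
        return 0
    n = 0
    for i in range(len(text) - len(pattern) + 1):
        if text[i : i + len(pattern)] == pattern:
            n += 1
    return n


def brute_mems(read: str, text: str, min_len: int) -> set:
    """All maximal exact matches (read_offset, text_pos, length) of length
    >= min_len; only A/C/G/T positions can match."""

    def ok(c):
        return c in "ACGT"

    out = set()
    for i in range(len(read)):
        for j in range(len(text)):
            if read[i] != text[j] or not ok(read[i]):
                continue
            if i > 0 and j > 0 and read[i - 1] == text[j - 1] and ok(read[i - 1]):
                continue  # not left-maximal: extendable
            l = 0
            while (
                i + l < len(read)
                and j + l < len(text)
                and read[i + l] == text[j + l]
                and ok(read[i + l])
            ):
                l += 1
            if l >= min_len:
                out.add((i, j, l))
    return out


def exhaustive_translation_cost(
    transitions: str, guide: list, trans_cost=1.0, emit_cost=1.0
) -> float:
    """Minimum translation cost over all 4^L base strings."""
    L = len(transitions) + 1
    bits = {"A": 0, "C": 1, "G": 2, "T": 3}
    best = float("inf")
    for combo in itertools.product("ACGT", repeat=L):
        cost = 0.0
        for i, b in enumerate(combo):
            g = guide[i]
            if g in bits and g != b:
                cost += emit_cost
        for i, c in enumerate(transitions):
            if c == ".":
                continue
            if (bits[combo[i]] ^ bits[combo[i + 1]]) != int(c):
                cost += trans_cost
        best = min(best, cost)
    return best
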