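"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as literal enumeration, deliberately ignoring the
vectorized/derived shortcuts the package itself uses.
"""

from collections import Counter


def brute_skipgram_frequencies(seq: str, k: int, include_zero: bool) -> dict:
    """Literal enumeration of the skip sets Skip(DT = a) for a <= k:
    every ordered position pair (i, j), i < j, whose interval length
    j - i - 1 equals a, contributes the dipeptide seq[i] + seq[j]."""
    counts: Counter = Counter()
    a_min = 0 if include_zero else 1
    for a in range(a_min, k + 1):
        for i in range(len(seq)):
            for j in range(len(seq)):
                if j > i and (j - i - 1) == a:
                    counts[seq[i] + seq[j]] += 1
    total = sum(counts.values())
    return {g: c / total for g, c in counts.items()} if total else {}


def pairwise_auc(scores, labels) -> float:
    """Mann-Whitney AUC by exhaustive positive-negative pair comparison;
    ties count one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def lcs_length(a: str, b: str) -> int:
    """Textbook quadratic longest-common-subsequence table."""
    table = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                table[i][j] = table[i - 1][j - 1] + 1
            else:
                table[i][j] = max(table[i - 1][j], table[i][j - 1])
    return table[-1][-1]
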