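"""n-gram and k-skip-n-gram feature models for peptide sequences.

The traditional n-gram model counts contiguous length-n windows of a sequence
S = A1 A2 ... AL and normalizes by the number of windows, giving a 20^n
frequency vector. The k-skip-n-gram model generalizes this by also counting
residue tuples whose members are separated by up to k intervening residues:
the distance between positions i < j is the interval length DT = j - i - 1,
and for n = 2 every ordered pair (A_i, A_j) with DT <= k contributes one
dipeptide occurrence. The *adaptive* variant sets k to each sequence's own
length, so every ordered position pair contributes and the model becomes
parameter free — for n = 2 this is a 400-dimensional dipeptide-frequency
vector whose entries sum to 1.

Dimensionality grows as 20^n, so gram orders are restricted to n <= 2.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .sequence_io import ALPHABET, Peptide

#: 400 dipeptide names, alphabetical by (first residue, second residue).
DIPEPTIDES: tuple[str, ...] = tuple(a + b for a in ALPHABET for b in ALPHABET)


def gram_names(n: int) -> tuple[str, ...]:
    """All 20^n gram names of order ``n`` in alphabetical order."""
    if n == 1:
        return tuple(ALPHABET)
    if n == 2:
        return DIPEPTIDES
    raise ValueError(f"gram order must be 1 or 2, got {n}")


@dataclass(frozen=True)
class SkipGramConfig:
    """Configuration of the skip-gram feature extractor.

    Parameters
    ----------
    n : int
        Gram order, 1 or 2 (higher orders overfit: 20^n dimensions).
    k_mode : {"adaptive", "fixed"}
        "adaptive" sets the maximum skip distance to each sequence's own
        length; "fixed" caps it at ``k``.
    k : int, optional
        Maximum skip distance in fixed mode (>= 1).
    include_zero_distance : bool
        Whether contiguous pairs (distance 0) are part of the skip set.
        True subsumes the traditional n-gram counts; False counts only
        pairs at distance 1..k.
    """

    n: int = 2
    k_mode: Literal["adaptive", "fixed"] = "adaptive"
    k: int | None = None
    include_zero_distance: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.n <= 2:
            raise ValueError(f"gram order n must be 1 or 2, got {self.n}")
        if self.k_mode not in ("adaptive", "fixed"):
            raise ValueError(f"k_mode must be adaptive or fixed, got {self.k_mode!r}")
        if self.k_mode == "fixed":
            if self.k is None or self.k < 1:
                raise ValueError("fixed k_mode requires k >= 1")


def residue_distance(i: int, j: int) -> int:
    """Interval length between 1-based positions ``i`` < ``j``.

    Contiguous residues are at distance 0: DT(1,2)=0, DT(1,3)=1, DT(1,4)=2.
    """
    if i >= j:
        raise ValueError(f"residue_distance requires i < j, got i={i}, j={j}")
    if i < 1:
        raise ValueError(f"positions are 1-based, got i={i}")
    return j - i - 1


def _normalize(counts: Counter, names: Sequence[str], context: str) -> pd.Series:
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"{context}: empty gram set, nothing to normalize")
    vec = pd.Series(0.0, index=list(names))
    for gram, c in counts.items():
        vec[gram] = c / total
    return vec


def extract_ngram(p: Peptide, n: int = 2) -> pd.Series:
    """Traditional n-gram frequencies of the L - n + 1 contiguous windows."""
    names = gram_names(n)
    seq = p.sequence
    if len(seq) < n:
        raise ValueError(
            f"peptide {p.id!r}: length {len(seq)} < gram order {n}"
        )
    counts = Counter(seq[i : i + n] for i in range(len(seq) - n + 1))
    return _normalize(counts, names, f"peptide {p.id!r}")


def extract_skipgram(p: Peptide, cfg: SkipGramConfig) -> pd.Series:
    """k-skip-n-gram frequencies of ``p`` under ``cfg``.

    For n = 2 the multiset of grams is the union over distances
    a = a_min..k_eff of all pairs (A_i, A_{i+a+1}); a_min is 0 when
    contiguous pairs are included, else 1, and k_eff is the sequence length
    in adaptive mode (distances beyond L - 2 contribute nothing) or the
    configured k in fixed mode. Counts use multiset semantics and are
    normalized by the multiset size.
    """
    seq = p.sequence
    L = len(seq)
    if L < cfg.n:
        raise ValueError(f"peptide {p.id!r}: length {L} < gram order {cfg.n}")
    if cfg.n == 1:
        # single residues carry no distance; the skip model degenerates to
        # plain amino-acid composition
        return extract_ngram(p, 1)

    a_min = 0 if cfg.include_zero_distance else 1
    k_eff = L if cfg.k_mode == "adaptive" else min(cfg.k, L)
    counts: Counter = Counter()
    for a in range(a_min, min(k_eff, L - 2) + 1):
        for i in range(L - a - 1):
            counts[seq[i] + seq[i + a + 1]] += 1
    return _normalize(counts, DIPEPTIDES, f"peptide {p.id!r}")


def extract_adaptive(p: Peptide) -> pd.Series:
    """Adaptive k-skip-2-gram features: all C(L,2) ordered position pairs.

    Convenience form of :func:`extract_skipgram` with n=2, adaptive k and
    contiguous pairs included; always 400-dimensional.
    """
    return extract_skipgram(p, SkipGramConfig())


def featurize_dataset(
    peptides: Iterable[Peptide], cfg: SkipGramConfig | None = None
) -> pd.DataFrame:
    """Feature matrix for a list of peptides.

    Rows follow input order and are indexed by peptide id; columns are the
    fixed alphabetical gram ordering (400 columns for n=2).
    """
    cfg = cfg if cfg is not None else SkipGramConfig()
    names = gram_names(cfg.n)
    rows = []
    ids = []
    for p in peptides:
        rows.append(extract_skipgram(p, cfg).to_numpy())
        ids.append(p.id)
    if not rows:
        return pd.DataFrame(np.empty((0, len(names))), columns=list(names))
    return pd.DataFrame(np.vstack(rows), index=ids, columns=list(names))
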