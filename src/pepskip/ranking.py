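"""Information-gain ranking of dipeptide features.

Each continuous feature column (a dipeptide frequency) is first discretized
by supervised entropy minimization: recursive binary splits are accepted
under the minimum-description-length (MDL) criterion of Fayyad & Irani, so
a column carrying no class information collapses to a single bin. The
information gain of the discretized column x with respect to the class c is

    IG(x, c) = H(c) - H(c | x)

with entropies in bits over empirical frequencies, hence IG lies in
[0, H(c)] (at most 1 bit for a balanced binary problem). Features are
ranked by descending IG with alphabetical tie-breaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class RankedFeature:
    rank: int
    gram: str
    ig: float


def _entropy_bits(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _class_counts(y: np.ndarray) -> np.ndarray:
    return np.bincount(y, minlength=2)


def mdl_cut_points(values: np.ndarray, labels: np.ndarray) -> list[float]:
    """Fayyad-Irani recursive MDL cut points for one continuous column.

    Candidate thresholds are midpoints between adjacent distinct values;
    the best (minimum class-entropy) split is accepted when its information
    gain exceeds the MDL cost, and both sides are then split recursively.
    """
    order = np.argsort(values, kind="mergesort")
    xs = values[order]
    ys = labels[order]
    cuts: list[float] = []

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 2:
            return
        x, y = xs[lo:hi], ys[lo:hi]
        # cumulative class counts left of each candidate boundary
        onehot = np.zeros((n, 2))
        onehot[np.arange(n), y] = 1
        cum = np.cumsum(onehot, axis=0)
        total = cum[-1]
        boundaries = np.flatnonzero(x[1:] != x[:-1]) + 1  # split before index
        if len(boundaries) == 0:
            return
        left = cum[boundaries - 1]
        right = total - left
        nl = boundaries.astype(float)
        nr = n - nl

        def ent(c: np.ndarray, m: np.ndarray) -> np.ndarray:
            with np.errstate(divide="ignore", invalid="ignore"):
                p = c / m[:, None]
                terms = np.where(p > 0, -p * np.log2(p), 0.0)
            return terms.sum(axis=1)

        weighted = (nl * ent(left, nl) + nr * ent(right, nr)) / n
        best = int(np.argmin(weighted))
        ent_s = _entropy_bits(total)
        gain = ent_s - weighted[best]

        k = int((total > 0).sum())
        kl = int((left[best] > 0).sum())
        kr = int((right[best] > 0).sum())
        ent_l = ent(left[best : best + 1], nl[best : best + 1])[0]
        ent_r = ent(right[best : best + 1], nr[best : best + 1])[0]
        delta = (
            math.log2(3**k - 2) - (k * ent_s - kl * ent_l - kr * ent_r)
        )
        threshold = (math.log2(n - 1) + delta) / n
        if gain <= threshold:
            return
        b = boundaries[best]
        cuts.append(float((x[b - 1] + x[b]) / 2))
        recurse(lo, lo + b)
        recurse(lo + b, hi)

    recurse(0, len(xs))
    return sorted(cuts)


def discretize_feature(values: Sequence[float], labels: Sequence[int]
                       ) -> np.ndarray:
    """Discretized bin codes for one column; a column with no accepted MDL
    split (e.g. a constant, or one independent of the labels) collapses to
    a single bin."""
    x = np.asarray(list(values), dtype=float)
    y = np.asarray(list(labels), dtype=int)
    if len(x) != len(y):
        raise ValueError("column and label lengths differ")
    cuts = mdl_cut_points(x, y)
    return np.searchsorted(cuts, x, side="left").astype(int)


def information_gain(discretized: Sequence[int], labels: Sequence[int]
                     ) -> float:
    """IG = H(c) - H(c | x) in bits over empirical frequencies."""
    x = np.asarray(list(discretized), dtype=int)
    y = np.asarray(list(labels), dtype=int)
    if len(x) != len(y):
        raise ValueError("column and label lengths differ")
    n = len(y)
    h_c = _entropy_bits(_class_counts(y))
    h_cond = 0.0
    for bin_code in np.unique(x):
        mask = x == bin_code
        h_cond += mask.sum() / n * _entropy_bits(_class_counts(y[mask]))
    return max(0.0, h_c - h_cond)


def rank_features(features: pd.DataFrame, labels: Sequence[int],
                  top: int | None = None) -> list[RankedFeature]:
    """Score every column via MDL discretization + information gain and
    return the ``top`` features sorted by descending IG (alphabetical
    tie-break)."""
    y = np.asarray(list(labels), dtype=int)
    if top is not None and top > features.shape[1]:
        raise ValueError(
            f"top={top} exceeds the {features.shape[1]} available columns"
        )
    scores = []
    for gram in features.columns:
        codes = discretize_feature(features[gram].to_numpy(), y)
        scores.append((str(gram), information_gain(codes, y)))
    scores.sort(key=lambda s: (-s[1], s[0]))
    if top is not None:
        scores = scores[:top]
    return [RankedFeature(rank=r, gram=g, ig=ig)
            for r, (g, ig) in enumerate(scores, start=1)]


def ranking_table(ranked: Sequence[RankedFeature]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rank": [f.rank for f in ranked],
            "IG": [f.ig for f in ranked],
            "feature": [f.gram for f in ranked],
        }
    )


def amino_acid_membership(ranked: Sequence[RankedFeature]) -> pd.Series:
    """How many of the given top features contain each amino acid."""
    from .sequence_io import ALPHABET

    counts = {aa: 0 for aa in ALPHABET}
    for f in ranked:
        for aa in set(f.gram):
            counts[aa] += 1
    return pd.Series(counts)
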