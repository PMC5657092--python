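"""Random-forest prediction model over dipeptide feature vectors.

The ensemble is scikit-learn's random forest (bootstrap sampling per tree,
random feature-subset selection at each split). Prediction confidence is
the fraction of trees voting for the predicted class, so it always lies in
[0.5, 1]; an exact 50/50 vote split is resolved to the negative (non-CPP)
class — the conservative choice when screening therapeutic candidates.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

FORMAT_VERSION = 1

#: Tree count giving the best jackknife accuracy in the reference sweep.
DEFAULT_TREES = 150


@dataclass
class Prediction:
    label: int
    confidence: float


class ForestModel:
    """Trained random-forest ensemble with a vote-fraction confidence
    contract.

    Parameters
    ----------
    t : int
        Number of trees (any integer > 1).
    seed : int
        Random state for bootstrap/feature sampling; fixed seed gives
        bit-identical models.
    max_features : int, float or str
        Features tried per split; default "sqrt" (20 of the 400 dipeptides).
    """

    def __init__(self, t: int = DEFAULT_TREES, seed: int = 0,
                 max_features: int | float | str = "sqrt") -> None:
        if t < 2:
            raise ValueError(f"tree count must be > 1, got {t}")
        self.t = t
        self.seed = seed
        self.max_features = max_features
        self.feature_names: list[str] | None = None
        self._forest: RandomForestClassifier | None = None

    # -- training ----------------------------------------------------------

    @classmethod
    def train(cls, features: pd.DataFrame, labels: Sequence[int],
              t: int = DEFAULT_TREES, seed: int = 0,
              max_features: int | float | str = "sqrt") -> "ForestModel":
        model = cls(t=t, seed=seed, max_features=max_features)
        model.fit(features, labels)
        return model

    def fit(self, features: pd.DataFrame, labels: Sequence[int]) -> "ForestModel":
        y = np.asarray(list(labels), dtype=int)
        X = np.asarray(features, dtype=float)
        if X.shape[0] != len(y):
            raise ValueError(
                f"{X.shape[0]} feature rows but {len(y)} labels"
            )
        if len(y) < 2:
            raise ValueError("need at least 2 training samples")
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        self.feature_names = [str(c) for c in features.columns]
        self._forest = RandomForestClassifier(
            n_estimators=self.t,
            max_features=self.max_features,
            bootstrap=True,
            random_state=self.seed,
            n_jobs=1,
        )
        self._forest.fit(X, y)
        return self

    # -- prediction --------------------------------------------------------

    def _check_features(self, features: pd.DataFrame) -> np.ndarray:
        if self._forest is None or self.feature_names is None:
            raise RuntimeError("model is not fitted")
        cols = [str(c) for c in features.columns]
        if cols != self.feature_names:
            missing = sorted(set(self.feature_names) - set(cols))
            extra = sorted(set(cols) - set(self.feature_names))
            raise ValueError(
                "feature columns do not match training; "
                f"missing={missing[:5]}{'...' if len(missing) > 5 else ''} "
                f"extra={extra[:5]}{'...' if len(extra) > 5 else ''}"
            )
        return np.asarray(features, dtype=float)

    def vote_fraction(self, features: pd.DataFrame) -> np.ndarray:
        """Fraction of trees voting for the positive (CPP) class, per row."""
        X = self._check_features(features)
        classes = self._forest.classes_
        votes = np.zeros(X.shape[0])
        for tree in self._forest.estimators_:
            votes += (classes[tree.predict(X).astype(int)] == 1)
        return votes / len(self._forest.estimators_)

    def predict(self, features: pd.DataFrame) -> list[Prediction]:
        """Predicted label and majority-vote confidence per row.

        Confidence of the two classes sums to 1; the reported confidence is
        the winning fraction, so it lies in [0.5, 1]. A tie votes negative.
        """
        frac = self.vote_fraction(features)
        out = []
        for f in frac:
            label = 1 if f > 0.5 else 0  # exact tie -> non-CPP
            out.append(Prediction(label=label, confidence=float(max(f, 1 - f))))
        return out

    def predict_table(self, features: pd.DataFrame) -> pd.DataFrame:
        preds = self.predict(features)
        return pd.DataFrame(
            {
                "id": list(features.index),
                "predicted_label": [p.label for p in preds],
                "confidence": [p.confidence for p in preds],
            }
        )

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Versioned serialized bundle (t, seed, feature names, trees)."""
        bundle = {
            "format_version": FORMAT_VERSION,
            "t": self.t,
            "seed": self.seed,
            "max_features": self.max_features,
            "feature_names": self.feature_names,
            "forest": self._forest,
        }
        with open(path, "wb") as fh:
            pickle.dump(bundle, fh)

    @classmethod
    def load(cls, path: str | Path) -> "ForestModel":
        with open(path, "rb") as fh:
            bundle = pickle.load(fh)
        if bundle.get("format_version") != FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {bundle.get('format_version')}"
            )
        model = cls(t=bundle["t"], seed=bundle["seed"],
                    max_features=bundle["max_features"])
        model.feature_names = bundle["feature_names"]
        model._forest = bundle["forest"]
        return model
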