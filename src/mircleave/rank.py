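"""Seeded random-forest ranking shared by the Drosha and Dicer stages.

Candidate processing sites are scored by the fraction of trees in a
bagged random-forest ensemble that vote "true site" — a vote fraction in
[0, 1], not a calibrated probability. Per hairpin, the candidate with the
highest score is the predicted site (ties break to the smaller position in
the stage modules).
"""

from __future__ import annotations

import hashlib
import math
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import sklearn
from sklearn.ensemble import RandomForestClassifier

SCHEMA_VERSION = 1

DEFAULT_N_TREES = 100


class ModelError(ValueError):
    """Training/scoring contract violation or unreadable model file."""


@dataclass
class RankModel:
    """A trained vote-fraction ranking forest with its training metadata."""

    forest: RandomForestClassifier
    n_trees: int
    seed: int
    feature_dim: int
    feature_names: list[str] = field(default_factory=list)
    training_digest: str = ""
    feature_mask: Optional[list[int]] = None  # indices of features used


def _training_digest(features: np.ndarray, labels: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(features, dtype=np.float64).tobytes())
    h.update(np.ascontiguousarray(labels, dtype=np.int8).tobytes())
    return h.hexdigest()[:16]


def train(
    features: np.ndarray,
    labels: Sequence[int],
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
    balance: bool = False,
    feature_mask: Optional[Sequence[int]] = None,
) -> RankModel:
    """Train a bagged random forest on candidate feature vectors.

    Trees are grown on bootstrap resamples with random feature-subset splits
    of size ``floor(log2(d)) + 1``. Identical inputs and seed give an
    identical model. ``feature_mask`` restricts training (and later scoring)
    to the given feature indices, e.g. a length-only ablation.

    Raises :class:`ModelError` on single-class labels or NaN features.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int8)
    if X.ndim != 2 or len(X) != len(y):
        raise ModelError("features must be a 2-D matrix matching labels")
    if np.isnan(X).any():
        raise ModelError("NaN in feature matrix")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ModelError("training labels contain a single class")
    full_dim = X.shape[1]
    mask = list(feature_mask) if feature_mask is not None else None
    Xm = X[:, mask] if mask is not None else X
    d = Xm.shape[1]
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=min(d, int(math.floor(math.log2(d))) + 1 if d > 1 else 1),
        bootstrap=True,
        class_weight="balanced" if balance else None,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(Xm, y)
    names = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(full_dim)
    ]
    return RankModel(
        forest=forest,
        n_trees=n_trees,
        seed=seed,
        feature_dim=full_dim,
        feature_names=names,
        training_digest=_training_digest(X, y),
        feature_mask=mask,
    )


def score(model: RankModel, features: np.ndarray) -> np.ndarray:
    """Vote fractions in [0, 1]: share of trees voting "true site".

    With ``n_trees=1`` scores are exactly 0 or 1. Rejects feature matrices
    whose dimension differs from the training dimension.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.feature_dim:
        raise ModelError(
            f"feature dimension {X.shape[1]} != model dimension {model.feature_dim}"
        )
    if np.isnan(X).any():
        raise ModelError("NaN in feature matrix")
    if model.feature_mask is not None:
        X = X[:, model.feature_mask]
    votes = np.zeros(len(X))
    for tree in model.forest.estimators_:
        votes += (tree.predict(X) == 1).astype(float)
    return votes / len(model.forest.estimators_)


def save(model: RankModel, path: str | Path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "sklearn_version": sklearn.__version__,
        "n_trees": model.n_trees,
        "seed": model.seed,
        "feature_dim": model.feature_dim,
        "feature_names": model.feature_names,
        "training_digest": model.training_digest,
        "feature_mask": model.feature_mask,
        "forest": model.forest,
    }
    with Path(path).open("wb") as fh:
        pickle.dump(payload, fh)


def load(path: str | Path) -> RankModel:
    try:
        with Path(path).open("rb") as fh:
            payload = pickle.load(fh)
    except (pickle.UnpicklingError, EOFError, AttributeError) as exc:
        raise ModelError(f"unreadable model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("schema_version") != SCHEMA_VERSION:
        raise ModelError(
            f"model file {path}: schema version mismatch "
            f"(got {payload.get('schema_version') if isinstance(payload, dict) else '?'}, "
            f"expected {SCHEMA_VERSION})"
        )
    return RankModel(
        forest=payload["forest"],
        n_trees=payload["n_trees"],
        seed=payload["seed"],
        feature_dim=payload["feature_dim"],
        feature_names=payload["feature_names"],
        training_digest=payload["training_digest"],
        feature_mask=payload["feature_mask"],
    )


def model_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
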