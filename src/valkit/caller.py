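"""Gradient-boosted HRD classification: training, cutoff calibration, calls.

An XGBoost tree ensemble is trained on scar feature vectors with a stratified
7:3 train/test split. The score in [0, 1] is the ensemble's positive-class
probability; the positivity cutoff is calibrated as the largest threshold
keeping sensitivity at or above a target (default 90%) on held-out positives,
but can be pinned to the conventional 0.7. Calls are three-state:
positive / negative / unknown, with unknown reserved for QC failure or an
effective tumor purity below the 10% floor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb

from .features import FEATURE_SCHEMA_VERSION

DEFAULT_CUTOFF = 0.7
DEFAULT_PURITY_FLOOR = 0.10
DEFAULT_TARGET_SENSITIVITY = 0.90

#: Desk-scale hyperparameters: a few hundred shallow trees. The production
#: ensemble's settings are not public; these are sized for cohorts of a few
#: hundred specimens.
DEFAULT_HYPERPARAMS = {
    "n_estimators": 200,
    "max_depth": 3,
    "learning_rate": 0.1,
    "subsample": 0.9,
    "colsample_bytree": 0.9,
    "n_jobs": 1,
    "tree_method": "hist",
}


@dataclass
class ModelArtifact:
    """Serialized tree ensemble plus the calibrated cutoff and metadata."""

    booster_raw: bytes
    feature_names: list[str]
    schema_version: str
    cutoff: float
    n_pos: int
    n_neg: int
    seed: int
    hyperparams: dict

    def __post_init__(self) -> None:
        if not 0 < self.cutoff < 1:
            raise ValueError("cutoff must lie in (0, 1)")

    def booster(self) -> xgb.Booster:
        b = xgb.Booster()
        b.load_model(bytearray(self.booster_raw))
        return b

    def save(self, path: str | Path) -> None:
        payload = {
            "booster": self.booster_raw.decode("utf-8"),
            "feature_names": self.feature_names,
            "schema_version": self.schema_version,
            "cutoff": self.cutoff,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "seed": self.seed,
            "hyperparams": self.hyperparams,
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ModelArtifact":
        payload = json.loads(Path(path).read_text())
        return cls(
            booster_raw=payload["booster"].encode("utf-8"),
            feature_names=payload["feature_names"],
            schema_version=payload["schema_version"],
            cutoff=payload["cutoff"],
            n_pos=payload["n_pos"],
            n_neg=payload["n_neg"],
            seed=payload["seed"],
            hyperparams=payload["hyperparams"],
        )


@dataclass(frozen=True)
class HrdCall:
    """One three-state call with its score (if any) and reason."""

    score: float | None
    status: str  # "positive" | "negative" | "unknown"
    reason: str  # "ok" | "low_purity" | "qc_fail"

    def __post_init__(self) -> None:
        if (self.status == "unknown") != (self.reason != "ok"):
            raise ValueError("status=unknown iff reason != ok")
        if self.reason == "qc_fail" and self.score is not None:
            raise ValueError("score must be absent on QC failure")


def split_train_test(
    features: pd.DataFrame,
    labels: pd.Series,
    ratio: float = 0.7,
    seed: int = 0,
) -> tuple[pd.Index, pd.Index]:
    """Stratified train/test split of sample ids at the given train ratio.

    Per class the train share is within one sample of ``ratio``; the two
    index sets are disjoint and cover all samples. Same seed → same split.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_ids: list = []
    test_ids: list = []
    for cls in sorted(labels.unique()):
        ids = labels.index[labels == cls].to_numpy()
        if len(ids) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        perm = rng.permutation(len(ids))
        n_train = int(round(ratio * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train_ids.extend(ids[perm[:n_train]])
        test_ids.extend(ids[perm[n_train:]])
    return pd.Index(train_ids), pd.Index(test_ids)


def train_model(
    features: pd.DataFrame,
    labels: pd.Series,
    hyperparams: dict | None = None,
    seed: int = 0,
    cutoff: float = DEFAULT_CUTOFF,
) -> ModelArtifact:
    """Fit the gradient-boosted ensemble on a labeled feature matrix.

    ``labels`` is 1 for HRD-positive, 0 for negative. Deterministic under
    seed (single-threaded histogram trees).
    """
    y = np.asarray(labels.reindex(features.index), dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    hp = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        hp.update(hyperparams)
    clf = xgb.XGBClassifier(random_state=seed, **hp)
    clf.fit(features.values, y)
    raw = clf.get_booster().save_raw(raw_format="json").decode("utf-8").encode("utf-8")
    return ModelArtifact(
        booster_raw=raw,
        feature_names=list(features.columns),
        schema_version=FEATURE_SCHEMA_VERSION,
        cutoff=cutoff,
        n_pos=int(y.sum()),
        n_neg=int((1 - y).sum()),
        seed=seed,
        hyperparams=hp,
    )


def score_samples(model: ModelArtifact, features: pd.DataFrame) -> pd.Series:
    """HRD scores in [0, 1] for a feature matrix matching the model schema."""
    if model.schema_version != FEATURE_SCHEMA_VERSION:
        raise ValueError("feature schema version mismatch")
    if list(features.columns) != model.feature_names:
        features = features.reindex(columns=model.feature_names)
        if features.isna().any().any():
            raise ValueError("feature matrix does not match the model schema")
    dm = xgb.DMatrix(features.values)
    scores = model.booster().predict(dm)
    return pd.Series(np.clip(scores, 0.0, 1.0), index=features.index, name="score")


def select_cutoff(
    scores: np.ndarray | pd.Series,
    labels: np.ndarray | pd.Series,
    target_sensitivity: float = DEFAULT_TARGET_SENSITIVITY,
) -> float:
    """Largest threshold t with sensitivity(score >= t) >= target.

    Ties resolve toward the larger threshold: t is the k-th largest positive
    score with k = ceil(target * n_pos).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = np.sort(s[y == 1])[::-1]
    if len(pos) == 0:
        raise ValueError("no positive labels")
    k = int(np.ceil(target_sensitivity * len(pos)))
    k = min(max(k, 1), len(pos))
    return float(pos[k - 1])


def make_call(
    score: float | None,
    effective_purity: float,
    qc_valid: bool,
    cutoff: float = DEFAULT_CUTOFF,
    purity_floor: float = DEFAULT_PURITY_FLOOR,
) -> HrdCall:
    """Three-state call: QC gate, then the purity floor, then the cutoff.

    A score exactly at the cutoff is positive (>= convention).
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie in (0, 1)")
    if not qc_valid:
        return HrdCall(None, "unknown", "qc_fail")
    if effective_purity < purity_floor:
        return HrdCall(score, "unknown", "low_purity")
    if score is None:
        raise ValueError("score required for a QC-valid replicate above the purity floor")
    status = "positive" if score >= cutoff else "negative"
    return HrdCall(float(score), status, "ok")
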