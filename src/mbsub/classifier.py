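"""Random-forest subgroup classification over ssGSEA profiles.

Workflow: stratified 70-30 train/test split; fit a forest on the training
profiles; linearly rescale impurity-based feature importances so the maximum
equals ``importance_scale_max`` (100); keep features with scaled importance
strictly above ``importance_threshold`` (8); refit on the *same* training
indices with the pruned feature set (the test set stays untouched); report
held-out accuracy. The same machinery serves the multiclass subgroup model
(WNT / SHH / Group 3 / Group 4) and the binary tumor-type model.

"Scaled importance > 8" is only meaningful on a declared scale; here the
scale ceiling and the strict threshold are both explicit, configurable and
persisted in the model manifest, as are forest size and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .ssgsea import EnrichmentProfile

__all__ = [
    "TrainConfig",
    "SubgroupModel",
    "stratified_split",
    "train_model",
    "train_binary_model",
    "predict_proba",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class TrainConfig:
    train_fraction: float = 0.70
    importance_threshold: float = 8.0
    importance_scale_max: float = 100.0
    n_trees: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if not 0.0 <= self.importance_threshold <= self.importance_scale_max:
            raise ValueError("importance_threshold must lie in [0, importance_scale_max]")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class SubgroupModel:
    """A fitted, pruned forest plus everything needed to audit or reuse it."""

    forest: RandomForestClassifier
    selected_features: list[str]
    classes: list[str]
    importances: pd.DataFrame  # feature, raw_importance, scaled_importance
    test_accuracy: float
    config: TrainConfig
    train_index: list[str] = field(default_factory=list)
    test_index: list[str] = field(default_factory=list)


def _as_frame(profiles: EnrichmentProfile | pd.DataFrame) -> pd.DataFrame:
    return profiles.scores if isinstance(profiles, EnrichmentProfile) else profiles


def stratified_split(
    labels: Sequence[str] | pd.Series,
    train_fraction: float = 0.70,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random split into train/test positional indices.

    Each class contributes ``round(train_fraction * n_class)`` training
    samples (clamped so both halves are non-empty); a class with fewer than
    2 samples is an error. Disjoint, exhaustive and seed-reproducible.
    """
    labels = pd.Series(list(labels))
    rng = np.random.default_rng(seed)
    train: list[int] = []
    test: list[int] = []
    for cls, idx in labels.groupby(labels).groups.items():
        idx = np.asarray(idx)
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        perm = rng.permutation(idx)
        train.extend(perm[:n_train])
        test.extend(perm[n_train:])
    return np.sort(np.array(train)), np.sort(np.array(test))


def train_model(
    profiles: EnrichmentProfile | pd.DataFrame,
    labels: Sequence[str] | pd.Series,
    config: TrainConfig = TrainConfig(),
) -> SubgroupModel:
    """Train the importance-pruned forest on enrichment profiles.

    Raises when labels misalign with profile rows, when any class has fewer
    than 2 samples, or when no feature clears the importance threshold (the
    error suggests lowering it).
    """
    x = _as_frame(profiles)
    y = pd.Series(list(labels), index=x.index)
    if len(y) != len(x):
        raise ValueError("labels do not align with profile rows")
    if y.nunique() < 2:
        raise ValueError("need at least 2 classes to train")

    train_idx, test_idx = stratified_split(y, config.train_fraction, config.seed)
    x_train, y_train = x.iloc[train_idx], y.iloc[train_idx]
    x_test, y_test = x.iloc[test_idx], y.iloc[test_idx]

    full = RandomForestClassifier(
        n_estimators=config.n_trees, random_state=config.seed, n_jobs=1
    )
    full.fit(x_train.to_numpy(), y_train.to_numpy())

    raw = full.feature_importances_
    peak = raw.max()
    scaled = raw * (config.importance_scale_max / peak) if peak > 0 else raw
    table = pd.DataFrame(
        {"feature": x.columns, "raw_importance": raw, "scaled_importance": scaled}
    ).sort_values("scaled_importance", ascending=False, ignore_index=True)

    selected = [
        f for f, s in zip(x.columns, scaled) if s > config.importance_threshold
    ]
    if not selected:
        raise ValueError(
            "no feature has scaled importance above "
            f"{config.importance_threshold}; lower importance_threshold"
        )

    pruned = RandomForestClassifier(
        n_estimators=config.n_trees, random_state=config.seed, n_jobs=1
    )
    pruned.fit(x_train[selected].to_numpy(), y_train.to_numpy())
    accuracy = float(
        (pruned.predict(x_test[selected].to_numpy()) == y_test.to_numpy()).mean()
    )

    return SubgroupModel(
        forest=pruned,
        selected_features=selected,
        classes=[str(c) for c in pruned.classes_],
        importances=table,
        test_accuracy=accuracy,
        config=config,
        train_index=[str(i) for i in x.index[train_idx]],
        test_index=[str(i) for i in x.index[test_idx]],
    )


def train_binary_model(
    profiles: EnrichmentProfile | pd.DataFrame,
    is_mb_labels: Sequence[str | bool] | pd.Series,
    config: TrainConfig = TrainConfig(),
) -> SubgroupModel:
    """Binary tumor-type variant (medulloblastoma vs not) of ``train_model``."""
    labels = pd.Series(list(is_mb_labels)).astype(str)
    if labels.nunique() != 2:
        raise ValueError("binary model needs exactly 2 label values")
    return train_model(profiles, labels, config)


def predict_proba(
    model: SubgroupModel, profiles: EnrichmentProfile | pd.DataFrame
) -> pd.DataFrame:
    """Class-probability rows for new samples; argmax gives the hard call.

    Profile columns must cover the model's selected features (extra columns
    are ignored; missing ones raise, listing their names).
    """
    x = _as_frame(profiles)
    missing = [f for f in model.selected_features if f not in x.columns]
    if missing:
        raise ValueError(f"profile is missing model features: {missing}")
    probs = model.forest.predict_proba(x[model.selected_features].to_numpy())
    return pd.DataFrame(probs, index=x.index, columns=model.classes)


def save_model(model: SubgroupModel, directory: str | Path) -> None:
    """Persist as a directory: joblib forest + JSON manifest + importances TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    joblib.dump(model.forest, directory / "forest.joblib")
    model.importances.to_csv(directory / "importances.tsv", sep="\t", index=False)
    manifest = {
        "selected_features": model.selected_features,
        "classes": model.classes,
        "test_accuracy": model.test_accuracy,
        "config": asdict(model.config),
        "train_index": model.train_index,
        "test_index": model.test_index,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_model(directory: str | Path) -> SubgroupModel:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    return SubgroupModel(
        forest=joblib.load(directory / "forest.joblib"),
        selected_features=manifest["selected_features"],
        classes=manifest["classes"],
        importances=pd.read_csv(directory / "importances.tsv", sep="\t"),
        test_accuracy=manifest["test_accuracy"],
        config=TrainConfig(**manifest["config"]),
        train_index=manifest["train_index"],
        test_index=manifest["test_index"],
    )
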