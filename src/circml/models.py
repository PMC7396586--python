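"""Model training and evaluation: the LightGBM circRNA classifier, six
comparison learners, repeated stratified cross-validation, the batched
hyperparameter grid search, and the three-classifier regulatory-interaction
ensemble with probability fusion.

All estimators run single-threaded with fixed seeds so that every fit is
bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import SGDClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from . import metrics as _metrics
from .seqio import FeatureTable
from .features import MinMaxParams

logger = logging.getLogger(__name__)

ALGORITHMS = ("gbm_light", "gbdt", "xgb", "rf", "svm_linear", "sgd", "gnb")

#: grid-searched optimum for the circRNA-vs-lncRNA LightGBM classifier
CIRCLGB_HYPERPARAMS: dict[str, float] = {
    "learning_rate": 0.1,
    "num_leaves": 60,
    "feature_fraction": 0.5,
    "bagging_fraction": 0.6,
    "reg_alpha": 0.01,
    "reg_lambda": 0.001,
}

#: grid-searched optima for the miRNA / RBP / TR interaction classifiers
ENSEMBLE_HYPERPARAMS: dict[str, dict[str, float]] = {
    "mirna": {"learning_rate": 0.1, "num_leaves": 20, "feature_fraction": 0.6,
              "bagging_fraction": 0.6, "reg_alpha": 0.01, "reg_lambda": 0.03},
    "rbp": {"learning_rate": 0.1, "num_leaves": 40, "feature_fraction": 0.6,
            "bagging_fraction": 0.6, "reg_alpha": 0.001, "reg_lambda": 0.001},
    "tr": {"learning_rate": 0.1, "num_leaves": 35, "feature_fraction": 0.6,
           "bagging_fraction": 0.5, "reg_alpha": 0.01, "reg_lambda": 0.01},
}

#: SFS-optimal prefix sizes for the three interaction classifiers
DEFAULT_TOP_K: dict[str, int] = {"mirna": 21, "rbp": 26, "tr": 15}

#: the batched grid searched over by :func:`grid_search_batched`
DEFAULT_GRID: dict[str, tuple] = {
    "learning_rate": (0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08, 0.09, 0.1, 0.2),
    "num_leaves": (20, 25, 30, 35, 40, 45, 50),
    "feature_fraction": (0.5, 0.6, 0.7, 0.8, 0.9),
    "bagging_fraction": (0.5, 0.6, 0.7, 0.8, 0.9),
    "reg_alpha": (0.001, 0.01, 0.03, 0.05),
    "reg_lambda": (0.001, 0.01, 0.03, 0.05),
}

GRID_BATCHES: tuple[tuple[str, str], ...] = (
    ("learning_rate", "num_leaves"),
    ("feature_fraction", "bagging_fraction"),
    ("reg_alpha", "reg_lambda"),
)


@dataclass
class ModelConfig:
    """Configuration of one binary classifier."""

    algorithm: str = "gbm_light"
    hyperparameters: dict = field(default_factory=lambda: dict(CIRCLGB_HYPERPARAMS))
    n_iterations: int = 100
    early_stopping_patience: int = 10
    objective: str = "binary"
    eval_metric: str = "auc"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")

    def with_seed(self, seed: int) -> "ModelConfig":
        return replace(self, seed=seed)


def build_estimator(config: ModelConfig):
    """Instantiate the scikit-learn–compatible estimator for ``config``."""
    hp = config.hyperparameters
    seed = config.seed
    if config.algorithm == "gbm_light":
        import lightgbm as lgb

        return lgb.LGBMClassifier(
            n_estimators=config.n_iterations,
            learning_rate=hp.get("learning_rate", 0.1),
            num_leaves=int(hp.get("num_leaves", 31)),
            colsample_bytree=hp.get("feature_fraction", 1.0),
            subsample=hp.get("bagging_fraction", 1.0),
            subsample_freq=1,
            reg_alpha=hp.get("reg_alpha", 0.0),
            reg_lambda=hp.get("reg_lambda", 0.0),
            objective=config.objective,
            random_state=seed,
            n_jobs=1,
            deterministic=True,
            force_row_wise=True,
            verbose=-1,
        )
    if config.algorithm == "gbdt":
        return GradientBoostingClassifier(
            n_estimators=config.n_iterations,
            learning_rate=hp.get("learning_rate", 0.1),
            random_state=seed,
        )
    if config.algorithm == "xgb":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=config.n_iterations,
            learning_rate=hp.get("learning_rate", 0.1),
            reg_alpha=hp.get("reg_alpha", 0.0),
            reg_lambda=hp.get("reg_lambda", 1.0),
            random_state=seed,
            n_jobs=1,
            verbosity=0,
            eval_metric="logloss",
        )
    if config.algorithm == "rf":
        return RandomForestClassifier(
            n_estimators=int(hp.get("n_trees", 20)), random_state=seed, n_jobs=1
        )
    if config.algorithm == "svm_linear":
        return SVC(
            kernel="linear", C=hp.get("C", 1.0), probability=True, random_state=seed
        )
    if config.algorithm == "sgd":
        return SGDClassifier(loss="log_loss", random_state=seed)
    if config.algorithm == "gnb":
        return GaussianNB()
    raise AssertionError(config.algorithm)


@dataclass
class FittedModel:
    """A trained classifier plus the feature-name order it expects."""

    estimator: object
    feature_names: list[str]
    config: ModelConfig

    def _matrix(self, table_or_array) -> pd.DataFrame:
        if isinstance(table_or_array, FeatureTable):
            values = table_or_array.select_features(self.feature_names).values
        else:
            values = np.asarray(table_or_array, dtype=float)
        return pd.DataFrame(values, columns=self.feature_names)

    def predict_proba(self, table_or_array) -> np.ndarray:
        """P(class 1) for each row."""
        X = self._matrix(table_or_array)
        return self.estimator.predict_proba(X)[:, 1]

    def predict(self, table_or_array, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(table_or_array) >= threshold).astype(int)


def train(
    table: FeatureTable,
    config: ModelConfig | None = None,
    valid: FeatureTable | None = None,
) -> FittedModel:
    """Fit a binary classifier on a labeled table.

    For the LightGBM algorithm a validation table activates AUC-monitored
    early stopping with the configured patience; other learners ignore it.
    """
    config = config or ModelConfig()
    if table.labels is None:
        raise ValueError("train requires a labeled table")
    classes = np.unique(table.labels)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    est = build_estimator(config)
    X = pd.DataFrame(table.values, columns=table.feature_names)
    y = table.labels
    if config.algorithm == "gbm_light" and valid is not None and valid.labels is not None:
        import lightgbm as lgb

        Xv = pd.DataFrame(
            valid.select_features(table.feature_names).values, columns=table.feature_names
        )
        est.fit(
            X, y,
            eval_set=[(Xv, valid.labels)],
            eval_metric=config.eval_metric,
            callbacks=[lgb.early_stopping(config.early_stopping_patience, verbose=False)],
        )
    else:
        est.fit(X, y)
    return FittedModel(estimator=est, feature_names=list(table.feature_names), config=config)


@dataclass
class CVResult:
    means: dict[str, float]
    sds: dict[str, float]
    fold_records: pd.DataFrame  # one row per (repeat, fold)


def cross_validate(
    table: FeatureTable,
    config: ModelConfig | None = None,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
) -> CVResult:
    """Repeated stratified k-fold cross-validation.

    Each repeat r uses fold assignments drawn with seed ``seed + r``; metrics
    (SE, SP, PRE, F1, ACC, MCC, AUC) are averaged over folds x repeats.  A
    test fold holding a single class scores MCC 0 and AUC 0.5 (logged).
    """
    config = config or ModelConfig()
    if table.labels is None:
        raise ValueError("cross_validate requires a labeled table")
    if table.n_transcripts < folds:
        raise ValueError(f"n={table.n_transcripts} < folds={folds}")
    records = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        for fold_i, (train_idx, test_idx) in enumerate(skf.split(table.values, table.labels)):
            sub_train = table.select_rows(train_idx)
            sub_test = table.select_rows(test_idx)
            model = train(sub_train, config.with_seed(config.seed))
            prob = model.predict_proba(sub_test.values)
            pred = (prob >= threshold).astype(int)
            report = _metrics.compute_metrics(_metrics.confusion(sub_test.labels, pred))
            if np.unique(sub_test.labels).size < 2:
                logger.warning("repeat %d fold %d: single-class test fold", r, fold_i)
                auc = 0.5
            else:
                auc = _metrics.roc_auc(sub_test.labels, prob)
            row = report.as_dict()
            row.update({"AUC": auc, "repeat": r, "fold": fold_i})
            records.append(row)
    df = pd.DataFrame.from_records(records)
    metric_cols = ["SE", "SP", "PRE", "F1", "ACC", "MCC", "AUC"]
    return CVResult(
        means={m: float(df[m].mean()) for m in metric_cols},
        sds={m: float(df[m].std(ddof=1)) if len(df) > 1 else 0.0 for m in metric_cols},
        fold_records=df,
    )


def train_val_test_split(
    table: FeatureTable,
    fractions: tuple[float, float, float] = (0.75, 0.10, 0.15),
    seed: int = 0,
) -> tuple[FeatureTable, FeatureTable, FeatureTable]:
    """Stratified train/validation/test split (75/10/15 for tool comparison,
    60/20/20 for independent-test evaluation)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if table.labels is None:
        raise ValueError("split requires labels for stratification")
    idx = np.arange(table.n_transcripts)
    train_idx, rest_idx = train_test_split(
        idx, test_size=fractions[1] + fractions[2], random_state=seed,
        stratify=table.labels,
    )
    rel_test = fractions[2] / (fractions[1] + fractions[2])
    val_idx, test_idx = train_test_split(
        rest_idx, test_size=rel_test, random_state=seed + 1,
        stratify=table.labels[rest_idx],
    )
    return (
        table.select_rows(sorted(train_idx)),
        table.select_rows(sorted(val_idx)),
        table.select_rows(sorted(test_idx)),
    )


def grid_search_batched(
    table: FeatureTable,
    grid: Mapping[str, Sequence] | None = None,
    base_config: ModelConfig | None = None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[ModelConfig, pd.DataFrame]:
    """Batched grid search maximizing 5-fold cross-validated AUC.

    Parameters are tuned in three batches — (learning_rate, num_leaves), then
    (feature_fraction, bagging_fraction), then (reg_alpha, reg_lambda) — with
    each batch's winners carried forward into the next.  Returns the best
    configuration and the per-candidate AUC table.
    """
    grid = dict(grid) if grid is not None else dict(DEFAULT_GRID)
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty grid")
    config = base_config or ModelConfig()
    hp = dict(config.hyperparameters)
    rows = []
    for batch_no, batch in enumerate(GRID_BATCHES):
        names = [p for p in batch if p in grid]
        if not names:
            continue
        best_auc, best_values = -np.inf, None
        candidates = [(v,) for v in grid[names[0]]]
        if len(names) == 2:
            candidates = [(a, b) for a in grid[names[0]] for b in grid[names[1]]]
        for values in candidates:
            trial = dict(hp)
            trial.update(dict(zip(names, values)))
            result = cross_validate(
                table, replace(config, hyperparameters=trial),
                folds=folds, repeats=1, seed=seed,
            )
            auc = result.means["AUC"]
            rows.append({"batch": batch_no, **dict(zip(names, values)), "AUC": auc})
            if auc > best_auc:
                best_auc, best_values = auc, dict(zip(names, values))
        hp.update(best_values)
    return replace(config, hyperparameters=hp), pd.DataFrame.from_records(rows)


INTERACTION_CLASSES = ("mirna", "rbp", "tr")


@dataclass
class EnsembleConfig:
    """Configuration of the three-classifier regulatory-interaction ensemble."""

    model_configs: dict[str, ModelConfig] = field(
        default_factory=lambda: {
            c: ModelConfig(hyperparameters=dict(ENSEMBLE_HYPERPARAMS[c]))
            for c in INTERACTION_CLASSES
        }
    )
    optimal_features: dict[str, list[str] | None] = field(
        default_factory=lambda: {c: None for c in INTERACTION_CLASSES}
    )
    fusion: str = "union"
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.fusion not in ("union", "majority"):
            raise ValueError("fusion must be 'union' or 'majority'")


@dataclass
class EnsemblePrediction:
    transcript_id: str
    prob: dict[str, float]
    labels: frozenset[str]


@dataclass
class CircMRTEnsemble:
    models: dict[str, FittedModel]
    config: EnsembleConfig


def circmrt_fit(tables: Mapping[str, FeatureTable], config: EnsembleConfig | None = None) -> CircMRTEnsemble:
    """Fit the miRNA, RBP and TR binary classifiers, each restricted to its
    own optimal-feature list (all features when the list is None)."""
    config = config or EnsembleConfig()
    missing = [c for c in INTERACTION_CLASSES if c not in tables]
    if missing:
        raise ValueError(f"missing training table(s): {missing}")
    models: dict[str, FittedModel] = {}
    for cls in INTERACTION_CLASSES:
        table = tables[cls]
        feats = config.optimal_features.get(cls)
        if feats is not None:
            table = table.select_features(feats)
        models[cls] = train(table, config.model_configs[cls])
    return CircMRTEnsemble(models=models, config=config)


def fuse_probabilities(
    prob: Mapping[str, float], threshold: float = 0.5, fusion: str = "union"
) -> frozenset[str]:
    """Fuse per-classifier probabilities into a multi-label interaction set.

    Union mode assigns every class whose probability reaches the threshold
    (possibly none, possibly all three).  Majority mode emits the single
    highest-probability class when at least two classifiers reach the
    threshold, otherwise it degrades to union semantics.
    """
    above = [c for c in INTERACTION_CLASSES if prob[c] >= threshold]
    if fusion == "union":
        return frozenset(above)
    if fusion == "majority":
        if len(above) >= 2:
            return frozenset({max(above, key=lambda c: (prob[c], -INTERACTION_CLASSES.index(c)))})
        return frozenset(above)
    raise ValueError(f"unknown fusion mode {fusion!r}")


def circmrt_predict(
    handle: CircMRTEnsemble,
    features_of_transcript: Mapping[str, float] | pd.Series,
    transcript_id: str = "",
    threshold: float | None = None,
    fusion: str | None = None,
) -> EnsemblePrediction:
    """Predict the regulatory-interaction label set for one transcript."""
    threshold = handle.config.threshold if threshold is None else threshold
    fusion = handle.config.fusion if fusion is None else fusion
    if isinstance(features_of_transcript, pd.Series):
        features_of_transcript = features_of_transcript.to_dict()
    prob: dict[str, float] = {}
    for cls, model in handle.models.items():
        missing = [n for n in model.feature_names if n not in features_of_transcript]
        if missing:
            raise KeyError(f"{cls} classifier: missing feature(s) {missing}")
        row = np.array([[features_of_transcript[n] for n in model.feature_names]])
        prob[cls] = float(model.predict_proba(row)[0])
    return EnsemblePrediction(
        transcript_id=transcript_id,
        prob=prob,
        labels=fuse_probabilities(prob, threshold, fusion),
    )


def circmrt_predict_table(
    handle: CircMRTEnsemble,
    table: FeatureTable,
    threshold: float | None = None,
    fusion: str | None = None,
) -> pd.DataFrame:
    """Vectorized ensemble prediction over a feature table.

    Returns a DataFrame with columns prob_mirna, prob_rbp, prob_tr and a
    comma-joined ``labels`` column, indexed by transcript id.
    """
    threshold = handle.config.threshold if threshold is None else threshold
    fusion = handle.config.fusion if fusion is None else fusion
    probs = {
        cls: model.predict_proba(table) for cls, model in handle.models.items()
    }
    rows = []
    for i, tid in enumerate(table.transcript_ids):
        p = {cls: float(probs[cls][i]) for cls in INTERACTION_CLASSES}
        labels = fuse_probabilities(p, threshold, fusion)
        rows.append(
            {
                "id": tid,
                **{f"prob_{c}": p[c] for c in INTERACTION_CLASSES},
                "labels": ",".join(sorted(labels)),
            }
        )
    return pd.DataFrame.from_records(rows).set_index("id")


def save_model_bundle(
    path: str | Path,
    model: FittedModel,
    norm_params: MinMaxParams | None = None,
) -> None:
    """Serialize a fitted model to a directory: the model file, its feature
    list, optional normalization (min, max) pairs, and the config as JSON."""
    import joblib

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    joblib.dump(model.estimator, path / "model.joblib")
    (path / "features.txt").write_text("\n".join(model.feature_names) + "\n")
    cfg = asdict(model.config)
    (path / "config.json").write_text(json.dumps(cfg, indent=2) + "\n")
    if norm_params is not None:
        norm_params.to_frame().to_csv(path / "normalization.tsv", sep="\t", index=False)


def load_model_bundle(path: str | Path) -> tuple[FittedModel, MinMaxParams | None]:
    import joblib

    path = Path(path)
    estimator = joblib.load(path / "model.joblib")
    feature_names = (path / "features.txt").read_text().split()
    cfg = json.loads((path / "config.json").read_text())
    model = FittedModel(estimator=estimator, feature_names=feature_names, config=ModelConfig(**cfg))
    norm = None
    norm_path = path / "normalization.tsv"
    if norm_path.exists():
        df = pd.read_csv(norm_path, sep="\t")
        norm = MinMaxParams(
            feature_names=list(df["feature"]),
            mins=df["min"].to_numpy(),
            maxs=df["max"].to_numpy(),
        )
    return model, norm
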