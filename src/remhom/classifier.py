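"""Superfamily classifiers: the embedding-fed network and its baseline panel.

The panel mirrors the standard comparison for embedding-based remote
homology detection: the neural classifier (on pLM embeddings or on sequence
length alone), multinomial logistic regression, a class-prior random
predictor, and best-hit homology-based inference (HBI) from a BLAST-style
hit table.  Everything is exposed twice: as scikit-learn estimators
(:class:`~remhom.mlp.SuperfamilyMLP`, :class:`LogisticBaseline`,
:class:`PriorRandomClassifier`) and as thin functional wrappers operating on
:class:`~remhom.embeddings.FeatureMatrix` objects.
"""

from __future__ import annotations

import io
import json
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from .embeddings import FeatureMatrix
from .mlp import SuperfamilyMLP
from .records import LabelSpace, NO_HIT_LABEL

__all__ = [
    "MLPConfig",
    "TrainedModel",
    "PredictionResult",
    "HitRecord",
    "LogisticBaseline",
    "PriorRandomClassifier",
    "train_mlp",
    "train_length_mlp",
    "train_logistic",
    "predict_proba",
    "extract_latent",
    "random_predictor",
    "hbi_best_hit",
    "read_hit_table",
    "save_model",
    "load_model",
]

FORMAT_VERSION = 1


@dataclass
class MLPConfig:
    """Hyper-parameters of the neural classifier (defaults are the reference
    recipe: one 128-unit hidden layer, dropout 0.3, batch norm, Adam at
    1e-3, batch size 256, at most 200 epochs with patience 20 on validation
    accuracy)."""

    hidden_units: int = 128
    dropout_rate: float = 0.3
    use_batch_norm: bool = True
    learning_rate: float = 1e-3
    max_epochs: int = 200
    patience: int = 20
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")

    def to_estimator(self) -> SuperfamilyMLP:
        return SuperfamilyMLP(
            hidden_units=self.hidden_units,
            dropout_rate=self.dropout_rate,
            use_batch_norm=self.use_batch_norm,
            learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            patience=self.patience,
            batch_size=self.batch_size,
            random_state=self.seed,
        )


@dataclass
class TrainedModel:
    """A fitted classifier plus its label space and training log."""

    kind: str  # mlp | logistic | length_mlp | random | hbi
    estimator: object
    label_space: LabelSpace
    training_log: List[dict] = field(default_factory=list)
    config: Optional[dict] = None


@dataclass
class PredictionResult:
    """Per-domain class probabilities and argmax labels.

    ``proba`` is None for non-probabilistic predictors (HBI); then
    ``max_proba`` is 1.0 for resolved queries and 0.0 for ``no_hit``.
    """

    ids: List[str]
    predicted_label: List[str]
    max_proba: np.ndarray
    proba: Optional[np.ndarray] = None
    label_space: Optional[LabelSpace] = None

    def __post_init__(self) -> None:
        self.max_proba = np.asarray(self.max_proba, dtype=np.float64)
        n = len(self.ids)
        if len(self.predicted_label) != n or len(self.max_proba) != n:
            raise ValueError("ids, predicted_label and max_proba must agree")
        if self.proba is not None:
            self.proba = np.asarray(self.proba, dtype=np.float64)
            if self.proba.shape[0] != n:
                raise ValueError("proba row count mismatch")
            if not np.allclose(self.proba.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError("probability rows must sum to 1")
            if not np.allclose(self.proba.max(axis=1), self.max_proba, atol=1e-9):
                raise ValueError("max_proba inconsistent with proba")

    @classmethod
    def from_proba(
        cls, ids: Sequence[str], proba: np.ndarray, label_space: LabelSpace
    ) -> "PredictionResult":
        proba = np.asarray(proba, dtype=np.float64)
        arg = proba.argmax(axis=1)
        return cls(
            ids=list(ids),
            predicted_label=[label_space.decode(i) for i in arg],
            max_proba=proba.max(axis=1),
            proba=proba,
            label_space=label_space,
        )


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class LogisticBaseline(ClassifierMixin, BaseEstimator):
    """Multinomial logistic regression baseline (lbfgs, max_iter 5000).

    Thin wrapper around :class:`sklearn.linear_model.LogisticRegression`
    that records non-convergence in ``training_log_`` instead of letting the
    warning escape.
    """

    def __init__(self, max_iterations: int = 5000, C: float = 1.0):
        self.max_iterations = max_iterations
        self.C = C

    def fit(self, X, y):
        self.training_log_ = []
        inner = LogisticRegression(
            solver="lbfgs", max_iter=self.max_iterations, C=self.C
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            inner.fit(X, y)
        for w in caught:
            if issubclass(w.category, ConvergenceWarning):
                self.training_log_.append(
                    {"warning": "did not converge", "detail": str(w.message)}
                )
        self._inner = inner
        self.classes_ = inner.classes_
        self.coef_ = inner.coef_
        self.intercept_ = inner.intercept_
        self.n_features_in_ = inner.n_features_in_
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "_inner")
        return self._inner.predict_proba(X)

    def predict(self, X):
        check_is_fitted(self, "_inner")
        return self._inner.predict(X)


class PriorRandomClassifier(ClassifierMixin, BaseEstimator):
    """Class-imbalance-aware random predictor.

    Labels are drawn i.i.d. with probability proportional to the training
    class counts; probability rows are the prior vector.  Its expected
    accuracy against labels from the same prior is the collision probability
    sum(p_i^2) — the sanity floor any learned model must beat.
    """

    def __init__(self, random_state: int = 0):
        self.random_state = random_state

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_, counts = np.unique(y, return_counts=True)
        self.class_prior_ = counts / counts.sum()
        self._rng = np.random.default_rng(self.random_state)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "class_prior_")
        return np.tile(self.class_prior_, (len(X), 1))

    def predict(self, X):
        check_is_fitted(self, "class_prior_")
        return self._rng.choice(self.classes_, size=len(X), p=self.class_prior_)


# ---------------------------------------------------------------------------
# functional wrappers over FeatureMatrix
# ---------------------------------------------------------------------------

def train_mlp(
    train: FeatureMatrix, val: FeatureMatrix, config: Optional[MLPConfig] = None
) -> TrainedModel:
    """Train the neural classifier with early stopping on ``val`` accuracy."""
    config = config or MLPConfig()
    if train.label_space.labels != val.label_space.labels:
        raise ValueError("train and validation label spaces differ")
    if val.n == 0:
        raise ValueError("validation set is empty")
    est = config.to_estimator()
    # fit on integer codes over the full label space so every class has an
    # output unit even if absent from the training sample
    est.fit(train.X, train.y, X_val=val.X, y_val=val.y)
    return TrainedModel(
        kind="mlp",
        estimator=est,
        label_space=train.label_space,
        training_log=est.training_log_,
        config=config.__dict__.copy(),
    )


def train_length_mlp(
    train: FeatureMatrix, val: FeatureMatrix, config: Optional[MLPConfig] = None
) -> TrainedModel:
    """The same network trained on (standardized) sequence length only."""
    model = train_mlp(train, val, config)
    model.kind = "length_mlp"
    return model


def train_logistic(train: FeatureMatrix, max_iterations: int = 5000) -> TrainedModel:
    est = LogisticBaseline(max_iterations=max_iterations)
    est.fit(train.X, train.y)
    return TrainedModel(
        kind="logistic",
        estimator=est,
        label_space=train.label_space,
        training_log=list(est.training_log_),
        config={"max_iterations": max_iterations},
    )


def _full_space_proba(model: TrainedModel, raw: np.ndarray) -> np.ndarray:
    """Expand probabilities over fitted classes to the full label space."""
    K = len(model.label_space)
    classes = np.asarray(model.estimator.classes_, dtype=np.int64)
    if len(classes) == K and np.array_equal(classes, np.arange(K)):
        return raw
    out = np.zeros((raw.shape[0], K))
    out[:, classes] = raw
    return out


def predict_proba(model: TrainedModel, X: FeatureMatrix) -> PredictionResult:
    """Class probabilities for a feature matrix (rows sum to 1)."""
    if model.kind in ("random",):
        raw = model.estimator.predict_proba(X.X)
    else:
        if X.dim != model.estimator.n_features_in_:
            raise ValueError(
                f"feature dim {X.dim} does not match model input "
                f"{model.estimator.n_features_in_}"
            )
        raw = model.estimator.predict_proba(X.X)
    proba = _full_space_proba(model, raw)
    return PredictionResult.from_proba(X.ids, proba, model.label_space)


def extract_latent(model: TrainedModel, X: FeatureMatrix) -> np.ndarray:
    """Hidden-layer (latent) representation of the trained network.

    These latent vectors are what the supervised training distils out of the
    input embeddings; their width equals ``hidden_units`` (128 by default).
    """
    if model.kind not in ("mlp", "length_mlp"):
        raise ValueError(f"latent extraction requires an mlp model, got {model.kind}")
    return model.estimator.transform(X.X)


def random_predictor(
    class_counts: Dict[str, int], n: int, seed: int = 0
) -> PredictionResult:
    """Draw ``n`` labels i.i.d. from the training class priors.

    Probability rows are the prior vector (columns in ``class_counts``
    iteration order); predicted labels are the random draws, not the argmax.
    """
    labels = list(class_counts)
    counts = np.array([class_counts[c] for c in labels], dtype=np.float64)
    if counts.sum() <= 0:
        raise ValueError("class counts must sum to > 0")
    prior = counts / counts.sum()
    rng = np.random.default_rng(seed)
    drawn = rng.choice(len(labels), size=n, p=prior)
    return PredictionResult(
        ids=[f"rand_{i}" for i in range(n)],
        predicted_label=[labels[i] for i in drawn],
        max_proba=np.full(n, prior.max()),
        proba=np.tile(prior, (n, 1)),
    )


# ---------------------------------------------------------------------------
# homology-based inference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HitRecord:
    """One pairwise-search hit (BLAST tabular dialect)."""

    query_id: str
    target_id: str
    evalue: float
    percent_identity: float  # percentage scale, 0..100
    target_label: str

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


def hbi_best_hit(
    hits: Sequence[HitRecord],
    queries: Sequence[str],
    strict: bool = False,
) -> PredictionResult:
    """Best-hit homology-based inference.

    Per query: keep hits with the minimal e-value; among those take the
    greatest percent identity; remaining ties resolve to the
    lexicographically smallest target_id.  The chosen hit's superfamily is
    the prediction.  Queries with no hits get the reserved ``no_hit``
    outcome (max_proba 0); resolved queries get max_proba 1 — HBI is not
    probabilistic.  Output is invariant to the ordering of ``hits``.
    """
    by_query: Dict[str, List[HitRecord]] = {q: [] for q in queries}
    for h in hits:
        if h.query_id not in by_query:
            if strict:
                raise KeyError(f"hit references unknown query {h.query_id!r}")
            continue
        by_query[h.query_id].append(h)

    labels, confid = [], []
    for q in queries:
        qhits = by_query[q]
        if not qhits:
            labels.append(NO_HIT_LABEL)
            confid.append(0.0)
            continue
        best = min(
            qhits, key=lambda h: (h.evalue, -h.percent_identity, h.target_id)
        )
        labels.append(best.target_label)
        confid.append(1.0)
    return PredictionResult(
        ids=list(queries), predicted_label=labels, max_proba=np.array(confid)
    )


def read_hit_table(path, target_labels: Dict[str, str]) -> List[HitRecord]:
    """Read a BLAST outfmt-6 tabular file.

    Expects at least the standard columns (qseqid, sseqid, pident, ...,
    evalue at column 11); ``target_labels`` maps sseqid to its superfamily.
    """
    hits = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 11:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 11 tab-separated "
                    f"columns (outfmt 6), got {len(f)}"
                )
            target = f[1]
            if target not in target_labels:
                raise KeyError(
                    f"{path}: line {lineno}: no superfamily mapping for {target!r}"
                )
            hits.append(
                HitRecord(
                    query_id=f[0],
                    target_id=target,
                    evalue=float(f[10]),
                    percent_identity=float(f[2]),
                    target_label=target_labels[target],
                )
            )
    return hits


# ---------------------------------------------------------------------------
# persistence: one-file zip archive with a JSON manifest + npz weights
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path) -> None:
    if model.kind in ("mlp", "length_mlp"):
        est = model.estimator
        arrays = {k: v for k, v in est._params.items()}
        arrays["run_mean"] = est._run_mean
        arrays["run_var"] = est._run_var
        arrays["classes"] = est.classes_
        est_meta = est.get_params()
    elif model.kind == "logistic":
        est = model.estimator
        arrays = {
            "coef": est.coef_,
            "intercept": est.intercept_,
            "classes": np.asarray(est.classes_),
        }
        est_meta = est.get_params()
    else:
        raise ValueError(f"serialization not supported for kind {model.kind!r}")
    manifest = {
        "format_version": FORMAT_VERSION,
        "kind": model.kind,
        "named_superfamilies": list(model.label_space.named_superfamilies),
        "has_other": model.label_space.has_other,
        "estimator_params": est_meta,
        "config": model.config,
        "training_log": model.training_log,
    }
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=2))
        zf.writestr("weights.npz", buf.getvalue())


def load_model(path) -> TrainedModel:
    with zipfile.ZipFile(path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
        arrays = np.load(io.BytesIO(zf.read("weights.npz")))
        arrays = {k: arrays[k] for k in arrays.files}
    if manifest["format_version"] != FORMAT_VERSION:
        raise ValueError(f"unsupported model format {manifest['format_version']}")
    label_space = LabelSpace(
        tuple(manifest["named_superfamilies"]), manifest["has_other"]
    )
    kind = manifest["kind"]
    if kind in ("mlp", "length_mlp"):
        est = SuperfamilyMLP(**manifest["estimator_params"])
        est.classes_ = arrays.pop("classes")
        est._run_mean = arrays.pop("run_mean")
        est._run_var = arrays.pop("run_var")
        est._params = arrays
        est.n_features_in_ = est._params["W1"].shape[0]
        est.training_log_ = manifest["training_log"]
    else:
        est = LogisticBaseline(**manifest["estimator_params"])
        inner = LogisticRegression(solver="lbfgs", max_iter=est.max_iterations)
        inner.classes_ = arrays["classes"]
        inner.coef_ = arrays["coef"]
        inner.intercept_ = arrays["intercept"]
        inner.n_features_in_ = inner.coef_.shape[1]
        est._inner = inner
        est.classes_ = inner.classes_
        est.coef_, est.intercept_ = inner.coef_, inner.intercept_
        est.n_features_in_ = inner.n_features_in_
        est.training_log_ = manifest["training_log"]
    return TrainedModel(
        kind=kind,
        estimator=est,
        label_space=label_space,
        training_log=manifest["training_log"],
        config=manifest.get("config"),
    )
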