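"""A seeded single-hidden-layer softmax network, scikit-learn style.

Architecture: input -> dense(hidden_units) -> ReLU -> dropout -> batch
normalization -> dense(K) -> softmax, trained with Adam on categorical
cross-entropy.  Early stopping monitors validation accuracy with a patience
window and restores the best-epoch weights.  The implementation is pure
NumPy: at the few-thousand-sample scale this package targets, CPU matrix
products train the model in seconds and keep every arithmetic step
reproducible for a given seed and thread count.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = ["SuperfamilyMLP"]

_EPS = 1e-8  # batch-norm variance guard
_BN_MOMENTUM = 0.9


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, params: Dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1c) / (
                np.sqrt(self.v[k] / b2c) + self.eps
            )


class SuperfamilyMLP(TransformerMixin, ClassifierMixin, BaseEstimator):
    """Embedding-fed superfamily classifier.

    Parameters
    ----------
    hidden_units : int, default 128
        Width of the single hidden layer; also the dimensionality of the
        latent representation returned by :meth:`transform`.
    dropout_rate : float, default 0.3
        Inverted dropout applied to the hidden activations during training.
    use_batch_norm : bool, default True
        Batch-normalize the (post-dropout) hidden activations; inference
        uses running statistics.
    learning_rate : float, default 1e-3
        Adam initial learning rate.
    max_epochs : int, default 200
    patience : int, default 20
        Epochs without a validation-accuracy improvement (> ``tol``) before
        stopping; best-epoch weights are restored.
    batch_size : int, default 256
    validation_fraction : float, default 0.1
        Used only when :meth:`fit` is not given an explicit validation set.
    tol : float, default 1e-6
        Minimum increase in validation accuracy that counts as improvement.
    random_state : int, default 0

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels seen in ``y``.
    training_log_ : list of dict
        Per-epoch ``{"epoch", "loss", "val_accuracy"}`` records.
    best_epoch_ : int
        Epoch (0-based) whose weights the fitted model carries.
    n_iter_ : int
        Number of epochs actually run.
    """

    def __init__(
        self,
        hidden_units: int = 128,
        dropout_rate: float = 0.3,
        use_batch_norm: bool = True,
        learning_rate: float = 1e-3,
        max_epochs: int = 200,
        patience: int = 20,
        batch_size: int = 256,
        validation_fraction: float = 0.1,
        tol: float = 1e-6,
        random_state: int = 0,
    ):
        self.hidden_units = hidden_units
        self.dropout_rate = dropout_rate
        self.use_batch_norm = use_batch_norm
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.tol = tol
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _validate_params_strict(self) -> None:
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")

    def fit(self, X, y, X_val=None, y_val=None):
        """Train with early stopping on held-out accuracy.

        ``X_val``/``y_val`` supply the early-stopping validation set; if
        omitted, ``validation_fraction`` of the training data is carved off
        (seeded shuffle).
        """
        self._validate_params_strict()
        X, y = check_X_y(X, y, dtype=np.float64)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        K = len(self.classes_)
        if K < 2:
            raise ValueError("need at least 2 classes")
        rng = np.random.default_rng(self.random_state)

        if X_val is None:
            n_val = max(1, int(round(self.validation_fraction * len(X))))
            perm = rng.permutation(len(X))
            val_pos, train_pos = perm[:n_val], perm[n_val:]
            X_val_arr, yv = X[val_pos], y_idx[val_pos]
            X, y_idx = X[train_pos], y_idx[train_pos]
        else:
            X_val_arr = check_array(X_val, dtype=np.float64, ensure_min_samples=0)
            if X_val_arr.shape[0] == 0:
                raise ValueError("validation set is empty; early stopping undefined")
            lut = {c: i for i, c in enumerate(self.classes_)}
            yv = np.array([lut[v] for v in np.asarray(y_val)], dtype=np.int64)

        n, d = X.shape
        self.n_features_in_ = d
        h = self.hidden_units
        p = self.dropout_rate

        params = {
            "W1": rng.standard_normal((d, h)) * np.sqrt(2.0 / d),
            "b1": np.zeros(h),
            "gamma": np.ones(h),
            "beta": np.zeros(h),
            "W2": rng.standard_normal((h, K)) * np.sqrt(2.0 / (h + K)),
            "b2": np.zeros(K),
        }
        run_mean = np.zeros(h)
        run_var = np.ones(h)
        opt = _Adam(params, self.learning_rate)

        self.training_log_: List[dict] = []
        best_acc = -np.inf
        best_state: Optional[dict] = None
        best_epoch = -1
        stall = 0

        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = X[idx], y_idx[idx]
                B = len(idx)

                z1 = xb @ params["W1"] + params["b1"]
                a = np.maximum(z1, 0.0)
                if p > 0.0:
                    mask = (rng.random(a.shape) >= p) / (1.0 - p)
                    dpd = a * mask
                else:
                    mask = None
                    dpd = a
                if self.use_batch_norm:
                    mu = dpd.mean(axis=0)
                    var = dpd.var(axis=0)
                    inv_std = 1.0 / np.sqrt(var + _EPS)
                    xhat = (dpd - mu) * inv_std
                    bn = params["gamma"] * xhat + params["beta"]
                    run_mean = _BN_MOMENTUM * run_mean + (1 - _BN_MOMENTUM) * mu
                    run_var = _BN_MOMENTUM * run_var + (1 - _BN_MOMENTUM) * var
                else:
                    bn = dpd
                logits = bn @ params["W2"] + params["b2"]
                proba = _softmax(logits)
                losses.append(
                    -np.mean(np.log(proba[np.arange(B), yb] + 1e-300))
                )

                dlogits = proba.copy()
                dlogits[np.arange(B), yb] -= 1.0
                dlogits /= B
                grads = {
                    "W2": bn.T @ dlogits,
                    "b2": dlogits.sum(axis=0),
                }
                dbn = dlogits @ params["W2"].T
                if self.use_batch_norm:
                    grads["gamma"] = (dbn * xhat).sum(axis=0)
                    grads["beta"] = dbn.sum(axis=0)
                    dxhat = dbn * params["gamma"]
                    ddpd = (inv_std / B) * (
                        B * dxhat
                        - dxhat.sum(axis=0)
                        - xhat * (dxhat * xhat).sum(axis=0)
                    )
                else:
                    grads["gamma"] = np.zeros(h)
                    grads["beta"] = np.zeros(h)
                    ddpd = dbn
                da = ddpd * mask if mask is not None else ddpd
                dz1 = da * (z1 > 0.0)
                grads["W1"] = xb.T @ dz1
                grads["b1"] = dz1.sum(axis=0)
                opt.step(params, grads)

            val_acc = self._accuracy(X_val_arr, yv, params, run_mean, run_var)
            self.training_log_.append(
                {
                    "epoch": epoch,
                    "loss": float(np.mean(losses)),
                    "val_accuracy": float(val_acc),
                }
            )
            if val_acc > best_acc + self.tol:
                best_acc = val_acc
                best_epoch = epoch
                best_state = {
                    "params": {k: v.copy() for k, v in params.items()},
                    "run_mean": run_mean.copy(),
                    "run_var": run_var.copy(),
                }
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break

        assert best_state is not None
        self._params = best_state["params"]
        self._run_mean = best_state["run_mean"]
        self._run_var = best_state["run_var"]
        self.best_epoch_ = best_epoch
        self.best_val_accuracy_ = float(best_acc)
        self.n_iter_ = len(self.training_log_)
        return self

    # ------------------------------------------------------------------
    def _hidden(self, X: np.ndarray, params, run_mean, run_var) -> np.ndarray:
        """Inference-mode latent: ReLU then batch-norm with running stats
        (dropout inactive)."""
        a = np.maximum(X @ params["W1"] + params["b1"], 0.0)
        if self.use_batch_norm:
            xhat = (a - run_mean) / np.sqrt(run_var + _EPS)
            return params["gamma"] * xhat + params["beta"]
        return a

    def _forward(self, X, params, run_mean, run_var) -> np.ndarray:
        bn = self._hidden(X, params, run_mean, run_var)
        return _softmax(bn @ params["W2"] + params["b2"])

    def _accuracy(self, X, y_idx, params, run_mean, run_var) -> float:
        proba = self._forward(X, params, run_mean, run_var)
        return float(np.mean(proba.argmax(axis=1) == y_idx))

    def _check_input(self, X) -> np.ndarray:
        check_is_fitted(self, "_params")
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        return X

    def predict_proba(self, X) -> np.ndarray:
        X = self._check_input(X)
        return self._forward(X, self._params, self._run_mean, self._run_var)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def transform(self, X) -> np.ndarray:
        """Latent representation: hidden-layer activations after the
        dropout/batch-norm stage, inference mode (width = hidden_units)."""
        X = self._check_input(X)
        return self._hidden(X, self._params, self._run_mean, self._run_var)
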