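"""Scikit-learn-style classifier for force-level motor-imagery trials.

``MSTCNAMClassifier`` consumes z-normalized epoched trials shaped
(n_trials, n_electrodes, n_timepoints) and learns the three-stage
convolution + channel-attention network.  It follows the sklearn
estimator contract (``get_params``/``set_params``, ``fit`` returning
``self``, fitted attributes with trailing underscores), so it composes
with ``sklearn.model_selection`` utilities.
"""

from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .nn.network import ModelConfig, MSTCNAMNetwork, cross_entropy, softmax
from .nn.optim import make_optimizer


class MSTCNAMClassifier(ClassifierMixin, BaseEstimator):
    """Multi-scale temporal CNN with channel attention for MI trials.

    Parameters mirror the architecture table (branch kernel widths and
    filter counts, spatial filters, pooling width, dropout, attention
    reduction ratio) and the training protocol (epochs, batch size,
    learning rate, Adam by default).  One iteration is one full pass
    over the training set.

    Examples
    --------
    >>> clf = MSTCNAMClassifier(n_epochs=50, random_state=0)
    >>> clf.fit(X_train, y_train)           # doctest: +SKIP
    >>> clf.score(X_test, y_test)           # doctest: +SKIP
    """

    def __init__(self, branch_kernel_widths=(3, 5, 7), branch_filters=8,
                 spatial_filters=48, pool_width=64, dropout_p=0.5,
                 attention_reduction=8, n_epochs=500, batch_size=16,
                 lr=0.001, optimizer="adam", iteration_unit="epoch",
                 random_state=None, validate_input=True):
        self.branch_kernel_widths = branch_kernel_widths
        self.branch_filters = branch_filters
        self.spatial_filters = spatial_filters
        self.pool_width = pool_width
        self.dropout_p = dropout_p
        self.attention_reduction = attention_reduction
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.lr = lr
        self.optimizer = optimizer
        self.iteration_unit = iteration_unit
        self.random_state = random_state
        self.validate_input = validate_input

    # -- internals ---------------------------------------------------------

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 3:
            raise ValueError(
                "X must be (n_trials, n_electrodes, n_timepoints)")
        if self.validate_input and not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X

    def _model_config(self, n_electrodes, n_timepoints, n_classes):
        return ModelConfig(
            n_electrodes=n_electrodes,
            n_timepoints=n_timepoints,
            branch_kernel_widths=tuple(self.branch_kernel_widths),
            branch_filters=self.branch_filters,
            spatial_filters=self.spatial_filters,
            pool_width=self.pool_width,
            dropout_p=self.dropout_p,
            attention_reduction=self.attention_reduction,
            n_classes=n_classes,
        )

    # -- sklearn API ---------------------------------------------------------

    def fit(self, X, y, eval_set=None):
        """Train on trials X with integer class labels y.

        ``eval_set=(X_val, y_val)`` additionally records held-out
        accuracy after every epoch in ``accuracy_curve_``.
        """
        X = self._check_X(X)
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")

        n, N, M = X.shape
        self.config_ = self._model_config(N, M, len(self.classes_))
        rng = np.random.default_rng(self.random_state)
        self.network_ = MSTCNAMNetwork(self.config_, rng)
        opt = make_optimizer(self.optimizer, self.network_.parameters(), self.lr)

        if self.iteration_unit not in ("epoch", "batch"):
            raise ValueError("iteration_unit must be 'epoch' or 'batch'")
        self.loss_curve_ = []
        self.accuracy_curve_ = [] if eval_set is not None else None
        steps = 0
        epoch = 0
        # one iteration = one full pass (epoch) by default; with
        # iteration_unit='batch', n_epochs counts mini-batch updates
        while (steps if self.iteration_unit == "batch" else epoch) < self.n_epochs:
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                if self.iteration_unit == "batch" and steps >= self.n_epochs:
                    break
                idx = order[start:start + self.batch_size]
                loss = self.network_.train_step(X[idx], y_enc[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}; lower the "
                        "learning rate or check input scaling")
                opt.step()
                steps += 1
                losses.append(loss)
            epoch += 1
            self.loss_curve_.append(float(np.mean(losses)))
            if eval_set is not None:
                Xv, yv = eval_set
                self.accuracy_curve_.append(float(self.score(Xv, yv)))
        self.n_features_in_ = N * M
        return self

    def predict_proba(self, X):
        """Class probabilities, rows summing to 1."""
        self._require_fitted()
        X = self._check_X(X)
        return self.network_.predict_proba(X, train=False,
                                           validate=self.validate_input)

    def predict(self, X):
        probs = self.predict_proba(X)
        # np.argmax breaks ties toward the lowest class index
        return self.classes_[np.argmax(probs, axis=1)]

    def loss(self, X, y) -> float:
        """Mean cross-entropy of the fitted model on (X, y)."""
        self._require_fitted()
        y_enc = np.searchsorted(self.classes_, np.asarray(y))
        return cross_entropy(self.predict_proba(X), y_enc)

    def _require_fitted(self):
        if not hasattr(self, "network_"):
            raise RuntimeError("classifier is not fitted; call fit first")

    # -- checkpointing -------------------------------------------------------

    def save(self, path, fingerprint: dict | None = None) -> None:
        """Save weights + configuration (and an optional provenance dict)."""
        self._require_fitted()
        meta = {
            "params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.get_params().items()},
            "classes": self.classes_.tolist(),
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(self.config_).items()},
            "fingerprint": fingerprint or {},
        }
        weights = {f"w{i}": w for i, w in
                   enumerate(self.network_.get_weights())}
        bn_state = []
        for layer in self._bn_layers():
            bn_state.append(layer.running_mean)
            bn_state.append(layer.running_var)
        np.savez(path, meta=json.dumps(meta),
                 bn=np.concatenate([b.ravel() for b in bn_state])
                 if bn_state else np.empty(0), **weights)

    def _bn_layers(self):
        from .nn.layers import BatchNorm
        seen = []
        for layer, _ in self.network_.parameters():
            if isinstance(layer, BatchNorm) and layer not in seen:
                seen.append(layer)
        return seen

    @classmethod
    def load(cls, path) -> "MSTCNAMClassifier":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["meta"]))
            weights = [f[f"w{i}"] for i in range(len([k for k in f.files
                                                      if k.startswith("w")]))]
            bn_flat = f["bn"]
        params = {k: (tuple(v) if isinstance(v, list) else v)
                  for k, v in meta["params"].items()}
        clf = cls(**params)
        cfgd = meta["config"]
        cfgd["branch_kernel_widths"] = tuple(cfgd["branch_kernel_widths"])
        clf.config_ = ModelConfig(**cfgd)
        clf.classes_ = np.asarray(meta["classes"])
        clf.network_ = MSTCNAMNetwork(clf.config_,
                                      np.random.default_rng(0))
        clf.network_.set_weights(weights)
        pos = 0
        for layer in clf._bn_layers():
            n = layer.running_mean.size
            layer.running_mean = bn_flat[pos:pos + n].copy(); pos += n
            layer.running_var = bn_flat[pos:pos + n].copy(); pos += n
        clf.fingerprint_ = meta["fingerprint"]
        clf.n_features_in_ = clf.config_.n_electrodes * clf.config_.n_timepoints
        return clf
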