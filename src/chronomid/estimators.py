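"""Scikit-learn style estimator facade over the network variants.

``ChronoMIDClassifier`` follows the sklearn estimator contract
(``get_params``/``set_params``, ``fit``/``predict``/``predict_proba``,
fitted attributes with trailing underscores), so it composes with sklearn
model selection utilities. ``X`` is a stack of 2-D images ``(n, H, W)``;
cross-modal variants additionally take ``diffs`` (the difference maps) and
timestamped variants ``weeks``, passed as fit/predict keyword arguments
since they are per-sample side channels rather than features in the tabular
sense.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .models import ArchitectureSpec, HyperParams, build_model
from .train_eval import TRAIN, VAL, Arrays, TrainConfig, train


class ChronoMIDClassifier(ClassifierMixin, BaseEstimator):
    """Longitudinal image-stack classifier over temporal difference maps.

    Parameters
    ----------
    variant : str
        One of ``cnn``, ``cnn_ts``, ``xcnn_abs``, ``xcnn_rel``,
        ``xcnn_abs_ts``, ``xcnn_rel_ts``.
    epochs, batch_size, learning_rate, l2_lambda, dropout_rate :
        Training hyperparameters (defaults follow the study protocol:
        batch 32, L2 lambda 3e-4, dropout 0.25).
    cross_after_regularisation : bool
        Whether cross-connections tap the streams after BN/dropout.
    validation_fraction : float
        Fraction of the training data tracked as per-epoch validation.
        0 disables validation tracking.
    random_state : int
        Seed for initialisation, shuffling and dropout.
    """

    def __init__(
        self,
        variant: str = "xcnn_abs",
        epochs: int = 5,
        batch_size: int = 32,
        learning_rate: float = 3e-3,
        l2_lambda: float = 0.0003,
        dropout_rate: float = 0.25,
        cross_after_regularisation: bool = True,
        validation_fraction: float = 0.0,
        random_state: int = 0,
    ):
        self.variant = variant
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.l2_lambda = l2_lambda
        self.dropout_rate = dropout_rate
        self.cross_after_regularisation = cross_after_regularisation
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- sklearn plumbing

    def _check_X(self, X):
        X = np.asarray(X)
        if X.ndim != 3:
            raise ValueError(f"X must be (n_samples, height, width); got shape {X.shape}")
        return X

    def _arrays(self, X, y, diffs, weeks):
        n = len(X)
        if diffs is not None:
            diffs = np.asarray(diffs)
            if diffs.shape != X.shape:
                raise ValueError("diffs must have the same shape as X")
        weeks_arr = np.zeros(n, dtype=np.int64) if weeks is None else np.asarray(weeks)
        return Arrays(images=X, diffs=diffs, weeks=weeks_arr, y=y)

    # -- estimator API

    def fit(self, X, y, diffs=None, weeks=None):
        X = self._check_X(X)
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y have inconsistent lengths")
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")

        spec = ArchitectureSpec(
            variant=self.variant,
            input_height=X.shape[1],
            input_width=X.shape[2],
            n_classes=len(self.classes_),
            hyper=HyperParams(
                batch_size=self.batch_size,
                l2_lambda=self.l2_lambda,
                dropout_rate=self.dropout_rate,
                learning_rate=self.learning_rate,
            ),
            cross_after_regularisation=self.cross_after_regularisation,
        )
        if spec.has_diff_stream and diffs is None:
            raise ValueError(f"variant {self.variant!r} requires diffs=")
        if spec.use_timestamp and weeks is None:
            raise ValueError(f"variant {self.variant!r} requires weeks=")

        arrays = self._arrays(X, y_enc, diffs, weeks)
        data = {TRAIN: arrays}
        if self.validation_fraction > 0:
            rng = np.random.default_rng(self.random_state)
            order = rng.permutation(len(arrays))
            n_val = int(round(self.validation_fraction * len(arrays)))
            data = {TRAIN: arrays.subset(order[n_val:]), VAL: arrays.subset(order[:n_val])}

        config = TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            seed=self.random_state,
            learning_rate=self.learning_rate,
            l2_lambda=self.l2_lambda,
        )
        self.model_ = build_model(spec, seed=self.random_state)
        self.history_ = train(self.model_, data, config)
        self.n_parameters_ = int(sum(p.size for p in self.model_.params()))
        return self

    def predict_proba(self, X, diffs=None, weeks=None):
        check_is_fitted(self, "model_")
        X = self._check_X(X)
        weeks_arr = np.zeros(len(X), dtype=np.int64) if weeks is None else np.asarray(weeks)
        if self.model_.spec.has_diff_stream and diffs is None:
            raise ValueError(f"variant {self.variant!r} requires diffs=")
        return self.model_.predict_proba(
            X, diffs, weeks_arr if self.model_.spec.use_timestamp else None
        )

    def predict(self, X, diffs=None, weeks=None):
        probs = self.predict_proba(X, diffs=diffs, weeks=weeks)
        return self.classes_[probs.argmax(axis=1)]

    def score(self, X, y, diffs=None, weeks=None):
        return float(np.mean(self.predict(X, diffs=diffs, weeks=weeks) == np.asarray(y)))
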