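"""Scikit-learn style estimator wrapping the segmentation network.

`DEFIFNetSegmenter` is a per-pixel binary classifier over RGB images: ``fit``
takes images shaped (n, H, W, 3) and binary masks (n, H, W), ``predict``
returns binary masks, ``predict_proba`` foreground probabilities and
``score`` the mean Dice similarity coefficient.  It follows the estimator
contract (``get_params``/``set_params``, fitted attributes with a trailing
underscore, ``clone``-compatible constructor) so it composes with
scikit-learn model selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .data import binarize_prediction
from .network import (DEFAULT_BOTTLENECK, DEFAULT_CHANNELS, DEFIFNet,
                      ModelConfig)
from .objective import LossWeights
from .train import TrainSettings, predict_proba, train_network


class DEFIFNetSegmenter(BaseEstimator):
    """Lightweight dual-encoder segmentation network as an estimator.

    Parameters
    ----------
    channels : per-level encoder widths (default: the calibrated schedule)
    bottleneck_width : bottleneck width
    alpha, beta : Dice / BCE weights of the combined loss (default 0.7 / 0.3)
    lr : initial Adam learning rate (default 1e-4)
    lr_decay : plateau decay factor (default 0.5)
    patience : epochs of loss plateau before decaying the learning rate
    epochs, batch_size : optimization schedule (defaults 200 / 8)
    val_fraction : fraction of the training set held out to monitor DSC
    threshold : probability threshold for `predict`
    seed : controls weight init, shuffling and the validation split
    verbose : per-epoch progress lines

    Attributes
    ----------
    net_ : the fitted network
    history_ : list of per-epoch records (losses, monitored DSC, lr)
    best_epoch_, best_dsc_ : model-selection outcome
    """

    def __init__(self, channels=DEFAULT_CHANNELS,
                 bottleneck_width=DEFAULT_BOTTLENECK, alpha=0.7, beta=0.3,
                 lr=1e-4, lr_decay=0.5, patience=10, epochs=200, batch_size=8,
                 val_fraction=0.0, threshold=0.5, seed=0, verbose=False):
        self.channels = channels
        self.bottleneck_width = bottleneck_width
        self.alpha = alpha
        self.beta = beta
        self.lr = lr
        self.lr_decay = lr_decay
        self.patience = patience
        self.epochs = epochs
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.threshold = threshold
        self.seed = seed
        self.verbose = verbose

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError(f"X must be (n, H, W, 3), got {X.shape}")
        if y.shape != X.shape[:3]:
            raise ValueError(f"y must be (n, H, W) aligned with X, got {y.shape}")
        cfg = ModelConfig(channels=tuple(self.channels),
                          bottleneck_width=self.bottleneck_width,
                          input_size=X.shape[1:3], seed=self.seed)
        self.net_ = DEFIFNet(cfg)
        if self.val_fraction > 0.0 and len(X) >= 4:
            rng = np.random.default_rng(self.seed)
            order = rng.permutation(len(X))
            n_val = max(1, int(round(self.val_fraction * len(X))))
            vi, ti = order[:n_val], order[n_val:]
            Xt, yt, Xv, yv = X[ti], y[ti], X[vi], y[vi]
        else:
            Xt, yt, Xv, yv = X, y, None, None
        settings = TrainSettings(
            epochs=self.epochs, batch_size=self.batch_size, lr=self.lr,
            lr_decay=self.lr_decay, patience=self.patience,
            weights=LossWeights(self.alpha, self.beta), seed=self.seed,
            verbose=self.verbose)
        result = train_network(self.net_, Xt, yt, Xv, yv, settings)
        self.history_ = result["history"]
        self.best_epoch_ = result["best_epoch"]
        self.best_dsc_ = result["best_dsc"]
        return self

    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    def predict_proba(self, X) -> np.ndarray:
        """(n, H, W) foreground probabilities in [0, 1]."""
        self._check_fitted()
        return predict_proba(self.net_, np.asarray(X), self.batch_size)

    def predict(self, X) -> np.ndarray:
        """(n, H, W) binary masks, thresholded at `threshold`."""
        return binarize_prediction(self.predict_proba(X), self.threshold)

    def score(self, X, y) -> float:
        """Mean Dice similarity coefficient against reference masks."""
        from .metrics import segmentation_metrics

        rep = segmentation_metrics(self.predict(X), np.asarray(y),
                                   with_hausdorff=False)
        return rep.mean["dsc"]
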