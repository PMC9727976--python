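"""scikit-learn style estimator around the segmentation network.

``RSAPNetSegmenter.fit`` consumes a stack of RGB images (N, S, S, 3) with
integer label masks (N, S, S) over {0 background, 1 disc, 2 cup} and trains
the network with SGD (momentum, weight decay) on the pixel-mean cross
entropy; ``predict`` returns argmax label masks.  All sources of randomness
(weight init, batch shuffling) derive from ``seed``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import nn
from .arch import ModelConfig, RSAPNet, cross_entropy_loss
from .metrics import confusion_counts, f1_score

__all__ = ["RSAPNetSegmenter"]


class RSAPNetSegmenter(BaseEstimator):
    """Joint disc/cup segmenter with a fit/predict interface.

    Architecture parameters mirror :class:`fundusseg.arch.ModelConfig`;
    optimisation defaults follow the standard recipe for this task
    (SGD, lr 0.001, momentum 0.9, weight decay 0.0005).

    Attributes set by ``fit``: ``net_`` (the trained network), ``config_``,
    ``loss_history_`` (mean loss per epoch) and ``n_iter_`` (gradient steps).
    """

    def __init__(self, input_size=512, base_channels=32,
                 encoder_stage_channels=None, mdc_dilations=(1, 2, 5),
                 gic_pool_sizes=(5, 6), gic_conv_specs=((2, 2), (3, 3)),
                 rsap_depths=(3, 2, 1), leaky_slope=0.01, lr=0.001,
                 momentum=0.9, weight_decay=0.0005, epochs=10, batch_size=4,
                 seed=0, verbose=0):
        self.input_size = input_size
        self.base_channels = base_channels
        self.encoder_stage_channels = encoder_stage_channels
        self.mdc_dilations = mdc_dilations
        self.gic_pool_sizes = gic_pool_sizes
        self.gic_conv_specs = gic_conv_specs
        self.rsap_depths = rsap_depths
        self.leaky_slope = leaky_slope
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.verbose = verbose

    # ------------------------------------------------------------------
    def _make_config(self) -> ModelConfig:
        return ModelConfig(
            input_size=self.input_size, base_channels=self.base_channels,
            encoder_stage_channels=self.encoder_stage_channels,
            mdc_dilations=tuple(self.mdc_dilations),
            gic_pool_sizes=tuple(self.gic_pool_sizes),
            gic_conv_specs=tuple(tuple(p) for p in self.gic_conv_specs),
            rsap_depths=tuple(self.rsap_depths),
            leaky_slope=self.leaky_slope, seed=self.seed)

    def _prepare_images(self, X) -> np.ndarray:
        arr = np.stack([np.asarray(im) for im in X]) if isinstance(X, (list, tuple)) else np.asarray(X)
        if arr.ndim == 3:
            arr = arr[None]
        if arr.ndim != 4 or arr.shape[-1] != 3:
            raise ValueError("expected images shaped (N, S, S, 3)")
        s = self.input_size
        if arr.shape[1] != s or arr.shape[2] != s:
            raise ValueError(f"images are {arr.shape[1]}x{arr.shape[2]} but "
                             f"input_size={s}; resize or re-warp first")
        # map 8-bit intensities to [-1, 1]
        x = (arr.astype(np.float32) / 255.0 - 0.5) * 2.0
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2))

    # ------------------------------------------------------------------
    def fit(self, X, y):
        x = self._prepare_images(X)
        targets = np.stack([np.asarray(m) for m in y]).astype(np.int64)
        if targets.shape != x.shape[:1] + x.shape[2:]:
            raise ValueError("mask stack shape does not match image stack")
        if targets.min() < 0 or targets.max() > 2:
            raise ValueError("mask labels must be in {0, 1, 2}")

        self.config_ = self._make_config()
        self.net_ = RSAPNet(self.config_)
        opt = nn.SGD(self.net_.parameters(), lr=self.lr,
                     momentum=self.momentum, weight_decay=self.weight_decay)
        rng = np.random.default_rng(self.seed)
        n = x.shape[0]
        self.loss_history_ = []
        self.n_iter_ = 0
        self.net_.train()
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                logits = self.net_(nn.Tensor(x[idx]))
                loss = cross_entropy_loss(logits, targets[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
                self.n_iter_ += 1
            self.loss_history_.append(float(np.mean(losses)))
            if self.verbose:
                print(f"epoch {epoch + 1}/{self.epochs} "
                      f"loss {self.loss_history_[-1]:.4f}")
        return self

    # ------------------------------------------------------------------
    def _forward_batches(self, X):
        check_is_fitted(self, "net_")
        x = self._prepare_images(X)
        self.net_.eval()
        chunks = []
        for start in range(0, x.shape[0], self.batch_size):
            logits = self.net_(nn.Tensor(x[start:start + self.batch_size]))
            chunks.append(logits.data)
        return np.concatenate(chunks, axis=0)

    def predict(self, X) -> np.ndarray:
        """Label masks (N, S, S) over {0, 1, 2}."""
        return self._forward_batches(X).argmax(axis=1).astype(np.uint8)

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel class probabilities, shaped (N, S, S, 3)."""
        logits = self._forward_batches(X)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return (e / e.sum(axis=1, keepdims=True)).transpose(0, 2, 3, 1)

    def score(self, X, y) -> float:
        """Mean of the disc and cup F1 scores over the given set."""
        preds = self.predict(X)
        scores = []
        for pred, gt in zip(preds, y):
            for structure in ("OD", "OC"):
                scores.append(f1_score(confusion_counts(pred, gt, structure)))
        return float(np.mean(scores))
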