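"""Scikit-learn style estimators wrapping the toolkit.

:class:`PCNNDenoiser` is a stateless transformer (PCNN impulse filtering
per image); :class:`SEResUNetSegmenter` is a fit/predict segmentation
estimator.  Both follow sklearn conventions (``get_params``/``set_params``
via ``__init__`` signature, fitted attributes with a trailing underscore)
and compose with sklearn pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import pcnn as _pcnn
from . import trainer as _trainer
from .errors import InputError
from .se_resunet import ModelConfig, build_model

__all__ = ["PCNNDenoiser", "SEResUNetSegmenter"]


class PCNNDenoiser(TransformerMixin, BaseEstimator):
    """Impulse-noise filter; ``transform`` denoises a stack of grayscale images.

    Parameters mirror :class:`hepaseg.pcnn.PCNNParams`; ``fit`` is a no-op
    (the filter has no trainable state) and exists for pipeline
    compatibility.
    """

    def __init__(self, beta: float = 0.5, v_e: float = 2.0, alpha_e: float = 0.3,
                 n_iter: int = 30, window: int = 1, feedback: str = "full"):
        self.beta = beta
        self.v_e = v_e
        self.alpha_e = alpha_e
        self.n_iter = n_iter
        self.window = window
        self.feedback = feedback

    def _params(self) -> _pcnn.PCNNParams:
        return _pcnn.PCNNParams(beta=self.beta, v_e=self.v_e, alpha_e=self.alpha_e,
                                n_iter=self.n_iter, feedback=self.feedback)

    def fit(self, X, y=None):
        self._params().validate()
        self.n_features_in_ = None
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X)
        params = self._params()
        if X.ndim == 2:
            return _pcnn.denoise(X, params, window=self.window)
        if X.ndim == 3:
            return np.stack([_pcnn.denoise(img, params, window=self.window) for img in X])
        raise InputError(f"expected (H, W) or (N, H, W) images, got shape {X.shape}")


class SEResUNetSegmenter(BaseEstimator):
    """SE-ResUnet pixel classifier with a sklearn fit/predict surface.

    ``X`` is a float array (N, C, H, W) with values in [0, 1] (H, W
    divisible by ``2**depth``); ``y`` binary masks (N, H, W).

    Fitted attributes: ``model_`` (the network), ``history_`` (per-epoch
    loss/metric rows).
    """

    def __init__(self, base_width: int = 32, depth: int = 4, se_ratio: int = 8,
                 block: str = "basic", skip_fusion: str = "concat",
                 in_channels: int = 3, epochs: int = 100, lr: float = 1e-4,
                 weight_decay: float = 1e-4, accumulation_steps: int = 5,
                 batch_size: int = 4, loss: str = "dice", threshold: float = 0.5,
                 val_fraction: float = 0.2, seed: int = 0):
        self.base_width = base_width
        self.depth = depth
        self.se_ratio = se_ratio
        self.block = block
        self.skip_fusion = skip_fusion
        self.in_channels = in_channels
        self.epochs = epochs
        self.lr = lr
        self.weight_decay = weight_decay
        self.accumulation_steps = accumulation_steps
        self.batch_size = batch_size
        self.loss = loss
        self.threshold = threshold
        self.val_fraction = val_fraction
        self.seed = seed

    def _model_config(self) -> ModelConfig:
        return ModelConfig(in_channels=self.in_channels, depth=self.depth,
                           base_width=self.base_width, se_ratio=self.se_ratio,
                           block=self.block, skip_fusion=self.skip_fusion)

    def _train_config(self) -> _trainer.TrainConfig:
        return _trainer.TrainConfig(epochs=self.epochs, lr=self.lr,
                                    weight_decay=self.weight_decay,
                                    accumulation_steps=self.accumulation_steps,
                                    batch_size=self.batch_size, seed=self.seed,
                                    loss=self.loss)

    def fit(self, X, y, checkpoint_dir: str | None = None):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        model = build_model(self._model_config(), seed=self.seed)
        if X.shape[0] >= 2 and self.val_fraction > 0:
            train_set, val_set = _trainer.split_dataset(X, y, self.val_fraction, self.seed)
        else:
            train_set = val_set = (X, y)
        self.model_, self.history_ = _trainer.train(
            model, train_set, val_set, self._train_config(), checkpoint_dir=checkpoint_dir
        )
        return self

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        return self.model_.predict_proba(np.asarray(X, dtype=np.float32))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= self.threshold).astype(np.uint8)

    def score(self, X, y) -> float:
        """Mean per-image Dice of thresholded predictions."""
        report = _trainer.evaluate(self.model_, (np.asarray(X, dtype=np.float32),
                                                 np.asarray(y)), self.threshold)
        return report.dice

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise InputError("estimator is not fitted; call fit(X, y) first")
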