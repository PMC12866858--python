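"""Estimator facade over the fusion pipeline.

:class:`LCRNFuser` packages validation, network construction, and the fitting
loop behind the familiar fit/predict estimator surface, so a fusion run is

    fuser = LCRNFuser(magnification=8, seed=0)
    fused = fuser.fit_predict(microscopy, ion)

All hyperparameters are plain constructor arguments, which also makes the
estimator usable with model-selection utilities (``get_params``,
``set_params``, cloning).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .io_formats import IonImage, MicroscopyImage
from .losses import EdgeKernel, LossWeights
from .network import NetworkSpec, build_cnn_baseline, build_network, config_hash
from .preprocess import validate_registration
from .trainer import TrainConfig, train

__all__ = ["LCRNFuser"]


class LCRNFuser(BaseEstimator):
    """Fit the loss-controlled residual network to one registered image pair.

    Parameters
    ----------
    magnification : int
        Integer ratio of the microscopy grid over the native ion grid.
    w_mse, w_edge : float
        Multipliers of the MSE and edge perceptual losses.
    kernel : str
        Name of the designated 3x3 edge kernel ("laplacian4", "laplacian8",
        "sobel_x", "sobel_y").
    lr, max_epochs, patience : training hyperparameters (Adam learning rate,
        epoch cap, cumulative count of edge-loss increases that halts).
    architecture : "lcrn" for the residual network, "cnn" for the plain
        3-layer baseline.
    seed : int
        Seeds the parameter initialization.

    Attributes (after ``fit``)
    --------------------------
    fused_image_ : FusedImage — best-epoch output (raw, unclipped values).
    trace_ : LossTrace — per-epoch losses and stopping record.
    model_ : the fitted network; pair_ : the validated RegisteredPair;
    n_epochs_ : epochs actually run; best_epoch_ : epoch of minimal edge loss.
    """

    def __init__(self, magnification: int = 8, w_mse: float = 1.0,
                 w_edge: float = 1.0, kernel: str = "laplacian4",
                 lr: float = 3e-4, max_epochs: int = 2000, patience: int = 5,
                 architecture: str = "lcrn", seed: int = 0,
                 checkpoint_every: int = 1):
        self.magnification = magnification
        self.w_mse = w_mse
        self.w_edge = w_edge
        self.kernel = kernel
        self.lr = lr
        self.max_epochs = max_epochs
        self.patience = patience
        self.architecture = architecture
        self.seed = seed
        self.checkpoint_every = checkpoint_every

    # -- internal -----------------------------------------------------------

    def _coerce(self, microscopy, ion):
        if not isinstance(microscopy, MicroscopyImage):
            microscopy = MicroscopyImage(values=np.asarray(microscopy))
        if not isinstance(ion, IonImage):
            ion = IonImage(values=np.asarray(ion))
        return microscopy, ion

    def _build_model(self):
        if self.architecture == "lcrn":
            return build_network(NetworkSpec(), seed=self.seed)
        if self.architecture == "cnn":
            return build_cnn_baseline(seed=self.seed)
        raise ValueError(f"unknown architecture {self.architecture!r}")

    # -- estimator API ------------------------------------------------------

    def fit(self, microscopy, ion, checkpoint_dir=None):
        """Fit to one pair: microscopy (H x W x 3) and native ion grid (h x w)."""
        microscopy, ion = self._coerce(microscopy, ion)
        self.config_hash_ = config_hash({**self.get_params(), "op": "fuse"})
        self.pair_ = validate_registration(microscopy, ion, self.magnification)
        self.model_ = self._build_model()
        cfg = TrainConfig(
            lr=self.lr, max_epochs=self.max_epochs, stop_patience=self.patience,
            weights=LossWeights(self.w_mse, self.w_edge), seed=self.seed,
            checkpoint_every=self.checkpoint_every,
        )
        self.fused_image_, self.trace_ = train(
            self.model_, self.pair_, EdgeKernel.from_name(self.kernel), cfg,
            checkpoint_dir=checkpoint_dir, config_hash=self.config_hash_,
        )
        self.n_epochs_ = self.trace_.stopped_at
        self.best_epoch_ = self.trace_.best_epoch
        return self

    def predict(self, microscopy=None):
        """Return the fused image clipped to [0, 1].

        With a new (registration-compatible) microscopy image the fitted model
        is re-applied to it; by default the best-epoch fusion is returned.
        """
        if not hasattr(self, "fused_image_"):
            raise RuntimeError("this LCRNFuser instance is not fitted yet")
        if microscopy is None:
            return self.fused_image_.clipped()
        microscopy, _ = self._coerce(microscopy, self.pair_.ion_interp)
        x = np.ascontiguousarray(microscopy.values.transpose(2, 0, 1))
        return np.clip(self.model_.forward(x), 0.0, 1.0)

    def transform(self, microscopy=None):
        return self.predict(microscopy)

    def fit_predict(self, microscopy, ion, **fit_kwargs):
        return self.fit(microscopy, ion, **fit_kwargs).predict()
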