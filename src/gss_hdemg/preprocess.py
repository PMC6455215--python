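"""Band-pass filtering, montage derivation, observation extension, whitening.

The decomposition operates on an *extended* observation matrix: each channel
is stacked together with ``R - 1`` delayed repetitions of itself, which turns
the convolutive MUAP mixture into an (approximately) instantaneous one.
Whitening ("convolutive sphering") then decorrelates the extended rows:
``X = W Z`` with ``W = U D^{-1/2} U^T`` from the eigendecomposition
``E{Z Z^T} = U D U^T``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator

from .simulate import EMGRecording

__all__ = [
    "WhiteningModel",
    "ExtendedObservation",
    "bandpass",
    "make_single_differential",
    "extend",
    "whiten",
    "ConvolutiveSphering",
]


@dataclass
class WhiteningModel:
    """Eigen-whitening transform ``W = U D^{-1/2} U^T`` with regularization."""

    W: np.ndarray
    U: np.ndarray
    D: np.ndarray  # regularized eigenvalues (vector)
    mean_vector: np.ndarray
    regularization: float


@dataclass
class ExtendedObservation:
    """Delayed-repetition (and optionally whitened) observation matrix.

    Row ``c * R + d`` of ``X`` is channel ``c`` delayed by ``d`` samples.
    After whitening the sample correlation of the rows is the identity, so
    ``Rxx_inv`` is the identity and the CKC estimator reduces to ``r^T X``.
    """

    X: np.ndarray
    R: int
    fs_hz: float
    n_channels: int
    source_montage: str = "single_differential"
    whitening: WhiteningModel | None = None
    _rxx_inv: np.ndarray | None = field(default=None, repr=False)

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def M(self) -> int:
        return self.X.shape[1]

    @property
    def Rxx_inv(self) -> np.ndarray:
        """Inverse sample correlation matrix (identity once whitened)."""
        if self.whitening is not None:
            return np.eye(self.N)
        if self._rxx_inv is None:
            rxx = (self.X @ self.X.T) / self.M
            eps = 1e-8 * float(np.trace(rxx)) / self.N
            self._rxx_inv = np.linalg.inv(rxx + eps * np.eye(self.N))
        return self._rxx_inv


def bandpass(rec: EMGRecording, low: float = 20.0, high: float = 500.0) -> EMGRecording:
    """Zero-phase first-order Butterworth band-pass, applied per channel."""
    if rec.fs_hz <= 2 * high:
        raise ValueError("sampling rate must exceed twice the upper cut-off")
    sos = sps.butter(1, (low, high), btype="bandpass", fs=rec.fs_hz, output="sos")
    return rec.copy_with(data=sps.sosfiltfilt(sos, rec.data, axis=1))


def make_single_differential(rec: EMGRecording) -> EMGRecording:
    """Differences of adjacent electrodes along the fiber (row) direction.

    ``out[r, c] = in[r + 1, c] - in[r, c]`` for every column, turning a
    rows × cols monopolar grid into (rows − 1) × cols channels and removing
    common-mode components.
    """
    if rec.montage != "monopolar":
        raise ValueError("input must be monopolar")
    g = rec.grid
    mono = rec.data.reshape(g.rows, g.cols, -1)
    sd = (mono[1:, :, :] - mono[:-1, :, :]).reshape((g.rows - 1) * g.cols, -1)
    return EMGRecording(data=sd, fs_hz=rec.fs_hz, grid=g, montage="single_differential")


def extend(rec: EMGRecording, R: int = 30) -> ExtendedObservation:
    """Stack each channel with ``R - 1`` delayed repetitions of itself.

    Delays are zero-padded at the start (half-open sample indexing); the
    per-row mean is removed after extension.
    """
    if R < 1:
        raise ValueError("extension factor R must be >= 1")
    data = np.asarray(rec.data)
    c, m = data.shape
    X = np.zeros((c * R, m), dtype=data.dtype)
    Xv = X.reshape(c, R, m)
    for d in range(R):
        Xv[:, d, d:] = data[:, : m - d]
    X -= X.mean(axis=1, keepdims=True)
    return ExtendedObservation(
        X=X, R=R, fs_hz=rec.fs_hz, n_channels=c, source_montage=rec.montage
    )


def whiten(obs: ExtendedObservation, reg: float = 1e-8) -> ExtendedObservation:
    """Eigen-whitening of the extended observation.

    Eigenvalues below ``reg × max eigenvalue`` are clamped to that floor
    before inversion, which regularizes rank-deficient covariances.
    """
    Z = obs.X
    mean = Z.mean(axis=1)
    Z = Z - mean[:, None]
    cov = (Z @ Z.T).astype(np.float64) / Z.shape[1]
    d, u = np.linalg.eigh(cov)
    floor = reg * float(d.max())
    d = np.maximum(d, floor)
    W = (u * (1.0 / np.sqrt(d))) @ u.T
    Xw = W.astype(Z.dtype, copy=False) @ Z  # keep the observation dtype
    model = WhiteningModel(W=W, U=u, D=d, mean_vector=mean, regularization=floor)
    return ExtendedObservation(
        X=Xw,
        R=obs.R,
        fs_hz=obs.fs_hz,
        n_channels=obs.n_channels,
        source_montage=obs.source_montage,
        whitening=model,
    )


class ConvolutiveSphering(BaseEstimator):
    """Extension + whitening as a scikit-learn style transformer.

    Parameters
    ----------
    R : int
        Number of delayed repetitions per channel (extension factor).
    reg : float
        Relative eigenvalue floor used when inverting the covariance.

    Attributes
    ----------
    whitening_model_ : WhiteningModel
        The fitted whitening transform.
    """

    def __init__(self, R: int = 30, reg: float = 1e-8):
        self.R = R
        self.reg = reg

    def fit(self, rec: EMGRecording, y=None) -> "ConvolutiveSphering":
        obs = extend(rec, self.R)
        white = whiten(obs, self.reg)
        self.whitening_model_ = white.whitening
        self._fitted_obs = white
        return self

    def transform(self, rec: EMGRecording) -> ExtendedObservation:
        obs = extend(rec, self.R)
        w = self.whitening_model_
        Z = obs.X - obs.X.mean(axis=1, keepdims=True)
        return ExtendedObservation(
            X=w.W.astype(Z.dtype, copy=False) @ Z,
            R=self.R,
            fs_hz=rec.fs_hz,
            n_channels=obs.n_channels,
            source_montage=rec.montage,
            whitening=w,
        )

    def fit_transform(self, rec: EMGRecording, y=None) -> ExtendedObservation:
        self.fit(rec)
        return self._fitted_obs
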