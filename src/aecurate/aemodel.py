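"""The 90-8-90 fully connected autoencoder and its MSLE anomaly score.

The model is deliberately minimal: one tanh bottleneck of 8 units between a
90-dimensional input and a linear 90-dimensional output.  It is trained only
on neural spike segments; segments it cannot reconstruct (periodic
artifacts, noise-dominated events) receive a high mean squared logarithmic
error and are classified as non-neural.

The reconstruction score for input x and reconstruction x_hat is

    S(x_hat, x) = (1/N) * sum_i (log(|x_hat[i]| + 1) - log(|x[i]| + 1))^2

with natural logarithms.  The absolute value and the +1 keep the logarithm
defined for signed, zero-crossing waveforms, and the log transform makes the
score robust to amplitude fluctuations between experimental setups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .preprocess import SEGMENT_LEN, FeatureVector

#: default MSLE decision threshold separating spikes from non-neural events
DEFAULT_THRESHOLD = 1.5


class EventDecision(str, Enum):
    SPIKE = "SPIKE"
    NON_NEURAL = "NON_NEURAL"

    __str__ = str.__str__


def msle(x: np.ndarray, xhat: np.ndarray) -> float:
    """Mean squared logarithmic error between two equal-length vectors.

    Symmetric in its arguments and insensitive to the sign of individual
    samples.  Zero iff the sample-wise magnitudes agree exactly.
    """
    x = np.asarray(x, dtype=np.float64)
    xhat = np.asarray(xhat, dtype=np.float64)
    if x.shape != xhat.shape or x.ndim != 1 or x.size < 1:
        raise ValueError(f"need two equal-length 1-d vectors, got {x.shape} and {xhat.shape}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(xhat))):
        raise ValueError("non-finite input to msle")
    d = np.log(np.abs(xhat) + 1.0) - np.log(np.abs(x) + 1.0)
    return float(np.mean(d * d))


def _msle_rows(x: np.ndarray, xhat: np.ndarray) -> np.ndarray:
    d = np.log(np.abs(xhat) + 1.0) - np.log(np.abs(x) + 1.0)
    return np.mean(d * d, axis=-1)


@dataclass
class ModelParams:
    """Weights of the encoder (input->code) and decoder (code->output).

    ``input_scale`` is a fixed conditioning constant (uV): inputs are divided
    by it before the encoder and outputs multiplied by it after the decoder,
    keeping tanh pre-activations and trainable weights of order one for
    microvolt-scale waveforms.  ``target_sigma`` records the noise floor (uV)
    of the training regime so that threshold transfer is self-documenting.
    """

    enc_w: np.ndarray
    enc_b: np.ndarray
    dec_w: np.ndarray
    dec_b: np.ndarray
    input_dim: int = SEGMENT_LEN
    code_dim: int = 8
    init_seed: int = 0
    input_scale: float = 100.0
    target_sigma: float = 10.0
    threshold: float = DEFAULT_THRESHOLD
    trained: bool = False

    def __post_init__(self) -> None:
        if self.enc_w.shape != (self.input_dim, self.code_dim):
            raise ValueError("encoder weight shape mismatch")
        if self.dec_w.shape != (self.code_dim, self.input_dim):
            raise ValueError("decoder weight shape mismatch")
        for p in (self.enc_w, self.enc_b, self.dec_w, self.dec_b):
            if not np.all(np.isfinite(p)):
                raise ValueError("non-finite model parameters")


@dataclass
class TrainReport:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    n_epochs: int = 0
    converged: bool = False
    initial_val_loss: float = float("nan")
    learning_rate: float = 1e-3
    batch_size: int = 32
    optimizer: str = "adam"


@dataclass
class EventScore:
    msle: float
    event_ref: object | None
    reconstruction: np.ndarray


def init_model(input_dim: int = SEGMENT_LEN, code_dim: int = 8, seed: int = 0,
               input_scale: float = 100.0) -> ModelParams:
    """Glorot-uniform initialization, reproducible for a fixed seed."""
    if code_dim >= input_dim:
        raise ValueError(f"code_dim ({code_dim}) must be smaller than input_dim ({input_dim})")
    rng = np.random.default_rng(seed)
    lim = np.sqrt(6.0 / (input_dim + code_dim))
    enc_w = rng.uniform(-lim, lim, (input_dim, code_dim))
    dec_w = rng.uniform(-lim, lim, (code_dim, input_dim))
    return ModelParams(enc_w, np.zeros(code_dim), dec_w, np.zeros(input_dim),
                       input_dim=input_dim, code_dim=code_dim, init_seed=seed,
                       input_scale=input_scale)


def _segments_to_array(segments) -> np.ndarray:
    if isinstance(segments, np.ndarray) and segments.ndim == 2:
        return np.asarray(segments, dtype=np.float64)
    rows = [s.z if isinstance(s, FeatureVector) else np.asarray(s, dtype=np.float64)
            for s in segments]
    return np.asarray(rows, dtype=np.float64)


def reconstruct(model: ModelParams, X: np.ndarray) -> np.ndarray:
    """Forward pass; X is (n, input_dim) or (input_dim,)."""
    X = np.asarray(X, dtype=np.float64)
    h = np.tanh(X / model.input_scale @ model.enc_w + model.enc_b)
    return (h @ model.dec_w + model.dec_b) * model.input_scale


def train(model: ModelParams, train_segments, val_segments, epochs: int = 20,
          learning_rate: float = 1e-3, batch_size: int = 32, seed: int = 0,
          objective: str = "msle") -> tuple[ModelParams, TrainReport]:
    """Train with minibatch Adam on the MSLE objective.

    ``train_segments`` must contain neural spike segments only: the model
    learns the norm for spikes, and everything it subsequently fails to
    reconstruct is scored as anomalous.  An ``objective="mse"`` switch is
    provided for comparison.  Returns the trained parameters and a per-epoch
    loss report; the convergence flag is set when the validation loss moved
    by less than 1% over the last three epochs.
    """
    X = _segments_to_array(train_segments)
    if X.size == 0:
        raise ValueError("empty training set")
    if X.shape[1] != model.input_dim:
        raise ValueError(f"training segments have length {X.shape[1]}, expected {model.input_dim}")
    Xv = _segments_to_array(val_segments) if len(val_segments) else X[:0]
    if objective not in ("msle", "mse"):
        raise ValueError(f"unknown objective {objective!r}")

    m = ModelParams(model.enc_w.copy(), model.enc_b.copy(), model.dec_w.copy(),
                    model.dec_b.copy(), model.input_dim, model.code_dim, model.init_seed,
                    model.input_scale, model.target_sigma, model.threshold)
    report = TrainReport(learning_rate=learning_rate, batch_size=batch_size)

    def val_loss() -> float:
        if Xv.shape[0] == 0:
            return float("nan")
        if objective == "msle":
            return float(np.mean(_msle_rows(Xv, reconstruct(m, Xv))))
        return float(np.mean((Xv - reconstruct(m, Xv)) ** 2))

    report.initial_val_loss = val_loss()
    if epochs == 0:
        m.trained = model.trained
        return m, report

    rng = np.random.default_rng(seed)
    params = [m.enc_w, m.enc_b, m.dec_w, m.dec_b]
    adam_m = [np.zeros_like(p) for p in params]
    adam_v = [np.zeros_like(p) for p in params]
    b1, b2, eps = 0.9, 0.999, 1e-8
    t = 0
    s = m.input_scale
    n = X.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        batch_losses = []
        for k in range(0, n, batch_size):
            B = X[order[k:k + batch_size]]
            nb = B.shape[0]
            h = np.tanh(B / s @ m.enc_w + m.enc_b)
            xhat = (h @ m.dec_w + m.dec_b) * s
            if objective == "msle":
                d = np.log(np.abs(xhat) + 1.0) - np.log(np.abs(B) + 1.0)
                batch_losses.append(float(np.mean(d * d)))
                # dL/dxhat of the elementwise squared log-magnitude difference
                g_out = 2.0 * d * np.sign(xhat) / (np.abs(xhat) + 1.0) / (m.input_dim * nb)
            else:
                r = xhat - B
                batch_losses.append(float(np.mean(r * r)))
                g_out = 2.0 * r / (m.input_dim * nb)
            g_dec_w = h.T @ g_out * s
            g_dec_b = g_out.sum(axis=0) * s
            g_h = (g_out @ m.dec_w.T * s) * (1.0 - h * h)
            g_enc_w = (B / s).T @ g_h
            g_enc_b = g_h.sum(axis=0)
            t += 1
            for p, g, ma, va in zip(params, [g_enc_w, g_enc_b, g_dec_w, g_dec_b],
                                    adam_m, adam_v):
                ma *= b1
                ma += (1 - b1) * g
                va *= b2
                va += (1 - b2) * g * g
                p -= learning_rate * (ma / (1 - b1 ** t)) / (np.sqrt(va / (1 - b2 ** t)) + eps)
        epoch_loss = float(np.mean(batch_losses))
        if not np.isfinite(epoch_loss):
            raise RuntimeError(f"training diverged (loss={epoch_loss}) at epoch {len(report.train_loss)}")
        report.train_loss.append(epoch_loss)
        report.val_loss.append(val_loss())
    report.n_epochs = epochs
    vl = report.val_loss
    if len(vl) >= 4 and np.isfinite(vl[-1]) and vl[-1] > 0:
        span = max(vl[-4:]) - min(vl[-4:])
        report.converged = bool(span < 0.01 * vl[-1])
    m.trained = True
    return m, report


def score(model: ModelParams, segment: FeatureVector | np.ndarray) -> EventScore:
    """MSLE between a segment and its reconstruction through the model."""
    if not model.trained:
        raise ValueError("model has not been trained")
    z = segment.z if isinstance(segment, FeatureVector) else np.asarray(segment, dtype=np.float64)
    xhat = reconstruct(model, z)
    ref = segment.source if isinstance(segment, FeatureVector) else None
    return EventScore(msle(z, xhat), ref, xhat)


def score_batch(model: ModelParams, segments) -> np.ndarray:
    """Vectorized MSLE scores for many segments; returns shape (n,)."""
    if not model.trained:
        raise ValueError("model has not been trained")
    X = _segments_to_array(segments)
    return _msle_rows(X, reconstruct(model, X))


def classify_event(event_score: EventScore | float, threshold: float = DEFAULT_THRESHOLD) -> EventDecision:
    """SPIKE iff the MSLE does not exceed the threshold (boundary inclusive)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    value = event_score.msle if isinstance(event_score, EventScore) else float(event_score)
    return EventDecision.SPIKE if value <= threshold else EventDecision.NON_NEURAL


def save_model(model: ModelParams, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for name in ("enc_w", "enc_b", "dec_w", "dec_b"):
            f.create_dataset(name, data=getattr(model, name))
        f.attrs.update({
            "input_dim": model.input_dim, "code_dim": model.code_dim,
            "train_seed": model.init_seed, "input_scale": model.input_scale,
            "target_sigma_uv": model.target_sigma, "threshold": model.threshold,
            "trained": model.trained,
        })


def load_model(path) -> ModelParams:
    import h5py

    with h5py.File(path, "r") as f:
        m = ModelParams(
            f["enc_w"][()], f["enc_b"][()], f["dec_w"][()], f["dec_b"][()],
            input_dim=int(f.attrs["input_dim"]), code_dim=int(f.attrs["code_dim"]),
            init_seed=int(f.attrs["train_seed"]), input_scale=float(f.attrs["input_scale"]),
            target_sigma=float(f.attrs["target_sigma_uv"]), threshold=float(f.attrs["threshold"]),
            trained=bool(f.attrs["trained"]),
        )
    return m
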