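"""Multi-layer perceptron inverting Fourier features to LV parameters.

A fully-connected network y_i = sigma_i(W_i x_i + b_i): ReLU hidden layers,
sigmoid output layer.  The sigmoid image is mapped affinely onto the
admissible parameter ranges, so predictions are confined to physically
meaningful values by construction.  Training minimizes the mean squared
error with Adam; implemented directly on numpy arrays, fully deterministic
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .failure_space import ParameterRanges, PARAMETER_NAMES

N_OUTPUTS = len(PARAMETER_NAMES)


@dataclass
class NetworkArchitecture:
    n_inputs: int = 22
    hidden_layers: int = 4
    hidden_units: int = 16
    n_outputs: int = N_OUTPUTS

    @property
    def layer_sizes(self) -> list[int]:
        return ([self.n_inputs]
                + [self.hidden_units] * self.hidden_layers
                + [self.n_outputs])


@dataclass
class TrainingConfig:
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 1000
    patience: int = 50      # early stopping on validation loss
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("require learning_rate > 0 and batch_size >= 1")


class FeatureScaler:
    """Per-feature standardization fitted on the training split only."""

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None

    def fit(self, x: np.ndarray) -> "FeatureScaler":
        self.mean_ = x.mean(axis=0)
        std = x.std(axis=0)
        self.std_ = np.where(std > 1e-12, std, 1.0)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean_) / self.std_


class OutputScaler:
    """Affine map between physical parameter ranges and (lo, hi) in (0, 1).

    The sub-interval default (0.05, 0.95) keeps targets away from the
    saturated tails of the sigmoid.  The inverse clips to the admissible
    range, so physical predictions never leave it.
    """

    def __init__(self, ranges: ParameterRanges, lo: float = 0.05, hi: float = 0.95):
        self.p_min = ranges.lower
        self.p_max = ranges.upper
        self.lo, self.hi = lo, hi

    def transform(self, y: np.ndarray) -> np.ndarray:
        frac = (y - self.p_min) / (self.p_max - self.p_min)
        return self.lo + (self.hi - self.lo) * frac

    def inverse(self, s: np.ndarray) -> np.ndarray:
        frac = (s - self.lo) / (self.hi - self.lo)
        y = self.p_min + frac * (self.p_max - self.p_min)
        return np.clip(y, self.p_min, self.p_max)


def _init_weights(sizes: list[int], rng: np.random.Generator):
    """Fan-in-scaled init (He for the ReLU stack, Glorot for the output)."""
    ws, bs = [], []
    for i, (n_in, n_out) in enumerate(zip(sizes[:-1], sizes[1:])):
        last = i == len(sizes) - 2
        scale = np.sqrt(1.0 / n_in) if last else np.sqrt(2.0 / n_in)
        ws.append(rng.normal(0.0, scale, size=(n_in, n_out)))
        bs.append(np.zeros(n_out))
    return ws, bs


def _forward_scaled(x: np.ndarray, ws, bs) -> np.ndarray:
    """Composition f_l o ... o f_1 on already-scaled features."""
    h = x
    for w, b in zip(ws[:-1], bs[:-1]):
        h = np.maximum(h @ w + b, 0.0)
    z = h @ ws[-1] + bs[-1]
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500.0, 500.0)))


@dataclass
class TrainedNetwork:
    architecture: NetworkArchitecture
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    feature_scaler: FeatureScaler
    output_scaler: OutputScaler
    config: TrainingConfig
    history: dict[str, list[float]] = field(default_factory=dict)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Physical-unit prediction for one 22-feature vector."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.architecture.n_inputs,):
            raise ValueError(
                f"expected feature vector of length {self.architecture.n_inputs}")
        return self.predict_batch(x[None, :])[0]

    def predict_batch(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:  # feature tensor slice (sample, signal, coefficient)
            x = x.reshape(x.shape[0], -1)
        if x.shape[1] != self.architecture.n_inputs:
            raise ValueError("feature dimension mismatch")
        s = _forward_scaled(self.feature_scaler.transform(x),
                            self.weights, self.biases)
        return self.output_scaler.inverse(s)

    # -- persistence ---------------------------------------------------------
    def save(self, path: str) -> None:
        arrays = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"w{i}"] = w
            arrays[f"b{i}"] = b
        np.savez(
            path,
            n_layers=len(self.weights),
            arch=np.array([self.architecture.n_inputs,
                           self.architecture.hidden_layers,
                           self.architecture.hidden_units,
                           self.architecture.n_outputs]),
            feat_mean=self.feature_scaler.mean_,
            feat_std=self.feature_scaler.std_,
            out_min=self.output_scaler.p_min,
            out_max=self.output_scaler.p_max,
            out_interval=np.array([self.output_scaler.lo, self.output_scaler.hi]),
            train_cfg=np.array([self.config.learning_rate, self.config.batch_size,
                                self.config.max_epochs, self.config.patience,
                                self.config.seed]),
            hist_train=np.asarray(self.history.get("train_loss", [])),
            hist_val=np.asarray(self.history.get("val_loss", [])),
            **arrays,
        )

    @classmethod
    def load(cls, path: str) -> "TrainedNetwork":
        with np.load(path) as z:
            n = int(z["n_layers"])
            ws = [z[f"w{i}"] for i in range(n)]
            bs = [z[f"b{i}"] for i in range(n)]
            ni, hl, hu, no = (int(v) for v in z["arch"])
            arch = NetworkArchitecture(ni, hl, hu, no)
            fs = FeatureScaler()
            fs.mean_, fs.std_ = z["feat_mean"], z["feat_std"]
            lo, hi = (float(v) for v in z["out_interval"])
            ranges = ParameterRanges(**{
                name: (float(z["out_min"][i]), float(z["out_max"][i]))
                for i, name in enumerate(PARAMETER_NAMES)})
            os_ = OutputScaler(ranges, lo, hi)
            lr, bsz, me, pat, seed = z["train_cfg"]
            cfg = TrainingConfig(float(lr), int(bsz), int(me), int(pat), int(seed))
            hist = {"train_loss": list(z["hist_train"]),
                    "val_loss": list(z["hist_val"])}
        return cls(arch, ws, bs, fs, os_, cfg, hist)


def train(x_train: np.ndarray, y_train: np.ndarray,
          x_val: np.ndarray, y_val: np.ndarray,
          ranges: ParameterRanges,
          cfg: TrainingConfig | None = None,
          architecture: NetworkArchitecture | None = None) -> TrainedNetwork:
    """Fit the MLP by Adam on the MSE of scaled targets.

    Returns the weights with the best validation loss seen; training aborts
    with a diagnostic if the loss diverges.  Deterministic under cfg.seed.
    """
    cfg = cfg or TrainingConfig()
    x_train = np.asarray(x_train, float).reshape(len(x_train), -1)
    x_val = np.asarray(x_val, float).reshape(len(x_val), -1)
    arch = architecture or NetworkArchitecture(n_inputs=x_train.shape[1])

    fs = FeatureScaler().fit(x_train)
    os_ = OutputScaler(ranges)
    xt, xv = fs.transform(x_train), fs.transform(x_val)
    yt, yv = os_.transform(np.asarray(y_train, float)), os_.transform(np.asarray(y_val, float))

    rng = np.random.default_rng(cfg.seed)
    ws, bs = _init_weights(arch.layer_sizes, rng)
    m_w = [np.zeros_like(w) for w in ws]
    v_w = [np.zeros_like(w) for w in ws]
    m_b = [np.zeros_like(b) for b in bs]
    v_b = [np.zeros_like(b) for b in bs]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    n = len(xt)
    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best = None
    since_best = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = xt[idx], yt[idx]

            # forward with cached activations
            acts = [xb]
            h = xb
            for w, b in zip(ws[:-1], bs[:-1]):
                h = np.maximum(h @ w + b, 0.0)
                acts.append(h)
            z = h @ ws[-1] + bs[-1]
            out = 1.0 / (1.0 + np.exp(-z))

            # backward (MSE in scaled units)
            delta = (2.0 / (len(xb) * out.shape[1])) * (out - yb)
            delta = delta * out * (1.0 - out)
            grads_w = [None] * len(ws)
            grads_b = [None] * len(bs)
            for li in range(len(ws) - 1, -1, -1):
                grads_w[li] = acts[li].T @ delta
                grads_b[li] = delta.sum(axis=0)
                if li > 0:
                    delta = (delta @ ws[li].T) * (acts[li] > 0.0)

            step += 1
            corr1 = 1.0 - beta1 ** step
            corr2 = 1.0 - beta2 ** step
            for li in range(len(ws)):
                for par, g, m, v in ((ws[li], grads_w[li], m_w[li], v_w[li]),
                                     (bs[li], grads_b[li], m_b[li], v_b[li])):
                    m *= beta1
                    m += (1 - beta1) * g
                    v *= beta2
                    v += (1 - beta2) * g * g
                    par -= cfg.learning_rate * (m / corr1) / (np.sqrt(v / corr2) + eps)

        train_loss = float(np.mean((_forward_scaled(xt, ws, bs) - yt) ** 2))
        val_loss = float(np.mean((_forward_scaled(xv, ws, bs) - yv) ** 2))
        if not (np.isfinite(train_loss) and np.isfinite(val_loss)):
            raise FloatingPointError(
                f"training diverged at epoch {epoch}: "
                f"train={train_loss}, val={val_loss}")
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)

        if val_loss < best_val:
            best_val = val_loss
            best = ([w.copy() for w in ws], [b.copy() for b in bs])
            since_best = 0
        else:
            since_best += 1
            if since_best > cfg.patience:
                break

    ws, bs = best
    return TrainedNetwork(arch, ws, bs, fs, os_, cfg, history)


def architecture_sweep(x_train, y_train, x_val, y_val, ranges,
                       layer_grid=(2, 3, 4, 5), width_grid=(8, 16, 32),
                       cfg: TrainingConfig | None = None):
    """Grid search over depth x width, selecting by validation loss.

    Ties (within 1%) are broken toward the smallest neuron count.
    """
    results = []
    for layers in layer_grid:
        for width in width_grid:
            arch = NetworkArchitecture(
                n_inputs=np.asarray(x_train).reshape(len(x_train), -1).shape[1],
                hidden_layers=layers, hidden_units=width)
            net = train(x_train, y_train, x_val, y_val, ranges, cfg, arch)
            results.append({
                "hidden_layers": layers,
                "hidden_units": width,
                "neurons": layers * width,
                "val_loss": min(net.history["val_loss"]),
                "network": net,
            })
    best_loss = min(r["val_loss"] for r in results)
    candidates = [r for r in results if r["val_loss"] <= 1.01 * best_loss]
    winner = min(candidates, key=lambda r: r["neurons"])
    return winner, results
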