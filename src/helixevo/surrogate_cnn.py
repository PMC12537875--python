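"""Convolutional sequence-to-fitness regressor for 20-residue TMD windows.

Architecture: one-hot encoding of the 20-residue sequence, two 1-D
convolutional layers of 128 filters each (ReLU) with max pooling, dropout
(p = 0.005) before two fully connected layers of 36 units (ReLU), and a
single linear output neuron. Training uses mean-squared error with the Adam
optimizer (learning rate 0.001), 16 epochs, batch size 64. Model selection
uses an 80/20 split with 4-fold cross-validation inside the 80%.

The network and its gradients are implemented directly in numpy: forward
and backward passes for valid 1-D convolution (via an im2col layout),
width-2 max pooling, inverted dropout, and dense layers. Training is
deterministic under a fixed seed and single-threaded execution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from helixevo.seqcore import ALPHABET, ALPHABET_INDEX

SEQ_LEN = 20
N_RESIDUES = 20


def one_hot(sequence: str) -> np.ndarray:
    """Encode a 20-residue sequence as a 20x20 binary matrix.

    Row i holds a single 1 at the alphabet index of residue i.
    """
    if len(sequence) != SEQ_LEN:
        raise ValueError(f"expected length {SEQ_LEN}, got {len(sequence)}")
    mat = np.zeros((SEQ_LEN, N_RESIDUES))
    for i, aa in enumerate(sequence):
        try:
            mat[i, ALPHABET_INDEX[aa]] = 1.0
        except KeyError:
            raise ValueError(f"unknown symbol {aa!r} at position {i + 1}")
    return mat


def decode_one_hot(matrix: np.ndarray) -> str:
    """Inverse of one_hot: recover the sequence from a valid matrix."""
    matrix = np.asarray(matrix)
    if matrix.shape != (SEQ_LEN, N_RESIDUES):
        raise ValueError("expected a 20x20 matrix")
    if not np.all(matrix.sum(axis=1) == 1) or not np.isin(matrix, (0, 1)).all():
        raise ValueError("rows must be one-hot")
    return "".join(ALPHABET[int(i)] for i in matrix.argmax(axis=1))


def encode_batch(sequences) -> np.ndarray:
    return np.stack([one_hot(s) for s in sequences])


@dataclass
class CNNSpec:
    """Hyperparameters of the fitness CNN."""

    conv_filters: int = 128
    conv_kernel: int = 3
    pool_width: int = 2
    dense_units: int = 36
    dropout: float = 0.005
    epochs: int = 16
    batch_size: int = 64
    learning_rate: float = 0.001
    folds: int = 4
    holdout_fraction: float = 0.20
    seed: int = 0

    def __post_init__(self):
        if min(self.conv_filters, self.conv_kernel, self.pool_width,
               self.dense_units, self.epochs, self.batch_size,
               self.folds) < 1:
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must be in (0, 1)")


def split_folds(n: int, spec: CNNSpec) -> dict:
    """Seeded 20% holdout + 4 disjoint cross-validation folds over the rest.

    Returns index arrays: {"holdout": ..., "folds": [...]}. Fold sizes differ
    by at most one; the union of all parts is the full index set.
    """
    if n < spec.folds:
        raise ValueError(f"dataset of size {n} cannot form {spec.folds} folds")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_holdout = int(round(n * spec.holdout_fraction))
    holdout = perm[:n_holdout]
    rest = perm[n_holdout:]
    folds = [rest[i::spec.folds] for i in range(spec.folds)]
    return {"holdout": np.sort(holdout), "folds": [np.sort(f) for f in folds]}


# ---------------------------------------------------------------------------
# Network internals

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, P, C) -> (B, P-k+1, k*C) sliding windows along the position axis."""
    win = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)  # (B, P-k+1, C, k)
    return win.transpose(0, 1, 3, 2).reshape(x.shape[0], x.shape[1] - k + 1, -1)


def _col2im(dcol: np.ndarray, shape, k: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add window gradients back to (B, P, C)."""
    B, P, C = shape
    dcol = dcol.reshape(B, P - k + 1, k, C)
    dx = np.zeros(shape)
    for offset in range(k):
        dx[:, offset:offset + P - k + 1, :] += dcol[:, :, offset, :]
    return dx


class _FitnessCNN:
    """The trainable network; use :func:`train` to build one."""

    def __init__(self, spec: CNNSpec, rng: np.random.Generator):
        self.spec = spec
        k, F, H = spec.conv_kernel, spec.conv_filters, spec.dense_units
        p1 = SEQ_LEN - k + 1                  # after conv1
        q1 = p1 // spec.pool_width            # after pool1
        p2 = q1 - k + 1                       # after conv2
        q2 = p2 // spec.pool_width            # after pool2
        self._dims = (p1, q1, p2, q2)
        flat = q2 * F

        def glorot(shape):
            limit = np.sqrt(6.0 / (shape[0] + shape[1]))
            return rng.uniform(-limit, limit, size=shape)

        self.params = {
            "W1": glorot((k * N_RESIDUES, F)), "b1": np.zeros(F),
            "W2": glorot((k * F, F)), "b2": np.zeros(F),
            "W3": glorot((flat, H)), "b3": np.zeros(H),
            "W4": glorot((H, H)), "b4": np.zeros(H),
            "W5": glorot((H, 1)), "b5": np.zeros(1),
        }
        self._adam_m = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._adam_v = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._adam_t = 0
        # label standardization (set during training)
        self.y_mean = 0.0
        self.y_std = 1.0

    # -- forward ------------------------------------------------------------

    def _pool(self, a: np.ndarray):
        w = self.spec.pool_width
        B, P, F = a.shape
        q = P // w
        trimmed = a[:, :q * w, :].reshape(B, q, w, F)
        arg = trimmed.argmax(axis=2)
        pooled = trimmed.max(axis=2)
        return pooled, (arg, a.shape)

    def _pool_back(self, dpooled: np.ndarray, cache) -> np.ndarray:
        arg, shape = cache
        w = self.spec.pool_width
        B, q, F = dpooled.shape
        da = np.zeros(shape)
        da_view = da[:, :q * w, :].reshape(B, q, w, F)
        np.put_along_axis(da_view, arg[:, :, None, :], dpooled[:, :, None, :],
                          axis=2)
        return da

    def _forward(self, x: np.ndarray, rng=None):
        """x: (B, 20, 20). Returns standardized predictions and a cache."""
        k = self.spec.conv_kernel
        p = self.params
        c1 = _im2col(x, k)
        z1 = c1 @ p["W1"] + p["b1"]
        a1 = np.maximum(z1, 0.0)
        h1, pc1 = self._pool(a1)
        c2 = _im2col(h1, k)
        z2 = c2 @ p["W2"] + p["b2"]
        a2 = np.maximum(z2, 0.0)
        h2, pc2 = self._pool(a2)
        flat = h2.reshape(h2.shape[0], -1)
        if rng is not None and self.spec.dropout > 0:
            keep = (rng.random(flat.shape) >= self.spec.dropout)
            flat = flat * keep / (1.0 - self.spec.dropout)
            drop_mask = keep
        else:
            drop_mask = None
        z3 = flat @ p["W3"] + p["b3"]
        a3 = np.maximum(z3, 0.0)
        z4 = a3 @ p["W4"] + p["b4"]
        a4 = np.maximum(z4, 0.0)
        out = (a4 @ p["W5"] + p["b5"]).ravel()
        cache = (x, c1, z1, a1, pc1, h1, c2, z2, a2, pc2, h2, flat,
                 drop_mask, z3, a3, z4, a4)
        return out, cache

    def _backward(self, dout: np.ndarray, cache) -> dict:
        (x, c1, z1, a1, pc1, h1, c2, z2, a2, pc2, h2, flat,
         drop_mask, z3, a3, z4, a4) = cache
        p = self.params
        k = self.spec.conv_kernel
        g = {}
        dout = dout[:, None]
        g["W5"] = a4.T @ dout
        g["b5"] = dout.sum(axis=0)
        da4 = dout @ p["W5"].T
        dz4 = da4 * (z4 > 0)
        g["W4"] = a3.T @ dz4
        g["b4"] = dz4.sum(axis=0)
        da3 = dz4 @ p["W4"].T
        dz3 = da3 * (z3 > 0)
        g["W3"] = flat.T @ dz3
        g["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ p["W3"].T
        if drop_mask is not None:
            dflat = dflat * drop_mask / (1.0 - self.spec.dropout)
        dh2 = dflat.reshape(h2.shape)
        da2 = self._pool_back(dh2, pc2)
        dz2 = da2 * (z2 > 0)
        g["W2"] = c2.reshape(-1, c2.shape[-1]).T @ dz2.reshape(-1, dz2.shape[-1])
        g["b2"] = dz2.sum(axis=(0, 1))
        dc2 = dz2 @ p["W2"].T
        dh1 = _col2im(dc2, h1.shape, k)
        da1 = self._pool_back(dh1, pc1)
        dz1 = da1 * (z1 > 0)
        g["W1"] = c1.reshape(-1, c1.shape[-1]).T @ dz1.reshape(-1, dz1.shape[-1])
        g["b1"] = dz1.sum(axis=(0, 1))
        return g

    def _adam_step(self, grads: dict) -> None:
        self._adam_t += 1
        lr, b1, b2, eps = self.spec.learning_rate, 0.9, 0.999, 1e-8
        t = self._adam_t
        for key, grad in grads.items():
            grad = grad.reshape(self.params[key].shape)
            m = self._adam_m[key] = b1 * self._adam_m[key] + (1 - b1) * grad
            v = self._adam_v[key] = b2 * self._adam_v[key] + (1 - b2) * grad ** 2
            mhat = m / (1 - b1 ** t)
            vhat = v / (1 - b2 ** t)
            self.params[key] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- public API ---------------------------------------------------------

    def fit(self, x: np.ndarray, y: np.ndarray, rng: np.random.Generator):
        y = np.asarray(y, dtype=float)
        self.y_mean = float(y.mean())
        self.y_std = float(y.std())
        if self.y_std == 0:
            raise ValueError("degenerate labels: zero variance")
        yz = (y - self.y_mean) / self.y_std
        n = len(x)
        bs = self.spec.batch_size
        for _ in range(self.spec.epochs):
            order = rng.permutation(n)
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                pred, cache = self._forward(x[idx], rng=rng)
                dout = 2.0 * (pred - yz[idx]) / len(idx)
                self._adam_step(self._backward(dout, cache))
        return self

    def predict_matrix(self, x: np.ndarray) -> np.ndarray:
        out = np.empty(len(x))
        for start in range(0, len(x), 512):
            pred, _ = self._forward(x[start:start + 512], rng=None)
            out[start:start + 512] = pred
        return out * self.y_std + self.y_mean

    def predict(self, sequences) -> np.ndarray:
        return self.predict_matrix(encode_batch(sequences))

    def __call__(self, sequence: str) -> float:
        return float(self.predict([sequence])[0])

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params,
                 y_mean=self.y_mean, y_std=self.y_std)
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump({"format_version": 1, "spec": self.spec.__dict__}, fh)

    @classmethod
    def load(cls, path) -> "_FitnessCNN":
        path = Path(path)
        with open(path.with_suffix(".json")) as fh:
            spec = CNNSpec(**json.load(fh)["spec"])
        model = cls(spec, np.random.default_rng(spec.seed))
        data = np.load(path.with_suffix(".npz"))
        for key in model.params:
            model.params[key] = data[key]
        model.y_mean = float(data["y_mean"])
        model.y_std = float(data["y_std"])
        return model


def train(dataset, spec: CNNSpec | None = None) -> _FitnessCNN:
    """Train the fitness CNN on (sequence, fitness) pairs.

    Deterministic under spec.seed (single-threaded). Returns a predictor
    callable on sequences.
    """
    if spec is None:
        spec = CNNSpec()
    sequences, y = zip(*dataset)
    x = encode_batch(sequences)
    rng = np.random.default_rng(spec.seed)
    return _FitnessCNN(spec, rng).fit(x, np.asarray(y, dtype=float), rng)


def evaluate(predictor, dataset) -> float:
    """Coefficient of determination R^2 = 1 - SS_res/SS_tot on a labeled set."""
    sequences, y = zip(*dataset)
    y = np.asarray(y, dtype=float)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("degenerate labels: R^2 undefined for zero variance")
    if hasattr(predictor, "predict"):
        pred = np.asarray(predictor.predict(list(sequences)), dtype=float)
    else:
        pred = np.array([float(predictor(s)) for s in sequences])
    ss_res = float(((y - pred) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def cross_validate(dataset, spec: CNNSpec | None = None) -> dict:
    """80/20 split + k-fold cross-validation inside the 80%.

    Returns per-fold test R^2, the holdout R^2 of a final model trained on
    the full 80%, and the split indices.
    """
    if spec is None:
        spec = CNNSpec()
    dataset = list(dataset)
    split = split_folds(len(dataset), spec)
    holdout = [dataset[i] for i in split["holdout"]]
    fold_sets = [[dataset[i] for i in f] for f in split["folds"]]
    fold_r2 = []
    for i in range(spec.folds):
        test = fold_sets[i]
        train_set = [item for j, f in enumerate(fold_sets) if j != i for item in f]
        model = train(train_set, spec)
        fold_r2.append(evaluate(model, test))
    train_all = [item for f in fold_sets for item in f]
    final = train(train_all, spec)
    return {"fold_r2": fold_r2, "holdout_r2": evaluate(final, holdout),
            "model": final, "split": split}


# ---------------------------------------------------------------------------
# Labeled dataset TSV `sequence<TAB>fitness`

def read_labeled_tsv(path) -> list:
    pairs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if header[:2] != ["sequence", "fitness"]:
            raise ValueError("expected header 'sequence\\tfitness'")
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            seq, fit = line.split("\t")[:2]
            pairs.append((seq, float(fit)))
    return pairs


def write_labeled_tsv(pairs, path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tfitness\n")
        for seq, fit in pairs:
            fh.write(f"{seq}\t{fit:.10g}\n")
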