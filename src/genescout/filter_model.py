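"""The result-filtering model: six features, SMOTE balancing, a 4-2-1
dense network with sigmoid output, and sensitivity-floor threshold
calibration.

The feature vector order is fixed:

    0. sim_pident        best percent identity of the region's HSPs [0,100]
    1. sim_gene_cov      best query coverage of the region's HSPs   [0,1]
    2. pred_hint_support percent of CDS bases covered by hints      [0,100]
    3. aln_pident        validation alignment percent identity      [0,100]
    4. aln_psim          validation alignment percent similarity    [0,100]
    5. aln_gene_cov      validation alignment query coverage        [0,1]

The network is trained with Adam (learning rate 1e-5) on binary
cross-entropy.  Percentage features are scaled to [0,1] inside the model
(the scale is part of the serialized archive): with all-positive raw
0-100 inputs a Glorot-initialized ReLU layer is frequently dead for every
sample at initialization, and at this learning rate training cannot
recover.  The decision threshold is the largest probability whose
training-set sensitivity still meets the configured floor (0.95 by
default): the tightest cut that keeps the stated fraction of true
candidates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .errors import StageError
from .regions import NNConfig

FEATURE_NAMES = (
    "sim_pident",
    "sim_gene_cov",
    "pred_hint_support",
    "aln_pident",
    "aln_psim",
    "aln_gene_cov",
)

_RANGES = ((0, 100), (0, 1), (0, 100), (0, 100), (0, 100), (0, 1))

#: Divisors mapping each raw feature into [0, 1] for the network input.
FEATURE_SCALE = np.array([100.0, 1.0, 100.0, 100.0, 100.0, 1.0])


def assemble_features(
    sim_pident: float | None,
    sim_gene_cov: float | None,
    pred_hint_support: float | None,
    aln_pident: float | None,
    aln_psim: float | None,
    aln_gene_cov: float | None,
) -> np.ndarray:
    """Build one feature vector, verifying every stage delivered its value."""
    stages = {
        "similarity summary": (sim_pident, sim_gene_cov),
        "prediction stage": (pred_hint_support,),
        "validation alignment": (aln_pident, aln_psim, aln_gene_cov),
    }
    for stage, values in stages.items():
        for v in values:
            if v is None or not np.isfinite(v):
                raise StageError(f"{stage} incomplete: missing feature value")
    vec = np.array(
        [sim_pident, sim_gene_cov, pred_hint_support, aln_pident, aln_psim, aln_gene_cov],
        dtype=float,
    )
    for value, (lo, hi) in zip(vec, _RANGES):
        if not lo <= value <= hi:
            raise StageError(f"feature value {value} outside [{lo},{hi}]")
    return vec


def smote_balance(
    vectors: np.ndarray, labels: np.ndarray, seed: int, k: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class to an exact 1:1 ratio (SMOTE).

    Synthetic samples are convex combinations of a minority sample and one
    of its k nearest minority neighbors.  Majority samples pass through
    unchanged.  A minority class with a single member falls back to
    duplication with a warning.  Deterministic given ``seed``.
    """
    X = np.asarray(vectors, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise StageError("feature/label length mismatch")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise StageError("both classes must be present for balancing")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    need = n_maj - n_min
    if need == 0:
        return X.copy(), y.copy()
    rng = np.random.default_rng(seed)
    minority_X = X[y == minority]
    if n_min < 2:
        warnings.warn("minority class has <2 members; duplicating instead of SMOTE")
        synth = np.repeat(minority_X, need, axis=0)[:need]
    else:
        k_eff = min(k, n_min - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(minority_X)
        _, idx = nn.kneighbors(minority_X)
        base = rng.integers(0, n_min, size=need)
        neigh_choice = rng.integers(1, k_eff + 1, size=need)
        gaps = rng.random(need)
        neighbors = minority_X[idx[base, neigh_choice]]
        synth = minority_X[base] + gaps[:, None] * (neighbors - minority_X[base])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(need, minority, dtype=int)])
    return X_out, y_out


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class FilterModel:
    """A 4-2-1 dense network with ReLU hidden layers and sigmoid output."""

    weights: list[np.ndarray] = field(default_factory=list)
    biases: list[np.ndarray] = field(default_factory=list)
    calibrated_threshold: float | None = None
    input_scale: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @classmethod
    def initialize(cls, seed: int, n_features: int = 6,
                   hidden_sizes: Sequence[int] = (4, 2)) -> "FilterModel":
        """Seeded Glorot-uniform initialization."""
        rng = np.random.default_rng(seed)
        sizes = [n_features, *hidden_sizes, 1]
        weights, biases = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            biases.append(np.zeros(fan_out))
        return cls(weights=weights, biases=biases, metadata={"seed": seed})

    @classmethod
    def zeros(cls, n_features: int = 6, hidden_sizes: Sequence[int] = (4, 2)) -> "FilterModel":
        """All-zero weights: outputs exactly 0.5 everywhere (sigmoid(0))."""
        sizes = [n_features, *hidden_sizes, 1]
        return cls(
            weights=[np.zeros((a, b)) for a, b in zip(sizes[:-1], sizes[1:])],
            biases=[np.zeros(b) for b in sizes[1:]],
            metadata={"seed": None},
        )

    def _forward(self, X: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        acts = [X]
        h = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ W + b, 0.0)
            acts.append(h)
        logits = (h @ self.weights[-1] + self.biases[-1]).ravel()
        return acts, logits

    def predict_proba(self, vectors: np.ndarray) -> np.ndarray:
        """Forward pass; probabilities strictly in (0,1)."""
        X = np.atleast_2d(np.asarray(vectors, dtype=float))
        if not np.all(np.isfinite(X)):
            raise StageError("feature vector contains non-finite values")
        if self.input_scale is not None:
            X = X / self.input_scale
        _, logits = self._forward(X)
        return _sigmoid(logits)

    # -- persistence -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "genescout-filter/1",
            "layer_shapes": [list(W.shape) for W in self.weights],
            "weights": [W.tolist() for W in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "calibrated_threshold": self.calibrated_threshold,
            "input_scale": None if self.input_scale is None else self.input_scale.tolist(),
            "feature_order": list(FEATURE_NAMES),
            "metadata": self.metadata,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "FilterModel":
        if d.get("format") != "genescout-filter/1":
            raise StageError("unrecognized filter model archive format")
        return cls(
            weights=[np.array(W, dtype=float) for W in d["weights"]],
            biases=[np.array(b, dtype=float) for b in d["biases"]],
            calibrated_threshold=d.get("calibrated_threshold"),
            input_scale=(None if d.get("input_scale") is None
                         else np.array(d["input_scale"], dtype=float)),
            metadata=d.get("metadata", {}),
        )

    @classmethod
    def load(cls, path) -> "FilterModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def train_filter(
    vectors: np.ndarray, labels: np.ndarray, config: NNConfig | None = None
) -> FilterModel:
    """Train the filter network with Adam on binary cross-entropy.

    Deterministic given ``config.seed``; the per-epoch loss curve is
    recorded in the model metadata.
    """
    config = config or NNConfig()
    X = np.asarray(vectors, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise StageError("feature/label length mismatch")
    if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
        raise StageError(f"expected {len(FEATURE_NAMES)} features per vector")
    model = FilterModel.initialize(config.seed, X.shape[1], config.hidden_sizes)
    model.input_scale = FEATURE_SCALE.copy()
    X = X / model.input_scale
    rng = np.random.default_rng(config.seed + 1)
    params = model.weights + model.biases
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    losses = []
    n = X.shape[0]
    n_batches = max(1, -(-n // config.batch_size))
    epochs = max(config.epochs, -(-config.min_steps // n_batches))
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            xb, yb = X[idx], y[idx]
            acts, logits = model._forward(xb)
            p = _sigmoid(logits)
            pc = np.clip(p, 1e-12, 1 - 1e-12)
            loss = -np.mean(yb * np.log(pc) + (1 - yb) * np.log(1 - pc))
            epoch_loss += loss * len(idx)
            # backprop
            delta = (p - yb)[:, None] / len(idx)
            grads_W, grads_b = [], []
            for li in range(len(model.weights) - 1, -1, -1):
                grads_W.insert(0, acts[li].T @ delta)
                grads_b.insert(0, delta.sum(axis=0))
                if li > 0:
                    delta = (delta @ model.weights[li].T) * (acts[li] > 0)
            step += 1
            grads = grads_W + grads_b
            for pi, (param, g) in enumerate(zip(params, grads)):
                m_t[pi] = beta1 * m_t[pi] + (1 - beta1) * g
                v_t[pi] = beta2 * v_t[pi] + (1 - beta2) * g * g
                mhat = m_t[pi] / (1 - beta1**step)
                vhat = v_t[pi] / (1 - beta2**step)
                param -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        mean_loss = epoch_loss / n
        if not np.isfinite(mean_loss):
            raise StageError("training diverged: non-finite loss")
        losses.append(float(mean_loss))
    if len(losses) > 200:  # keep the archive small: <=200 checkpoints
        keep = np.unique(np.linspace(0, len(losses) - 1, 200).astype(int))
        losses = [losses[i] for i in keep]
    model.metadata.update(
        {
            "seed": config.seed,
            "epochs": epochs,
            "batch_size": config.batch_size,
            "learning_rate": config.learning_rate,
            "hidden_activation": "relu",
            "loss_curve": losses,
        }
    )
    return model


def calibrate_threshold(
    model: FilterModel,
    vectors: np.ndarray,
    labels: np.ndarray,
    target_sensitivity: float = 0.95,
) -> float:
    """Choose the decision threshold by the sensitivity-floor rule.

    Candidate thresholds are the distinct predicted probabilities of the
    calibration set; the returned value is the largest one whose
    sensitivity (with >= decision rule) still meets the target.  Stored on
    the model.
    """
    y = np.asarray(labels, dtype=int).ravel()
    if not np.any(y == 1):
        raise StageError("calibration requires at least one positive example")
    probs = model.predict_proba(vectors)
    pos = probs[y == 1]
    chosen = None
    for t in sorted(np.unique(probs)):
        sens = float(np.mean(pos >= t))
        if sens >= target_sensitivity:
            chosen = float(t)
        else:
            break  # sensitivity is non-increasing in t
    if chosen is None:  # unreachable while positives exist
        raise StageError("no threshold attains the target sensitivity")
    model.calibrated_threshold = chosen
    return chosen
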