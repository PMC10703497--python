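"""Masked feedforward network with a predictive head per hidden layer.

The architecture mirrors a layered pathway graph: hidden layer k computes

    h_k = tanh((M_k o W_k) @ h_{k-1} + b_k)

where ``M_k`` is the binary connectivity mask and ``o`` the Hadamard
product, so a weight exists only where the hierarchy has an edge. After
every hidden layer a dense predictive head maps the layer's activations to
class scores, turned into probabilities by a softmax. Training minimizes
the unweighted sum of the per-head mean cross-entropies plus an L2 penalty
on the effective (masked) weights, with the Adam optimizer. The final
label is a plurality vote over the heads' argmax predictions, ties broken
by the largest probability mass summed across heads.

Masking is enforced by construction: gradients are multiplied by the mask,
and masked entries are initialized to zero, so they stay exactly zero
through training.

Implemented directly on numpy arrays; everything is deterministic under
the seed, which a full autograd framework would not guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .hierarchy import MaskStack
from .preprocess import compute_metrics

__all__ = [
    "TrainingConfig",
    "ModelParams",
    "PredictionResult",
    "init_model",
    "forward",
    "train",
    "vote",
    "predict",
    "grid_search_cv",
]


@dataclass
class TrainingConfig:
    """Optimization hyperparameters (Adam, cross-entropy + L2)."""

    batch_size: int = 32
    learning_rate: float = 0.001
    l2: float = 0.0001
    epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size <= 0 or self.learning_rate <= 0 or self.epochs <= 0:
            raise ValueError("batch_size, learning_rate and epochs must be positive")
        if self.l2 < 0:
            raise ValueError("l2 must be non-negative")


@dataclass
class ModelParams:
    """Per-layer weights/biases plus one affine head per hidden layer."""

    weights: list          # W_k, shaped like mask k (in x out)
    biases: list           # b_k, length out
    head_weights: list     # V_k: hidden_k x C
    head_biases: list      # c_k: C
    classes: list          # class labels, index = head output column

    @property
    def n_classes(self) -> int:
        return len(self.classes)


@dataclass
class PredictionResult:
    probabilities: list    # per head: cells x C
    head_labels: np.ndarray  # heads x cells (object array of labels)
    voted: np.ndarray | None = None
    activations: list = field(default_factory=list)  # per hidden layer: cells x width


INIT_SCALE = 0.7        # overall magnitude of initial hidden weights
INIT_NOISE = 0.3        # relative jitter around the membership average


def init_model(masks: MaskStack, classes, seed: int = 0) -> ModelParams:
    """Fan-in-scaled random initialization on unmasked entries, zeros elsewhere.

    Each hidden weight starts at ``INIT_SCALE * (1 + INIT_NOISE * eps) /
    fan_in`` where ``eps`` is standard normal and fan-in is the mask column
    sum (the number of real incoming edges). A pathway neuron therefore
    begins close to the (scaled) average of its member genes — an
    interpretable, informative feature from step one — with enough jitter
    to break symmetry. Predictive heads start at exactly zero (uniform
    class probabilities): like a zero-initialized logistic regression,
    every optimizer step then moves the heads by signal rather than by
    undoing a random start, which matters at small step budgets.
    Deterministic under ``seed``.
    """
    classes = list(classes)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    weights, biases, head_w, head_b = [], [], [], []
    for m in masks.masks:
        m = m.astype(float)
        fan_in = np.maximum(m.sum(axis=0), 1.0)  # per output unit
        w = INIT_SCALE * (1.0 + INIT_NOISE * rng.standard_normal(m.shape)) / fan_in[None, :]
        weights.append(w * m)
        biases.append(np.zeros(m.shape[1]))
    for m in masks.masks:
        head_w.append(np.zeros((m.shape[1], len(classes))))
        head_b.append(np.zeros(len(classes)))
    return ModelParams(weights, biases, head_w, head_b, classes)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def forward(params: ModelParams, masks: MaskStack, X: np.ndarray) -> PredictionResult:
    """Run the masked forward pass; X is cells x genes in mask gene order."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != masks.masks[0].shape[0]:
        raise ValueError(
            f"input has {X.shape[1] if X.ndim == 2 else '?'} features, "
            f"layer 0 expects {masks.masks[0].shape[0]} genes"
        )
    activations, probs, head_labels = [], [], []
    h = X
    for k, (m, w, b) in enumerate(zip(masks.masks, params.weights, params.biases)):
        if h.shape[1] != m.shape[0]:
            raise ValueError(f"shape mismatch entering hidden layer {k}")
        h = np.tanh(h @ (m * w) + b)
        activations.append(h)
        p = _softmax(h @ params.head_weights[k] + params.head_biases[k])
        probs.append(p)
        head_labels.append(np.asarray(params.classes, dtype=object)[p.argmax(axis=1)])
    return PredictionResult(
        probabilities=probs,
        head_labels=np.stack(head_labels),
        activations=activations,
    )


def vote(head_labels: np.ndarray, probabilities: list, classes) -> np.ndarray:
    """Plurality vote across heads; ties broken by summed probability.

    ``head_labels`` is heads x cells; ``probabilities`` is a list of
    cells x C arrays whose columns follow ``classes``. Among classes tied
    for the most head votes, the one with the largest probability mass
    summed over all heads wins (residual ties: lexicographic).
    """
    head_labels = np.asarray(head_labels, dtype=object)
    if head_labels.ndim == 1:
        head_labels = head_labels[None, :]
    n_heads, n_cells = head_labels.shape
    if n_heads == 0:
        raise ValueError("need at least one head")
    if n_heads == 1:
        return head_labels[0].copy()
    col = {str(lab): j for j, lab in enumerate(classes)}
    summed = np.sum(probabilities, axis=0)  # cells x C
    out = np.empty(n_cells, dtype=object)
    for i in range(n_cells):
        labels, counts = np.unique(head_labels[:, i].astype(str), return_counts=True)
        tied = labels[counts == counts.max()]
        if len(tied) == 1:
            out[i] = tied[0]
        else:
            out[i] = max(sorted(tied), key=lambda lab: summed[i, col[lab]])
    return out


def predict(params: ModelParams, masks: MaskStack, X: np.ndarray) -> PredictionResult:
    """Forward pass plus voting; returns a complete PredictionResult."""
    res = forward(params, masks, X)
    res.voted = vote(res.head_labels, res.probabilities, params.classes)
    return res


def train(
    params: ModelParams,
    masks: MaskStack,
    X: np.ndarray,
    y_labels,
    cfg: TrainingConfig,
) -> tuple[ModelParams, list]:
    """Adam on summed per-head cross-entropy + L2 on effective weights.

    Returns the trained parameters and the per-epoch loss trace. Masked
    entries receive masked gradients, so they remain exactly zero.
    """
    X = np.asarray(X, dtype=float)
    y_labels = np.asarray(y_labels)
    class_index = {lab: i for i, lab in enumerate(params.classes)}
    present = set(np.unique(y_labels).tolist())
    if len(present) < 2:
        raise ValueError("training labels contain a single class")
    unknown = present - set(params.classes)
    if unknown:
        raise ValueError(f"labels not in model classes: {sorted(map(str, unknown))}")
    y = np.array([class_index[lab] for lab in y_labels])
    n, C = len(y), params.n_classes
    L = len(masks.masks)
    mask_f = [m.astype(float) for m in masks.masks]

    params = ModelParams(
        [w.copy() for w in params.weights],
        [b.copy() for b in params.biases],
        [w.copy() for w in params.head_weights],
        [b.copy() for b in params.head_biases],
        list(params.classes),
    )
    flat = params.weights + params.biases + params.head_weights + params.head_biases
    mom = [np.zeros_like(p) for p in flat]
    vel = [np.zeros_like(p) for p in flat]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    rng = np.random.default_rng(cfg.seed)
    trace = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            nb = len(idx)

            # forward
            hs = [xb]
            for k in range(L):
                hs.append(np.tanh(hs[-1] @ (mask_f[k] * params.weights[k]) + params.biases[k]))
            loss = 0.0
            dhs = [np.zeros_like(h) for h in hs]
            grads_w = [None] * L
            grads_b = [None] * L
            grads_hw = [None] * L
            grads_hb = [None] * L
            for k in range(L):
                z = hs[k + 1] @ params.head_weights[k] + params.head_biases[k]
                p = _softmax(z)
                loss -= np.log(np.maximum(p[np.arange(nb), yb], 1e-300)).mean()
                dz = p.copy()
                dz[np.arange(nb), yb] -= 1.0
                dz /= nb
                grads_hw[k] = hs[k + 1].T @ dz
                grads_hb[k] = dz.sum(axis=0)
                dhs[k + 1] += dz @ params.head_weights[k].T
            for k in range(L):
                eff = mask_f[k] * params.weights[k]
                loss += cfg.l2 * float((eff * eff).sum())
            # backward through hidden stack
            for k in range(L - 1, -1, -1):
                da = dhs[k + 1] * (1.0 - hs[k + 1] ** 2)
                eff = mask_f[k] * params.weights[k]
                grads_w[k] = mask_f[k] * (hs[k].T @ da) + 2.0 * cfg.l2 * eff
                grads_b[k] = da.sum(axis=0)
                dhs[k] += da @ eff.T

            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            epoch_loss += loss
            n_batches += 1

            grads = grads_w + grads_b + grads_hw + grads_hb
            step += 1
            lr_t = cfg.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
            for p_arr, g, m_arr, v_arr in zip(flat, grads, mom, vel):
                m_arr *= beta1
                m_arr += (1 - beta1) * g
                v_arr *= beta2
                v_arr += (1 - beta2) * g * g
                p_arr -= lr_t * m_arr / (np.sqrt(v_arr) + eps)
            # keep masked entries exactly zero against numerical drift
            for k in range(L):
                params.weights[k] *= mask_f[k]
        trace.append(epoch_loss / max(n_batches, 1))
    return params, trace


def grid_search_cv(
    X: np.ndarray,
    y_labels,
    masks: MaskStack,
    grid,
    folds: int = 5,
    seed: int = 0,
):
    """Pick the TrainingConfig with the best stratified-CV macro F1.

    ``grid`` is an iterable of TrainingConfig; ties keep grid order.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty parameter grid")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y_labels = np.asarray(y_labels)
    _, counts = np.unique(y_labels, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} cells < {folds} folds; use fewer folds"
        )
    classes = sorted(set(y_labels.tolist()))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    best_cfg, best_score = None, -np.inf
    scores = []
    for cfg in grid:
        fold_scores = []
        for tr, te in skf.split(X, y_labels):
            p0 = init_model(masks, classes, seed=cfg.seed)
            trained, _ = train(p0, masks, X[tr], y_labels[tr], cfg)
            pred = predict(trained, masks, X[te])
            fold_scores.append(compute_metrics(y_labels[te], pred.voted)["macro_f1"])
        mean = float(np.mean(fold_scores))
        scores.append(mean)
        if mean > best_score:
            best_cfg, best_score = cfg, mean
    return replace(best_cfg), best_score, scores
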