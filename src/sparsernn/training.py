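"""Training by backpropagation under mask and Dale constraints.

Networks are trained with the Adam optimizer (learning rate 0.001) on the
cross-entropy loss over one-hot targets. Two projections run after every
optimizer step:

* mask projection (standard mode): hidden-layer weights between unconnected
  nodes are reset to exactly 0, so the wiring stays fixed for life;
* Dale projection: any outgoing weight of a hidden node whose sign would
  flip relative to the node's fixed excitatory/inhibitory identity is set
  to exactly 0 instead — the weight remains trainable afterwards.

The "sparse_to_dense" mode initializes weights from a sparse mask but skips
the mask projection, letting zero-initialized weights become nonzero.

Gradients are computed by hand-derived backpropagation through time; an
independent finite-difference oracle in the test suite pins their
correctness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .encoding import SequenceDataset
from .model import forward_feedforward, forward_recurrent, predict
from .topology import NetworkParams

__all__ = [
    "TrainingConfig",
    "TrainingTrace",
    "train",
    "single_epoch_accuracy",
    "evaluate_accuracy",
    "cross_entropy_loss",
    "backward_recurrent",
    "backward_feedforward",
    "sign_change_stats",
    "record_gradient_magnitude",
]


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.001
    optimizer: Literal["adam"] = "adam"
    loss: Literal["cross_entropy"] = "cross_entropy"
    batch_size: int = 100
    max_epochs: int = 50
    early_stop_patience: int | None = None
    mode: Literal["standard", "sparse_to_dense"] = "standard"
    record_gradients: bool = False
    record_sign_changes: bool = False
    # stop as soon as test accuracy first exceeds chance + this margin
    # (used by training-delay experiments); None disables
    stop_above_chance_margin: float | None = None
    eval_batch_size: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.early_stop_patience is not None and self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1 when set")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainingTrace:
    """Per-epoch record of training dynamics."""

    test_accuracy: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    mean_abs_gradient_hh: list[float] = field(default_factory=list)
    # per epoch: dict with pos_to_neg, neg_to_pos, zeroed_by_dale
    sign_change_counts: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.test_accuracy)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_loss(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean cross-entropy of softmax(logits) against integer labels."""
    p = _softmax(logits)
    return float(-np.mean(np.log(p[np.arange(len(labels)), labels] + 1e-300)))


def _phi_deriv(h: np.ndarray, activation: str) -> np.ndarray:
    # derivative expressed through the activation value itself
    if activation == "relu":
        return (h > 0).astype(np.float64)
    return 1.0 - h * h  # tanh


def backward_recurrent(
    params: NetworkParams, x: np.ndarray, labels: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Loss and gradients for one batch via backprop through time.

    ``x`` is (batch, T, d). Returns (loss, grads) with grads keyed by
    'w_in', 'w_hh', 'w_out'. Gradients are of the batch-mean loss.
    """
    traj, logits = forward_recurrent(params, x, return_trajectory=True)
    batch, T, _ = x.shape
    loss = cross_entropy_loss(logits, labels)

    dlogits = _softmax(logits)
    dlogits[np.arange(batch), labels] -= 1.0
    dlogits /= batch

    h_T = traj[:, -1]
    g_out = h_T.T @ dlogits
    g_in = np.zeros_like(params.w_in)
    g_hh = np.zeros_like(params.w_hh)
    dh = dlogits @ params.w_out.T
    for t in range(T - 1, -1, -1):
        da = dh * _phi_deriv(traj[:, t], params.activation)
        g_in += x[:, t].T @ da
        if t > 0:
            g_hh += traj[:, t - 1].T @ da
            dh = da @ params.w_hh.T
    return loss, {"w_in": g_in, "w_hh": g_hh, "w_out": g_out}


def backward_feedforward(
    params: NetworkParams, x: np.ndarray, labels: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Loss and gradients for the two-layer feedforward control."""
    l1, l2, logits = forward_feedforward(params, x)
    batch = x.shape[0]
    loss = cross_entropy_loss(logits, labels)

    dlogits = _softmax(logits)
    dlogits[np.arange(batch), labels] -= 1.0
    dlogits /= batch

    g_out = l2.T @ dlogits
    dl2 = (dlogits @ params.w_out.T) * _phi_deriv(l2, params.activation)
    g_hh = l1.T @ dl2
    dl1 = (dl2 @ params.w_hh.T) * _phi_deriv(l1, params.activation)
    g_in = x.T @ dl1
    return loss, {"w_in": g_in, "w_hh": g_hh, "w_out": g_out}


class Adam:
    """Standard Adam with bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, weights: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            m_hat = self.m[k] / (1 - self.beta1**self.t)
            v_hat = self.v[k] / (1 - self.beta2**self.t)
            weights[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _dale_clip(params: NetworkParams, signs: np.ndarray) -> int:
    """Zero outgoing weights whose sign flipped against the node identity.

    Returns the number of entries zeroed."""
    zeroed = 0
    for w in (params.w_hh, params.w_out):
        bad = (w * signs[:, None]) < 0
        zeroed += int(bad.sum())
        w[bad] = 0.0
    return zeroed


def record_gradient_magnitude(
    grad_hh: np.ndarray, mask: np.ndarray | None = None
) -> float | None:
    """Mean absolute hidden-layer gradient over trainable (unmasked) entries.

    Returns None when the mask admits no entries."""
    if mask is None:
        return float(np.mean(np.abs(grad_hh)))
    n_edges = mask.sum()
    if n_edges == 0:
        return None
    return float(np.abs(grad_hh * mask).sum() / n_edges)


def evaluate_accuracy(
    params: NetworkParams, dataset: SequenceDataset, batch_size: int = 1000
) -> float:
    """Test-set classification accuracy, evaluated in batches."""
    correct = 0
    for start in range(0, len(dataset), batch_size):
        sl = slice(start, start + batch_size)
        if params.architecture == "recurrent":
            _, logits = forward_recurrent(params, dataset.sequences[sl])
        else:
            _, _, logits = forward_feedforward(
                params, dataset.flat_inputs()[sl]
            )
        correct += int((predict(logits) == dataset.labels[sl]).sum())
    return correct / len(dataset)


def train(
    params: NetworkParams,
    mask: np.ndarray,
    signs: np.ndarray | None,
    train_set: SequenceDataset,
    test_set: SequenceDataset,
    config: TrainingConfig,
    epoch_callback=None,
) -> tuple[NetworkParams, TrainingTrace]:
    """Optimize a network, returning final parameters and the trace.

    The input ``params`` is not modified. Training data are reshuffled each
    epoch (seeded); test accuracy is evaluated on the full test split after
    every epoch. Early stopping (when configured) halts once test accuracy
    has not improved for ``early_stop_patience`` consecutive epochs.
    ``epoch_callback(epoch, params, trace)``, when given, runs after every
    epoch (used e.g. to audit the constraint projections).
    """
    dale = signs is not None
    params = params.copy()
    weights = {"w_in": params.w_in, "w_hh": params.w_hh, "w_out": params.w_out}
    opt = Adam(config.learning_rate)
    rng = np.random.default_rng(config.seed)
    trace = TrainingTrace()
    backward = (
        backward_recurrent if params.architecture == "recurrent"
        else backward_feedforward
    )
    inputs = (
        train_set.sequences if params.architecture == "recurrent"
        else train_set.flat_inputs()
    )
    apply_mask = config.mode == "standard"
    chance = 1.0 / train_set.n_classes

    best_acc, since_best = -1.0, 0
    for _epoch in range(config.max_epochs):
        order = rng.permutation(len(train_set))
        losses: list[float] = []
        grad_mags: list[float] = []
        zeroed_by_dale = 0
        w_hh_epoch_start = params.w_hh.copy()
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            loss, grads = backward(params, inputs[idx], train_set.labels[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss {loss} at epoch {_epoch}, step "
                    f"{start // config.batch_size}"
                )
            if config.record_gradients:
                gm = record_gradient_magnitude(
                    grads["w_hh"], mask if apply_mask else None
                )
                if gm is not None:
                    grad_mags.append(gm)
            if apply_mask:
                grads["w_hh"] *= mask
            opt.step(weights, grads)
            if apply_mask:
                params.w_hh *= mask
            if dale:
                zeroed_by_dale += _dale_clip(params, signs)
            losses.append(loss)

        acc = evaluate_accuracy(params, test_set, config.eval_batch_size)
        trace.test_accuracy.append(acc)
        trace.train_loss.append(float(np.mean(losses)))
        if config.record_gradients:
            trace.mean_abs_gradient_hh.append(
                float(np.mean(grad_mags)) if grad_mags else float("nan")
            )
        if config.record_sign_changes or dale:
            stats = sign_change_stats(w_hh_epoch_start, params.w_hh)
            trace.sign_change_counts.append(
                {
                    "pos_to_neg": stats["pos_to_neg"],
                    "neg_to_pos": stats["neg_to_pos"],
                    "zeroed_by_dale": zeroed_by_dale,
                }
            )

        if epoch_callback is not None:
            epoch_callback(_epoch, params, trace)

        if (
            config.stop_above_chance_margin is not None
            and acc > chance + config.stop_above_chance_margin
        ):
            break
        if config.early_stop_patience is not None:
            if acc > best_acc:
                best_acc, since_best = acc, 0
            else:
                since_best += 1
                if since_best >= config.early_stop_patience:
                    break
    return params, trace


def single_epoch_accuracy(
    params: NetworkParams,
    mask: np.ndarray,
    signs: np.ndarray | None,
    train_set: SequenceDataset,
    test_set: SequenceDataset,
    config: TrainingConfig,
) -> float:
    """Test accuracy after exactly one pass over the training data — the
    time-limited-learning metric."""
    cfg = TrainingConfig(
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        max_epochs=1,
        mode=config.mode,
        record_gradients=config.record_gradients,
        eval_batch_size=config.eval_batch_size,
        seed=config.seed,
    )
    _, trace = train(params, mask, signs, train_set, test_set, cfg)
    return trace.test_accuracy[0]


def sign_change_stats(
    w_before: np.ndarray, w_after: np.ndarray
) -> dict[str, int]:
    """Tally weight sign transitions and magnitude growth between two
    snapshots of the same weight matrix.

    Counts: pos_to_neg, neg_to_pos, and — among entries keeping their sign —
    magnitude increases of negative and of positive weights.
    """
    if w_before.shape != w_after.shape:
        raise ValueError("weight snapshots differ in shape")
    pos_to_neg = int(((w_before > 0) & (w_after < 0)).sum())
    neg_to_pos = int(((w_before < 0) & (w_after > 0)).sum())
    neg_mag_up = int(
        ((w_before < 0) & (w_after < 0) & (np.abs(w_after) > np.abs(w_before))).sum()
    )
    pos_mag_up = int(
        ((w_before > 0) & (w_after > 0) & (np.abs(w_after) > np.abs(w_before))).sum()
    )
    return {
        "pos_to_neg": pos_to_neg,
        "neg_to_pos": neg_to_pos,
        "neg_magnitude_increase": neg_mag_up,
        "pos_magnitude_increase": pos_mag_up,
    }
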