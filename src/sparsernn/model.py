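"""Forward computation of recurrent and feedforward-control networks.

The recurrent network unrolls h_t = phi(x_t W_in + h_{t-1} W_hh) over the T
timesteps of a sequence, starting from h_0 = 0, and reads out linearly from
the final hidden state only: logits = h_T W_out. ReLU gives nodes a firing
threshold (net input below zero produces exactly no output); tanh is the
symmetric control.
"""

from __future__ import annotations

import numpy as np

from .topology import NetworkParams

__all__ = ["forward_recurrent", "forward_feedforward", "predict"]


def _phi(x: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return np.maximum(x, 0.0)
    if activation == "tanh":
        return np.tanh(x)
    raise ValueError(f"unknown activation {activation!r}")


def forward_recurrent(
    params: NetworkParams, sequences: np.ndarray, return_trajectory: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Run the recurrence over a batch of sequences.

    Parameters
    ----------
    sequences
        Array (batch, T, d) or a single (T, d) sequence.
    return_trajectory
        If True the returned hidden array holds all T states
        (batch, T, N); otherwise only the final state (batch, N).

    Returns
    -------
    (hidden, logits) where logits is (batch, n_classes).
    """
    x = np.asarray(sequences, dtype=np.float64)
    single = x.ndim == 2
    if single:
        x = x[None]
    batch, T, d = x.shape
    if d != params.w_in.shape[0]:
        raise ValueError(
            f"input dim {d} != w_in rows {params.w_in.shape[0]}"
        )
    n = params.w_hh.shape[0]
    h = np.zeros((batch, n))
    traj = np.empty((batch, T, n)) if return_trajectory else None
    for t in range(T):
        h = _phi(x[:, t] @ params.w_in + h @ params.w_hh, params.activation)
        if traj is not None:
            traj[:, t] = h
    logits = h @ params.w_out
    hidden = traj if traj is not None else h
    if single:
        hidden, logits = hidden[0], logits[0]
    return hidden, logits


def forward_feedforward(
    params: NetworkParams, flat_inputs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-hidden-layer feedforward control on flattened inputs.

    layer1 = phi(x W_in); layer2 = phi(layer1 W_12) with the inter-layer
    weights masked at the connection probability; logits = layer2 W_out.
    Returns (layer1, layer2, logits).
    """
    x = np.asarray(flat_inputs, dtype=np.float64)
    single = x.ndim == 1
    if single:
        x = x[None]
    if x.shape[1] != params.w_in.shape[0]:
        raise ValueError(
            f"input dim {x.shape[1]} != w_in rows {params.w_in.shape[0]}"
        )
    l1 = _phi(x @ params.w_in, params.activation)
    l2 = _phi(l1 @ params.w_hh, params.activation)
    logits = l2 @ params.w_out
    if single:
        l1, l2, logits = l1[0], l2[0], logits[0]
    return l1, l2, logits


def forward(params: NetworkParams, dataset_inputs: np.ndarray) -> np.ndarray:
    """Architecture-dispatching forward pass returning logits only."""
    if params.architecture == "recurrent":
        return forward_recurrent(params, dataset_inputs)[1]
    flat = dataset_inputs.reshape(dataset_inputs.shape[0], -1)
    return forward_feedforward(params, flat)[2]


def predict(logits: np.ndarray) -> np.ndarray:
    """Argmax class prediction; ties break toward the lowest class index."""
    logits = np.asarray(logits)
    if np.isnan(logits).any():
        raise FloatingPointError("NaN logits")
    return np.argmax(logits, axis=-1)
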