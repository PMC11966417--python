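"""Network construction: connectivity masks, E/I sign assignment, weight init.

Networks have a single hidden layer of ``n_hidden`` nodes. A binary mask
decides which directed hidden-hidden (or, for the feedforward control,
layer1-to-layer2) weights exist; each admissible edge is drawn independently
with the connection probability ``p``, which for recurrent masks without
self-loops equals the expected network density D = E / [N(N-1)].

Under Dale's principle every hidden node is fixed as excitatory (+1) or
inhibitory (-1) and all its outgoing weights (hidden-hidden rows and readout
rows) carry that sign for the whole of training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ConnectivitySpec",
    "NetworkParams",
    "sample_mask",
    "network_density",
    "assign_ei",
    "init_weights",
    "matched_parameter_grid",
]

Architecture = Literal["recurrent", "feedforward_2layer"]
Activation = Literal["relu", "tanh"]


@dataclass(frozen=True)
class ConnectivitySpec:
    """All knobs defining one network architecture draw.

    Parameters
    ----------
    n_hidden
        Number of hidden-layer nodes N (>= 2). For the feedforward control
        the nodes are split 50/50 into two layers.
    connection_probability
        Probability p in [0, 1] that a directed trainable hidden-hidden
        edge exists.
    architecture
        ``"recurrent"`` (single recurrently connected hidden layer) or
        ``"feedforward_2layer"`` (control: two feedforward hidden layers).
    activation
        Hidden-node nonlinearity, ``"relu"`` or ``"tanh"``.
    dale
        If True, nodes get fixed excitatory/inhibitory identities and all
        outgoing weights keep the node's sign.
    inhibitory_fraction
        Fraction of inhibitory nodes (default 0.115, the proportion
        reported for sensory cortex). Only meaningful when ``dale``.
    inhibitory_scale
        Multiplier applied to initial inhibitory weight magnitudes
        (10 reproduces the strengthened-inhibition manipulation).
    weight_init_bound
        Half-width b of the uniform init; weights are drawn from
        U(-b, b), or magnitude U(0, b) times the node sign under Dale.
    seed
        Seed for mask, sign and weight draws.
    """

    n_hidden: int
    connection_probability: float
    architecture: Architecture = "recurrent"
    activation: Activation = "relu"
    dale: bool = False
    inhibitory_fraction: float = 0.115
    inhibitory_scale: float = 1.0
    weight_init_bound: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hidden < 2:
            raise ValueError(f"n_hidden must be >= 2, got {self.n_hidden}")
        if not 0.0 <= self.connection_probability <= 1.0:
            raise ValueError(
                f"connection_probability must be in [0, 1], got "
                f"{self.connection_probability}"
            )
        if not 0.0 <= self.inhibitory_fraction <= 1.0:
            raise ValueError(
                f"inhibitory_fraction must be in [0, 1], got "
                f"{self.inhibitory_fraction}"
            )
        if self.inhibitory_scale <= 0:
            raise ValueError("inhibitory_scale must be positive")
        if self.weight_init_bound <= 0:
            raise ValueError("weight_init_bound must be positive")
        if self.architecture not in ("recurrent", "feedforward_2layer"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.activation not in ("relu", "tanh"):
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class NetworkParams:
    """Trainable weight tensors of one network.

    ``w_hh[i, j]`` is the weight of the directed edge from hidden node i to
    hidden node j (for the feedforward control, from layer-1 node i to
    layer-2 node j); it is exactly 0 wherever the mask is 0, at all times.
    """

    w_in: np.ndarray  # input_dim x N (or input_dim x N1 for feedforward)
    w_hh: np.ndarray  # N x N masked (or N1 x N2)
    w_out: np.ndarray  # N x n_classes (or N2 x n_classes)
    architecture: Architecture = "recurrent"
    activation: Activation = "relu"

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.w_in.copy(),
            self.w_hh.copy(),
            self.w_out.copy(),
            self.architecture,
            self.activation,
        )


def sample_mask(
    n_pre: int, n_post: int, p: float, recurrent: bool, seed: int
) -> np.ndarray:
    """Sample a binary connectivity mask.

    Each admissible entry is 1 independently with probability ``p``.
    Recurrent masks are square with the diagonal excluded (no
    self-connections), so the expected density E/[N(N-1)] equals p.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"connection probability must be in [0, 1], got {p}")
    if recurrent and n_pre != n_post:
        raise ValueError("recurrent mask must be square")
    rng = np.random.default_rng(seed)
    mask = (rng.random((n_pre, n_post)) < p).astype(np.float64)
    if recurrent:
        np.fill_diagonal(mask, 0.0)
    return mask


def network_density(mask: np.ndarray) -> float:
    """Density D = E / [N(N-1)] of a square recurrent mask (no self-loops)."""
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.shape[0] != mask.shape[1]:
        raise ValueError(f"density requires a square mask, got shape {mask.shape}")
    n = mask.shape[0]
    return float(mask.sum() / (n * (n - 1)))


def assign_ei(n: int, inhibitory_fraction: float, seed: int) -> np.ndarray:
    """Assign fixed excitatory (+1) / inhibitory (-1) identities.

    Exactly ``round(inhibitory_fraction * n)`` nodes become inhibitory, at
    uniformly random positions, so the cortical 11.5% figure is honored
    deterministically rather than in expectation.
    """
    if not 0.0 <= inhibitory_fraction <= 1.0:
        raise ValueError(
            f"inhibitory_fraction must be in [0, 1], got {inhibitory_fraction}"
        )
    n_inhib = int(round(inhibitory_fraction * n))
    rng = np.random.default_rng(seed)
    signs = np.ones(n, dtype=np.float64)
    inhib_idx = rng.choice(n, size=n_inhib, replace=False)
    signs[inhib_idx] = -1.0
    return signs


def _uniform_init(rng: np.random.Generator, shape, bound: float) -> np.ndarray:
    return rng.uniform(-bound, bound, size=shape)


def init_weights(
    spec: ConnectivitySpec,
    mask: np.ndarray,
    signs: np.ndarray | None,
    input_dim: int,
    n_classes: int,
    seed: int,
) -> NetworkParams:
    """Initialize weight tensors for the given spec and mask.

    Non-Dale: every weight is drawn U(-b, b) with b = weight_init_bound.
    Dale: outgoing weights of hidden node i have magnitude U(0, b) times
    signs[i]; inhibitory magnitudes are additionally multiplied by
    ``inhibitory_scale``. The input projection has no E/I identity and uses
    the unsigned scheme. Masked hidden-hidden entries are exactly 0.
    """
    if spec.dale and signs is None:
        raise ValueError("Dale networks require a sign vector")
    rng = np.random.default_rng(seed)
    b = spec.weight_init_bound

    if spec.architecture == "recurrent":
        n = spec.n_hidden
        if mask.shape != (n, n):
            raise ValueError(f"mask shape {mask.shape} != ({n}, {n})")
        w_in = _uniform_init(rng, (input_dim, n), b)
        if spec.dale:
            assert signs is not None
            scale = np.where(signs < 0, spec.inhibitory_scale, 1.0)
            mags_hh = rng.uniform(0.0, b, size=(n, n))
            w_hh = mags_hh * (signs * scale)[:, None]
            mags_out = rng.uniform(0.0, b, size=(n, n_classes))
            w_out = mags_out * (signs * scale)[:, None]
        else:
            w_hh = _uniform_init(rng, (n, n), b)
            w_out = _uniform_init(rng, (n, n_classes), b)
        w_hh = w_hh * mask
    else:
        n1 = spec.n_hidden // 2
        n2 = spec.n_hidden - n1
        if mask.shape != (n1, n2):
            raise ValueError(f"mask shape {mask.shape} != ({n1}, {n2})")
        if spec.dale:
            raise ValueError("Dale constraint is defined for recurrent networks only")
        w_in = _uniform_init(rng, (input_dim, n1), b)
        w_hh = _uniform_init(rng, (n1, n2), b) * mask
        w_out = _uniform_init(rng, (n2, n_classes), b)

    return NetworkParams(w_in, w_hh, w_out, spec.architecture, spec.activation)


def build_network(
    spec: ConnectivitySpec, input_dim: int, n_classes: int
) -> tuple[NetworkParams, np.ndarray, np.ndarray | None]:
    """Draw (params, mask, signs) for a spec, deriving sub-seeds from spec.seed."""
    ss = np.random.SeedSequence(spec.seed)
    mask_seed, sign_seed, w_seed = [int(s) for s in ss.generate_state(3) % (2**31)]
    if spec.architecture == "recurrent":
        mask = sample_mask(
            spec.n_hidden, spec.n_hidden, spec.connection_probability, True, mask_seed
        )
    else:
        n1 = spec.n_hidden // 2
        n2 = spec.n_hidden - n1
        mask = sample_mask(n1, n2, spec.connection_probability, False, mask_seed)
    signs = (
        assign_ei(spec.n_hidden, spec.inhibitory_fraction, sign_seed)
        if spec.dale
        else None
    )
    params = init_weights(spec, mask, signs, input_dim, n_classes, w_seed)
    return params, mask, signs


def matched_parameter_grid(
    target_edge_count: int, candidate_p: Sequence[float]
) -> list[tuple[int, float]]:
    """Find (n, p) pairs with a fixed hidden-layer weight budget.

    For each candidate connection probability, returns the network size n
    minimizing |n(n-1)p - target_edge_count|, enabling comparisons between
    larger-sparse and smaller-dense networks with the same number of
    trainable hidden weights.
    """
    if target_edge_count < 1:
        raise ValueError("target_edge_count must be >= 1")
    if len(candidate_p) == 0:
        raise ValueError("candidate_p must be non-empty")
    out: list[tuple[int, float]] = []
    for p in candidate_p:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"candidate probabilities must be in (0, 1], got {p}")
        # expected edges n(n-1)p grows monotonically in n; search around root
        n_star = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * target_edge_count / p))
        best_n, best_err = 2, float("inf")
        lo = max(2, int(n_star) - 2)
        for n in range(lo, int(n_star) + 3):
            err = abs(n * (n - 1) * p - target_edge_count)
            # ties broken toward the larger network
            if err <= best_err:
                best_n, best_err = n, err
        out.append((best_n, p))
    return out
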