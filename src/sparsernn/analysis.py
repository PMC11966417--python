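"""Representation and training-dynamics analyses.

All representation analyses operate on the final-timestep hidden
activations — the only vector the linear readout sees. They quantify how
distributed the input code is (fraction of nonzero activations, pairwise
mutual information), how redundant it is at initialization (pairwise Pearson
correlations), and how robust it is to silencing random subsets of nodes at
test time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.feature_selection import mutual_info_regression

from .encoding import SequenceDataset
from .model import forward_recurrent, predict
from .topology import NetworkParams

__all__ = [
    "ActivationRecord",
    "DelayResult",
    "record_activations",
    "nonzero_fraction",
    "pairwise_mutual_information",
    "init_correlations",
    "dropout_robustness",
    "training_delay",
    "activation_magnitude_summary",
]


@dataclass
class ActivationRecord:
    """Final-timestep hidden activations (n_samples x N) plus metadata."""

    activations: np.ndarray
    meta: dict | None = None

    def __post_init__(self) -> None:
        self.activations = np.asarray(self.activations, dtype=np.float64)
        if self.activations.ndim != 2:
            raise ValueError("activations must be (n_samples, N)")
        if self.activations.size == 0:
            raise ValueError("empty activation record")


@dataclass(frozen=True)
class DelayResult:
    """Training delay: epochs at chance before performance exceeds it."""

    delay_epochs: int | None  # None encodes "never"
    chance_level: float
    margin: float

    @property
    def never(self) -> bool:
        return self.delay_epochs is None


def record_activations(
    params: NetworkParams,
    dataset: SequenceDataset,
    batch_size: int = 1000,
    meta: dict | None = None,
) -> ActivationRecord:
    """Final-timestep hidden activations in response to every sample."""
    outs = []
    for start in range(0, len(dataset), batch_size):
        h, _ = forward_recurrent(params, dataset.sequences[start:start + batch_size])
        outs.append(h)
    return ActivationRecord(np.vstack(outs), meta)


def nonzero_fraction(record: ActivationRecord) -> dict:
    """Per-sample fraction of hidden nodes sending a strictly nonzero
    (here: strictly positive under ReLU) activation to the readout."""
    fracs = (record.activations > 0).mean(axis=1)
    return {
        "per_sample": fracs,
        "mean": float(fracs.mean()),
        "sd": float(fracs.std(ddof=1)) if len(fracs) > 1 else 0.0,
    }


def _sample_pairs(
    n_nodes: int, n_pairs: int, rng: np.random.Generator
) -> np.ndarray:
    """Distinct unordered node pairs sampled without replacement."""
    total = n_nodes * (n_nodes - 1) // 2
    if n_pairs >= total:
        iu = np.triu_indices(n_nodes, k=1)
        return np.column_stack(iu)
    # draw linear indices into the strict upper triangle
    flat = rng.choice(total, size=n_pairs, replace=False)
    i = (
        n_nodes - 2
        - np.floor(
            np.sqrt(-8.0 * flat + 4.0 * n_nodes * (n_nodes - 1) - 7) / 2.0 - 0.5
        )
    ).astype(np.int64)
    j = (flat + i + 1 - n_nodes * (n_nodes - 1) // 2
         + (n_nodes - i) * (n_nodes - i - 1) // 2).astype(np.int64)
    return np.column_stack([i, j])


def pairwise_mutual_information(
    record: ActivationRecord,
    n_pairs: int = 10_000,
    k_neighbors: int = 3,
    seed: int = 0,
) -> dict:
    """k-NN (Kraskov-type) mutual information between random node pairs.

    Pairs of distinct hidden nodes are sampled without replacement; MI is
    estimated per pair from the responses to the full probe/test set, in
    nats. A pair containing a constant-activation node has MI defined as 0;
    small negative estimates (estimator jitter) are clipped to 0 and
    counted.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    acts = record.activations
    rng = np.random.default_rng(seed)
    pairs = _sample_pairs(acts.shape[1], n_pairs, rng)
    constant = np.ptp(acts, axis=0) == 0.0
    mi = np.zeros(len(pairs))
    n_clipped = 0
    for idx, (i, j) in enumerate(pairs):
        if constant[i] or constant[j]:
            continue
        est = mutual_info_regression(
            acts[:, [i]],
            acts[:, j],
            n_neighbors=k_neighbors,
            random_state=int(rng.integers(2**31)),
        )[0]
        if est < 0:
            n_clipped += 1
            est = 0.0
        mi[idx] = est
    return {
        "pairs": pairs,
        "mi": mi,
        "mean": float(mi.mean()),
        "sd": float(mi.std(ddof=1)) if len(mi) > 1 else 0.0,
        "n_clipped": n_clipped,
    }


def init_correlations(
    params: NetworkParams,
    probe_set: SequenceDataset,
    n_pairs: int | None = 10_000,
    seed: int = 0,
) -> dict:
    """Pairwise Pearson R between node activations on a probe set.

    Intended for untrained networks (the redundancy-at-initialization
    analysis). Constant-activation nodes are excluded and their count
    reported; pairs are subsampled (seeded) when the full set is infeasible.
    """
    record = record_activations(params, probe_set)
    acts = record.activations
    varying = np.flatnonzero(np.ptp(acts, axis=0) > 0)
    n_constant = acts.shape[1] - len(varying)
    if len(varying) < 2:
        raise ValueError("fewer than 2 hidden nodes vary across the probe set")
    acts = acts[:, varying]
    rng = np.random.default_rng(seed)
    if n_pairs is None:
        pairs = np.column_stack(np.triu_indices(acts.shape[1], k=1))
    else:
        pairs = _sample_pairs(acts.shape[1], n_pairs, rng)
    centered = acts - acts.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    r = (centered[:, pairs[:, 0]] * centered[:, pairs[:, 1]]).sum(axis=0) / (
        norms[pairs[:, 0]] * norms[pairs[:, 1]]
    )
    r = np.clip(r, -1.0, 1.0)
    return {
        "r": r,
        "mean_abs": float(np.abs(r).mean()),
        "mean": float(r.mean()),
        "n_constant_excluded": int(n_constant),
    }


def dropout_robustness(
    params: NetworkParams,
    test_set: SequenceDataset,
    fractions: list[float],
    n_repeats: int = 1,
    seed: int = 0,
    batch_size: int = 1000,
) -> dict:
    """Test-time dropout: silence a random fraction of hidden outputs.

    For every test sample (independently, resampled per sample and per
    repeat) a random subset of round(fraction * N) nodes has its
    final-timestep output set to zero before the readout; surviving
    activations are not rescaled. Returns accuracy per fraction, averaged
    over repeats.
    """
    for f in fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"dropout fraction must be in [0, 1], got {f}")
    h_all = record_activations(params, test_set, batch_size).activations
    n_samples, n_nodes = h_all.shape
    rng = np.random.default_rng(seed)
    accuracies = {}
    for f in fractions:
        n_drop = int(round(f * n_nodes))
        accs = []
        for _ in range(n_repeats):
            if n_drop == 0:
                h = h_all
            else:
                h = h_all.copy()
                # per-sample independent subset of exactly n_drop nodes
                scores = rng.random((n_samples, n_nodes))
                drop = np.argpartition(scores, n_drop - 1, axis=1)[:, :n_drop]
                np.put_along_axis(h, drop, 0.0, axis=1)
            preds = predict(h @ params.w_out)
            accs.append(float((preds == test_set.labels).mean()))
        # degenerate fractions (0 and 1) give identical repeats; keep the
        # value bit-exact rather than routed through a floating mean
        mean = accs[0] if len(set(accs)) == 1 else float(np.mean(accs))
        accuracies[f] = {
            "mean": mean,
            "sd": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        }
    return accuracies


def training_delay(
    test_accuracy: list[float] | np.ndarray,
    n_classes: int,
    margin: float = 0.02,
    sustained: bool = False,
) -> DelayResult:
    """Epochs before test accuracy exceeds chance level.

    Returns the smallest 1-based epoch index whose accuracy exceeds
    1/n_classes + margin (with ``sustained``, the crossing must hold for two
    consecutive epochs); ``delay_epochs`` is None ("never") if no epoch
    qualifies.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    acc = np.asarray(test_accuracy, dtype=np.float64)
    chance = 1.0 / n_classes
    above = acc > chance + margin
    for e in range(len(acc)):
        if above[e] and (not sustained or (e + 1 < len(acc) and above[e + 1])):
            return DelayResult(e + 1, chance, margin)
    return DelayResult(None, chance, margin)


def activation_magnitude_summary(
    record: ActivationRecord, n_bins: int = 50
) -> dict:
    """Histogram and moments of the nonzero activations sent to the readout."""
    nonzero = record.activations[record.activations != 0]
    if nonzero.size == 0:
        return {
            "hist": np.array([]), "bin_edges": np.array([]),
            "mean": 0.0, "sd": 0.0, "n_nonzero": 0,
        }
    hist, edges = np.histogram(nonzero, bins=n_bins)
    return {
        "hist": hist,
        "bin_edges": edges,
        "mean": float(nonzero.mean()),
        "sd": float(nonzero.std(ddof=1)) if nonzero.size > 1 else 0.0,
        "n_nonzero": int(nonzero.size),
    }
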