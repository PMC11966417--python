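"""Synthetic sequence-classification tasks with row-scanned-image structure.

The generator stands in for row-encoded image benchmarks: each class is
defined by a fixed non-negative spatiotemporal template (T x d, mostly
zero, like a dark digit image), and each sample is the template temporally
jittered, corrupted with additive Gaussian noise, and clipped to [0, 1].
Classes are exactly balanced and train/test draws are disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import SequenceDataset

__all__ = ["SyntheticTaskSpec", "make_task", "make_probe_inputs"]


@dataclass(frozen=True)
class SyntheticTaskSpec:
    """Parameters of one synthetic task draw.

    Defaults mirror a desk-scale row-scanned digit benchmark: 10 classes of
    28x28 non-negative patterns with 30% nonzero template entries
    (mostly-dark images), additive noise sd 0.1 and ±1-step temporal jitter,
    200 training and 100 test examples per class.
    """

    n_classes: int = 10
    seq_len: int = 28
    input_dim: int = 28
    n_train: int = 2000
    n_test: int = 1000
    template_sparsity: float = 0.3
    noise_sd: float = 0.1
    jitter: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.seq_len < 1 or self.input_dim < 1:
            raise ValueError("seq_len and input_dim must be >= 1")
        if not 0.0 <= self.template_sparsity <= 1.0:
            raise ValueError("template_sparsity must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        if self.n_train % self.n_classes or self.n_test % self.n_classes:
            raise ValueError("n_train and n_test must be divisible by n_classes")


def _class_templates(spec: SyntheticTaskSpec, rng: np.random.Generator) -> np.ndarray:
    """One fixed (T, d) template per class: sparse, non-negative, in [0, 1]."""
    shape = (spec.n_classes, spec.seq_len, spec.input_dim)
    support = rng.random(shape) < spec.template_sparsity
    values = rng.uniform(0.3, 1.0, size=shape)  # clearly above the noise floor
    return np.where(support, values, 0.0)


def _draw_samples(
    templates: np.ndarray,
    n_per_class: int,
    spec: SyntheticTaskSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    n_classes, T, d = templates.shape
    n_total = n_per_class * n_classes
    labels = np.repeat(np.arange(n_classes), n_per_class)
    seqs = np.empty((n_total, T, d))
    for s in range(n_total):
        base = templates[labels[s]]
        if spec.jitter > 0:
            shift = int(rng.integers(-spec.jitter, spec.jitter + 1))
            base = np.roll(base, shift, axis=0)
        seqs[s] = base + rng.normal(0.0, spec.noise_sd, size=(T, d))
    np.clip(seqs, 0.0, 1.0, out=seqs)
    order = rng.permutation(n_total)
    return seqs[order], labels[order]


def make_task(spec: SyntheticTaskSpec) -> tuple[SequenceDataset, SequenceDataset]:
    """Generate (train, test) datasets for a synthetic task spec.

    Templates are drawn once per spec; train and test samples are
    independent draws around the same templates, so the task is solvable by
    any classifier that recovers the class templates.
    """
    ss = np.random.SeedSequence(spec.seed)
    tmpl_rng, train_rng, test_rng = [np.random.default_rng(s) for s in ss.spawn(3)]
    templates = _class_templates(spec, tmpl_rng)
    train = SequenceDataset(
        *_draw_samples(templates, spec.n_train // spec.n_classes, spec, train_rng),
        n_classes=spec.n_classes, split="train",
    )
    test = SequenceDataset(
        *_draw_samples(templates, spec.n_test // spec.n_classes, spec, test_rng),
        n_classes=spec.n_classes, split="test",
    )
    return train, test


def make_probe_inputs(n: int, T: int, d: int, seed: int) -> SequenceDataset:
    """Unstructured probe stimuli: i.i.d. uniform [0, 1] sequences.

    Used to probe untrained networks (initialization correlations, E/I
    imbalance); labels are all 0 and carry no meaning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    seqs = rng.random((n, T, d))
    return SequenceDataset(seqs, np.zeros(n, dtype=np.int64), n_classes=1,
                           split="probe")
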