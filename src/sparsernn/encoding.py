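"""Sequence encoding: images and timeseries to time-major network input.

Recurrent networks consume each image as a time series, one row of pixel
values per timestep: a 28x28 grayscale image becomes T=28 steps of d=28
inputs, a 32x32 RGB image T=32 steps of d=96 (three interleaved channel
values per pixel). Intensities are scaled to [0, 1].
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SequenceDataset",
    "image_to_sequence",
    "reduce_training_set",
    "load_mnist_idx",
]


@dataclass
class SequenceDataset:
    """Time-major input sequences with integer class labels.

    ``sequences`` has shape (n_samples, T, d); ``labels`` take values in
    [0, n_classes).
    """

    sequences: np.ndarray
    labels: np.ndarray
    n_classes: int
    split: str = "train"

    def __post_init__(self) -> None:
        self.sequences = np.asarray(self.sequences, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.sequences.ndim != 3:
            raise ValueError(
                f"sequences must be (n_samples, T, d), got {self.sequences.shape}"
            )
        if len(self.labels) != len(self.sequences):
            raise ValueError("labels and sequences disagree in length")
        if len(self.labels) and (
            self.labels.min() < 0 or self.labels.max() >= self.n_classes
        ):
            raise ValueError("labels outside [0, n_classes)")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def seq_len(self) -> int:
        return self.sequences.shape[1]

    @property
    def input_dim(self) -> int:
        return self.sequences.shape[2]

    def flat_inputs(self) -> np.ndarray:
        """Flatten sequences to (n_samples, T*d) for feedforward networks."""
        return self.sequences.reshape(len(self), -1)


def image_to_sequence(image: np.ndarray, intensity_max: float = 255.0) -> np.ndarray:
    """Encode one image as a row-scanned sequence.

    A (H, W) grayscale image yields a (H, W) sequence (T=H, d=W); a
    (H, W, 3) RGB image a (H, W*3) sequence with per-pixel (r, g, b)
    interleaving. Values are divided by ``intensity_max`` to land in [0, 1];
    pass 1.0 for already-normalized input.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        seq = image
    elif image.ndim == 3:
        if image.shape[2] not in (1, 3):
            raise ValueError(f"unsupported channel count {image.shape[2]}")
        seq = image.reshape(image.shape[0], -1)
    else:
        raise ValueError(f"image must be 2-D or 3-D, got shape {image.shape}")
    return seq / intensity_max


def images_to_dataset(
    images: np.ndarray,
    labels: np.ndarray,
    n_classes: int,
    split: str = "train",
    intensity_max: float = 255.0,
) -> SequenceDataset:
    """Row-encode a stack of images (n, H, W[, C]) into a SequenceDataset."""
    seqs = np.stack([image_to_sequence(im, intensity_max) for im in images])
    return SequenceDataset(seqs, labels, n_classes, split)


def reduce_training_set(
    dataset: SequenceDataset, per_class: int, seed: int
) -> SequenceDataset:
    """Subsample a label-stratified training set: ``per_class`` examples per
    class, drawn without replacement. Used for data-limited training; the
    test split is never reduced."""
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for c in range(dataset.n_classes):
        idx = np.flatnonzero(dataset.labels == c)
        if len(idx) < per_class:
            raise ValueError(
                f"class {c} has only {len(idx)} examples, need {per_class}"
            )
        chosen.append(rng.choice(idx, size=per_class, replace=False))
    order = rng.permutation(np.concatenate(chosen))
    return SequenceDataset(
        dataset.sequences[order], dataset.labels[order], dataset.n_classes,
        dataset.split,
    )


def _read_idx(path: Path) -> np.ndarray:
    """Parse one file in the IDX format used by the MNIST distribution."""
    data = path.read_bytes()
    if len(data) < 4:
        raise ValueError(f"{path}: truncated IDX header")
    zero1, zero2, dtype_code, ndim = struct.unpack(">BBBB", data[:4])
    if zero1 != 0 or zero2 != 0:
        raise ValueError(f"{path}: bad IDX magic number")
    dtypes = {0x08: np.uint8, 0x09: np.int8, 0x0B: np.dtype(">i2"),
              0x0C: np.dtype(">i4"), 0x0D: np.dtype(">f4"), 0x0E: np.dtype(">f8")}
    if dtype_code not in dtypes:
        raise ValueError(f"{path}: unknown IDX dtype 0x{dtype_code:02x}")
    header_len = 4 + 4 * ndim
    dims = struct.unpack(f">{ndim}I", data[4:header_len])
    arr = np.frombuffer(data, dtype=dtypes[dtype_code], offset=header_len)
    expected = int(np.prod(dims))
    if arr.size != expected:
        raise ValueError(f"{path}: expected {expected} elements, found {arr.size}")
    return arr.reshape(dims)


def load_mnist_idx(
    images_path: str | Path,
    labels_path: str | Path,
    split: str = "train",
) -> SequenceDataset:
    """Load an MNIST-style IDX image/label file pair as a row-encoded
    SequenceDataset (28 timesteps of 28 inputs, intensities in [0, 1])."""
    images = _read_idx(Path(images_path))
    labels = _read_idx(Path(labels_path))
    if images.ndim != 3:
        raise ValueError(f"expected 3-D image tensor, got shape {images.shape}")
    if len(images) != len(labels):
        raise ValueError("image and label files disagree in sample count")
    return SequenceDataset(
        images.astype(np.float64) / 255.0,
        labels.astype(np.int64),
        n_classes=int(labels.max()) + 1,
        split=split,
    )
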