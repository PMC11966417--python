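"""HDF5 persistence for network checkpoints and sequence datasets."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np

from .encoding import SequenceDataset
from .topology import ConnectivitySpec, NetworkParams

__all__ = [
    "save_checkpoint",
    "load_checkpoint",
    "save_dataset",
    "load_dataset",
]


def save_checkpoint(
    path: str | Path,
    spec: ConnectivitySpec,
    params: NetworkParams,
    mask: np.ndarray,
    signs: np.ndarray | None,
    run_id: str = "run0",
) -> None:
    """Store spec, mask, signs and weights under one run-id group."""
    with h5py.File(path, "a") as f:
        if run_id in f:
            del f[run_id]
        g = f.create_group(run_id)
        for key, value in asdict(spec).items():
            g.attrs[key] = value
        g.create_dataset("mask", data=mask, compression="gzip")
        if signs is not None:
            g.create_dataset("signs", data=signs)
        g.create_dataset("w_in", data=params.w_in, compression="gzip")
        g.create_dataset("w_hh", data=params.w_hh, compression="gzip")
        g.create_dataset("w_out", data=params.w_out, compression="gzip")


def load_checkpoint(
    path: str | Path, run_id: str = "run0"
) -> tuple[ConnectivitySpec, NetworkParams, np.ndarray, np.ndarray | None]:
    with h5py.File(path, "r") as f:
        g = f[run_id]
        attrs = {k: v for k, v in g.attrs.items()}
        spec = ConnectivitySpec(
            n_hidden=int(attrs["n_hidden"]),
            connection_probability=float(attrs["connection_probability"]),
            architecture=str(attrs["architecture"]),
            activation=str(attrs["activation"]),
            dale=bool(attrs["dale"]),
            inhibitory_fraction=float(attrs["inhibitory_fraction"]),
            inhibitory_scale=float(attrs["inhibitory_scale"]),
            weight_init_bound=float(attrs["weight_init_bound"]),
            seed=int(attrs["seed"]),
        )
        mask = g["mask"][:]
        signs = g["signs"][:] if "signs" in g else None
        params = NetworkParams(
            g["w_in"][:], g["w_hh"][:], g["w_out"][:],
            spec.architecture, spec.activation,
        )
    return spec, params, mask, signs


def save_dataset(path: str | Path, dataset: SequenceDataset) -> None:
    with h5py.File(path, "a") as f:
        if dataset.split in f:
            del f[dataset.split]
        g = f.create_group(dataset.split)
        g.attrs["n_classes"] = dataset.n_classes
        g.create_dataset("sequences", data=dataset.sequences, compression="gzip")
        g.create_dataset("labels", data=dataset.labels)


def load_dataset(path: str | Path, split: str) -> SequenceDataset:
    with h5py.File(path, "r") as f:
        g = f[split]
        return SequenceDataset(
            g["sequences"][:], g["labels"][:], int(g.attrs["n_classes"]), split
        )
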