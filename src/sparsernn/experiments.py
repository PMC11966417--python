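"""Experiment orchestration: size x sparsity grids and Dale delay curves.

Each grid point is one ConnectivitySpec trained with ``n_seeds`` independent
initializations (connectivity, signs and weights all redrawn per seed);
results are reported per row and summarized as mean ± standard deviation
per spec. The desk-scale preset keeps networks small enough for a single
CPU; the full-size grids of the original study (10,000–24,000 nodes) are
the same code at larger settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .analysis import training_delay
from .encoding import SequenceDataset
from .topology import ConnectivitySpec, build_network, network_density
from .training import TrainingConfig, train

__all__ = ["ExperimentGrid", "run_grid", "delay_vs_size", "summarize_grid"]


@dataclass
class ExperimentGrid:
    """A set of network specs to train repeatedly on one dataset."""

    specs: list[ConnectivitySpec]
    n_seeds: int = 10
    training: TrainingConfig = field(default_factory=TrainingConfig)
    delay_margin: float = 0.02

    def __post_init__(self) -> None:
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")


def _run_one(
    spec: ConnectivitySpec,
    seed: int,
    train_set: SequenceDataset,
    test_set: SequenceDataset,
    grid: ExperimentGrid,
) -> dict:
    spec_s = replace(spec, seed=seed)
    params, mask, signs = build_network(
        spec_s, train_set.input_dim, train_set.n_classes
    )
    cfg = replace(grid.training, seed=seed)
    _, trace = train(params, mask, signs, train_set, test_set, cfg)
    delay = training_delay(
        trace.test_accuracy, test_set.n_classes, grid.delay_margin
    )
    row = {
        "n_hidden": spec.n_hidden,
        "p": spec.connection_probability,
        "architecture": spec.architecture,
        "activation": spec.activation,
        "dale": spec.dale,
        "inhibitory_fraction": spec.inhibitory_fraction,
        "seed": seed,
        "single_epoch_accuracy": trace.test_accuracy[0],
        "best_accuracy": max(trace.test_accuracy),
        "final_accuracy": trace.test_accuracy[-1],
        "epochs_run": len(trace),
        "delay_epochs": np.nan if delay.never else delay.delay_epochs,
        "delay_never": delay.never,
    }
    if spec.architecture == "recurrent":
        row["density"] = network_density(mask)
    return row


def run_grid(
    grid: ExperimentGrid,
    train_set: SequenceDataset,
    test_set: SequenceDataset,
) -> pd.DataFrame:
    """Train every (spec, seed) combination; one result row each.

    A failed run is recorded (``error`` column) and the grid continues."""
    rows = []
    for spec in grid.specs:
        for seed in range(grid.n_seeds):
            try:
                rows.append(_run_one(spec, seed, train_set, test_set, grid))
            except Exception as exc:  # noqa: BLE001 - grid must survive a bad run
                rows.append(
                    {
                        "n_hidden": spec.n_hidden,
                        "p": spec.connection_probability,
                        "dale": spec.dale,
                        "seed": seed,
                        "error": f"{type(exc).__name__}: {exc}",
                    }
                )
    return pd.DataFrame(rows)


def summarize_grid(results: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sd per spec over seeds, for the numeric result columns."""
    metrics = [
        c
        for c in ("single_epoch_accuracy", "best_accuracy", "delay_epochs")
        if c in results.columns
    ]
    ok = results[results.get("error").isna()] if "error" in results else results
    return ok.groupby(["n_hidden", "p", "dale"])[metrics].agg(["mean", "std"])


def delay_vs_size(
    sizes: list[int],
    p_values: list[float],
    train_set: SequenceDataset,
    test_set: SequenceDataset,
    base_spec: ConnectivitySpec,
    training: TrainingConfig,
    n_seeds: int = 3,
    margin: float = 0.02,
) -> pd.DataFrame:
    """Training delay as a function of network size, per connection
    probability, for Dale-constrained networks.

    Training stops as soon as a network first exceeds chance + margin (the
    delay is then determined), capped at ``training.max_epochs``; a network
    that never crosses within the cap is recorded as delay >= max_epochs
    (``delay_never`` True)."""
    if not base_spec.dale:
        raise ValueError("delay_vs_size expects a Dale-constrained base spec")
    cfg = replace(training, stop_above_chance_margin=margin)
    rows = []
    for n in sizes:
        for p in p_values:
            spec = replace(base_spec, n_hidden=n, connection_probability=p)
            grid = ExperimentGrid(
                [spec], n_seeds=n_seeds, training=cfg, delay_margin=margin
            )
            rows.append(run_grid(grid, train_set, test_set))
    return pd.concat(rows, ignore_index=True)
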