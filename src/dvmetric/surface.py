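"""DVM/accuracy surfaces over (sample size x feature count) grids.

``compute_surface`` subsamples a dataset to every (n, p) grid point
(rows and feature columns drawn without replacement, seeded per
replicate), computes the DVM — and, for supervised models, the paired
held-out accuracy on the same splits — and aggregates over replicates.
Failures in individual cells (e.g. degenerate clustering at tiny n) are
recorded per cell and do not abort the sweep.

The regularizer of every cell is normalized at the largest grid point, so
a 1 x 1 grid reproduces a direct ``compute_dvm`` call exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import LabeledDataset
from .dvm import (FidelityConfig, _ci95, compute_dvm,
                  fidelity_supervised)
from .exceptions import BoundsError, ConfigError, DVMError
from .models import SUPERVISED, make_model

__all__ = ["CellResult", "SurfaceGrid", "compute_surface",
           "evaluate_accuracy", "surface_seeds", "write_results"]

logger = logging.getLogger("dvmetric")


@dataclass
class CellResult:
    """Aggregated DVM/accuracy of one (n, p) grid cell."""

    n: int
    p: int
    dvm_mean: float = np.nan
    dvm_ci95: tuple = (np.nan, np.nan)
    fidelity_mean: float = np.nan
    accuracy_mean: float | None = None
    accuracy_ci95: tuple | None = None
    per_replicate_dvm: list = field(default_factory=list)
    per_replicate_accuracy: list = field(default_factory=list)
    results: list = field(default_factory=list)
    error: str | None = None


@dataclass
class SurfaceGrid:
    """Per-cell DVM/accuracy records over an (n, p) grid."""

    n_values: list
    p_values: list
    cells: dict  # (n, p) -> CellResult
    model_id: str
    descriptor: str
    seed: int
    replicates: int

    def cell(self, n: int, p: int) -> CellResult:
        return self.cells[(int(n), int(p))]

    def to_tidy_frame(self) -> pd.DataFrame:
        """One row per (cell, replicate)."""
        rows = []
        for (n, p), cell in self.cells.items():
            if cell.error is not None:
                rows.append({"n": n, "p": p, "replicate": -1,
                             "dvm": np.nan, "fidelity": np.nan,
                             "accuracy": np.nan, "error": cell.error})
                continue
            for k, res in enumerate(cell.results):
                rows.append({"n": n, "p": p, "replicate": k,
                             "dvm": res.dvm, "fidelity": res.fidelity,
                             "accuracy": res.accuracy, "error": None})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        cells = []
        for (n, p), cell in self.cells.items():
            cells.append({
                "n": n, "p": p, "dvm_mean": cell.dvm_mean,
                "dvm_ci95": list(cell.dvm_ci95),
                "fidelity_mean": cell.fidelity_mean,
                "accuracy_mean": cell.accuracy_mean,
                "per_replicate_dvm": cell.per_replicate_dvm,
                "per_replicate_accuracy": cell.per_replicate_accuracy,
                "error": cell.error,
            })
        return {"model": self.model_id, "descriptor": self.descriptor,
                "seed": self.seed, "replicates": self.replicates,
                "n_values": list(self.n_values),
                "p_values": list(self.p_values), "cells": cells}

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text

    def plot(self, metric: str = "dvm", ax=None):
        """Cross-section line plots of a metric against n (one line per p)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for p in self.p_values:
            xs, ys, los, his = [], [], [], []
            for n in self.n_values:
                cell = self.cell(n, p)
                if cell.error is not None:
                    continue
                xs.append(n)
                if metric == "accuracy":
                    ys.append(cell.accuracy_mean)
                    lo, hi = cell.accuracy_ci95 or (np.nan, np.nan)
                else:
                    ys.append(cell.dvm_mean)
                    lo, hi = cell.dvm_ci95
                los.append(lo)
                his.append(hi)
            ax.plot(xs, ys, marker="o", label=f"p={p}")
            ax.fill_between(xs, los, his, alpha=0.2)
        ax.set_xlabel("sample size n")
        ax.set_ylabel(metric)
        ax.legend()
        return ax


def surface_seeds(seed: int, n_cells: int, replicates: int) -> np.ndarray:
    """Deterministic per-(cell, replicate) seeds, row-major cell order."""
    state = np.random.SeedSequence(seed).generate_state(
        n_cells * replicates) % (2**31)
    return state.reshape(n_cells, replicates)


def compute_surface(data: LabeledDataset, model, n_values, p_values,
                    cfg: FidelityConfig | None = None, lam: float = 0.01,
                    replicates: int = 5, seed: int = 0,
                    descriptor: str = "") -> SurfaceGrid:
    """DVM (and paired accuracy) over an (n, p) subsampling grid."""
    cfg = cfg or FidelityConfig()
    model = make_model(model)
    n_values = sorted(int(v) for v in n_values)
    p_values = sorted(int(v) for v in p_values)
    if n_values[-1] > data.n or p_values[-1] > data.p:
        raise BoundsError(
            f"grid maximum ({n_values[-1]}, {p_values[-1]}) exceeds dataset "
            f"dimensions ({data.n}, {data.p})")
    reference = (n_values[-1], p_values[-1])
    cells_idx = [(n, p) for n in n_values for p in p_values]
    seeds = surface_seeds(seed, len(cells_idx), replicates)

    cells = {}
    for ci, (n, p) in enumerate(cells_idx):
        cell = CellResult(n=n, p=p)
        try:
            for k in range(replicates):
                s = int(seeds[ci, k])
                sub = data.subsample(n=n, p=p, seed=s)
                res = compute_dvm(sub, model, cfg, lam, reference=reference,
                                  seed=s)
                cell.results.append(res)
                cell.per_replicate_dvm.append(res.dvm)
                if res.accuracy is not None:
                    cell.per_replicate_accuracy.append(res.accuracy)
            dvms = np.asarray(cell.per_replicate_dvm)
            cell.dvm_mean = float(dvms.mean())
            cell.fidelity_mean = float(np.mean(
                [r.fidelity for r in cell.results]))
            cell.dvm_ci95 = (_ci95(dvms) if len(dvms) > 1
                             else cell.results[0].ci95)
            if cell.per_replicate_accuracy:
                accs = np.asarray(cell.per_replicate_accuracy)
                cell.accuracy_mean = float(accs.mean())
                cell.accuracy_ci95 = (_ci95(accs) if len(accs) > 1
                                      else cell.results[0].accuracy_ci95)
        except DVMError as exc:
            cell.error = f"{type(exc).__name__}: {exc}"
            logger.warning("cell (n=%d, p=%d) failed: %s", n, p, cell.error)
        logger.info("cell (n=%d, p=%d): dvm=%.4f acc=%s", n, p,
                    cell.dvm_mean, cell.accuracy_mean)
        cells[(n, p)] = cell
    return SurfaceGrid(n_values, p_values, cells, model.model_id,
                       descriptor, int(seed), int(replicates))


def evaluate_accuracy(data: LabeledDataset, model,
                      cfg: FidelityConfig | None = None, seed: int = 0
                      ) -> tuple[float, tuple[float, float]]:
    """Mean held-out accuracy (with 95% CI) over the fidelity splits.

    Uses exactly the same split and model-seed derivation as the fidelity
    computation with the same seed, so the two metrics are paired.
    """
    cfg = cfg or FidelityConfig()
    model = make_model(model)
    if model.mode != SUPERVISED:
        raise ConfigError("accuracy is defined for supervised models only")
    if data.label_kind != "categorical":
        raise ConfigError("accuracy is defined for categorical labels")
    parts = fidelity_supervised(data, model, cfg, seed, compute_mi=False)
    accs = parts.per_split_accuracy
    return float(np.mean(accs)), _ci95(accs)


def write_results(obj, path) -> Path:
    """Write a DVMResult, SelectionTrace or SurfaceGrid to JSON (always)
    and, for traces and grids, a tidy CSV next to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    obj.to_json(path.with_suffix(".json"))
    if isinstance(obj, SurfaceGrid):
        obj.to_tidy_frame().to_csv(path.with_suffix(".csv"), index=False)
    elif hasattr(obj, "to_csv"):
        obj.to_csv(path.with_suffix(".csv"))
    return path.with_suffix(".json")
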