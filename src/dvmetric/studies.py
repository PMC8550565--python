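"""Reference study protocols for validating the Data Value Metric.

These functions bundle the package's standard simulation experiments:

* ``blob_signal_study`` — random-forest DVM and held-out accuracy on the
  5-center Gaussian blob classification data across (n, p) cells and
  replicate data draws;
* ``feature_selection_benchmark`` — forward selection on the 4-cluster
  20-dimensional benchmark;
* ``fidelity_bound_sweep`` — exhaustive check of the fidelity upper bound
  on small discrete joint tables with deterministic representations.

Each protocol is deterministic given its seed(s) and returns plain
data structures, so the same entry points serve scripted reproduction
runs and the test suite.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd

from .datasets import (
    BlobConfig,
    ClusterSquareConfig,
    make_blobs_dataset,
    make_cluster_square_dataset,
)
from .dvm import FidelityConfig, compute_dvm, fidelity_exact
from .selection import SelectionTrace, select_features

__all__ = ["blob_signal_study", "feature_selection_benchmark",
           "fidelity_bound_sweep"]


def blob_signal_study(seeds, cells=((2000, 800),), *, cluster_std=20.0,
                      n=2000, p=800, centers=5, model="random_forest",
                      beta=0.1, lam=0.01, n_splits=10) -> pd.DataFrame:
    """Random-forest DVM/accuracy on blob data at the requested grid cells.

    For each replicate seed a fresh dataset is drawn; each (n_cell,
    p_cell) is a seeded row/column subsample scored by ``compute_dvm``
    with the regularizer normalized at the full (n, p) generation size.
    Returns one row per (seed, cell) with dvm, fidelity and accuracy.
    """
    cfg = FidelityConfig(beta=beta, n_splits=n_splits)
    rows = []
    for seed in seeds:
        ds = make_blobs_dataset(BlobConfig(n=n, p=p, centers=centers,
                                           cluster_std=cluster_std,
                                           seed=int(seed)))
        sub_seeds = np.random.SeedSequence(int(seed)).generate_state(
            len(cells)) % (2**31)
        for (nc, pc), s in zip(cells, sub_seeds):
            sub = ds.subsample(n=int(nc), p=int(pc), seed=int(s))
            res = compute_dvm(sub, model, cfg, lam, reference=(n, p),
                              seed=int(s))
            rows.append({"seed": int(seed), "n": int(nc), "p": int(pc),
                         "dvm": res.dvm, "fidelity": res.fidelity,
                         "accuracy": res.accuracy,
                         "regularizer": res.regularizer})
    return pd.DataFrame(rows)


def feature_selection_benchmark(seeds, *, n=1000, d=20, r=15,
                                cluster_std=0.2, model="decision_tree",
                                beta=0.1, lam=0.01, n_splits=10
                                ) -> list[SelectionTrace]:
    """Forward selection traces on the 4-cluster unit-square benchmark.

    A decision tree is the default scoring model: its fit cost is tiny,
    which matters because each of the r steps scores every remaining
    candidate feature on all M splits.
    """
    cfg = FidelityConfig(beta=beta, n_splits=n_splits)
    traces = []
    for seed in seeds:
        ds = make_cluster_square_dataset(ClusterSquareConfig(
            n=n, d=d, cluster_std=cluster_std, seed=int(seed)))
        traces.append(select_features(ds, model, r=r, cfg=cfg, lam=lam,
                                      seed=int(seed)))
    return traces


def _expand_table(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Replicate a joint count table into paired sample vectors."""
    xs, ys = [], []
    for i, j in product(range(counts.shape[0]), range(counts.shape[1])):
        xs += [i] * int(counts[i, j])
        ys += [j] * int(counts[i, j])
    return np.asarray(xs), np.asarray(ys)


def _deterministic_maps(n_states: int, rng: np.random.Generator,
                        n_random: int = 3) -> list[np.ndarray]:
    """Identity, a merging map, a constant map, and a few random maps."""
    maps = [np.arange(n_states)]
    if n_states > 2:
        merge = np.arange(n_states)
        merge[-1] = merge[-2]
        maps.append(merge)
    maps.append(np.zeros(n_states, dtype=int))
    for _ in range(n_random):
        maps.append(rng.integers(0, n_states, size=n_states))
    return maps


def fidelity_bound_sweep(seed: int = 0, betas=(0.0, 0.1, 1.0),
                         n_tables: int = 30, max_states: int = 6) -> dict:
    """Exact plug-in fidelity over enumerated discrete joint tables.

    Random joint count tables for (X, Y) with up to ``max_states`` states
    per variable are expanded into samples; for every deterministic map
    T = g(X) and every beta, the exact fidelity is evaluated.  The sweep
    always includes the perfect-inference construction (Y = X, g =
    identity), where the fidelity attains its upper bound exactly.

    Returns ``max_fidelity``, ``attains_bound`` (fidelity at the
    perfect-inference case) and the list of all evaluated fidelities.
    """
    rng = np.random.default_rng(seed)
    values = []

    # perfect-inference construction: Y = X, T = X
    x = np.repeat(np.arange(3), [4, 3, 5])
    attained = [fidelity_exact(x, x, x, beta) for beta in betas]
    values += attained

    for _ in range(n_tables):
        nx = int(rng.integers(2, max_states + 1))
        ny = int(rng.integers(2, max_states + 1))
        counts = rng.integers(0, 5, size=(nx, ny))
        counts[rng.integers(nx), rng.integers(ny)] += 2  # nonempty
        if counts.sum(axis=1).min() == 0 or counts.sum(axis=0).min() == 0:
            counts += 1
        xs, ys = _expand_table(counts)
        from .mi import estimate_mi_plugin

        if estimate_mi_plugin(xs, ys).value < 1e-12:
            continue  # independent table: fidelity undefined
        for g in _deterministic_maps(nx, rng):
            ts = g[xs]
            for beta in betas:
                values.append(fidelity_exact(xs, ts, ys, beta))

    return {"max_fidelity": float(np.max(values)),
            "attains_bound": float(np.max(attained)),
            "n_cases": len(values),
            "betas": list(betas),
            "fidelities": [float(v) for v in values]}
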