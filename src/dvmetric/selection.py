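"""Greedy forward feature selection by DVM gain.

Starting from the empty set, each of r steps scores every not-yet-selected
feature j by the DVM of the augmented subset and adds the argmax (ties
broken by lowest feature index).  Within a step every candidate is
evaluated on identical train/test splits, so comparisons are paired.  The
full r-step trace is reported together with the local maximum — the curve
is not expected to be monotone, because the complexity regularizer and the
estimator's dimensionality burden both grow with the subset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import LabeledDataset
from .dvm import (FidelityConfig, _full_mi, compute_dvm,
                  make_supervised_splits)
from .exceptions import DegenerateSignalError, ParameterError
from .models import SUPERVISED, make_model

__all__ = ["SelectionTrace", "select_features"]


@dataclass
class SelectionTrace:
    """Ordered record of a forward-selection run."""

    steps: list  # [(feature_name, dvm_after_adding), ...]
    best_subset: list
    best_dvm: float
    r: int
    model_id: str = ""
    seed: int = 0
    audit: list = field(default_factory=list)  # per-step split fingerprints

    @property
    def selected(self) -> list:
        return [name for name, _ in self.steps]

    @property
    def dvm_curve(self) -> np.ndarray:
        return np.asarray([v for _, v in self.steps])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step_feature", "dvm"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {"steps": [[name, float(v)] for name, v in self.steps],
                "best_subset": list(self.best_subset),
                "best_dvm": float(self.best_dvm),
                "r": self.r, "model": self.model_id, "seed": self.seed}

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary(self) -> str:
        lines = ["DVM forward feature selection", "=" * 40,
                 f"{'step':>4}  {'feature':<12} {'DVM':>8}"]
        for i, (name, v) in enumerate(self.steps, 1):
            marker = "  <- best" if name == (self.best_subset[-1]
                                             if self.best_subset else None) \
                and len(self.best_subset) == i else ""
            lines.append(f"{i:>4}  {name:<12} {v:>8.4f}{marker}")
        lines.append(f"best subset ({len(self.best_subset)} features, "
                     f"DVM={self.best_dvm:.4f}): "
                     + ", ".join(self.best_subset))
        return "\n".join(lines)


def select_features(data: LabeledDataset, model, r: int,
                    cfg: FidelityConfig | None = None, lam: float = 0.01,
                    seed: int = 0) -> SelectionTrace:
    """Forward-select up to r features by greedy DVM maximisation.

    The DVM of the empty set is taken as 0.  Every candidate subset is
    scored with the fidelity denominator I(X;Y) of the *full* feature
    set, estimated once, so DVM{F} measures the fraction of the
    dataset's total task information captured by F and subsets of
    different sizes are comparable.  The regularizer of every candidate
    subset is likewise normalized at the full-dataset reference (n, p),
    so it grows as features are added.
    """
    if not 1 <= r <= data.p:
        raise ParameterError(f"r must satisfy 1 <= r <= p; got r={r}, "
                             f"p={data.p}")
    cfg = cfg or FidelityConfig()
    model = make_model(model)
    labels = data.require_labels()
    ss = np.random.SeedSequence(seed)
    step_seeds = ss.generate_state(r + 1) % (2**31)
    try:
        denominator = _full_mi(data, labels, data.label_kind, cfg,
                               int(step_seeds[r]))
    except DegenerateSignalError:
        denominator = None  # zero-signal data: all subsets score ~0

    selected: list[int] = []
    steps, audit = [], []
    for step in range(r):
        step_seed = int(step_seeds[step])
        if model.mode == SUPERVISED:
            splits = make_supervised_splits(data.n, labels, data.label_kind,
                                            cfg, step_seed)
        else:
            from .dvm import make_threeway_splits

            splits = make_threeway_splits(data.n, cfg, step_seed)
        candidates = [j for j in range(data.p) if j not in selected]
        best_j, best_val, fingerprints = None, -np.inf, []
        for j in candidates:
            subset = selected + [j]
            sub = data.select_features(subset)
            if denominator is not None:
                res = compute_dvm(sub, model, cfg, lam,
                                  reference=(data.n, data.p),
                                  seed=step_seed, splits=splits,
                                  denominator=denominator)
                val = res.dvm
                fingerprints.append((j, hash(tuple(
                    int(i) for tr_te in res.splits for part in tr_te
                    for i in part))))
            else:
                # zero-signal data: fidelity of every subset is taken as 0
                from .complexity import normalized_regularizer

                reg = normalized_regularizer(
                    model, data.n, len(subset), data.n, data.p,
                    allow_default_cost=bool(
                        model.hyperparams.get("allow_default_cost", False)))
                val = 0.0 - lam * reg
            if val > best_val:  # strict: ties keep lowest index
                best_j, best_val = j, val
        selected.append(best_j)
        steps.append((data.feature_names[best_j], float(best_val)))
        audit.append(fingerprints)

    curve = np.asarray([v for _, v in steps])
    best_idx = int(np.argmax(curve))
    return SelectionTrace(
        steps=steps,
        best_subset=[name for name, _ in steps[:best_idx + 1]],
        best_dvm=float(curve[best_idx]),
        r=r, model_id=model.model_id, seed=seed, audit=audit)
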