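"""Nonparametric bootstrap stability of Bradley-Terry partition trees.

The whole grow-and-prune pipeline is re-run on B subject-level resamples
(with replacement, original sample size), and two summaries are kept per
covariate: the selection probability — the fraction of resamples whose
pruned tree uses the covariate in at least one split — and the empirical
distribution of the cutpoints at which it split.  A stable tree shows
selection probabilities near one for the originally selected covariates
and cutpoint distributions concentrated near the original rule values.

Each resample draws its RNG substream from one master seed via
``SeedSequence.spawn``, so resamples are independent, any execution order
yields identical summaries, and increasing B leaves earlier resamples
unchanged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .llbt import GroupSpec
from .partition import Covariate, PartitionTree, TreeConfig, grow_tree
from .rankings import ItemSet, Ranking

__all__ = [
    "BootstrapConfig",
    "StabilitySummary",
    "bootstrap_trees",
    "summarize_cutpoints",
    "summary_to_csv",
    "summary_to_json",
]

logger = logging.getLogger(__name__)


@dataclass
class BootstrapConfig:
    """Bootstrap controls: B resamples (study default 1000), master seed,
    and the TreeConfig applied identically to every resample."""

    B: int = 1000
    seed: int = 0
    tree_config: TreeConfig = field(default_factory=TreeConfig)

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")


@dataclass
class StabilitySummary:
    """Per-covariate split stability over B bootstrap trees."""

    B: int
    covariates: list[str]
    selection_counts: dict[str, int]
    cutpoints: dict[str, list[float]]
    n_degenerate: int = 0

    @property
    def selection_probability(self) -> dict[str, float]:
        return {c: self.selection_counts[c] / self.B for c in self.covariates}

    def mean_cutpoint(self, covariate: str) -> Optional[float]:
        pts = self.cutpoints.get(covariate, [])
        return float(np.mean(pts)) if pts else None


def _tree_splits(tree: PartitionTree) -> list:
    return tree.split_rules()


def bootstrap_trees(
    rankings: Sequence[Ranking],
    covariates: Sequence[Covariate],
    items: ItemSet,
    config: BootstrapConfig,
    groups: Optional[GroupSpec] = None,
) -> StabilitySummary:
    """Grow + prune B trees on subject-level resamples and summarize splits.

    Rankings and covariates move together: a resample draws subject
    indices with replacement and carries each subject's ranking, covariate
    values and (optional) group label as one unit.  A degenerate resample
    (every subject identical) yields a single-node tree and is counted.
    """
    rankings = list(rankings)
    n = len(rankings)
    cov_names = [c.name for c in covariates]
    counts = {c: 0 for c in cov_names}
    cutpoints: dict[str, list[float]] = {c: [] for c in cov_names}
    n_degenerate = 0

    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(config.B)
    for b in range(config.B):
        rng = np.random.default_rng(streams[b])
        idx = rng.integers(0, n, size=n)
        # a resample is represented as integer case weights over the
        # original subjects, so each unique subject stays one unit in the
        # score-fluctuation tests while fits and node sizes are weighted
        mult = np.bincount(idx, minlength=n)
        boot_weights = {
            rankings[i].subject_id: int(m) for i, m in enumerate(mult) if m > 0
        }
        drawn = [rankings[i] for i in sorted(set(idx.tolist()))]
        if len({r.ordering for r in drawn}) <= 1:
            n_degenerate += 1
            logger.info("bootstrap resample %d is degenerate (identical subjects)", b)
        tree = grow_tree(
            rankings, covariates, items, config.tree_config, groups,
            weights=boot_weights,
        )
        used = set()
        for rule in _tree_splits(tree):
            used.add(rule.covariate)
            if rule.kind in ("numeric", "ordinal") and rule.cutpoint is not None:
                cutpoints[rule.covariate].append(float(rule.cutpoint))
        for c in used:
            counts[c] += 1
    return StabilitySummary(config.B, cov_names, counts, cutpoints, n_degenerate)


def summarize_cutpoints(
    summary: StabilitySummary, covariate: str, bins: int = 10
) -> dict:
    """Mean cutpoint and binned frequencies for one covariate.

    A never-selected covariate yields an explicitly empty result
    (``{"empty": True}``), not zeros.
    """
    if covariate not in summary.covariates:
        raise KeyError(f"unknown covariate {covariate!r}")
    pts = summary.cutpoints.get(covariate, [])
    if not pts:
        return {"covariate": covariate, "empty": True}
    arr = np.asarray(pts, dtype=float)
    freq, edges = np.histogram(arr, bins=bins)
    return {
        "covariate": covariate,
        "empty": False,
        "n": int(arr.size),
        "mean": float(arr.mean()),
        "min": float(arr.min()),
        "max": float(arr.max()),
        "bin_edges": edges.tolist(),
        "bin_counts": freq.tolist(),
    }


def summary_to_csv(summary: StabilitySummary, path) -> None:
    rows = []
    for c in summary.covariates:
        pts = summary.cutpoints.get(c, [])
        rows.append(
            {
                "covariate": c,
                "selection_probability": summary.selection_probability[c],
                "n_cutpoints": len(pts),
                "mean_cutpoint": float(np.mean(pts)) if pts else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


def summary_to_json(summary: StabilitySummary, path) -> None:
    d = {
        "B": summary.B,
        "n_degenerate": summary.n_degenerate,
        "selection_probability": summary.selection_probability,
        "cutpoints": summary.cutpoints,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(d, fh, indent=2)
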