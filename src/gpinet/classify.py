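"""Condition classification by PCA over posterior linkage probabilities.

Each exposure condition yields one learned posterior; flattening its
off-diagonal linkage probabilities gives a D = P(P-1)-dimensional
fingerprint of how the condition rewired the network.  PCA over the
condition-by-fingerprint table then places conditions in a low-
dimensional map where chemicals with similar network effects cluster
and distance from the control condition measures effect size.  The
module is fully deterministic: centering, SVD, and a fixed sign
convention (the largest-magnitude loading of each component is made
positive).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .bayesnet import PosteriorSummary

__all__ = [
    "LinkageVectorTable",
    "ClassificationResult",
    "vectorize",
    "run_pca",
    "condition_map",
    "kmedoids_grouping",
    "score_plot",
]


@dataclass
class LinkageVectorTable:
    """C conditions × D ordered-pair linkage probabilities."""

    conditions: list[str]
    vectors: np.ndarray
    pair_index: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        C, D = self.vectors.shape
        if C != len(self.conditions):
            raise ValueError("row count does not match condition count")
        if D != len(self.pair_index):
            raise ValueError("column count does not match pair index")
        if C < 2:
            raise ValueError(f"classification needs >= 2 conditions, got {C}")
        if np.any((self.vectors < 0) | (self.vectors > 1)):
            raise ValueError("linkage probabilities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{p}->{c}" for p, c in self.pair_index]
        return pd.DataFrame(self.vectors, index=self.conditions, columns=cols)


@dataclass
class ClassificationResult:
    """PCA scores/loadings over condition linkage fingerprints."""

    conditions: list[str]
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    centered: bool = True
    scaled: bool = False

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def vectorize(posteriors: Mapping[str, PosteriorSummary]) -> LinkageVectorTable:
    """Flatten per-condition posterior edge probabilities into rows.

    Column order is canonical: row-major over ordered (parent, child)
    pairs, diagonal skipped; identical for every condition.  All
    posteriors must share one node list.
    """
    if len(posteriors) < 2:
        raise ValueError(
            f"classification needs >= 2 conditions, got {len(posteriors)}"
        )
    conditions = list(posteriors)
    ref_names = posteriors[conditions[0]].node_names
    for cond in conditions:
        if posteriors[cond].node_names != ref_names:
            raise ValueError(
                f"condition {cond!r} has a different node list than "
                f"{conditions[0]!r}"
            )
    P = len(ref_names)
    pair_index = [
        (ref_names[i], ref_names[j]) for i in range(P) for j in range(P) if i != j
    ]
    off_diag = ~np.eye(P, dtype=bool)
    vectors = np.vstack(
        [posteriors[c].edge_prob[off_diag] for c in conditions]
    )
    return LinkageVectorTable(conditions, vectors, pair_index)


def run_pca(
    table: LinkageVectorTable,
    scale: bool = False,
    k: int | None = None,
) -> ClassificationResult:
    """Centered (optionally unit-variance-scaled) SVD decomposition.

    Zero-variance columns are left centered when scaling.  Ratios are
    singular values squared over total variance, so they are
    non-increasing and sum to 1 over the full rank.  Sign convention:
    the largest-|loading| entry of each component is positive.
    """
    X = table.vectors.astype(float)
    C, D = X.shape
    max_k = min(C - 1, D)
    if k is None:
        k = max_k
    if not (1 <= k <= max_k):
        raise ValueError(f"k must lie in [1, {max_k}] for C={C}, D={D}; got {k}")
    Xc = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = Xc.std(axis=0, ddof=0)
        nonzero = sd > 0
        Xc[:, nonzero] = Xc[:, nonzero] / sd[nonzero]
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, s, Vt = U[:, :max_k], s[:max_k], Vt[:max_k]
    total = float(np.sum(s**2))
    if total > 1e-20:
        ratio = s**2 / total
    else:
        ratio = np.zeros_like(s)  # all rows (numerically) identical
    # deterministic orientation
    for comp in range(max_k):
        pivot = int(np.argmax(np.abs(Vt[comp])))
        if Vt[comp, pivot] < 0:
            Vt[comp] *= -1.0
            U[:, comp] *= -1.0
    scores = U * s
    return ClassificationResult(
        conditions=list(table.conditions),
        scores=scores[:, :k],
        loadings=Vt[:k].T,
        explained_variance_ratio=ratio[:k],
        centered=True,
        scaled=scale,
    )


def condition_map(result: ClassificationResult, control: str) -> pd.DataFrame:
    """Score coordinates plus distance-from-control ranking.

    Distances are Euclidean in the retained-component space; the 2-D
    (PC1, PC2) coordinates are reported for plotting.  Rows are sorted by
    distance, control first.
    """
    if control not in result.conditions:
        raise KeyError(f"unknown control condition {control!r}")
    scores = result.scores
    ctrl = scores[result.conditions.index(control)]
    dist = np.linalg.norm(scores - ctrl, axis=1)
    df = pd.DataFrame(
        {
            "condition": result.conditions,
            "pc1": scores[:, 0],
            "pc2": scores[:, 1] if scores.shape[1] > 1 else 0.0,
            "distance_from_control": dist,
        }
    )
    df = df.sort_values(
        ["distance_from_control", "condition"], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(len(df))
    return df


def kmedoids_grouping(result: ClassificationResult, k: int) -> dict[str, int]:
    """Exact k-medoids grouping of conditions in score space.

    Convenience only — grouping in the original study was done by eye on
    the score plot, not by an algorithm.  Exhaustive search over medoid
    subsets (fine for tens of conditions).
    """
    C = len(result.conditions)
    if not (1 <= k <= C):
        raise ValueError(f"k must lie in [1, {C}]")
    from math import comb

    if comb(C, k) > 200_000:
        raise ValueError("too many conditions for exhaustive k-medoids")
    d = np.linalg.norm(
        result.scores[:, None, :] - result.scores[None, :, :], axis=2
    )
    best_cost, best = np.inf, None
    for medoids in combinations(range(C), k):
        cost = d[:, medoids].min(axis=1).sum()
        if cost < best_cost - 1e-12:
            best_cost, best = cost, medoids
    assign = d[:, best].argmin(axis=1)
    return {cond: int(a) for cond, a in zip(result.conditions, assign)}


def score_plot(result: ClassificationResult, path, control: str | None = None) -> None:
    """PC1–PC2 scatter with condition labels (PNG/SVG by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = result.scores
    pc2 = scores[:, 1] if scores.shape[1] > 1 else np.zeros(len(result.conditions))
    fig, ax = plt.subplots(figsize=(6, 5))
    for idx, cond in enumerate(result.conditions):
        is_ctrl = cond == control
        ax.scatter(
            scores[idx, 0],
            pc2[idx],
            s=60,
            marker="s" if is_ctrl else "o",
            color="black" if is_ctrl else "tab:blue",
            zorder=3,
        )
        ax.annotate(cond, (scores[idx, 0], pc2[idx]),
                    textcoords="offset points", xytext=(5, 4), fontsize=8)
    evr = result.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0]*100:.1f}% variance)")
    if len(evr) > 1:
        ax.set_ylabel(f"PC2 ({evr[1]*100:.1f}% variance)")
    else:
        ax.set_ylabel("PC2")
    ax.axhline(0, color="0.8", lw=0.5, zorder=0)
    ax.axvline(0, color="0.8", lw=0.5, zorder=0)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
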