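"""Two-step feature optimization: mRMR importance ranking followed by
sequential forward search (SFS) maximizing cross-validated MCC.

The mRMR variant is the greedy MID (mutual-information difference) scheme:
the first feature maximizes relevance I(f; y); each subsequent pick maximizes
I(f; y) minus the mean mutual information with the already-selected set.
Continuous features are discretized by equal-frequency binning (5 bins by
default); columns with at most ``bins`` distinct values are used as-is.
All tie-breaks fall back to input column order, so the ranking is
deterministic without any seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .seqio import FeatureTable

logger = logging.getLogger(__name__)


def _mi_discrete(cx: np.ndarray, cy: np.ndarray) -> float:
    """I(X; Y) in nats from two integer code vectors via the contingency table."""
    nx = int(cx.max()) + 1
    ny = int(cy.max()) + 1
    joint = np.bincount(cx * ny + cy, minlength=nx * ny).astype(float).reshape(nx, ny)
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(px, py)
    return float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))


@dataclass
class RankedFeatureList:
    names: list[str]
    score_of: dict[str, float]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("ranked feature list contains duplicates")

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class CVConfig:
    folds: int = 5
    repeats: int = 10
    seed: int = 0


@dataclass
class SelectionResult:
    ranked: RankedFeatureList
    mcc_trace: np.ndarray
    k_opt: int
    optimal_features: list[str]

    @property
    def max_mcc(self) -> float:
        return float(self.mcc_trace[self.k_opt - 1])


def discretize(x, bins: int = 5) -> np.ndarray:
    """Equal-frequency discretization into ``bins`` integer codes.

    Ties are broken by value order (stable sort by value, then input index),
    so the binning is deterministic and seed-free.  Columns with at most
    ``bins`` distinct values are treated as already categorical.
    """
    x = np.asarray(x, dtype=float)
    uniq = np.unique(x)
    if uniq.size <= bins:
        return np.searchsorted(uniq, x).astype(np.int64)
    order = np.argsort(x, kind="stable")
    codes = np.empty(x.size, dtype=np.int64)
    codes[order] = (np.arange(x.size, dtype=np.int64) * bins) // x.size
    return codes


def mutual_information(x, y, bins: int = 5) -> float:
    """I(X; Y) in nats on the discretized contingency table (>= 0)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    if np.unique(y).size < 2:
        logger.warning("constant target; mutual information is 0")
        return 0.0
    _, cy = np.unique(y, return_inverse=True)
    return _mi_discrete(discretize(x, bins), cy.astype(np.int64))


def mrmr_rank(table: FeatureTable, bins: int = 5) -> RankedFeatureList:
    """Rank all features by the greedy MID mRMR rule.

    Pick argmax I(f; y) first; thereafter pick
    argmax [ I(f; y) - (1/|S|) sum_{s in S} I(f; s) ].
    Ties resolve to the earliest input column.
    """
    if table.labels is None:
        raise ValueError("mrmr_rank requires a labeled table")
    names = list(table.feature_names)
    n_feat = len(names)
    if n_feat < 2:
        return RankedFeatureList(names=names, score_of={n: 0.0 for n in names})

    codes = [discretize(table.values[:, j], bins) for j in range(n_feat)]
    uy, cy = np.unique(table.labels, return_inverse=True)
    cy = cy.astype(np.int64)
    if uy.size < 2:
        logger.warning("constant labels; returning input order")
        return RankedFeatureList(names=names, score_of={n: 0.0 for n in names})
    relevance = np.array([_mi_discrete(c, cy) for c in codes])

    selected: list[int] = []
    scores: dict[str, float] = {}
    remaining = list(range(n_feat))
    redundancy_sum = np.zeros(n_feat)

    first = int(np.argmax(relevance))
    selected.append(first)
    scores[names[first]] = float(relevance[first])
    remaining.remove(first)

    while remaining:
        last = selected[-1]
        for j in remaining:
            redundancy_sum[j] += _mi_discrete(codes[j], codes[last])
        objective = relevance[np.array(remaining)] - redundancy_sum[np.array(remaining)] / len(selected)
        best_pos = int(np.argmax(objective))  # first occurrence wins ties
        j = remaining[best_pos]
        scores[names[j]] = float(objective[best_pos])
        selected.append(j)
        remaining.remove(j)

    return RankedFeatureList(names=[names[j] for j in selected], score_of=scores)


def sfs_select(
    table: FeatureTable,
    ranked: RankedFeatureList,
    model_config=None,
    cv_config: CVConfig | None = None,
    max_k: int | None = None,
) -> SelectionResult:
    """Sequential forward search over ranked-prefix feature sets.

    For each prefix size k the mean MCC under stratified cross-validation is
    recorded; ``k_opt`` is the smallest k attaining the maximum of the trace
    and ``optimal_features`` is that prefix.  ``max_k`` truncates the search
    (the full feature count by default).
    """
    from .models import ModelConfig, cross_validate  # deferred: avoids import cycle

    if table.labels is None:
        raise ValueError("sfs_select requires a labeled table")
    unknown = set(ranked.names) - set(table.feature_names)
    if unknown:
        raise ValueError(f"ranked list names features absent from the table: {sorted(unknown)}")
    cv_config = cv_config or CVConfig()
    model_config = model_config or ModelConfig()

    K = len(ranked.names) if max_k is None else min(max_k, len(ranked.names))
    trace = np.zeros(K)
    for k in range(1, K + 1):
        prefix = ranked.names[:k]
        sub = table.select_features(prefix)
        result = cross_validate(
            sub, model_config, folds=cv_config.folds, repeats=cv_config.repeats,
            seed=cv_config.seed,
        )
        trace[k - 1] = result.means["MCC"]
    k_opt = int(np.argmax(trace)) + 1  # argmax returns the smallest index at ties
    return SelectionResult(
        ranked=ranked,
        mcc_trace=trace,
        k_opt=k_opt,
        optimal_features=list(ranked.names[:k_opt]),
    )
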