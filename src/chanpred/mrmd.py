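"""Maximum-relevance-maximum-distance (MRMD) feature ranking and selection.

Each feature f gets two scores:

* relevance MR_f — the absolute Pearson correlation between feature column f
  and the integer-encoded class labels (encoded 0..C-1 in first-seen order);
* distance MD_f — the mean, over three distance functions, of f's average
  distance to every other feature column: Euclidean distance on min-max
  scaled columns divided by sqrt(n_instances), cosine distance
  (1 - cosine similarity), and Tanimoto distance (1 - Tanimoto coefficient).
  A large MD means the feature is far from the others, i.e. carries little
  redundant signal.

The combined score is w_r * MR + w_d * MD (unit weights by default);
features are ranked by descending score with ties broken by original column
order.  Relevance against an arbitrary integer encoding is a known semantic
weakness for multi-class problems; it is retained as the method's standard
formulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputDataError


def encode_labels(labels: Sequence[str]) -> np.ndarray:
    """Integer-encode labels 0..C-1 in first-seen order."""
    seen: dict[str, int] = {}
    out = np.empty(len(labels), dtype=int)
    for i, label in enumerate(labels):
        if label not in seen:
            seen[label] = len(seen)
        out[i] = seen[label]
    return out


def _as_array(matrix: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), list(matrix.columns)
    arr = np.asarray(matrix, dtype=float)
    return arr, [f"f{i}" for i in range(arr.shape[1])]


def pearson_relevance(matrix: pd.DataFrame | np.ndarray, labels: Sequence[str]) -> np.ndarray:
    """Per-feature relevance: |Pearson r| against the encoded class labels.

    Constant feature columns have undefined correlation and get MR = 0.
    Raises on single-class labels (relevance is undefined there).
    """
    X, _ = _as_array(matrix)
    if X.shape[0] < 2:
        raise InputDataError("relevance needs at least 2 instances")
    y = encode_labels(list(labels)).astype(float)
    if np.all(y == y[0]):
        raise InputDataError("relevance undefined with a single class")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r[sx == 0] = 0.0
    return np.abs(r)


def _minmax_columns(X: np.ndarray) -> np.ndarray:
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    out = np.zeros_like(X, dtype=float)
    nz = span > 0
    out[:, nz] = (X[:, nz] - lo[nz]) / span[nz]
    return out


def _cosine_distance_matrix(S: np.ndarray) -> np.ndarray:
    norms = np.sqrt((S**2).sum(axis=0))
    dot = S.T @ S
    denom = np.outer(norms, norms)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = dot / denom
    # zero-vector conventions: two zero columns are identical (sim 1),
    # a zero against a nonzero column is maximally dissimilar (sim 0)
    zero = norms == 0
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    sim[np.ix_(zero, zero)] = 1.0
    return 1.0 - sim


def _tanimoto_distance_matrix(S: np.ndarray) -> np.ndarray:
    dot = S.T @ S
    sq = np.diag(dot)
    denom = sq[:, None] + sq[None, :] - dot
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = dot / denom
    zero = sq == 0
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    sim[np.ix_(zero, zero)] = 1.0
    sim[np.isnan(sim)] = 1.0  # denom 0 with nonzero sq cannot happen; identical columns
    return 1.0 - sim


def distance_redundancy(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Per-feature distance score MD (higher = less redundant).

    Columns are min-max scaled to [0, 1] first so the three distances act on
    commensurate scales.  A single-feature matrix gets MD = 0 by convention.
    """
    X, _ = _as_array(matrix)
    n_inst, n_feat = X.shape
    if n_feat < 2:
        return np.zeros(n_feat)
    S = _minmax_columns(X)

    diff_sq = (
        (S**2).sum(axis=0)[:, None] + (S**2).sum(axis=0)[None, :] - 2.0 * (S.T @ S)
    )
    np.clip(diff_sq, 0.0, None, out=diff_sq)
    euclid = np.sqrt(diff_sq) / np.sqrt(n_inst)
    cosine = _cosine_distance_matrix(S)
    tanimoto = _tanimoto_distance_matrix(S)

    md = np.zeros(n_feat)
    for D in (euclid, cosine, tanimoto):
        np.fill_diagonal(D, 0.0)
        md += D.sum(axis=1) / (n_feat - 1)
    return md / 3.0


@dataclass
class MrmdRanking:
    """Per-feature MRMD scores and rank order.

    ``table`` has columns feature, MR, MD, score, rank (1 = best), one row
    per feature in original column order; ``order`` lists feature names by
    descending score (stable under ties).
    """

    table: pd.DataFrame

    @property
    def order(self) -> list[str]:
        return list(self.table.sort_values("rank")["feature"])

    def top(self, m: int) -> list[str]:
        return self.order[:m]

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def rank_features(
    mr: np.ndarray,
    md: np.ndarray,
    feature_names: Sequence[str] | None = None,
    weights: tuple[float, float] = (1.0, 1.0),
) -> MrmdRanking:
    """Combine relevance and distance into scores and a stable ranking."""
    w_r, w_d = weights
    if w_r < 0 or w_d < 0:
        raise ConfigurationError(f"weights must be nonnegative, got {weights}")
    mr = np.asarray(mr, dtype=float)
    md = np.asarray(md, dtype=float)
    if mr.shape != md.shape:
        raise InputDataError(f"MR and MD lengths differ: {mr.shape} vs {md.shape}")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(len(mr))]
    score = w_r * mr + w_d * md
    # stable: ties keep original column order
    order = np.argsort(-score, kind="stable")
    rank = np.empty(len(score), dtype=int)
    rank[order] = np.arange(1, len(score) + 1)
    table = pd.DataFrame(
        {"feature": list(feature_names), "MR": mr, "MD": md, "score": score, "rank": rank}
    )
    return MrmdRanking(table)


def rank_matrix(
    matrix: pd.DataFrame,
    labels: Sequence[str],
    weights: tuple[float, float] = (1.0, 1.0),
) -> MrmdRanking:
    """Convenience: relevance + redundancy + ranking in one call."""
    mr = pearson_relevance(matrix, labels)
    md = distance_redundancy(matrix)
    return rank_features(mr, md, list(matrix.columns), weights)


def select_subset(
    matrix: pd.DataFrame,
    labels: Sequence[str],
    m: int | str = "auto",
    weights: tuple[float, float] = (1.0, 1.0),
    folds: int = 10,
    seed: int = 0,
    grid_step: float = 0.05,
) -> tuple[list[str], pd.DataFrame, MrmdRanking]:
    """Select the top-m MRMD features; returns (names, reduced matrix, ranking).

    With ``m="auto"``, nested prefixes of the ranking (sizes on a 5%-of-
    features grid) are scored by seeded cross-validated overall accuracy
    with a random forest, and the smallest size within one standard error
    of the best is kept.
    """
    ranking = rank_matrix(matrix, labels, weights)
    n_feat = matrix.shape[1]
    if m == "auto":
        from .classify import cross_validate  # local import: classify depends on mrmd

        sizes = sorted(
            {max(1, int(np.ceil(frac * n_feat))) for frac in np.arange(grid_step, 1.0 + 1e-9, grid_step)}
        )
        results = []
        for size in sizes:
            sub = matrix[ranking.top(size)]
            cv = cross_validate(sub, labels, folds=folds, seed=seed, backend="random-forest")
            accs = np.array(cv.fold_accuracies)
            results.append((size, accs.mean(), accs.std(ddof=1) / np.sqrt(len(accs))))
        best_size, best_mean, best_se = max(results, key=lambda t: t[1])
        chosen = min(size for size, mean, _ in results if mean >= best_mean - best_se)
        m = chosen
    else:
        if not (1 <= int(m) <= n_feat):
            raise ConfigurationError(f"m must be in 1..{n_feat}, got {m}")
        m = int(m)
    names = ranking.top(m)
    return names, matrix[names], ranking
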