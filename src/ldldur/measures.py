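"""Per-word network measures used as duration predictors, plus neighbor analyses.

A word's *articulatory path* is its own ordered triphone sequence.  Each node
(triphone) receives a semantic support from the word's predicted form vector
c_hat: the node's (non-negative) activation normalized over all inventory
cues that share its two-symbol left context — a selection probability against
its competitors, bounded by 1.

From the path and the predicted semantic vector s_hat the five measures are:

- path sum: summed node supports (grows with both support and word length);
- mean word support: path sum divided by path length — average per-node
  certainty, comparable across word lengths;
- path entropies: Shannon entropy (bits) of the normalized node supports —
  uncertainty along the path;
- semantic vector length: L1 norm of s_hat — semantic activation diversity;
- semantic density: mean correlation of s_hat with its top-k (default 8)
  semantic neighbors — transparency of the word's neighborhood;
- target correlation: Pearson r between s_hat and the target vector s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ldldur.form import to_triphones
from ldldur.lexicon import LexiconEntry

logger = logging.getLogger(__name__)


def word_path(entry: LexiconEntry, cue_inventory: Sequence[str]) -> list[str]:
    """The word's own triphone sequence, checked against the cue inventory."""
    cues = set(cue_inventory)
    path = to_triphones(entry.transcription)
    missing = [t for t in path if t not in cues]
    if missing:
        raise KeyError(
            f"{entry.word_id}: triphones {missing} not in the cue inventory"
        )
    return path


def _competitor_groups(cue_inventory: Sequence[str]) -> dict[str, list[int]]:
    groups: dict[str, list[int]] = {}
    for j, cue in enumerate(cue_inventory):
        groups.setdefault(cue[:2], []).append(j)
    return groups


def node_supports(
    path: Sequence[str],
    c_hat_row: pd.Series,
    cue_inventory: Sequence[str] | None = None,
) -> np.ndarray:
    """Per-node selection probabilities along a path.

    For node t with left context h (its first two symbols), the competitors
    are all inventory cues starting with h; support(t) is max(c_hat[t], 0)
    normalized over the competitors' clamped activations, or 0 when no
    competitor has positive activation.
    """
    if cue_inventory is None:
        cue_inventory = list(c_hat_row.index)
    values = c_hat_row.reindex(cue_inventory).to_numpy(dtype=float)
    clamped = np.maximum(values, 0.0)
    groups = _competitor_groups(cue_inventory)
    position = {cue: j for j, cue in enumerate(cue_inventory)}
    supports = np.zeros(len(path))
    for i, cue in enumerate(path):
        if cue not in position:
            raise KeyError(f"cue {cue!r} not in the cue inventory")
        denom = clamped[groups[cue[:2]]].sum()
        if denom > 0:
            supports[i] = clamped[position[cue]] / denom
    return supports


def path_sum(supports: np.ndarray) -> float:
    """Summed semantic support of the path."""
    if len(supports) == 0:
        raise ValueError("empty path")
    return float(np.sum(supports))


def mean_word_support(
    total: float, path: Sequence[str], divisor: str = "nodes"
) -> float:
    """Path sum divided by path length, controlling for word length.

    ``divisor="nodes"`` divides by the node count (the default);
    ``divisor="transitions"`` divides by the transition count (nodes - 1,
    floored at 1 for single-node paths).
    """
    if not path:
        raise ValueError("empty path")
    if divisor == "nodes":
        d = len(path)
    elif divisor == "transitions":
        d = max(len(path) - 1, 1)
    else:
        raise ValueError(f"unknown divisor {divisor!r}")
    return total / d


def path_entropy(supports: np.ndarray) -> float:
    """Shannon entropy (bits) of the path's normalized node supports.

    Returns NaN (the measure is flagged missing) when the path receives no
    positive support at all.
    """
    total = float(np.sum(supports))
    if total <= 0:
        logger.info("path_entropy: zero total support, measure missing")
        return float("nan")
    p = np.asarray(supports, dtype=float) / total
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def semantic_vector_length(s_hat_row: np.ndarray | pd.Series) -> float:
    """L1 (city-block) norm of the predicted semantic vector."""
    row = np.asarray(s_hat_row, dtype=float)
    if not np.isfinite(row).all():
        raise ValueError("non-finite semantic vector")
    return float(np.abs(row).sum())


def _neighbor_correlations(matrix: pd.DataFrame) -> np.ndarray:
    """All-pairs row correlations with the diagonal removed (set to -inf)."""
    x = matrix.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    z = xc / safe[:, None]
    r = z @ z.T
    np.fill_diagonal(r, -np.inf)
    r[norms == 0, :] = -np.inf
    r[:, norms == 0] = -np.inf
    return r


def semantic_density(
    word_id: str, s_hat: pd.DataFrame, k: int = 8
) -> float:
    """Mean correlation of the word's predicted vector with its top-k neighbors."""
    if s_hat.shape[0] < k + 1:
        raise ValueError(f"need at least {k + 1} words for {k} neighbors")
    r = _neighbor_correlations(s_hat)
    i = s_hat.index.get_loc(word_id)
    top = np.sort(r[i])[-k:]
    return float(top.mean())


def target_correlation(
    s_hat_row: np.ndarray | pd.Series, s_row: np.ndarray | pd.Series
) -> float:
    """Pearson r between predicted and target semantic vectors (NaN if degenerate)."""
    a = np.asarray(s_hat_row, dtype=float)
    b = np.asarray(s_row, dtype=float)
    if a.size < 3:
        raise ValueError("need at least 3 dimensions")
    if np.std(a) == 0 or np.std(b) == 0:
        logger.info("target_correlation: zero-variance vector, measure missing")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class NeighborReport:
    """Top-k semantic neighbors per word and per-category neighbor diversity."""

    neighbors: dict[str, list[tuple[str, float]]]
    type_diversity: dict[str, int]
    k: int


def neighbor_report(
    s_hat: pd.DataFrame,
    lexicon: Sequence[LexiconEntry],
    k: int = 8,
) -> NeighborReport:
    """Ranked top-k neighbor lists and, per morphological category, the number
    of unique word types appearing in any member's top-k list."""
    if s_hat.shape[0] < k + 1:
        raise ValueError(f"need at least {k + 1} words for {k} neighbors")
    r = _neighbor_correlations(s_hat)
    ids = list(s_hat.index)
    neighbors: dict[str, list[tuple[str, float]]] = {}
    for i, wid in enumerate(ids):
        order = np.argsort(-r[i])[:k]
        neighbors[wid] = [(ids[j], float(r[i, j])) for j in order]
    diversity: dict[str, set[str]] = {}
    for e in lexicon:
        if e.category is None or e.word_id not in neighbors:
            continue
        diversity.setdefault(e.category, set()).update(
            nid for nid, _ in neighbors[e.word_id]
        )
    return NeighborReport(
        neighbors=neighbors,
        type_diversity={cat: len(s) for cat, s in diversity.items()},
        k=k,
    )


def compare_distributions(
    values_a: Sequence[float], values_b: Sequence[float]
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value for a group contrast.

    Exact for small tie-free samples, normal approximation with tie
    correction otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.pvalue)


def compute_measures(
    lexicon: Sequence[LexiconEntry],
    s: pd.DataFrame,
    s_hat: pd.DataFrame,
    c_hat: pd.DataFrame,
    divisor: str = "nodes",
    k: int = 8,
    neighbor_source: str = "predicted",
) -> pd.DataFrame:
    """Per-word measure table (one row per word type, keyed by word_id).

    ``neighbor_source`` selects the matrix providing the neighbors' vectors
    for semantic density: the predicted matrix S_hat (default) or the target
    matrix S.
    """
    if neighbor_source not in ("predicted", "target"):
        raise ValueError(f"unknown neighbor source {neighbor_source!r}")
    cue_inventory = list(c_hat.columns)
    groups_matrix = s_hat if neighbor_source == "predicted" else s
    r_neighbors = _neighbor_correlations(groups_matrix)
    if s_hat.shape[0] < k + 1:
        raise ValueError(f"need at least {k + 1} words for {k} neighbors")
    rows = []
    for i, entry in enumerate(lexicon):
        path = word_path(entry, cue_inventory)
        supports = node_supports(path, c_hat.loc[entry.word_id], cue_inventory)
        total = path_sum(supports)
        top = np.sort(r_neighbors[i])[-k:]
        rows.append(
            {
                "word_id": entry.word_id,
                "path_sum": total,
                "mean_word_support": mean_word_support(total, path, divisor),
                "path_entropies": path_entropy(supports),
                "semantic_vector_length": semantic_vector_length(
                    s_hat.iloc[i].to_numpy()
                ),
                "semantic_density": float(top.mean()),
                "target_correlation": target_correlation(
                    s_hat.iloc[i].to_numpy(), s.iloc[i].to_numpy()
                ),
            }
        )
    return pd.DataFrame(rows).set_index("word_id")
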