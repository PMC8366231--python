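"""Comprehension and production mappings between form and meaning.

The network is a pair of linear transformations estimated by least squares
with the Moore-Penrose generalized inverse:

    C F = S   (comprehension: form -> meaning,  F = C+ S)
    S G = C   (production:    meaning -> form,  G = S+ C)

Predicted matrices are S_hat = C F and C_hat = S G.  A word's meaning (form)
counts as correctly recognized (produced) when its predicted row correlates
more strongly with its own target row than with any other word's target row;
ties are scored incorrect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def solve_mapping(x: np.ndarray | pd.DataFrame, y: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Least-squares transformation B = X+ Y minimizing ||X B - Y||_F.

    Uses the SVD-based pseudoinverse with numpy's relative singular-value
    cutoff, which handles the rank deficiency the generalized inverse is
    there for.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape[0] != yv.shape[0]:
        raise ValueError(
            f"row mismatch: X has {xv.shape[0]} rows, Y has {yv.shape[0]}"
        )
    if not (np.isfinite(xv).all() and np.isfinite(yv).all()):
        raise ValueError("non-finite entries in mapping inputs")
    return np.linalg.pinv(xv) @ yv


@dataclass
class PredictedMatrices:
    """Predicted semantic (S_hat = C F) and form (C_hat = S G) matrices."""

    s_hat: pd.DataFrame
    c_hat: pd.DataFrame


def predict(
    c: pd.DataFrame,
    s: pd.DataFrame,
    f: np.ndarray,
    g: np.ndarray,
) -> PredictedMatrices:
    if c.shape[1] != f.shape[0]:
        raise ValueError(f"C has {c.shape[1]} cues but F has {f.shape[0]} rows")
    if s.shape[1] != g.shape[0]:
        raise ValueError(f"S has {s.shape[1]} dimensions but G has {g.shape[0]} rows")
    s_hat = pd.DataFrame(c.to_numpy(dtype=float) @ f, index=c.index, columns=s.columns)
    c_hat = pd.DataFrame(s.to_numpy(dtype=float) @ g, index=s.index, columns=c.columns)
    return PredictedMatrices(s_hat=s_hat, c_hat=c_hat)


def _row_correlation_matrix(pred: np.ndarray, targ: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson correlations between predicted and target rows.

    Returns the correlation matrix and a mask of rows valid in both matrices
    (zero-variance rows are invalid and excluded by the caller).
    """
    pc = pred - pred.mean(axis=1, keepdims=True)
    tc = targ - targ.mean(axis=1, keepdims=True)
    pn = np.linalg.norm(pc, axis=1)
    tn = np.linalg.norm(tc, axis=1)
    valid = (pn > 0) & (tn > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (pc / np.where(pn == 0, 1, pn)[:, None]) @ (
            tc / np.where(tn == 0, 1, tn)[:, None]
        ).T
    return r, valid


@dataclass
class AccuracyReport:
    """Recognition accuracy of a predicted matrix against its targets."""

    accuracy: float
    ranks: pd.Series  # per-word rank of the own target (1 = best)
    n_ties: int
    n_excluded: int
    correct: pd.Series = field(repr=False)


def evaluate_accuracy(
    predicted: pd.DataFrame,
    targets: pd.DataFrame,
    tolerance: float = 1e-12,
) -> AccuracyReport:
    """Fraction of words whose own target row is the strict correlation argmax.

    A word is correct iff the correlation of its predicted row with its own
    target exceeds its correlation with every other target row by more than
    ``tolerance``; ties (within tolerance of the maximum) are counted and
    scored incorrect.  Zero-variance rows are excluded and logged.
    """
    if list(predicted.index) != list(targets.index):
        raise ValueError("predicted and target matrices must align rows")
    n = predicted.shape[0]
    if n < 2:
        raise ValueError("need at least 2 words to evaluate accuracy")
    r, valid = _row_correlation_matrix(
        predicted.to_numpy(dtype=float), targets.to_numpy(dtype=float)
    )
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.info("evaluate_accuracy: excluded %d zero-variance rows", n_excluded)
    idx = np.where(valid)[0]
    own = r[idx, idx]
    correct = np.zeros(n, dtype=bool)
    ranks = np.full(n, np.nan)
    n_ties = 0
    for k, i in enumerate(idx):
        row = r[i]
        others = np.delete(row, i)
        best_other = others.max() if others.size else -np.inf
        ranks[i] = 1 + int((others > own[k] + tolerance).sum())
        if own[k] > best_other + tolerance:
            correct[i] = True
        elif abs(own[k] - best_other) <= tolerance:
            n_ties += 1
    n_valid = len(idx)
    accuracy = float(correct.sum()) / n_valid if n_valid else float("nan")
    return AccuracyReport(
        accuracy=accuracy,
        ranks=pd.Series(ranks, index=predicted.index, name="target_rank"),
        n_ties=n_ties,
        n_excluded=n_excluded,
        correct=pd.Series(correct, index=predicted.index, name="correct"),
    )
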