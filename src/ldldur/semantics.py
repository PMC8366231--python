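"""The semantic matrix S under the three network architectures.

Three architectures differ only in how a *derived* word's semantic row is
assembled from the lexome store (monomorphemic rows are always the word's own
content vector):

- ``idiosyncratic``: the derivative's own content vector, nothing else.  The
  network receives no information about morphological category.
- ``morphology``: derivative vector + its category's function vector, keeping
  idiosyncratic meaning while sharing the category component.
- ``base``: base vector + category function vector — a strictly compositional
  meaning with no idiosyncratic component.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from ldldur.lexicon import LexiconEntry, validate_lexicon
from ldldur.vectors import LexomeVectorStore

logger = logging.getLogger(__name__)

IDIOSYNCRATIC = "idiosyncratic"
MORPHOLOGY = "morphology"
BASE = "base"
NETWORK_VARIANTS = (IDIOSYNCRATIC, MORPHOLOGY, BASE)


def build_semantic_matrix(
    lexicon: Sequence[LexiconEntry],
    store: LexomeVectorStore,
    variant: str,
) -> pd.DataFrame:
    """Word x dimension semantic matrix S, row order following the lexicon."""
    if variant not in NETWORK_VARIANTS:
        raise ValueError(f"unknown network variant {variant!r}")
    validate_lexicon(lexicon)
    rows = np.empty((len(lexicon), store.dimension))
    for i, entry in enumerate(lexicon):
        try:
            if not entry.is_derived:
                rows[i] = store[entry.word_id]
            elif variant == IDIOSYNCRATIC:
                rows[i] = store[entry.word_id]
            elif variant == MORPHOLOGY:
                rows[i] = store[entry.word_id] + store[entry.category]
            else:  # BASE
                rows[i] = store[entry.base_id] + store[entry.category]
        except KeyError as err:
            raise KeyError(f"variant {variant!r}: {err.args[0]}") from None
    frame = pd.DataFrame(
        rows,
        index=[e.word_id for e in lexicon],
        columns=[f"dim_{j}" for j in range(store.dimension)],
    )
    if not np.isfinite(rows).all():
        raise ValueError("non-finite values in semantic matrix")
    return frame


def mean_row_correlation(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Mean Pearson correlation of corresponding rows of two word x D matrices.

    Rows with zero variance in either matrix carry no correlation and are
    excluded (the exclusion count is logged).
    """
    if list(a.index) != list(b.index):
        raise ValueError("matrices must index the same words in the same order")
    if a.shape[1] < 3 or b.shape[1] < 3:
        raise ValueError("need at least 3 dimensions for row correlations")
    x = a.to_numpy(dtype=float)
    y = b.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(xc, axis=1)
    yn = np.linalg.norm(yc, axis=1)
    ok = (xn > 0) & (yn > 0)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("mean_row_correlation: excluded %d zero-variance rows", n_excluded)
    if not ok.any():
        raise ValueError("all rows have zero variance")
    r = (xc[ok] * yc[ok]).sum(axis=1) / (xn[ok] * yn[ok])
    return float(r.mean())
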