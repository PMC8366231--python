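"""Triphone form encoding and the binary cue matrix C.

Words are represented by overlapping three-symbol windows over their
boundary-padded transcription.  Triphones act as proxies for articulatory
transitions: the word "k{t" (cat) is padded to "#k{t#" and yields the cues
#k{, k{t, {t#.  The cue matrix C is a binary word x triphone matrix in which
cell (i, j) codes whether triphone j occurs anywhere in word i (presence or
absence only; repeated occurrences collapse to a single 1).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from ldldur.lexicon import BOUNDARY, LexiconEntry, PhonemeInventory, validate_lexicon


def to_triphones(
    transcription: str,
    inventory: PhonemeInventory | None = None,
    boundary: str = BOUNDARY,
) -> list[str]:
    """All length-3 windows over the boundary-padded transcription, in order.

    A word of n phones yields exactly n triphones.  Consecutive triphones
    overlap in two symbols, so chaining them reconstructs the padded string.
    """
    if not transcription:
        raise ValueError("empty transcription")
    if inventory is not None:
        inventory.validate_transcription(transcription)
        boundary = inventory.boundary_symbol
    elif boundary in transcription:
        raise ValueError(
            f"boundary symbol {boundary!r} may not occur inside a transcription"
        )
    padded = boundary + transcription + boundary
    return [padded[i : i + 3] for i in range(len(padded) - 2)]


def triphones_to_transcription(triphones: Sequence[str], boundary: str = BOUNDARY) -> str:
    """Invert :func:`to_triphones` by chaining the overlapping windows."""
    if not triphones:
        raise ValueError("empty triphone sequence")
    chained = triphones[0]
    for prev, cue in zip(triphones, triphones[1:]):
        if prev[1:] != cue[:2]:
            raise ValueError(f"non-overlapping triphones {prev!r} -> {cue!r}")
        chained += cue[2]
    return chained.strip(boundary)


def build_cue_matrix(
    lexicon: Sequence[LexiconEntry],
    inventory: PhonemeInventory | None = None,
) -> pd.DataFrame:
    """Binary cue matrix C: rows are word_ids, columns the lexicographically
    sorted union of all triphones in the lexicon."""
    validate_lexicon(lexicon)
    per_word = {e.word_id: to_triphones(e.transcription, inventory) for e in lexicon}
    cues = sorted(set().union(*per_word.values()))
    cue_index = {cue: j for j, cue in enumerate(cues)}
    values = np.zeros((len(lexicon), len(cues)), dtype=np.int8)
    for i, e in enumerate(lexicon):
        for cue in per_word[e.word_id]:
            values[i, cue_index[cue]] = 1
    return pd.DataFrame(values, index=[e.word_id for e in lexicon], columns=cues)
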