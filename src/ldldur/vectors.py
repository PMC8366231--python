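"""The lexome vector store: real-valued semantic vectors keyed by lexome id.

Lexomes are atomic pointers to meanings.  Content lexomes stand for words
(bases and derivatives); function lexomes stand for morphological categories
(e.g. NESS).  Both live in the same D-dimensional space, so a derived word's
meaning can be expressed additively (base or derivative vector plus the
category's function vector).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONTENT = "content"
FUNCTION = "function"


@dataclass
class LexomeVectorStore:
    """Map lexome_id -> length-D real vector, with a content/function kind tag."""

    dimension: int
    vectors: dict[str, np.ndarray] = field(default_factory=dict)
    kinds: dict[str, str] = field(default_factory=dict)

    def add(self, lexome_id: str, vector: np.ndarray, kind: str = CONTENT) -> None:
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (self.dimension,):
            raise ValueError(
                f"vector for {lexome_id!r} has shape {vector.shape}, "
                f"expected ({self.dimension},)"
            )
        if kind not in (CONTENT, FUNCTION):
            raise ValueError(f"unknown lexome kind {kind!r}")
        self.vectors[lexome_id] = vector
        self.kinds[lexome_id] = kind

    def __getitem__(self, lexome_id: str) -> np.ndarray:
        try:
            return self.vectors[lexome_id]
        except KeyError:
            raise KeyError(f"no vector for lexome {lexome_id!r}") from None

    def __contains__(self, lexome_id: str) -> bool:
        return lexome_id in self.vectors

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            np.vstack([self.vectors[k] for k in self.vectors]),
            index=list(self.vectors),
            columns=[f"dim_{j}" for j in range(self.dimension)],
        )
        frame.index.name = "lexome_id"
        return frame

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str | Path, kinds: dict[str, str] | None = None) -> "LexomeVectorStore":
        frame = pd.read_csv(path, sep="\t", index_col="lexome_id")
        store = cls(dimension=frame.shape[1])
        for lexome_id, row in frame.iterrows():
            kind = kinds.get(str(lexome_id), CONTENT) if kinds else CONTENT
            store.add(str(lexome_id), row.to_numpy(), kind)
        return store
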