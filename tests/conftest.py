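"""Shared fixtures: a hand-built DISC-style mini-lexicon and small study configs."""

from __future__ import annotations

import numpy as np
import pytest

from ldldur.lexicon import LexiconEntry, PhonemeInventory
from ldldur.synthetic import AffixSpec, GeneratorConfig


@pytest.fixture(scope="session")
def disc_inventory() -> PhonemeInventory:
    """Inventory covering the DISC-style example transcriptions (cat, happiness...)."""
    return PhonemeInventory(tuple("k{thpInsw$lEm@"))


@pytest.fixture(scope="session")
def mini_lexicon(disc_inventory) -> list[LexiconEntry]:
    """cat, walk, lemon, happy and happiness (one NESS derivative)."""
    return [
        LexiconEntry("k{t", "k{t"),
        LexiconEntry("w$k", "w$k"),
        LexiconEntry("lEm@n", "lEm@n"),
        LexiconEntry("h{pI", "h{pI"),
        LexiconEntry("h{pInIs", "h{pInIs", base_id="h{pI", category="NESS"),
    ]


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A fast, small synthetic study used across module tests."""
    return GeneratorConfig(
        seed=7,
        n_bases=40,
        affixes=(
            AffixSpec("NESS", "ik", "suffix", shift_vector_scale=0.7, n_types=12),
            AffixSpec("LESS", "uk", "suffix", shift_vector_scale=1.5, n_types=12),
            AffixSpec("DIS", "ta", "prefix", shift_vector_scale=1.1, n_types=12),
        ),
        dimension=60,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
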