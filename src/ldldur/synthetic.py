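"""Synthetic lexicons, semantic vector stores, segment tables and token data.

The generator emulates the statistical structure the duration analysis
assumes, with known ground truth:

- word forms are random phone strings over a small inventory; derived words
  concatenate an affix form to a sampled base (prefix or suffix);
- semantic vectors are i.i.d. standard normal per dimension for content
  lexomes; each morphological category has an independent function (shift)
  vector, and a derived word's content vector is base + shift + idiosyncratic
  noise whose sd tunes semantic transparency;
- segment mean durations are drawn once per phone;
- token durations follow a known linear model on word-level covariates
  (baseline duration, network measures) plus a speech-rate term, a type-level
  random intercept and Gaussian residual noise; non-positive draws are
  rejected and redrawn.

A single seed threads through all stages via spawned substreams, so identical
configurations reproduce byte-identical outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ldldur.lexicon import LexiconEntry, PhonemeInventory, validate_lexicon
from ldldur.vectors import CONTENT, FUNCTION, LexomeVectorStore

logger = logging.getLogger(__name__)

PREFIX = "prefix"
SUFFIX = "suffix"

# Default phone inventory: deliberately small, so that a few hundred word
# types saturate the space of possible triphones and the form matrix is not
# trivially full row rank (mirroring the regime of large natural lexicons).
DEFAULT_SYMBOLS = ("p", "t", "k", "a", "i", "u")


@dataclass(frozen=True)
class AffixSpec:
    """One derivational category: its label, form, position, semantic shift
    magnitude, and how many derived types to generate."""

    category_label: str
    affix_form: str
    position: str = SUFFIX
    shift_vector_scale: float = 1.0
    n_types: int = 20

    def __post_init__(self) -> None:
        if not self.affix_form:
            raise ValueError("affix_form must be non-empty")
        if self.position not in (PREFIX, SUFFIX):
            raise ValueError(f"position must be prefix or suffix, got {self.position!r}")
        if self.n_types < 1:
            raise ValueError("n_types must be >= 1")
        if self.shift_vector_scale < 0:
            raise ValueError("shift_vector_scale must be >= 0")


def _default_affixes() -> tuple[AffixSpec, ...]:
    # Five categories emulating the prefix/suffix mix and the differing
    # semantic transparency of English derivational functions.
    return (
        AffixSpec("DIS", "ta", PREFIX, shift_vector_scale=1.2, n_types=48),
        AffixSpec("NESS", "ik", SUFFIX, shift_vector_scale=0.7, n_types=48),
        AffixSpec("LESS", "uk", SUFFIX, shift_vector_scale=1.5, n_types=48),
        AffixSpec("ATION", "api", SUFFIX, shift_vector_scale=0.9, n_types=48),
        AffixSpec("IZE", "at", SUFFIX, shift_vector_scale=1.1, n_types=48),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """All tunable knobs of the synthetic study, with the defaults defining
    the study conditions used throughout the analysis."""

    seed: int = 0
    n_bases: int = 160
    affixes: tuple[AffixSpec, ...] = field(default_factory=_default_affixes)
    inventory: PhonemeInventory = field(
        default_factory=lambda: PhonemeInventory(DEFAULT_SYMBOLS)
    )
    base_length_range: tuple[int, int] = (3, 6)
    dimension: int = 150
    transparency_sd: float = 0.5
    content_scale_sd: float = 0.4
    segment_duration_range_ms: tuple[float, float] = (40.0, 120.0)
    tokens_per_type_mean: float = 4.0
    duration_coefficients: Mapping[str, float] = field(
        default_factory=lambda: {
            "baseline_duration_ms": 1.0,
            "mean_word_support": 12.0,
            "path_entropies": -6.0,
            "semantic_vector_length": -5.0,
            "semantic_density": 0.0,
        }
    )
    intercept_ms: float = 60.0
    speech_rate_coefficient: float = -15.0
    speech_rate_mean: float = 4.0
    speech_rate_sd: float = 1.0
    type_intercept_sd: float = 12.0
    residual_sd: float = 30.0

    def __post_init__(self) -> None:
        if self.n_bases < 1:
            raise ValueError("n_bases must be >= 1")
        for name in ("transparency_sd", "speech_rate_sd", "type_intercept_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tokens_per_type_mean < 1:
            raise ValueError("tokens_per_type_mean must be >= 1")
        labels = [a.category_label for a in self.affixes]
        if len(set(labels)) != len(labels):
            raise ValueError("affix category labels must be unique")

    def substream(self, stage: int) -> np.random.Generator:
        """Deterministic per-stage random stream derived from the single seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(stage + 1)[stage])


def generate_lexicon(
    config: GeneratorConfig,
) -> tuple[list[LexiconEntry], PhonemeInventory]:
    """Monomorphemic bases plus, per affix, derived forms over sampled bases.

    Word ids are the transcriptions themselves (unique by construction).
    Fails explicitly when the phone alphabet is too small to supply enough
    unique forms.
    """
    rng = config.substream(0)
    inv = config.inventory
    symbols = list(inv.symbols)
    lo, hi = config.base_length_range
    capacity = sum(len(symbols) ** n for n in range(lo, hi + 1))
    if capacity < config.n_bases:
        raise ValueError(
            f"alphabet of {len(symbols)} symbols cannot supply "
            f"{config.n_bases} unique base forms of length {lo}-{hi}"
        )
    bases: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(bases) < config.n_bases:
        attempts += 1
        if attempts > 1000 * config.n_bases:
            raise ValueError("failed to sample enough unique base forms")
        length = int(rng.integers(lo, hi + 1))
        form = "".join(rng.choice(symbols, size=length))
        if form not in seen:
            seen.add(form)
            bases.append(form)
    entries = [LexiconEntry(word_id=b, transcription=b) for b in bases]
    for affix in config.affixes:
        inv.validate_transcription(affix.affix_form)
        if affix.n_types > config.n_bases:
            raise ValueError(
                f"{affix.category_label}: n_types={affix.n_types} exceeds "
                f"n_bases={config.n_bases}"
            )
        order = rng.permutation(config.n_bases)
        made = 0
        for idx in order:
            if made == affix.n_types:
                break
            base = bases[idx]
            form = (
                affix.affix_form + base
                if affix.position == PREFIX
                else base + affix.affix_form
            )
            if form in seen:
                continue
            seen.add(form)
            entries.append(
                LexiconEntry(
                    word_id=form,
                    transcription=form,
                    base_id=base,
                    category=affix.category_label,
                )
            )
            made += 1
        if made < affix.n_types:
            raise ValueError(
                f"{affix.category_label}: could only derive {made} of "
                f"{affix.n_types} unique forms"
            )
    validate_lexicon(entries)
    return entries, inv


def generate_vector_store(
    lexicon: Sequence[LexiconEntry], config: GeneratorConfig
) -> LexomeVectorStore:
    """Semantic vectors with additive category structure.

    Content vectors of monomorphemic words are i.i.d. standard normal per
    dimension, scaled by a per-word lognormal magnitude factor
    (``content_scale_sd``) emulating the broad word-to-word magnitude
    variation of empirical lexome vectors.  Each category's function vector
    is i.i.d. normal with sd ``shift_vector_scale``.  A derived word's
    content vector is base + function + N(0, transparency_sd^2 I).
    """
    if config.dimension < 2:
        raise ValueError("semantic dimension must be >= 2")
    if not lexicon:
        raise ValueError("empty lexicon")
    rng = config.substream(1)
    d = config.dimension
    store = LexomeVectorStore(dimension=d)
    scales = {a.category_label: a.shift_vector_scale for a in config.affixes}
    for e in lexicon:
        if not e.is_derived:
            scale = math.exp(config.content_scale_sd * rng.standard_normal())
            store.add(e.word_id, scale * rng.standard_normal(d), CONTENT)
    for affix in config.affixes:
        store.add(
            affix.category_label,
            affix.shift_vector_scale * rng.standard_normal(d),
            FUNCTION,
        )
    for e in lexicon:
        if e.is_derived:
            if e.category not in store:
                raise KeyError(f"no function vector for category {e.category!r}")
            noise = config.transparency_sd * rng.standard_normal(d)
            store.add(e.word_id, store[e.base_id] + store[e.category] + noise, CONTENT)
    return store


def generate_segment_table(config: GeneratorConfig) -> dict[str, float]:
    """Mean duration (ms) per phone, drawn uniformly over the configured range."""
    rng = config.substream(2)
    lo, hi = config.segment_duration_range_ms
    if lo <= 0:
        raise ValueError("segment durations must be positive")
    return {
        sym: float(rng.uniform(lo, hi)) for sym in config.inventory.symbols
    }


@dataclass
class TokenGroundTruth:
    """The generating model behind a token table, kept for recovery tests."""

    intercept_ms: float
    coefficients: dict[str, float]
    speech_rate_coefficient: float
    residual_sd: float
    type_intercept_sd: float
    type_intercepts: pd.Series
    n_redraws: int


def draw_token_skeleton(
    lexicon: Sequence[LexiconEntry], config: GeneratorConfig
) -> pd.DataFrame:
    """Token counts and speech rates without durations.

    Per word type the token count is zero-truncated geometric with the
    configured mean (so hapax types occur at rate 1/mean); speech rate is
    drawn per token.
    """
    rng = config.substream(3)
    p = 1.0 / config.tokens_per_type_mean
    rows = []
    for e in lexicon:
        count = int(rng.geometric(p))
        for _ in range(count):
            rows.append(
                {
                    "word_id": e.word_id,
                    "speech_rate": float(
                        rng.normal(config.speech_rate_mean, config.speech_rate_sd)
                    ),
                }
            )
    frame = pd.DataFrame(rows)
    frame.insert(0, "token_id", [f"tok{i:05d}" for i in range(len(frame))])
    return frame


def assign_durations(
    skeleton: pd.DataFrame,
    covariates: pd.DataFrame,
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, TokenGroundTruth]:
    """Observed durations from the known linear model.

    ``covariates`` may be type-level (indexed by word_id, one row per type)
    or token-level (aligned with the skeleton).  Every predictor named in
    ``duration_coefficients`` must be present.  Non-positive duration draws
    are rejected and redrawn (count recorded).
    """
    rng = config.substream(4)
    coeffs = dict(config.duration_coefficients)
    if covariates.index.name == "word_id" or not covariates.index.equals(
        pd.RangeIndex(len(covariates))
    ):
        token_cov = covariates.reindex(skeleton["word_id"]).reset_index(drop=True)
    else:
        if len(covariates) != len(skeleton):
            raise ValueError("token-level covariates must align with the skeleton")
        token_cov = covariates.reset_index(drop=True)
    for name in coeffs:
        if name not in token_cov.columns:
            raise KeyError(f"missing predictor column {name!r} in covariate table")
    if token_cov[list(coeffs)].isna().any().any():
        raise ValueError("covariate table contains missing values for predictors")
    word_ids = skeleton["word_id"].to_numpy()
    types = pd.unique(word_ids)
    type_intercepts = pd.Series(
        config.type_intercept_sd * rng.standard_normal(len(types)),
        index=types,
        name="type_intercept",
    )
    mean = np.full(len(skeleton), config.intercept_ms)
    for name, beta in coeffs.items():
        mean = mean + beta * token_cov[name].to_numpy(dtype=float)
    mean = mean + config.speech_rate_coefficient * skeleton["speech_rate"].to_numpy()
    mean = mean + type_intercepts.loc[word_ids].to_numpy()
    durations = mean + config.residual_sd * rng.standard_normal(len(mean))
    n_redraws = 0
    bad = durations <= 0
    passes = 0
    while bad.any():
        passes += 1
        if passes > 1000:
            raise ValueError(
                "duration rejection sampling did not terminate: the linear "
                "model yields means far below zero; check the coefficients"
            )
        n_redraws += int(bad.sum())
        durations[bad] = mean[bad] + config.residual_sd * rng.standard_normal(
            int(bad.sum())
        )
        bad = durations <= 0
    if n_redraws:
        logger.info("assign_durations: redrew %d non-positive durations", n_redraws)
    tokens = skeleton.copy()
    for col in token_cov.columns:
        if col not in tokens.columns:
            tokens[col] = token_cov[col].to_numpy()
    tokens["observed_duration_ms"] = durations
    truth = TokenGroundTruth(
        intercept_ms=config.intercept_ms,
        coefficients=coeffs,
        speech_rate_coefficient=config.speech_rate_coefficient,
        residual_sd=config.residual_sd,
        type_intercept_sd=config.type_intercept_sd,
        type_intercepts=type_intercepts,
        n_redraws=n_redraws,
    )
    return tokens, truth


def generate_tokens(
    lexicon: Sequence[LexiconEntry],
    covariate_table: pd.DataFrame,
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, TokenGroundTruth]:
    """Token table from a type-level covariate table (indexed by word_id)."""
    skeleton = draw_token_skeleton(lexicon, config)
    return assign_durations(skeleton, covariate_table, config)
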