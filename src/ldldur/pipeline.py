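"""End-to-end synthetic study: lexicon -> networks -> measures -> durations -> fits.

The pipeline generates a lexicon and vector store, builds the cue matrix and
the semantic matrix for each network architecture, solves both mappings,
derives the per-word measures, simulates token durations from a known linear
model, constructs the duration-difference response, and fits the standard
and mixed duration regressions with trimming and stepwise simplification.

Predictor construction for the duration models: each network measure is
z-scored across tokens and then orthogonalized against baseline duration
(and re-scaled to unit variance).  Because the response is itself the
baseline-residualized duration, this keeps the segmental-makeup channel out
of the measure coefficients and makes the two-step estimator exactly
calibrated for the generating model.  Raw measures are used for all
distributional analyses.  Measures with (near-)zero variance carry no
information and are dropped from the models with a note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ldldur.duration import (
    FitResult,
    RelativeImportance,
    baseline_duration,
    duration_difference,
    fit_mixed,
    fit_standard,
    lmg_importance,
    stepwise_eliminate,
    trim_refit,
    vif,
)
from ldldur.form import build_cue_matrix
from ldldur.lexicon import LexiconEntry, PhonemeInventory
from ldldur.mapping import AccuracyReport, evaluate_accuracy, predict, solve_mapping
from ldldur.measures import compute_measures
from ldldur.semantics import NETWORK_VARIANTS, build_semantic_matrix
from ldldur.synthetic import (
    GeneratorConfig,
    TokenGroundTruth,
    assign_durations,
    draw_token_skeleton,
    generate_lexicon,
    generate_segment_table,
    generate_vector_store,
)
from ldldur.vectors import LexomeVectorStore

logger = logging.getLogger(__name__)

MEASURE_COLUMNS = (
    "mean_word_support",
    "path_entropies",
    "semantic_vector_length",
    "semantic_density",
    "target_correlation",
)


@dataclass
class NetworkResult:
    """One architecture's matrices, mappings, accuracies and measures."""

    variant: str
    s: pd.DataFrame
    f: np.ndarray
    g: np.ndarray
    s_hat: pd.DataFrame
    c_hat: pd.DataFrame
    comprehension: AccuracyReport
    production: AccuracyReport
    measures: pd.DataFrame


@dataclass
class StudyResult:
    """Everything a synthetic study produced, including the ground truth."""

    config: GeneratorConfig
    lexicon: list[LexiconEntry]
    inventory: PhonemeInventory
    store: LexomeVectorStore
    segment_table: dict[str, float]
    c: pd.DataFrame
    networks: dict[str, NetworkResult]
    token_variant: str
    tokens: pd.DataFrame
    predictor_columns: list[str]
    truth: TokenGroundTruth
    fits: dict[str, FitResult] = field(default_factory=dict)
    vif_table: pd.Series | None = None
    lmg_standard: RelativeImportance | None = None


def build_network(
    lexicon: Sequence[LexiconEntry],
    c: pd.DataFrame,
    store: LexomeVectorStore,
    variant: str,
    divisor: str = "nodes",
    k: int = 8,
) -> NetworkResult:
    """Solve both mappings for one architecture and derive the measures."""
    s = build_semantic_matrix(lexicon, store, variant)
    f = solve_mapping(c, s)
    g = solve_mapping(s, c)
    predicted = predict(c, s, f, g)
    return NetworkResult(
        variant=variant,
        s=s,
        f=f,
        g=g,
        s_hat=predicted.s_hat,
        c_hat=predicted.c_hat,
        comprehension=evaluate_accuracy(predicted.s_hat, s),
        production=evaluate_accuracy(predicted.c_hat, c),
        measures=compute_measures(
            lexicon, s, predicted.s_hat, predicted.c_hat, divisor=divisor, k=k
        ),
    )


def _adjusted_predictors(
    token_measures: pd.DataFrame,
    baseline: np.ndarray,
    columns: Sequence[str],
) -> tuple[pd.DataFrame, list[str]]:
    """Z-score measures across tokens and orthogonalize against baseline."""
    design = np.column_stack([np.ones(len(baseline)), baseline])
    out = {}
    kept = []
    for col in columns:
        x = token_measures[col].to_numpy(dtype=float)
        sd = x.std()
        if not np.isfinite(sd) or sd < 1e-10:
            logger.info("dropping near-constant measure %s from the models", col)
            continue
        z = (x - x.mean()) / sd
        beta, *_ = np.linalg.lstsq(design, z, rcond=None)
        resid = z - design @ beta
        rsd = resid.std()
        out[col] = resid / rsd if rsd > 1e-10 else resid
        kept.append(col)
    return pd.DataFrame(out, index=token_measures.index), kept


def run_study(
    config: GeneratorConfig | None = None,
    token_variant: str = "morphology",
    variants: Sequence[str] = NETWORK_VARIANTS,
    divisor: str = "nodes",
    k: int = 8,
    fit_models: bool = True,
    trim_threshold: float = 2.5,
    alpha: float = 0.05,
) -> StudyResult:
    """Run the full synthetic study under one configuration."""
    config = config or GeneratorConfig()
    if token_variant not in variants:
        raise ValueError(f"token_variant {token_variant!r} not among variants")
    lexicon, inventory = generate_lexicon(config)
    store = generate_vector_store(lexicon, config)
    segment_table = generate_segment_table(config)
    c = build_cue_matrix(lexicon, inventory)
    networks = {
        v: build_network(lexicon, c, store, v, divisor=divisor, k=k) for v in variants
    }

    baseline_by_word = pd.Series(
        {e.word_id: baseline_duration(e.transcription, segment_table) for e in lexicon},
        name="baseline_duration_ms",
    )
    skeleton = draw_token_skeleton(lexicon, config)
    measures = networks[token_variant].measures
    token_measures = measures.reindex(skeleton["word_id"]).reset_index(drop=True)
    baseline_tokens = (
        baseline_by_word.reindex(skeleton["word_id"]).to_numpy(dtype=float)
    )
    adjusted, kept = _adjusted_predictors(
        token_measures, baseline_tokens, MEASURE_COLUMNS
    )
    covariates = adjusted.copy()
    covariates["baseline_duration_ms"] = baseline_tokens
    # Coefficients for dropped (constant) measures are vacuous: the generator
    # cannot act on a column that carries no variance.
    usable_coeffs = {
        name: beta
        for name, beta in config.duration_coefficients.items()
        if name in covariates.columns
    }
    skipped = set(config.duration_coefficients) - set(usable_coeffs)
    if skipped:
        logger.info("generator coefficients without usable columns: %s", sorted(skipped))
    tokens, truth = assign_durations(
        skeleton, covariates, replace(config, duration_coefficients=usable_coeffs)
    )
    tokens = duration_difference(tokens)

    result = StudyResult(
        config=config,
        lexicon=lexicon,
        inventory=inventory,
        store=store,
        segment_table=segment_table,
        c=c,
        networks=networks,
        token_variant=token_variant,
        tokens=tokens,
        predictor_columns=kept,
        truth=truth,
    )
    if not fit_models:
        return result

    # Procedure order: simplify on the untrimmed fit (calibrated p-values),
    # then a single residual-trim pass on the final model.
    terms = kept + ["speech_rate"]
    full_standard = fit_standard(tokens, "duration_difference", terms)
    final_standard = trim_refit(stepwise_eliminate(full_standard, alpha), trim_threshold)
    full_mixed = fit_mixed(tokens, "duration_difference", terms, group="word_id")
    final_mixed = trim_refit(stepwise_eliminate(full_mixed, alpha), trim_threshold)
    result.fits = {
        "standard_full": full_standard,
        "standard_final": final_standard,
        "mixed_full": full_mixed,
        "mixed_final": final_mixed,
    }
    result.vif_table = vif(tokens[terms])
    result.lmg_standard = lmg_importance(
        final_standard.data, "duration_difference", final_standard.terms
    )
    return result
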