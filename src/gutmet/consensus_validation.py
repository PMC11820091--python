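"""Consensus predictions, unseen/background set construction, enrichment tests.

A consumption model and a production model each emit (negative, positive)
class probabilities for an instance. The consensus combines them so both
models contribute equally to a single consumption-vs-production call:

    p_consumption = mean(consumption-model positive, production-model negative)
    p_production  = mean(consumption-model negative, production-model positive)

The label is the argmax, or "unspecified" at an exact tie. Probabilities are
always reported explicitly named, never positional.

This module also builds the validation scaffolding around the models:
cross-combined unseen negative sets (metabolites of one strictly-labelled set
paired with the bacteria of the other), random background sets that re-pair
each experimental instance's metabolite with a different bacterium, per-
instance protein/enzyme interactor counts, and the Mann-Whitney U test used
to compare experimental against background counts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .encoders import ECNumber
from .features import collect_instance_enzymes
from .io_model import EnzymeAnnotation, InteractionRecord

UNSPECIFIED = "unspecified"
_TOL = 1e-9


@dataclass(frozen=True)
class ConsensusResult:
    p_consumption: float
    p_production: float
    label: str  # consumption | production | unspecified


@dataclass
class BackgroundSet:
    instances: list[InteractionRecord]
    pairing_log: list[tuple[str, str]]  # (original bacterium, replacement)


@dataclass
class CrossNegativeResult:
    instances: list[InteractionRecord]
    n_generated: int
    n_retained: int


def _check_pair(pair: tuple[float, float], name: str) -> None:
    p_neg, p_pos = pair
    if not (0.0 <= p_neg <= 1.0 and 0.0 <= p_pos <= 1.0):
        raise ValueError(f"{name} probabilities outside [0, 1]: {pair}")
    if abs(p_neg + p_pos - 1.0) > _TOL:
        raise ValueError(f"{name} probabilities do not sum to 1: {pair}")


def predict_label(p_neg: float, p_pos: float) -> str:
    """positive / negative by majority probability; unspecified at an exact tie."""
    _check_pair((p_neg, p_pos), "model")
    if p_pos > 0.5:
        return "positive"
    if p_pos < 0.5:
        return "negative"
    return UNSPECIFIED


def consensus(
    cons_model_probs: tuple[float, float], prod_model_probs: tuple[float, float]
) -> ConsensusResult:
    """Average the two models' class probabilities into one directional call.

    Each argument is that model's (negative, positive) class probability pair.
    A compound consumed should look positive to the consumption model and
    negative to the production model, so those two probabilities average into
    p_consumption, and symmetrically for p_production; the two consensus
    probabilities sum to 1 by construction.
    """
    _check_pair(cons_model_probs, "consumption model")
    _check_pair(prod_model_probs, "production model")
    cons_neg, cons_pos = cons_model_probs
    prod_neg, prod_pos = prod_model_probs
    p_consumption = (cons_pos + prod_neg) / 2.0
    p_production = (cons_neg + prod_pos) / 2.0
    if p_consumption > p_production:
        label = "consumption"
    elif p_production > p_consumption:
        label = "production"
    else:
        label = UNSPECIFIED
    return ConsensusResult(p_consumption, p_production, label)


def round_probability(p: float, ndigits: int = 2) -> float:
    """Round half-up, matching how probabilities are reported in tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(p)).quantize(q, rounding=ROUND_HALF_UP))


def build_cross_negative_set(
    metabolites_from: Sequence[str],
    bacteria_from: Sequence[str],
    annotations: dict[str, list[EnzymeAnnotation]],
    scores: dict[tuple[str, str], list[tuple[str, int]]],
    label: str,
) -> CrossNegativeResult:
    """Unseen negatives: the Cartesian product of one set's metabolites with the
    other set's bacteria, keeping only instances with at least one scored,
    EC-annotated enzyme."""
    if not metabolites_from or not bacteria_from:
        raise ValueError("both input sets must be non-empty")
    instances = []
    n_generated = 0
    for metabolite in metabolites_from:
        for bacterium in bacteria_from:
            n_generated += 1
            ranked = collect_instance_enzymes(bacterium, metabolite, annotations, scores)
            if ranked.valid:
                instances.append(
                    InteractionRecord(bacterium, metabolite, label, provenance="unseen")
                )
    return CrossNegativeResult(instances, n_generated, len(instances))


def build_random_background(
    strict_set: Sequence[InteractionRecord],
    bacteria_pool: Sequence[str],
    seed: int = 0,
) -> BackgroundSet:
    """Re-pair each instance's metabolite with a random different bacterium.

    The replacement is drawn uniformly from the pool minus the instance's own
    bacterium; metabolite and label are preserved, so the background set keeps
    the metabolite marginal distribution exactly.
    """
    pool = list(bacteria_pool)
    if len(pool) < 2:
        raise ValueError("bacteria pool must contain at least 2 taxa")
    rng = np.random.default_rng(seed)
    instances, log = [], []
    for record in strict_set:
        options = [b for b in pool if b != record.bacterium]
        replacement = options[int(rng.integers(len(options)))]
        instances.append(
            replace(record, bacterium=replacement, provenance="background")
        )
        log.append((record.bacterium, replacement))
    return BackgroundSet(instances, log)


def count_interactors(
    instance: InteractionRecord,
    annotations: dict[str, list[EnzymeAnnotation]],
    scores: dict[tuple[str, str], list[tuple[str, int]]],
    role_model: Callable[[ECNumber, str], bool] | None = None,
) -> tuple[int, int, int]:
    """(proteins, enzymes, role enzymes) interacting with the instance's metabolite.

    Proteins are everything with an association score to the metabolite in
    this bacterium; enzymes the subset with a real (non-placeholder) EC; role
    enzymes the subset a trained substrate/product classifier accepts.
    """
    score_rows = scores.get((instance.metabolite, instance.bacterium), ())
    n_proteins = len(score_rows)
    ranked = collect_instance_enzymes(
        instance.bacterium, instance.metabolite, annotations, scores
    )
    n_enzymes = len(ranked.entries)
    n_role = 0
    if role_model is not None:
        n_role = sum(
            1 for _, ec, _ in ranked.entries if role_model(ec, instance.metabolite)
        )
    return n_proteins, n_enzymes, n_role


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (midranks) with a two-sided normal-approximation p-value.

    The returned U counts pairs where a > b plus half the ties; the p-value
    uses tie and continuity corrections. Identical samples give U = |a||b|/2.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    result = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(result.statistic), float(result.pvalue)
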