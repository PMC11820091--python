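"""Theoretical (negative) interaction sets.

Experimentally curated interactions are all positive, so classification needs
constructed negatives. The strategy has two steps per direction label:

1. *Category-exclusion superset* - for each bacterium with positives, pair it
   with every metabolite whose chemical category differs from the categories
   of all that bacterium's positive metabolites (and which is not itself a
   positive partner). Category identity is the only exclusion rule.
2. *Score-distribution matching* - down-sample the superset so the
   distribution of metabolite-enzyme association scores matches the positive
   set's, removing affinity bias from the classification task. Matching is by
   per-bin quota (largest-remainder rounding) over equal-width bins of the
   0-1000 score scale, verified with a two-sample chi-square test.

A separate constructor builds balanced enzyme-metabolite reaction
classification sets (substrate/product style): negatives pair enzymes absent
from the positive set with the metabolite panel, matched in count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .encoders import ECNumber
from .io_model import InteractionRecord, MetaboliteRecord

logger = logging.getLogger(__name__)


@dataclass
class NegativeSupersetResult:
    candidates: list[InteractionRecord]
    excluded_category_map: dict[str, set[str]]


@dataclass
class MatchResult:
    selected: list[InteractionRecord]
    chi2_stat: float
    p_value: float
    bin_edges: np.ndarray
    pos_bin_counts: np.ndarray
    neg_bin_counts: np.ndarray
    n_dropped_unscored: int = 0


def build_negative_superset(
    positives: list[InteractionRecord],
    metabolites: list[MetaboliteRecord],
    label: str,
) -> NegativeSupersetResult:
    """Candidate negatives for one direction label by category exclusion."""
    category = {m.metabolite: m.category for m in metabolites}
    pos_of_label = [p for p in positives if p.label == label]
    for p in pos_of_label:
        if p.metabolite not in category:
            raise ValueError(f"positive metabolite {p.metabolite!r} missing category")

    pos_pairs = {(p.bacterium, p.metabolite) for p in pos_of_label}
    excluded: dict[str, set[str]] = {}
    for p in pos_of_label:
        excluded.setdefault(p.bacterium, set()).add(category[p.metabolite])

    candidates = []
    for bacterium, banned in excluded.items():
        for m in metabolites:
            if m.category in banned:
                continue
            if (bacterium, m.metabolite) in pos_pairs:
                continue
            candidates.append(
                InteractionRecord(bacterium, m.metabolite, label, provenance="negative")
            )
    return NegativeSupersetResult(candidates, excluded)


def instance_score_summary(
    record: InteractionRecord,
    scores: dict[tuple[str, str], list[tuple[str, int]]],
    stat: str = "max",
) -> float | None:
    """Representative association score of one instance, or None if unscored.

    The per-instance statistic is the maximum (default) or mean over the
    metabolite-protein scores of that (bacterium, metabolite) pair. Instances
    without any scored protein are dropped from distribution matching.
    """
    pairs = scores.get((record.metabolite, record.bacterium))
    if not pairs:
        return None
    values = [s for _, s in pairs]
    if stat == "max":
        return float(max(values))
    if stat == "mean":
        return float(np.mean(values))
    raise ValueError(f"unknown summary statistic {stat!r}")


def chi_square_two_sample(
    counts_a: np.ndarray, counts_b: np.ndarray
) -> tuple[float, float]:
    """Pearson chi-square on the 2 x B contingency table of two binned samples.

    Bins empty in both samples are dropped before computing degrees of freedom.
    """
    a = np.asarray(counts_a, dtype=int)
    b = np.asarray(counts_b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("count vectors must have equal length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be non-negative")
    keep = (a + b) > 0
    if not keep.any():
        raise ValueError("all bins empty in both samples")
    table = np.vstack([a[keep], b[keep]])
    if table.shape[1] == 1:
        # Single populated bin: distributions are trivially identical.
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def _largest_remainder_quotas(proportions: np.ndarray, total: int) -> np.ndarray:
    """Integer quotas summing exactly to ``total``, proportional to ``proportions``."""
    raw = proportions * total
    quotas = np.floor(raw).astype(int)
    remainder = total - quotas.sum()
    order = np.argsort(-(raw - quotas), kind="stable")
    quotas[order[:remainder]] += 1
    return quotas


def match_score_distributions(
    pos: list[InteractionRecord],
    candidates: list[InteractionRecord],
    scores: dict[tuple[str, str], list[tuple[str, int]]],
    target_n: int,
    n_bins: int = 10,
    seed: int = 0,
    stat: str = "max",
    max_retries: int = 0,
    p_threshold: float = 0.95,
) -> MatchResult:
    """Down-sample candidates so their score distribution matches the positives'.

    Scores are binned into ``n_bins`` equal-width bins over [0, 1000]; each bin
    receives a quota proportional to the positives' bin mass (largest-remainder
    rounding, so quotas sum exactly to ``target_n``), and candidates are drawn
    without replacement per bin. A quota that exceeds a bin's candidate pool is
    redistributed to the nearest non-empty bins. Sampling is one-shot by
    default; set ``max_retries`` > 0 to re-seed until the chi-square p-value
    reaches ``p_threshold``.
    """
    if target_n <= 0:
        raise ValueError("target_n must be positive")

    pos_scores = []
    for r in pos:
        s = instance_score_summary(r, scores, stat)
        if s is not None:
            pos_scores.append(s)
    if not pos_scores:
        raise ValueError("no scored positive instances")

    cand_scored: list[tuple[InteractionRecord, float]] = []
    n_dropped = 0
    for r in candidates:
        s = instance_score_summary(r, scores, stat)
        if s is None:
            n_dropped += 1
        else:
            cand_scored.append((r, s))
    if target_n > len(cand_scored):
        raise ValueError(
            f"target_n={target_n} exceeds {len(cand_scored)} scored candidates"
        )

    edges = np.linspace(0.0, 1000.0, n_bins + 1)
    pos_counts, _ = np.histogram(pos_scores, bins=edges)
    cand_bins: list[list[InteractionRecord]] = [[] for _ in range(n_bins)]
    for record, s in cand_scored:
        idx = min(int(np.searchsorted(edges, s, side="right")) - 1, n_bins - 1)
        cand_bins[idx].append(record)
    avail = np.array([len(b) for b in cand_bins])
    if not avail.any():
        raise ValueError("no candidate falls in any score bin")

    quotas = _largest_remainder_quotas(pos_counts / pos_counts.sum(), target_n)

    # Redistribute quota that cannot be filled to the nearest non-empty bins.
    alloc = np.minimum(quotas, avail)
    deficit = int(target_n - alloc.sum())
    while deficit > 0:
        room = avail - alloc
        open_bins = np.flatnonzero(room > 0)
        if open_bins.size == 0:  # cannot happen given target_n <= len(cand_scored)
            raise ValueError("candidate pool exhausted during redistribution")
        # nearest open bin to any deficit bin; ties to the lower bin
        deficit_bins = np.flatnonzero(quotas > alloc)
        anchor = deficit_bins[0] if deficit_bins.size else int(np.argmax(room))
        nearest = open_bins[int(np.argmin(np.abs(open_bins - anchor)))]
        take = min(deficit, int(room[nearest]))
        alloc[nearest] += take
        deficit -= take

    last: MatchResult | None = None
    for attempt in range(max_retries + 1):
        rng = np.random.default_rng(seed + attempt)
        selected: list[InteractionRecord] = []
        for idx in range(n_bins):
            if alloc[idx] == 0:
                continue
            chosen = rng.choice(len(cand_bins[idx]), size=int(alloc[idx]), replace=False)
            selected.extend(cand_bins[idx][j] for j in sorted(chosen))
        sel_counts, _ = np.histogram(
            [instance_score_summary(r, scores, stat) for r in selected], bins=edges
        )
        chi2, p = chi_square_two_sample(pos_counts, sel_counts)
        last = MatchResult(
            [replace(r, provenance="negative") for r in selected],
            chi2,
            p,
            edges,
            pos_counts,
            sel_counts,
            n_dropped,
        )
        if p >= p_threshold or max_retries == 0:
            break
        logger.info("match attempt %d: p=%.3f < %.2f, re-seeding", attempt, p, p_threshold)
    assert last is not None
    return last


@dataclass(frozen=True)
class ReactionInstance:
    """One (enzyme, metabolite) pair with a binary reactant-role label."""

    ec: ECNumber
    metabolite: str
    label: int


def build_reaction_classification_set(
    positive_pairs: list[tuple[ECNumber, str]],
    enzyme_pool: list[ECNumber],
    metabolites: list[str],
    seed: int = 0,
) -> list[ReactionInstance]:
    """Balanced substrate/product-style dataset: positives plus equal negatives.

    Negatives are sampled uniformly without replacement from
    {pool enzymes not in any positive pair} x {metabolites}, minus the positive
    pairs themselves, so no negative duplicates a positive.
    """
    if not positive_pairs:
        raise ValueError("positive_pairs must be non-empty")
    positive_keys = {(str(ec), m) for ec, m in positive_pairs}
    positive_ecs = {str(ec) for ec, _ in positive_pairs}
    pool = [ec for ec in enzyme_pool if str(ec) not in positive_ecs]
    candidates = [
        (ec, m) for ec in pool for m in metabolites if (str(ec), m) not in positive_keys
    ]
    n = len(positive_pairs)
    if len(candidates) < n:
        raise ValueError(
            f"only {len(candidates)} candidate negative pairs for {n} positives"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n, replace=False)
    dataset = [ReactionInstance(ec, m, 1) for ec, m in positive_pairs]
    dataset += [ReactionInstance(*candidates[i], 0) for i in sorted(chosen)]
    return dataset
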