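"""Synthetic interaction worlds with planted enzymatic signal.

The generator emulates the statistical structure of the real inputs without
any external data: bacteria carrying enzyme repertoires over a hierarchical
EC universe, metabolites with chemical categories and simple valid SMILES,
metabolite-protein association scores on the 0-1000 integer scale, and
consumption/production labels driven by planted pathway signal.

Every metabolite is assigned a consuming and a producing EC prefix (three
fields deep); a bacterium that adopts a metabolite's pathway carries several
enzymes under that prefix, and those enzymes score high against the
metabolite (normal draws centred near 700) while unrelated proteins score
near background (about 300). A pair is labelled consumed/produced when the
bacterium carries at least ``min_signal_enzymes`` enzymes under the matching
prefix, then flipped with probability ``label_noise``. The bundle round-trips
through the io_model readers and feeds every downstream stage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io_model
from .encoders import ECNumber, parse_ec
from .io_model import EnzymeAnnotation, InteractionRecord, MetaboliteRecord

CATEGORY_NAMES = (
    "alcohols",
    "amines",
    "aromatics",
    "amino_acids",
    "carbohydrates",
    "carboxylic_acid_derivatives",
    "fatty_acids",
    "nucleosides",
    "steroid_derivatives",
    "vitamins",
)

# Per-category SMILES scaffolds: simple valid strings any engine can parse,
# grown by chain extension so each metabolite is distinct. {c} expands to a
# run of aliphatic carbons.
_CATEGORY_TEMPLATES = {
    "alcohols": "C{c}CO",
    "amines": "C{c}CN",
    "aromatics": "C{c}Cc1ccccc1",
    "amino_acids": "NC(C{c}C)C(=O)O",
    "carbohydrates": "OCC(O)C(O)C{c}CO",
    "carboxylic_acid_derivatives": "C{c}CC(=O)OC",
    "fatty_acids": "C{c}CCCC(=O)O",
    "nucleosides": "OCC1OC(n2ccnc2)C(O)C1{c}O",
    "steroid_derivatives": "CC12CCC(CC1)C{c}CC2O",
    "vitamins": "OC(=O)C{c}Cc1ccncc1",
}


@dataclass
class WorldConfig:
    """Generation parameters for one synthetic world.

    ``enzymes_per_bacterium`` is the (mean, spread) of each bacterium's
    background repertoire size; ``adopt_consumption``/``adopt_production`` are
    the per-pair probabilities that a bacterium carries a metabolite's pathway;
    ``min_signal_enzymes`` is the planted-label threshold on pathway enzymes;
    scores are integer draws clipped to [0, 1000].
    """

    n_bacteria: int = 48
    n_metabolites: int = 36
    n_categories: int = 10
    members_per_prefix: int = 6
    n_background_ecs: int = 150
    enzymes_per_bacterium: tuple[float, float] = (60.0, 15.0)
    adopt_consumption: float = 0.22
    adopt_production: float = 0.12
    min_signal_enzymes: int = 3
    signal_score_mean: float = 700.0
    background_score_mean: float = 300.0
    score_noise: float = 120.0
    background_proteins_per_pair: int = 6
    label_noise: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_bacteria", "n_metabolites", "n_categories", "members_per_prefix",
                     "n_background_ecs", "min_signal_enzymes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        if self.n_categories > len(CATEGORY_NAMES):
            raise ValueError(f"at most {len(CATEGORY_NAMES)} categories available")
        if self.min_signal_enzymes > self.members_per_prefix:
            raise ValueError("min_signal_enzymes cannot exceed members_per_prefix")


@dataclass
class World:
    """In-memory synthetic dataset; ``write`` produces the four-file TSV bundle."""

    config: WorldConfig
    interactions: list[InteractionRecord]
    metabolites: list[MetaboliteRecord]
    annotations: dict[str, list[EnzymeAnnotation]]
    scores: dict[tuple[str, str], list[tuple[str, int]]]
    pathway_map: dict[str, tuple[str, str]]  # metabolite -> (consume, produce) prefix

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "interactions": outdir / "interactions.tsv",
            "metabolites": outdir / "metabolites.tsv",
            "enzymes": outdir / "enzymes.tsv",
            "scores": outdir / "scores.tsv",
        }
        io_model.write_interactions(paths["interactions"], self.interactions)
        io_model.write_metabolites(paths["metabolites"], self.metabolites)
        io_model.write_enzyme_annotations(paths["enzymes"], self.annotations)
        io_model.write_association_scores(paths["scores"], self.scores)
        return paths


def _category_smiles(category: str, index: int) -> str:
    return _CATEGORY_TEMPLATES[category].format(c="C" * (index % 7))


def _draw_score(rng: np.random.Generator, mean: float, sd: float) -> int:
    return int(np.clip(round(rng.normal(mean, sd)), 0, 1000))


def generate_world(config: WorldConfig) -> World:
    """Deterministically generate a complete synthetic world from the config."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # Hierarchical EC universe: one 3-field prefix per metabolite role, each
    # with members_per_prefix serial numbers, plus unrelated background ECs.
    n_prefixes = 2 * config.n_metabolites
    prefixes = []
    used = set()
    while len(prefixes) < n_prefixes:
        p = f"{rng.integers(1, 7)}.{rng.integers(1, 21)}.{rng.integers(1, 31)}"
        if p not in used:
            used.add(p)
            prefixes.append(p)
    prefix_members = {
        p: [parse_ec(f"{p}.{serial}") for serial in range(1, config.members_per_prefix + 1)]
        for p in prefixes
    }
    background_ecs = []
    seen_bg = set()
    while len(background_ecs) < config.n_background_ecs:
        p = f"{rng.integers(1, 7)}.{rng.integers(21, 60)}.{rng.integers(1, 31)}"
        ec = f"{p}.{rng.integers(1, 50)}"
        if ec not in seen_bg:
            seen_bg.add(ec)
            background_ecs.append(parse_ec(ec))

    categories = CATEGORY_NAMES[: config.n_categories]
    metabolites = []
    pathway_map: dict[str, tuple[str, str]] = {}
    for i in range(config.n_metabolites):
        mid = f"M{i:04d}"
        category = categories[i % len(categories)]
        metabolites.append(
            MetaboliteRecord(mid, _category_smiles(category, i // len(categories)), category)
        )
        pathway_map[mid] = (prefixes[2 * i], prefixes[2 * i + 1])

    # Bacteria: background repertoire plus adopted pathways.
    annotations: dict[str, list[EnzymeAnnotation]] = {}
    adopted_consume: dict[str, set[str]] = {}
    adopted_produce: dict[str, set[str]] = {}
    for b in range(config.n_bacteria):
        taxon = f"B{b:04d}"
        mean, sd = config.enzymes_per_bacterium
        n_bg = max(5, int(round(rng.normal(mean, sd))))
        n_bg = min(n_bg, len(background_ecs))
        repertoire: list[ECNumber] = [
            background_ecs[i]
            for i in sorted(rng.choice(len(background_ecs), size=n_bg, replace=False))
        ]
        adopted_consume[taxon] = set()
        adopted_produce[taxon] = set()
        for m in metabolites:
            consume_prefix, produce_prefix = pathway_map[m.metabolite]
            if rng.random() < config.adopt_consumption:
                adopted_consume[taxon].add(m.metabolite)
                n_members = int(rng.integers(config.min_signal_enzymes,
                                             config.members_per_prefix + 1))
                repertoire.extend(prefix_members[consume_prefix][:n_members])
            if rng.random() < config.adopt_production:
                adopted_produce[taxon].add(m.metabolite)
                n_members = int(rng.integers(config.min_signal_enzymes,
                                             config.members_per_prefix + 1))
                repertoire.extend(prefix_members[produce_prefix][:n_members])
        annotations[taxon] = [
            EnzymeAnnotation(taxon, f"{taxon}_P{j:04d}", ec, float(round(rng.uniform(0.5, 0.99), 3)))
            for j, ec in enumerate(repertoire)
        ]

    # Association scores and labels.
    scores: dict[tuple[str, str], list[tuple[str, int]]] = {}
    interactions: list[InteractionRecord] = []
    for taxon, m in itertools.product(annotations, metabolites):
        consume_prefix, produce_prefix = pathway_map[m.metabolite]
        rows: list[tuple[str, int]] = []
        n_signal = {io_model.CONSUMPTION: 0, io_model.PRODUCTION: 0}
        others = []
        for a in annotations[taxon]:
            p3 = a.ec.prefix(3)
            if p3 == consume_prefix:
                n_signal[io_model.CONSUMPTION] += 1
                rows.append((a.protein, _draw_score(rng, config.signal_score_mean,
                                                    config.score_noise)))
            elif p3 == produce_prefix:
                n_signal[io_model.PRODUCTION] += 1
                rows.append((a.protein, _draw_score(rng, config.signal_score_mean,
                                                    config.score_noise)))
            else:
                others.append(a.protein)
        n_bg_rows = min(config.background_proteins_per_pair, len(others))
        if n_bg_rows:
            for i in sorted(rng.choice(len(others), size=n_bg_rows, replace=False)):
                rows.append((others[i], _draw_score(rng, config.background_score_mean,
                                                    config.score_noise)))
        if rows:
            scores[(m.metabolite, taxon)] = rows
        for label in (io_model.CONSUMPTION, io_model.PRODUCTION):
            positive = n_signal[label] >= config.min_signal_enzymes
            if rng.random() < config.label_noise:
                positive = not positive
            if positive:
                interactions.append(InteractionRecord(taxon, m.metabolite, label))

    return World(config, interactions, metabolites, annotations, scores, pathway_map)


# ---------------------------------------------------------------------------
# Enzyme-metabolite reaction worlds (substrate/product classification inputs)


@dataclass
class ReactionWorld:
    positive_pairs: list[tuple[ECNumber, str]]
    enzyme_pool: list[ECNumber]
    metabolites: list[MetaboliteRecord]
    pathway_map: dict[str, str] = field(default_factory=dict)


def generate_reaction_world(config: WorldConfig) -> ReactionWorld:
    """Planted (enzyme, metabolite) substrate-style pairs plus a disjoint pool.

    Positives pair each metabolite with the member enzymes of its planted
    pathway prefix; the pool holds unrelated background enzymes only, feeding
    the balanced negative sampler.
    """
    world = generate_world(config)
    positive_pairs: list[tuple[ECNumber, str]] = []
    pathway_map: dict[str, str] = {}
    rng = np.random.default_rng(config.seed + 1)
    for m in world.metabolites:
        prefix = world.pathway_map[m.metabolite][0]
        pathway_map[m.metabolite] = prefix
        members = [parse_ec(f"{prefix}.{s}") for s in range(1, config.members_per_prefix + 1)]
        for ec in members:
            positive_pairs.append((ec, m.metabolite))
    positive_ecs = {str(ec) for ec, _ in positive_pairs}
    pool_set = set()
    pool: list[ECNumber] = []
    while len(pool) < config.n_background_ecs:
        ec = f"{rng.integers(1, 7)}.{rng.integers(21, 60)}.{rng.integers(1, 31)}.{rng.integers(1, 50)}"
        if ec not in pool_set and ec not in positive_ecs:
            pool_set.add(ec)
            pool.append(parse_ec(ec))
    return ReactionWorld(positive_pairs, pool, world.metabolites, pathway_map)
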