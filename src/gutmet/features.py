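"""Fixed-width feature vectors: top-k enzyme encodings plus metabolite embedding.

For each (bacterium, metabolite) instance, the bacterium's enzymes that carry
both an association score to the metabolite and an EC assignment are ranked by
descending score; the top k are encoded as consecutive 1024-dimensional blocks,
any shortfall is padded with the non-enzyme placeholder encoding (EC 0.0.0.0),
and the 300-dimensional metabolite embedding closes the vector. With the
default widths a k-enzyme vector has k*1024 + 300 entries (15 enzymes ->
15,660 features; 10 -> 10,540).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoders import ECNumber, PLACEHOLDER_EC
from .io_model import EnzymeAnnotation, InteractionRecord


@dataclass(frozen=True)
class RankedEnzymeList:
    """Per-instance enzymes ordered by (score desc, EC asc, protein asc)."""

    entries: tuple[tuple[str, ECNumber, int], ...]  # (protein, ec, score)

    @property
    def valid(self) -> bool:
        """An instance is valid only if at least one scored enzyme exists."""
        return len(self.entries) > 0


def collect_instance_enzymes(
    bacterium: str,
    metabolite: str,
    annotations: dict[str, list[EnzymeAnnotation]],
    scores: dict[tuple[str, str], list[tuple[str, int]]],
) -> RankedEnzymeList:
    """Rank the bacterium's metabolite-scored, EC-annotated enzymes.

    Proteins without an EC assignment (or annotated as the non-enzyme
    placeholder) are excluded: the feature blocks encode EC identity. The
    ordering is total - score descending, then EC string, then protein ID -
    so the result is independent of input row order.
    """
    ec_of: dict[str, ECNumber] = {}
    for a in annotations.get(bacterium, ()):  # last annotation wins per protein
        ec_of[a.protein] = a.ec
    entries = []
    for protein, score in scores.get((metabolite, bacterium), ()):
        ec = ec_of.get(protein)
        if ec is None or not ec.is_enzyme:
            continue
        entries.append((protein, ec, score))
    entries.sort(key=lambda e: (-e[2], str(e[1]), e[0]))
    return RankedEnzymeList(tuple(entries))


def feature_dimension(k: int, d_e: int = 1024, d_m: int = 300) -> int:
    """Width of a k-enzyme feature vector: k*d_e + d_m."""
    if k <= 0 or d_e <= 0 or d_m < 0:
        raise ValueError("k and d_e must be positive, d_m non-negative")
    return k * d_e + d_m


def build_feature_vector(
    ranked: RankedEnzymeList,
    metabolite_embedding: np.ndarray,
    k: int,
    ec_encoder,
) -> np.ndarray:
    """Concatenate the top-k enzyme encodings and the metabolite embedding.

    Layout: [enzyme 1 | ... | enzyme k | metabolite]. When fewer than k
    enzymes are available, the remaining blocks carry the placeholder
    (EC 0.0.0.0) encoding.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not ranked.valid:
        raise ValueError("instance has no scored, EC-annotated enzyme")
    d_e = ec_encoder.dim
    metabolite_embedding = np.asarray(metabolite_embedding, dtype=float)
    out = np.empty(feature_dimension(k, d_e, metabolite_embedding.size))
    pad = ec_encoder.encode(PLACEHOLDER_EC)
    for i in range(k):
        block = (
            ec_encoder.encode(ranked.entries[i][1]) if i < len(ranked.entries) else pad
        )
        out[i * d_e : (i + 1) * d_e] = block
    out[k * d_e :] = metabolite_embedding
    return out


def build_feature_matrix(
    records: list[InteractionRecord],
    annotations: dict[str, list[EnzymeAnnotation]],
    scores: dict[tuple[str, str], list[tuple[str, int]]],
    metabolite_embeddings: dict[str, np.ndarray],
    k: int,
    ec_encoder,
) -> tuple[np.ndarray, list[InteractionRecord], list[InteractionRecord]]:
    """Feature matrix for a record list; returns (X, kept records, invalid records).

    Records without any scored EC-annotated enzyme, or without a metabolite
    embedding, are invalid and reported separately rather than silently
    dropped.
    """
    rows, kept, invalid = [], [], []
    for r in records:
        ranked = collect_instance_enzymes(r.bacterium, r.metabolite, annotations, scores)
        embedding = metabolite_embeddings.get(r.metabolite)
        if not ranked.valid or embedding is None:
            invalid.append(r)
            continue
        rows.append(build_feature_vector(ranked, embedding, k, ec_encoder))
        kept.append(r)
    X = np.vstack(rows) if rows else np.empty((0, 0))
    return X, kept, invalid
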