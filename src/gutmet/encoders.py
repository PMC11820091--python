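"""EC-number parsing, hierarchical bitwise accuracy, and vector encoders.

Enzyme Commission (EC) numbers are four dot-separated fields
(class.subclass.sub-subclass.serial); trailing fields may be missing, written
``-`` or simply absent. ``0.0.0.0`` is the non-enzyme placeholder used to pad
fixed-width feature vectors.

Two encoder families turn tokens into dense vectors: a 1024-dimensional enzyme
encoding and a 300-dimensional metabolite structural embedding. Externally
trained embedding tables (EC2Vec- or Mol2vec-style) plug in through a simple
token -> vector TSV; when no table is supplied, deterministic fallback encoders
are used. The enzyme fallback sums seeded pseudo-random unit vectors keyed by
the EC's digit prefixes of length 1..4, so enzymes sharing a classification
prefix receive nearby vectors; the metabolite fallback projects fingerprint
on-bits through seeded random directions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np

from .chem import Fingerprint, hashed_fingerprint

MISSING = "-"
ENZYME_DIM = 1024
METABOLITE_DIM = 300

#: Library seed constant for the fallback encoders (overridable per encoder).
DEFAULT_ENCODER_SEED = 170469


@dataclass(frozen=True)
class ECNumber:
    """An EC number as a 4-tuple of tokens; missing trailing tokens are '-'."""

    tokens: tuple[str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.tokens) != 4:
            raise ValueError("ECNumber carries exactly 4 token slots")
        if self.tokens[0] == MISSING:
            raise ValueError("first EC field must be present")
        seen_missing = False
        for token in self.tokens:
            if token == MISSING:
                seen_missing = True
            elif seen_missing:
                raise ValueError(f"non-missing token after missing one in {self.tokens}")

    @property
    def is_enzyme(self) -> bool:
        """False only for the 0.0.0.0 non-enzyme placeholder."""
        return self.tokens != ("0", "0", "0", "0")

    @property
    def n_fields(self) -> int:
        return sum(1 for t in self.tokens if t != MISSING)

    def prefix(self, length: int) -> str:
        return ".".join(self.tokens[:length])

    def __str__(self) -> str:
        return ".".join(t for t in self.tokens if t != MISSING)


PLACEHOLDER_EC = ECNumber(("0", "0", "0", "0"))


def parse_ec(text: str) -> ECNumber:
    """Parse a dot-separated EC string; '-' and absent trailing fields are missing."""
    if not text or not text.strip():
        raise ValueError("empty EC string")
    parts = [p.strip() for p in text.strip().split(".")]
    if len(parts) > 4:
        raise ValueError(f"EC number {text!r} has more than 4 fields")
    if any(p == "" for p in parts):
        raise ValueError(f"EC number {text!r} contains an empty field")
    tokens = parts + [MISSING] * (4 - len(parts))
    return ECNumber(tuple(tokens))


# ---------------------------------------------------------------------------
# Bitwise hierarchical accuracy


@dataclass(frozen=True)
class BitwiseResult:
    """Per-level correctness of a predicted EC number at digit prefixes 1-4."""

    level_correct: tuple[bool, bool, bool, bool]
    levels_evaluated: tuple[bool, bool, bool, bool]


def bitwise_accuracy(pred: ECNumber, true_ec: ECNumber) -> BitwiseResult:
    """Score a prediction at the four hierarchy levels.

    The first digit gates everything: if it differs from the truth, all four
    levels are incorrect. Otherwise level L is correct when every available
    digit among the first L matches; a field missing on either side is skipped
    (a prediction is judged only on the digits that can be compared).
    ``levels_evaluated`` flags the levels where the truth actually carries a
    digit.
    """
    evaluated = tuple(t != MISSING for t in true_ec.tokens)
    if pred.tokens[0] != true_ec.tokens[0]:
        return BitwiseResult((False, False, False, False), evaluated)
    correct = []
    ok = True
    for i in range(4):
        p, t = pred.tokens[i], true_ec.tokens[i]
        if ok and t != MISSING and p != MISSING and p != t:
            ok = False
        correct.append(ok)
    return BitwiseResult(tuple(correct), evaluated)


def aggregate_bitwise(pairs: Sequence[tuple[ECNumber, ECNumber]]) -> tuple[float, float, float, float]:
    """Mean per-level accuracy over (predicted, true) pairs."""
    if not pairs:
        raise ValueError("aggregate_bitwise requires at least one pair")
    sums = np.zeros(4)
    for pred, true_ec in pairs:
        sums += np.array(bitwise_accuracy(pred, true_ec).level_correct, dtype=float)
    return tuple(sums / len(pairs))


# ---------------------------------------------------------------------------
# Deterministic fallback encoders


@lru_cache(maxsize=65536)
def _unit_vector(key: str, dim: int, seed: int) -> np.ndarray:
    """Seeded pseudo-random unit vector, a pure function of (key, dim, seed)."""
    digest = hashlib.blake2b(f"{seed}:{key}".encode(), digest_size=8).digest()
    rng = np.random.default_rng(int.from_bytes(digest, "big") % (2**63))
    v = rng.standard_normal(dim)
    v /= np.linalg.norm(v)
    v.flags.writeable = False
    return v


class FallbackECEncoder:
    """Hierarchy-aware deterministic enzyme encoding.

    The vector is the sum of four seeded unit vectors keyed by the EC's digit
    prefixes of length 1..4, so e.g. 1.1.1.1 and 1.1.1.2 share three of four
    terms and end up close in cosine similarity, while enzymes from different
    top-level classes share none. The non-enzyme placeholder encodes to the
    zero vector: padding must be inert in downstream tree splits.
    """

    dim = ENZYME_DIM

    def __init__(self, seed: int = DEFAULT_ENCODER_SEED) -> None:
        self.seed = seed

    def encode(self, ec: ECNumber) -> np.ndarray:
        if not ec.is_enzyme:
            return np.zeros(self.dim)
        out = np.zeros(self.dim)
        for length in range(1, 5):
            out += _unit_vector(f"ec:{ec.prefix(length)}", self.dim, self.seed)
        return out


class FallbackMetaboliteEncoder:
    """Deterministic metabolite embedding via seeded random projection.

    Fingerprint on-bits are mapped to seeded unit directions and summed,
    which is a fixed random projection of the fingerprint into 300 dims.
    """

    dim = METABOLITE_DIM

    def __init__(self, seed: int = DEFAULT_ENCODER_SEED, engine=None) -> None:
        self.seed = seed
        self.engine = engine

    def _fingerprint(self, smiles: str) -> Fingerprint:
        if self.engine is not None:
            return self.engine.fingerprint(smiles)
        return hashed_fingerprint(smiles)

    def encode(self, smiles: str) -> np.ndarray:
        fp = self._fingerprint(smiles)
        out = np.zeros(self.dim)
        for bit in sorted(fp.bits):
            out += _unit_vector(f"fpbit:{bit}", self.dim, self.seed)
        return out


class TableEncoder:
    """Encoder backed by a token -> vector table (TSV: token then floats).

    This is the plug-in path for externally trained embedding models; the
    table is queried with the literal token (an EC string or a metabolite ID).
    """

    def __init__(self, path: str | Path, dim: int) -> None:
        self.dim = dim
        self.table: dict[str, np.ndarray] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            token, *values = line.split("\t")
            vector = np.array([float(v) for v in values])
            if vector.shape != (dim,):
                raise ValueError(
                    f"embedding for {token!r} has length {len(values)}, expected {dim}"
                )
            self.table[token] = vector

    def encode(self, token) -> np.ndarray:
        key = str(token)
        try:
            return self.table[key]
        except KeyError:
            raise KeyError(f"token {key!r} absent from embedding table") from None


def load_ec_encoder(model_dir: str | Path | None = None, seed: int = DEFAULT_ENCODER_SEED):
    """EC encoder from ``model_dir/ec_vectors.tsv`` if present, else fallback."""
    if model_dir is not None:
        table = Path(model_dir) / "ec_vectors.tsv"
        if table.exists():
            return TableEncoder(table, ENZYME_DIM)
    return FallbackECEncoder(seed)


def load_metabolite_encoder(model_dir: str | Path | None = None, seed: int = DEFAULT_ENCODER_SEED):
    """Metabolite encoder from ``model_dir/metabolite_vectors.tsv``, else fallback."""
    if model_dir is not None:
        table = Path(model_dir) / "metabolite_vectors.tsv"
        if table.exists():
            return TableEncoder(table, METABOLITE_DIM)
    return FallbackMetaboliteEncoder(seed)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u.v / (|u||v|); defined as 0.0 when either vector is zero."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"vector lengths differ: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))
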