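"""Physico-chemical properties, fingerprints and Tanimoto similarity.

Chemistry is accessed through a small engine interface so that the rest of the
pipeline never imports a toolkit directly. Two engines are provided:

* :class:`RDKitEngine` - RDKit-backed properties (average molecular weight,
  Wildman-Crippen logP, Lipinski H-bond donor/acceptor counts) and 2048-bit
  Morgan fingerprints (radius 2).
* :class:`FixtureEngine` - reads precomputed properties from a metabolite
  table and fingerprints the SMILES string itself by hashing character
  n-grams; useful wherever a full toolkit is unnecessary.

Both fingerprint flavours are deterministic carriers for Tanimoto similarity;
the similarity search itself does not depend on which one is used, only on it
being applied consistently to both sides.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Iterable, Protocol

DEFAULT_NBITS = 2048


class SmilesError(ValueError):
    """A SMILES string could not be interpreted."""


@dataclass(frozen=True)
class PropertySet:
    """Molecular weight (Da), logP, and hydrogen-bond donor/acceptor counts."""

    mw: float
    logp: float
    hbd: int
    hba: int

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError("mw must be positive")
        if self.hbd < 0 or self.hba < 0:
            raise ValueError("hbd/hba must be non-negative")


@dataclass(frozen=True)
class Fingerprint:
    bits: frozenset[int]
    nbits: int = DEFAULT_NBITS

    def __post_init__(self) -> None:
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.nbits):
            raise ValueError("fingerprint bit index outside [0, nbits)")


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|a & b| / |a | b|, with 0.0 for two empty fingerprints."""
    if a.nbits != b.nbits:
        raise ValueError(f"fingerprint widths differ: {a.nbits} vs {b.nbits}")
    union = a.bits | b.bits
    if not union:
        return 0.0
    return len(a.bits & b.bits) / len(union)


class ChemistryEngine(Protocol):
    def compute_properties(self, smiles: str) -> PropertySet: ...

    def fingerprint(self, smiles: str) -> Fingerprint: ...


# Two-letter element symbols whose first letter is C but which are not carbon.
_NOT_CARBON = ("Cl", "Ca", "Cd", "Ce", "Cf", "Cm", "Co", "Cr", "Cs", "Cu", "Cn")
_BRACKET_ATOM = re.compile(r"\[([^\]]+)\]")


def smiles_has_carbon(smiles: str) -> bool:
    """Token-level scan for at least one carbon atom (aliphatic or aromatic)."""
    if not smiles:
        raise SmilesError("empty SMILES")
    # Bracket atoms: element symbol follows an optional isotope number.
    rest = smiles
    for match in _BRACKET_ATOM.finditer(smiles):
        body = re.sub(r"^\d+", "", match.group(1))
        if body.startswith("c") or (
            body.startswith("C") and not any(body.startswith(sym) for sym in _NOT_CARBON)
        ):
            return True
    rest = _BRACKET_ATOM.sub("", smiles)
    i = 0
    while i < len(rest):
        ch = rest[i]
        if ch == "c":
            return True
        if ch == "C":
            if rest[i : i + 2] in _NOT_CARBON:
                i += 2
                continue
            return True
        i += 1
    return False


def hashed_fingerprint(smiles: str, nbits: int = DEFAULT_NBITS) -> Fingerprint:
    """Deterministic fallback fingerprint: hashed character n-grams (n = 1..3)."""
    if not smiles:
        raise SmilesError("empty SMILES")
    bits = set()
    for n in (1, 2, 3):
        for i in range(len(smiles) - n + 1):
            digest = hashlib.blake2b(
                f"{n}:{smiles[i : i + n]}".encode(), digest_size=8
            ).digest()
            bits.add(int.from_bytes(digest, "big") % nbits)
    return Fingerprint(frozenset(bits), nbits)


class RDKitEngine:
    """RDKit-backed properties and Morgan fingerprints (radius 2, 2048 bits)."""

    def __init__(self, nbits: int = DEFAULT_NBITS, radius: int = 2) -> None:
        self.nbits = nbits
        self.radius = radius

    def _mol(self, smiles: str):
        from rdkit import Chem

        if not smiles:
            raise SmilesError("empty SMILES")
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise SmilesError(f"RDKit could not parse SMILES {smiles!r}")
        return mol

    def compute_properties(self, smiles: str) -> PropertySet:
        from rdkit.Chem import Crippen, Descriptors, Lipinski

        mol = self._mol(smiles)
        return PropertySet(
            mw=Descriptors.MolWt(mol),
            logp=Crippen.MolLogP(mol),
            hbd=Lipinski.NumHDonors(mol),
            hba=Lipinski.NumHAcceptors(mol),
        )

    def fingerprint(self, smiles: str) -> Fingerprint:
        from rdkit.Chem import rdFingerprintGenerator

        mol = self._mol(smiles)
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=self.radius, fpSize=self.nbits
        )
        fp = gen.GetFingerprint(mol)
        return Fingerprint(frozenset(fp.GetOnBits()), self.nbits)

    def canonical_smiles(self, smiles: str) -> str:
        from rdkit import Chem

        return Chem.MolToSmiles(self._mol(smiles))


@dataclass
class FixtureEngine:
    """Chemistry engine reading precomputed properties from a metabolite table.

    ``records`` is any iterable of objects with smiles/mw/logp/hbd/hba
    attributes (e.g. :class:`gutmet.io_model.MetaboliteRecord`). Fingerprints
    are hashed n-gram fingerprints of the raw SMILES string.
    """

    records: Iterable = ()
    nbits: int = DEFAULT_NBITS
    _table: dict = field(init=False, default_factory=dict)

    def __post_init__(self) -> None:
        for r in self.records:
            if r.mw is None:
                continue
            self._table[r.smiles] = PropertySet(
                mw=r.mw,
                logp=r.logp if r.logp is not None else 0.0,
                hbd=r.hbd if r.hbd is not None else 0,
                hba=r.hba if r.hba is not None else 0,
            )

    def compute_properties(self, smiles: str) -> PropertySet:
        try:
            return self._table[smiles]
        except KeyError:
            raise SmilesError(f"no precomputed properties for SMILES {smiles!r}") from None

    def fingerprint(self, smiles: str) -> Fingerprint:
        return hashed_fingerprint(smiles, self.nbits)


_default: ChemistryEngine | None = None


def default_engine() -> ChemistryEngine:
    """The process-wide engine: RDKit if importable, else hashed-fingerprint only."""
    global _default
    if _default is None:
        try:
            import rdkit  # noqa: F401

            _default = RDKitEngine()
        except ImportError:  # pragma: no cover - rdkit is a declared extra
            _default = FixtureEngine()
    return _default


def set_default_engine(engine: ChemistryEngine | None) -> None:
    global _default
    _default = engine
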