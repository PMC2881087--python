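"""Cheminformatics primitives exposed both as plain functions and as custom
SPARQL extension functions.

* :func:`fingerprint` — 166-slot binary substructure descriptor (MACCS keys by
  default; the backend is pluggable so pipelines can run without a chemistry
  engine).
* :func:`tanimoto` — set-overlap similarity N_C / (N_A + N_B - N_C) between
  two fingerprints, where N_C is the shared set-bit count and N_A, N_B the
  per-fingerprint set-bit counts.
* :func:`rule_of_five` — Lipinski drug-likeness: MW <= 500 Da, logP <= 5,
  H-bond donors <= 5, H-bond acceptors <= 10 (boundaries inclusive); a
  compound passes only if all four rules hold.
* :func:`is_active` — PubChem-style activity gate: outcome code 2 (active)
  with normalized score strictly greater than the threshold (default 50).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from rdflib import Literal, URIRef
from rdflib.plugins.sparql.operators import register_custom_function

from .errors import DimensionError, StructureParseError
from .vocab import FN

FINGERPRINT_LENGTH = 166


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary substructure descriptor."""

    bits: tuple[int, ...]

    def __post_init__(self):
        if len(self.bits) != FINGERPRINT_LENGTH:
            raise DimensionError(
                f"fingerprint must have {FINGERPRINT_LENGTH} bits, got {len(self.bits)}"
            )
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("fingerprint bits must be 0 or 1")

    @classmethod
    def from_on_bits(cls, on_bits: Sequence[int]) -> "Fingerprint":
        bits = [0] * FINGERPRINT_LENGTH
        for i in on_bits:
            bits[i] = 1
        return cls(tuple(bits))

    @classmethod
    def from_string(cls, text: str) -> "Fingerprint":
        return cls(tuple(int(c) for c in text))

    @property
    def set_count(self) -> int:
        return sum(self.bits)

    def __len__(self) -> int:
        return len(self.bits)

    def __str__(self) -> str:
        return "".join(str(b) for b in self.bits)


# -- fingerprint backends --------------------------------------------------

FingerprintBackend = Callable[[str], Sequence[int]]


def maccs_backend(structure: str) -> Sequence[int]:
    """Default backend: the standard 166 MACCS structural keys via RDKit.

    RDKit numbers MACCS keys 1..166 in a 167-slot vector whose slot 0 is
    unused; slots 1..166 are returned.
    """
    from rdkit import Chem, RDLogger
    from rdkit.Chem import MACCSkeys

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise StructureParseError(structure)
    keys = MACCSkeys.GenMACCSKeys(mol)
    return [int(keys.GetBit(i)) for i in range(1, FINGERPRINT_LENGTH + 1)]


class TableBackend:
    """Table-driven backend mapping structures to preset on-bit lists.

    Useful in tests and fixtures where determinism matters and chemistry does
    not; unknown structures raise the same parse error as a real engine.
    """

    def __init__(self, table: Mapping[str, Sequence[int]]):
        self.table = dict(table)

    def __call__(self, structure: str) -> Sequence[int]:
        try:
            on_bits = self.table[structure]
        except KeyError:
            raise StructureParseError(structure) from None
        return Fingerprint.from_on_bits(on_bits).bits


def fingerprint(structure: str, backend: FingerprintBackend | None = None) -> Fingerprint:
    """Compute the 166-bit structural fingerprint of a SMILES string."""
    backend = backend or maccs_backend
    return Fingerprint(tuple(int(b) for b in backend(structure)))


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient N_C / (N_A + N_B - N_C); 0 when both are empty."""
    if len(a) != len(b):
        raise DimensionError(f"fingerprint lengths differ: {len(a)} vs {len(b)}")
    n_c = sum(x & y for x, y in zip(a.bits, b.bits))
    denom = a.set_count + b.set_count - n_c
    if denom == 0:
        return 0.0
    return n_c / denom


# -- drug-likeness ----------------------------------------------------------


@dataclass(frozen=True)
class MoleculeDescriptors:
    """The four descriptors the drug-likeness rules evaluate."""

    molecular_weight: float  # daltons
    logp: float
    hbd_count: int
    hba_count: int

    def __post_init__(self):
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be positive")
        if self.hbd_count < 0 or self.hba_count < 0:
            raise ValueError("H-bond donor/acceptor counts must be non-negative")


@dataclass(frozen=True)
class RuleOfFiveResult:
    mw_ok: bool
    logp_ok: bool
    hbd_ok: bool
    hba_ok: bool

    @property
    def passes(self) -> bool:
        return self.mw_ok and self.logp_ok and self.hbd_ok and self.hba_ok


def rule_of_five(d: MoleculeDescriptors) -> RuleOfFiveResult:
    """Evaluate the four Lipinski rules (inclusive boundaries)."""
    return RuleOfFiveResult(
        mw_ok=d.molecular_weight <= 500,
        logp_ok=d.logp <= 5,
        hbd_ok=d.hbd_count <= 5,
        hba_ok=d.hba_count <= 10,
    )


# -- bioassay activity -------------------------------------------------------

OUTCOME_INACTIVE = 1
OUTCOME_ACTIVE = 2


@dataclass(frozen=True)
class ActivityRecord:
    """One bioassay outcome row: compound x assay x target."""

    compound_id: int
    assay_id: str
    target_accession: str
    outcome: int
    score: float

    def __post_init__(self):
        if self.compound_id <= 0:
            raise ValueError("compound_id (CID) must be positive")
        if self.outcome not in (OUTCOME_INACTIVE, OUTCOME_ACTIVE):
            raise ValueError("outcome must be 1 (inactive) or 2 (active)")
        if not 0 <= self.score <= 100:
            raise ValueError("score must lie in [0, 100]")


def is_active(r: ActivityRecord, score_threshold: float = 50) -> bool:
    """Active means outcome code 2 AND score strictly above the threshold."""
    return r.outcome == OUTCOME_ACTIVE and r.score > score_threshold


# -- SPARQL extension functions ----------------------------------------------

FN_FINGERPRINT = URIRef(FN["fingerprint"])
FN_TANIMOTO = URIRef(FN["tanimoto"])
FN_RULE_OF_FIVE = URIRef(FN["ruleOfFive"])

_registered = False


def _coerce_fingerprint(value, backend: FingerprintBackend | None) -> Fingerprint:
    text = str(value)
    if len(text) == FINGERPRINT_LENGTH and set(text) <= {"0", "1"}:
        return Fingerprint.from_string(text)
    return fingerprint(text, backend=backend)


def register_sparql_functions(backend: FingerprintBackend | None = None) -> None:
    """Register fingerprint/tanimoto/ruleOfFive as SPARQL filter functions.

    After registration queries may use e.g.
    ``FILTER (fn:tanimoto(?smiles, "CCO") > 0.8)`` where ``fn:`` is the
    package function namespace; tanimoto accepts SMILES strings or 166-char
    bit strings interchangeably. Safe to call repeatedly.
    """
    global _registered

    def _fn_fingerprint(arg):
        return Literal(str(fingerprint(str(arg), backend=backend)))

    def _fn_tanimoto(a, b):
        fa = _coerce_fingerprint(a, backend)
        fb = _coerce_fingerprint(b, backend)
        return Literal(tanimoto(fa, fb))

    def _fn_rule_of_five(mw, logp, hbd, hba):
        d = MoleculeDescriptors(
            float(mw.toPython()), float(logp.toPython()),
            int(hbd.toPython()), int(hba.toPython()),
        )
        return Literal(rule_of_five(d).passes)

    for uri, func in (
        (FN_FINGERPRINT, _fn_fingerprint),
        (FN_TANIMOTO, _fn_tanimoto),
        (FN_RULE_OF_FIVE, _fn_rule_of_five),
    ):
        register_custom_function(uri, func, override=True)
    _registered = True
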