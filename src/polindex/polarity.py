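"""Dipeptide polarity-transition matrix and rank-position signature.

The polarity-index method classifies a peptide by the *positions* of
the most and least populated cells of a 4x4 transition matrix.  The 20
amino acids fall into four side-chain polarity groups, kept in the
fixed order

    P+ (basic hydrophilic: H, K, R)   -> rows/cols 1
    P- (polar acidic:      D, E, Y)   -> rows/cols 2
    N  (neutral polar:     C, G, N, Q, S, T) -> rows/cols 3
    NP (non-polar:         A, F, I, L, M, P, V, W) -> rows/cols 4

Every overlapping residue pair (i, i+1) of a sequence increments the
cell addressed by (group of first residue, group of second residue).
Cells are referred to by their 1-based row-major position 1..16.  The
signature of a matrix is the set of the four highest-incidence
positions {M1..M4} plus the single lowest-incidence position M16.  A
peptide is called SCAAP-like when its signature coincides with that of
a template matrix pooled from reference peptides of high therapeutic
index.

Ties are resolved in favour of the higher position index, both when
filling the top four and when picking the minimum; this is the total
rule under which the pooled two-peptide template reproduces the
published signature {16, 4, 13, 15, 10}.  M16 is chosen among the
twelve positions not already consumed by the top four.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .peptide import PeptideRecord, SequenceError, validate_sequence

logger = logging.getLogger(__name__)

#: Group codes in matrix order (row/column 1..4).
GROUP_ORDER: tuple[str, ...] = ("P+", "P-", "N", "NP")

#: Side-chain polarity classification of the 20 canonical residues.
GROUP_RESIDUES: Mapping[str, str] = {
    "P+": "HKR",
    "P-": "DEY",
    "N": "CGNQST",
    "NP": "AFILMPVW",
}

DEFAULT_WEIGHT_FACTOR = 0.30
ALPHABET_VERSION = "side-chain-polarity-v1"


@dataclass(frozen=True)
class PolarityGroup:
    """One of the four polarity groups, with its 1-based matrix index."""

    code: str
    index: int

    def __post_init__(self):
        if self.code not in GROUP_ORDER:
            raise ValueError(f"unknown polarity group {self.code!r}")
        if GROUP_ORDER[self.index - 1] != self.code:
            raise ValueError(
                f"group {self.code!r} must carry index "
                f"{GROUP_ORDER.index(self.code) + 1}, got {self.index}")


@dataclass(frozen=True)
class PolarityAlphabet:
    """Total mapping from the 20 canonical residues to polarity groups."""

    residue_to_group: Mapping[str, PolarityGroup]
    version: str = ALPHABET_VERSION

    def __post_init__(self):
        residues = set(self.residue_to_group)
        if len(residues) != 20:
            raise ValueError(
                f"alphabet must cover exactly 20 residues, got {len(residues)}")

    @classmethod
    def default(cls) -> "PolarityAlphabet":
        mapping = {}
        for index, code in enumerate(GROUP_ORDER, start=1):
            group = PolarityGroup(code=code, index=index)
            for residue in GROUP_RESIDUES[code]:
                mapping[residue] = group
        return cls(residue_to_group=mapping)

    def group_of(self, residue: str) -> PolarityGroup:
        try:
            return self.residue_to_group[residue.upper()]
        except KeyError:
            raise SequenceError(
                f"non-canonical residue {residue!r} has no polarity group"
            ) from None


DEFAULT_ALPHABET = PolarityAlphabet.default()


def classify_residue(residue: str,
                     alphabet: PolarityAlphabet = DEFAULT_ALPHABET
                     ) -> PolarityGroup:
    """Return the polarity group of a single one-letter residue code."""
    if len(residue) != 1:
        raise ValueError(f"expected a single character, got {residue!r}")
    return alphabet.group_of(residue)


def pair_position(first: str, second: str,
                  alphabet: PolarityAlphabet = DEFAULT_ALPHABET) -> int:
    """1-based row-major matrix position of an adjacent residue pair.

    The first residue selects the row, the second the column:
    ``position = 4 * (row - 1) + col``.
    """
    row = classify_residue(first, alphabet).index
    col = classify_residue(second, alphabet).index
    return 4 * (row - 1) + col


def position_label(position: int) -> str:
    """Human-readable ``(row-group, col-group)`` label of a 1..16 position."""
    if not 1 <= position <= 16:
        raise ValueError(f"position must be in 1..16, got {position}")
    row, col = divmod(position - 1, 4)
    return f"({GROUP_ORDER[row]},{GROUP_ORDER[col]})"


@dataclass(frozen=True)
class IncidenceMatrix:
    """16-cell dipeptide polarity-transition matrix.

    ``counts`` holds raw pair counts in row-major position order
    (index 0 of the array is position 1).  ``weighted`` is the relative
    frequency distribution scaled by ``weight_factor``; the scaling is
    strictly positive and therefore never changes the rank order of the
    cells.
    """

    counts: np.ndarray
    weight_factor: float = DEFAULT_WEIGHT_FACTOR

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (16,):
            raise ValueError(f"counts must have 16 cells, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total_pairs(self) -> int:
        return int(self.counts.sum())

    @property
    def weighted(self) -> np.ndarray:
        total = self.total_pairs
        if total == 0:
            return np.zeros(16)
        return self.weight_factor * self.counts / total

    def count_at(self, position: int) -> int:
        """Raw count at a 1-based position."""
        if not 1 <= position <= 16:
            raise ValueError(f"position must be in 1..16, got {position}")
        return int(self.counts[position - 1])

    def as_dict(self) -> dict[int, int]:
        """Non-zero cells as {position: count}."""
        return {p: int(c) for p, c in enumerate(self.counts, start=1) if c}


@dataclass(frozen=True)
class Signature:
    """Rank-position signature {M1..M4, M16} of an incidence matrix."""

    top4_ordered: tuple[int, int, int, int]
    m16: int
    tie_note: bool = False

    @property
    def top4(self) -> frozenset[int]:
        return frozenset(self.top4_ordered)

    def __str__(self) -> str:
        cells = ",".join(str(p) for p in self.top4_ordered)
        return f"{{{cells};{self.m16}}}"


def _sequence_pairs(record: PeptideRecord, alphabet: PolarityAlphabet,
                    lenient: bool) -> Iterable[int]:
    seq = record.sequence
    if len(seq) < 2:
        raise SequenceError(
            f"sequence of length {len(seq)} has no residue pairs", record.id)
    if not lenient:
        validate_sequence(seq, record.id)
    for i in range(len(seq) - 1):
        a, b = seq[i], seq[i + 1]
        try:
            yield pair_position(a, b, alphabet)
        except SequenceError:
            if lenient:
                logger.warning(
                    "record %s: skipping pair %r at position %d "
                    "(non-canonical residue)", record.id, a + b, i + 1)
                continue
            raise


def build_incidence_matrix(records: Sequence[PeptideRecord] | PeptideRecord,
                           alphabet: PolarityAlphabet = DEFAULT_ALPHABET,
                           weight_factor: float = DEFAULT_WEIGHT_FACTOR,
                           lenient: bool = False) -> IncidenceMatrix:
    """Count adjacent residue pairs of one or more peptides into 16 cells.

    Pairs are read left to right with a one-residue step; no pair spans
    a boundary between two input sequences.  In lenient mode, pairs
    containing a non-canonical residue are skipped with a warning
    instead of raising.
    """
    if isinstance(records, PeptideRecord):
        records = [records]
    if not records:
        raise ValueError("at least one peptide is required")
    counts = np.zeros(16, dtype=np.int64)
    for record in records:
        for position in _sequence_pairs(record, alphabet, lenient):
            counts[position - 1] += 1
    return IncidenceMatrix(counts=counts, weight_factor=weight_factor)


def extract_signature(matrix: IncidenceMatrix) -> Signature:
    """Top-4 and minimum cell positions of a non-empty incidence matrix.

    Positions are ranked by count descending; ties fall to the higher
    position index.  The minimum is taken over the twelve positions not
    in the top four, again breaking ties towards the higher index.
    ``tie_note`` is set when a tie touched either selection boundary.
    """
    if matrix.total_pairs == 0:
        raise ValueError("cannot extract a signature from an empty matrix")
    counts = matrix.counts
    # rank all 16 positions: count desc, then position index desc
    order = sorted(range(1, 17), key=lambda p: (-counts[p - 1], -p))
    top4 = tuple(order[:4])
    rest = order[4:]
    min_count = min(counts[p - 1] for p in rest)
    m16 = max(p for p in rest if counts[p - 1] == min_count)
    boundary_tie = bool(counts[order[3] - 1] == counts[order[4] - 1])
    min_tie = sum(1 for p in rest if counts[p - 1] == min_count) > 1
    if boundary_tie:
        logger.warning(
            "top-4 selection boundary tie at count %d; higher-index rule "
            "applied", int(counts[order[3] - 1]))
    return Signature(top4_ordered=top4, m16=m16,
                     tie_note=boundary_tie or min_tie)


@dataclass(frozen=True)
class TemplateModel:
    """Pooled template matrix and signature of the reference SCAAP set."""

    q_matrix: IncidenceMatrix
    signature: Signature
    source_ids: tuple[str, ...]
    ti_threshold: float = 1000.0
    alphabet_version: str = ALPHABET_VERSION

    def to_json(self) -> str:
        payload = {
            "format": "polindex-template-v1",
            "alphabet_version": self.alphabet_version,
            "counts": [int(c) for c in self.q_matrix.counts],
            "weight_factor": self.q_matrix.weight_factor,
            "ti_threshold": self.ti_threshold,
            "source_ids": list(self.source_ids),
            "signature": {
                "top4_ordered": list(self.signature.top4_ordered),
                "top4_set": sorted(self.signature.top4),
                "m16": self.signature.m16,
                "tie_note": self.signature.tie_note,
            },
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TemplateModel":
        payload = json.loads(text)
        matrix = IncidenceMatrix(
            counts=np.array(payload["counts"], dtype=np.int64),
            weight_factor=float(payload["weight_factor"]))
        sig = payload["signature"]
        signature = Signature(
            top4_ordered=tuple(sig["top4_ordered"]),
            m16=int(sig["m16"]),
            tie_note=bool(sig["tie_note"]))
        return cls(q_matrix=matrix, signature=signature,
                   source_ids=tuple(payload["source_ids"]),
                   ti_threshold=float(payload["ti_threshold"]),
                   alphabet_version=payload.get(
                       "alphabet_version", ALPHABET_VERSION))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "TemplateModel":
        return cls.from_json(Path(path).read_text())


def build_template(candidates: Sequence[tuple[PeptideRecord, float]],
                   ti_threshold: float = 1000.0,
                   alphabet: PolarityAlphabet = DEFAULT_ALPHABET,
                   weight_factor: float = DEFAULT_WEIGHT_FACTOR
                   ) -> TemplateModel:
    """Pool the high-therapeutic-index candidates into a template.

    Candidates with therapeutic index >= ``ti_threshold`` (inclusive)
    are retained; their raw pair counts are summed into one matrix
    whose signature becomes the classification template.
    """
    selected = [(rec, ti) for rec, ti in candidates if ti >= ti_threshold]
    if not selected:
        rejected = ", ".join(
            f"{rec.id}={ti:g}" for rec, ti in candidates)
        raise ValueError(
            f"no candidate reaches therapeutic index {ti_threshold:g} "
            f"(rejected: {rejected})")
    records = [rec for rec, _ in selected]
    matrix = build_incidence_matrix(records, alphabet=alphabet,
                                    weight_factor=weight_factor)
    return TemplateModel(q_matrix=matrix,
                         signature=extract_signature(matrix),
                         source_ids=tuple(rec.id for rec in records),
                         ti_threshold=ti_threshold)


def compare_signatures(subject: Signature, template: Signature,
                       mode: str = "strict") -> bool:
    """Signature coincidence test.

    ``strict``: the top-4 position sets are equal *and* the minimum
    positions agree.  ``top4``: only the top-4 sets are compared.  The
    top four are compared as unordered sets throughout.
    """
    if mode not in ("strict", "top4"):
        raise ValueError(f"mode must be 'strict' or 'top4', got {mode!r}")
    if subject.top4 != template.top4:
        return False
    if mode == "top4":
        return True
    return subject.m16 == template.m16


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of matching one peptide against the template signature."""

    record_id: str
    signature: Signature
    is_scaap: bool
    mode: str
    template_signature: Signature
    matrix: IncidenceMatrix = field(compare=False, repr=False, default=None)


def classify_peptide(record: PeptideRecord, template: TemplateModel,
                     mode: str = "strict",
                     alphabet: PolarityAlphabet = DEFAULT_ALPHABET,
                     weight_factor: float = DEFAULT_WEIGHT_FACTOR,
                     lenient: bool = False) -> ClassificationResult:
    """Build the peptide's matrix, extract its signature, match the template."""
    matrix = build_incidence_matrix(record, alphabet=alphabet,
                                    weight_factor=weight_factor,
                                    lenient=lenient)
    signature = extract_signature(matrix)
    verdict = compare_signatures(signature, template.signature, mode=mode)
    return ClassificationResult(record_id=record.id, signature=signature,
                                is_scaap=verdict, mode=mode,
                                template_signature=template.signature,
                                matrix=matrix)
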