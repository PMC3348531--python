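"""Peptide records and sequence validation.

Sequences are strings of the 20 canonical one-letter amino-acid codes.
Input is normalised by uppercasing and stripping whitespace; anything
else (``X``, ``B``, ``Z``, ``U``, ``O``, gaps, digits) is non-canonical.
Strict handling rejects such sequences outright; lenient handling keeps
them and lets downstream consumers skip the offending residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class SequenceError(ValueError):
    """A peptide sequence failed validation.

    Carries the offending record id so batch drivers can report the
    failure per record instead of aborting.
    """

    def __init__(self, message: str, record_id: str | None = None):
        super().__init__(message)
        self.record_id = record_id


def clean_sequence(raw: str) -> str:
    """Uppercase a raw sequence and drop all whitespace."""
    return "".join(raw.split()).upper()


def validate_sequence(sequence: str, record_id: str | None = None,
                      min_length: int = 2) -> str:
    """Check that *sequence* is canonical and long enough.

    Returns the sequence unchanged on success.  Raises
    :class:`SequenceError` naming the first offending character and its
    1-based position, or complaining about the length.
    """
    if len(sequence) < min_length:
        raise SequenceError(
            f"sequence of length {len(sequence)} is shorter than the "
            f"minimum of {min_length}", record_id)
    for pos, residue in enumerate(sequence, start=1):
        if residue not in CANONICAL_RESIDUES:
            raise SequenceError(
                f"non-canonical residue {residue!r} at position {pos}",
                record_id)
    return sequence


@dataclass(frozen=True)
class PeptideRecord:
    """A named peptide sequence.

    ``amidated_name_hint`` is set when the name suggests a C-terminally
    amidated peptide (e.g. ends in "NH2"); it is informational only and
    does not change any default computation.
    """

    id: str
    sequence: str
    amidated: bool = False
    amidated_name_hint: bool = field(default=False, compare=False)

    @classmethod
    def from_raw(cls, record_id: str, raw_sequence: str,
                 amidated: bool = False) -> "PeptideRecord":
        """Build a record from raw text, normalising the sequence."""
        sequence = clean_sequence(raw_sequence)
        hint = "NH2" in record_id.upper()
        return cls(id=record_id, sequence=sequence, amidated=amidated,
                   amidated_name_hint=hint)

    def validated(self, min_length: int = 2) -> "PeptideRecord":
        """Return self after strict canonical-residue validation."""
        validate_sequence(self.sequence, self.id, min_length=min_length)
        return self
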