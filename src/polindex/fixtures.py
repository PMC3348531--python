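"""Packaged reference data and seeded synthetic peptide generation.

Two reference tables ship with the package so the whole pipeline runs
without any download:

``table2``
    The seven SCAAP template candidates with their published
    isoelectric point (IP), hydrophobic moment (HM) and therapeutic
    index (TI).  The two entries with TI >= 1000 (Cecropin-A and
    CA(1-8)M(1-18)NH2) define the classification template.

``table4``
    The 51 peptides identified by the polarity-index screen of the
    antimicrobial-peptide database, with their published IP/HM values
    and an acceptance mark (six rows are flagged as rejected by the
    IP/HM gate).

Values are transcribed as printed.  One sequence (Phylloseptin-H11)
contains a typographic internal space in the source; whitespace is
stripped on transcription.  "Clavanin D" appears twice (rows 1 and 31)
with different sequences; both are kept as printed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .peptide import PeptideRecord
from .polarity import GROUP_ORDER, GROUP_RESIDUES


@dataclass(frozen=True)
class TemplateCandidate:
    """One template-candidate row: published IP/HM/TI plus sequence."""

    entry: int
    name: str
    sequence: str
    ip: float
    hm: float
    ti: float

    def as_record(self) -> PeptideRecord:
        return PeptideRecord.from_raw(self.name, self.sequence)


@dataclass(frozen=True)
class ScreenedPeptide:
    """One screened-peptide row: published IP/HM plus acceptance mark."""

    number: int
    name: str
    sequence: str
    ip: float
    hm: float
    accepted: bool  # False where the source marks the row rejected (X)

    def as_record(self) -> PeptideRecord:
        return PeptideRecord.from_raw(self.name, self.sequence)


TABLE2: tuple[TemplateCandidate, ...] = tuple(
    TemplateCandidate(*row) for row in [
        (1, "(KIAKKIA)2NH2", "KIAKKIAKIAKKIA", 11.5, 0.48, 86.2),
        (2, "(KLGKKLG)3NH2", "KLGKKLGKLGKKLGKLGKKLG", 11.7, 0.49, 98.3),
        (3, "Cecropin-A",
         "KWKLFKKIEKVGQNIRDGIIKAGPAVAVVGQATQIAK", 11.2, 0.44, 1000.0),
        (4, "Melittin", "GIGAVLKVLTTGLPALISWIKRKRQQ", 12.6, 0.46, 500.0),
        (5, "Magainin 2", "GIGKFLHSAKKFGKAFVGEIMNS", 10.8, 0.56, 75.0),
        (6, "CA(1-13)M(1-13)NH2",
         "KWKLFKKIEKVGQGIGAVLKVLTTGL", 11.1, 0.53, 400.0),
        (7, "CA(1-8)M(1-18)NH2",
         "KWKLFKKIGIGAVLKVLTTGLPALIS", 10.4, 0.43, 2000.0),
    ])

#: Published template signature: ordered {M1, M2, M3, M4} and M16.
TEMPLATE_TOP4_PUBLISHED: tuple[int, int, int, int] = (16, 4, 13, 15)
TEMPLATE_M16_PUBLISHED: int = 10

TABLE4: tuple[ScreenedPeptide, ...] = tuple(
    ScreenedPeptide(number, name, seq, ip, hm, not flagged)
    for number, name, seq, ip, hm, flagged in [
        (1, "Clavanin D", "AFKLLGRIIHHVGNFVYGFSHVF", 10.85, 0.54, False),
        (2, "Palustrin-1b", "ALFSILRGLKKLGNMGQAFVNCKIYKKC", 10.80, 0.49, False),
        (3, "Palustrin-1d", "ALSILKGLEKLAKMGIALTNCKATKKC", 10.50, 0.35, False),
        (4, "Palustrin-1c", "ALSILRGLEKLAKMGIALTNCKATKKC", 10.60, 0.35, False),
        (5, "Brevinin-1PRc", "FFPMLAGVAARVVPKVICLITKKC", 10.50, 0.38, False),
        (6, "Brevinin-1Be", "FLPAIVGAAAKFLPKIFCVISKKC", 10.30, 0.43, False),
        (7, "Brevinin-1HSa", "FLPAVLRVAAKIVPTVFCAISKKC", 10.50, 0.40, False),
        (8, "Brevinin-1Ba", "FLPFIAGMAAKFLPKIFCAISKKC", 10.30, 0.50, False),
        (9, "Brevinin-1Bc", "FLPFIAGVAAKFLPKIFCAISKKC", 10.30, 0.49, False),
        (10, "RANATUERIN 4", "FLPFIARLAAKVFPSIICSVTKKC", 10.50, 0.46, False),
        (11, "Phylloseptin-H11", "FLSLIPHAINAVGVHAKHF", 9.65, 0.36, False),
        (12, "Phylloseptin-H5", "FLSLIPHAINAVSAIAKHF", 9.65, 0.45, False),
        (13, "Phylloseptin-H2", "FLSLIPHAINAVSTLVHHF", 7.80, 0.46, True),
        (14, "Phylloseptin-B1", "FLSLIPHIVSGVAALAKHL", 9.65, 0.46, False),
        (15, "Papilosin",
         "GFWKKVGSAAWGGVKAAAKGAAVGGLNALAKHIQ", 11.40, 0.32, False),
        (16, "SMAP-34",
         "GLFGRLRDSLQRGGQKILEKAERIWCKIKDIFR", 10.43, 0.48, False),
        (17, "Caerin 1.17", "GLFSVLGSVAKHLLPHVAPIIAEKL", 9.50, 0.49, False),
        (18, "Caerin 1.18", "GLFSVLGSVAKHLLPHVVPVIAEKL", 9.50, 0.50, False),
        (19, "Fallaxidin 3.2", "GLLDFAKHVIGIASKL", 9.50, 0.49, False),
        (20, "Fallaxidin 3.1", "GLLDLAKHVIGIASKL", 9.50, 0.48, False),
        (21, "Dahlein 5.2", "GLLGSIGNAIGAFIANKLKPK", 11.10, 0.52, False),
        (22, "Caerin 1.2", "GLLGVLGSVAKHVLPHVVPVIAEHL", 7.02, 0.49, True),
        (23, "Caerin 1.4", "GLLSSLSSVAKHVLPHVVPVIAEHL", 7.02, 0.48, True),
        (24, "Palustrin-2SIb",
         "GLWNSIKIAGKKLFVNVLDKIRCKVAGGCKTSPDVE", 10.10, 0.36, False),
        (25, "XPF", "GWASKIGQTLGKIAKVGLKELIQPK", 11.00, 0.40, False),
        (26, "Pleurocidin", "GWGSFFKKAAHVGKHVGKAALTHYL", 11.00, 0.34, False),
        (27, "Cecropin",
         "GWLKKIGKKIERVGQNTRDATVKGLEVAQQAANVAATVR", 11.30, 0.36, False),
        (28, "Pm_mastoparan PMM", "INWKKIASIGKEVLKAL", 10.80, 0.37, False),
        (29, "Hinnavin II",
         "KWKIFKKIEHMGQNIRDGLIKAGPAVQVVGQAATIYKG", 10.12, 0.45, False),
        (30, "Ostrich AvBD2",
         "LFCRKGTCHFGGCPAHLVKVGSCFGFRACCKWPWDV", 8.94, 0.33, True),
        (31, "Clavanin D", "LFKLLGKIIHHVGNFVHGFSHVF", 10.80, 0.56, False),
        (32, "Enterocin Q",
         "MNFLKNGIAKWMTGAELQAYKKKYGCLPWEKISC", 10.00, 0.39, False),
        (33, "Temporin-1Lb", "NFLGTLINLAKKIM", 10.80, 0.41, False),
        (34, "Bovine beta-defensin 6",
         "QGVRNHVTCRIYGGFCVPIRCPGRTRQIGTCFGRPVKCCRRW", 11.30, 0.37, False),
        (35, "mBD-4",
         "QIINNPITCMTNGAICWGPCPTAFRQIGNCGHFKVRCCKIR", 8.91, 0.33, True),
        (36, "ChBac5",
         "RFRPPIRRPPIRPPFNPPFRPPVRPPFRPPFRPPFRPPIGPFP", 13.45, 0.50, False),
        (37, "Cyclic dodecapeptide", "RICRIIFLRVCR", 12.00, 0.36, False),
        (38, "Bactenecin", "RLCRIVVIRVCR", 12.00, 0.33, False),
        (39, "RL-37",
         "RLGNFFRKVKEKIGGGLKKVGQKIKDFLGNLVPRTAS", 11.90, 0.59, False),
        (40, "BACTENECIN 7",
         "RRIRPRPPRLPRPRPRPLPFPRPGPRPIPRPLPFPRPGPRPIPRPLPFPRPGPRPIPRPL",
         13.20, 0.25, False),
        (41, "Bac4",
         "RRLHPQHQRFPRERPWPKPLSLPLPRPGPRPWPKPL", 12.90, 0.23, False),
        (42, "Hyphancin IIIE",
         "RWKFFKKIERVGQNVRDGLIKAGPAIQVLGAAKAL", 11.80, 0.41, False),
        (43, "Cecropin B",
         "RWKIFKKIEKMGRNIRDGIVKAGPAIEVLGSAKAI", 11.40, 0.42, False),
        (44, "Hyphancin IIID",
         "RWKIFKKIERVGQNVRDGIIKAGPAIQVLGTAKAL", 11.80, 0.41, False),
        (45, "Hyphancin IIIG",
         "RWKVFKKIEKVGRHIRDGVIKAGPAITVVGQATAL", 11.80, 0.38, False),
        (46, "Hyphancin IIIF",
         "RWKVFKKIEKVGRNIRDGVIKAGPAIAVVGQAKAL", 11.80, 0.39, False),
        (47, "Phylloseptin-H4", "SLIPHAINAVSAIAKHF", 9.65, 0.47, False),
        (48, "Pep5",
         "TAGPAIRASVKQCQKTLKATRLFTVSCKGKNGCK", 11.10, 0.27, False),
        (49, "Clavanin C", "VFHLLGKIIHHVGNFVYGFSHVF", 9.55, 0.47, False),
        (50, "Andropin",
         "VFIDILDKVENAIHNAAQVGIGFAKPFEKLINPK", 7.50, 0.45, True),
        (51, "Clavanin A", "VFQFLGKIIHHVGNFVHGFSHVF", 9.71, 0.61, False),
    ])

_FIXTURES = {"table2": TABLE2, "table4": TABLE4}


def load_fixture(name: str):
    """Return the packaged reference table ``table2`` or ``table4``."""
    try:
        return _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None


def fixture_checksum() -> str:
    """SHA-256 over all transcribed sequences, in table order.

    Pinned by the test suite so any accidental edit of the reference
    data breaks the build.
    """
    sequences = [row.sequence for row in TABLE2] + \
                [row.sequence for row in TABLE4]
    return hashlib.sha256("\n".join(sequences).encode()).hexdigest()


def template_candidates() -> list[tuple[PeptideRecord, float]]:
    """(record, therapeutic index) pairs of the packaged candidate table."""
    return [(row.as_record(), row.ti) for row in TABLE2]


def duplicate_names(table) -> set[str]:
    """Names that occur more than once in a fixture table."""
    seen: set[str] = set()
    dupes: set[str] = set()
    for row in table:
        (dupes if row.name in seen else seen).add(row.name)
    return dupes


def generate_peptides(n: int,
                      length_range: tuple[int, int] = (10, 40),
                      group_weights=(0.25, 0.25, 0.25, 0.25),
                      seed: int | None = None,
                      rng: np.random.Generator | None = None
                      ) -> list[PeptideRecord]:
    """Seeded random peptides with controlled polarity-group composition.

    For each residue a polarity group is drawn with the given weights
    (order P+, P-, N, NP) and then a residue uniformly within that
    group, so expected group frequencies equal the weights regardless
    of group sizes.  Lengths are uniform over ``length_range``
    (inclusive).  Output is deterministic for a given seed and always
    passes strict validation.
    """
    if n < 1:
        raise ValueError(f"n must be at least 1, got {n}")
    lo, hi = length_range
    if lo < 2 or hi < lo:
        raise ValueError(f"invalid length range {length_range}")
    weights = np.asarray(group_weights, dtype=float)
    if weights.shape != (4,) or (weights < 0).any() or \
            abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(
            "group_weights must be 4 non-negative values summing to 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    group_pool = [GROUP_RESIDUES[code] for code in GROUP_ORDER]
    records = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        groups = rng.choice(4, size=length, p=weights)
        residues = [group_pool[g][rng.integers(len(group_pool[g]))]
                    for g in groups]
        records.append(PeptideRecord(id=f"synthetic_{i + 1}",
                                     sequence="".join(residues)))
    return records
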