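"""Brute-force oracles, independent of the package implementation.

The dipeptide oracle tabulates all 400 ordered dipeptides, assigns
each to one of the 16 polarity-transition cells from a literal copy of
the side-chain classification, and counts overlapping occurrences by
string scanning.  It shares no code path with the package's
position-arithmetic matrix builder.
"""

import math

_GROUPS_IN_ORDER = [
    ("P+", "HKR"),
    ("P-", "DEY"),
    ("N", "CGNQST"),
    ("NP", "AFILMPVW"),
]

_RESIDUES = "".join(members for _, members in _GROUPS_IN_ORDER)

#: cell index (1..16) of every ordered dipeptide, all 400 of them
DIPEPTIDE_CELL = {}
for _row, (_, _first_members) in enumerate(_GROUPS_IN_ORDER, start=1):
    for _col, (_, _second_members) in enumerate(_GROUPS_IN_ORDER, start=1):
        for _a in _first_members:
            for _b in _second_members:
                DIPEPTIDE_CELL[_a + _b] = 4 * (_row - 1) + _col
assert len(DIPEPTIDE_CELL) == 400


def oracle_counts(sequences):
    """16-cell counts of one or more sequences by dipeptide tabulation."""
    cells = dict.fromkeys(range(1, 17), 0)
    for seq in sequences:
        for dipeptide, cell in DIPEPTIDE_CELL.items():
            cells[cell] += sum(
                1 for i in range(len(seq) - 1)
                if seq[i:i + 2] == dipeptide)
    return cells


def homogeneous_moment(h, n, delta_deg):
    """Closed-form mean-vector moment of n equal hydrophobicities."""
    delta = math.radians(delta_deg)
    return abs(h) * abs(math.sin(n * delta / 2) / math.sin(delta / 2)) / n
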