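"""Isoelectric point, hydrophobic moment and the SCAAP physicochemical gate.

The screening gate accepts a peptide when its isoelectric point lies
in [9.65, 11.80] pH units and its hydrophobic moment in [0.16, 0.57]
(both inclusive) — the cationic, amphipathic corner of property space.

Isoelectric point
-----------------
Net charge at a given pH follows the Henderson-Hasselbalch model: each
basic group (N-terminus, K, R, H) contributes ``1/(1+10^(pH-pKa))``,
each acidic group (C-terminus, D, E, C, Y) ``-1/(1+10^(pKa-pH))``.
The charge is strictly decreasing in pH, so the isoelectric point is
the unique zero crossing on [0, 14], found by bisection.  The default
pKa set is EMBOSS-style; Lehninger- and Bjellqvist-style sets are
available by name.

Hydrophobic moment
------------------
The Eisenberg moment places successive residue hydrophobicities at
100-degree angular steps (alpha-helical periodicity) and takes the
magnitude of their vector sum per residue:

    uH(w) = |sum_n h_n exp(i n delta)| / N

The reported value is, by default, the maximum of uH over all
11-residue windows using the normalized Eisenberg consensus scale —
the classic sliding-window procedure.  Window, aggregation, scale and
angle are all configurable; ``window=None`` computes the single
whole-sequence moment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping

from .peptide import PeptideRecord, SequenceError, validate_sequence

logger = logging.getLogger(__name__)

DEFAULT_IP_RANGE = (9.65, 11.80)
DEFAULT_HM_RANGE = (0.16, 0.57)


@dataclass(frozen=True)
class PkaSet:
    """Named set of side-chain and terminal pKa values."""

    name: str
    n_term: float
    c_term: float
    side_chain: Mapping[str, float]  # keys: D E C Y H K R

    def __post_init__(self):
        values = [self.n_term, self.c_term, *self.side_chain.values()]
        if not all(0 < v < 14 for v in values):
            raise ValueError(f"pKa values must lie in (0, 14): {values}")
        if set(self.side_chain) != set("DECYHKR"):
            raise ValueError("side-chain pKa set must cover D,E,C,Y,H,K,R")


PKA_SETS: dict[str, PkaSet] = {
    "emboss": PkaSet(
        name="emboss", n_term=8.6, c_term=3.6,
        side_chain={"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
                    "H": 6.5, "K": 10.8, "R": 12.5}),
    "lehninger": PkaSet(
        name="lehninger", n_term=9.69, c_term=2.34,
        side_chain={"D": 3.86, "E": 4.25, "C": 8.33, "Y": 10.07,
                    "H": 6.0, "K": 10.53, "R": 12.48}),
    "bjellqvist": PkaSet(
        name="bjellqvist", n_term=7.5, c_term=3.55,
        side_chain={"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
                    "H": 5.98, "K": 10.0, "R": 12.0}),
}
DEFAULT_PKA = PKA_SETS["emboss"]

_BASIC = "KRH"
_ACIDIC = "DECY"


@dataclass(frozen=True)
class HydrophobicityScale:
    """Per-residue hydrophobicity values plus the helical rotation angle."""

    name: str
    values: Mapping[str, float]
    delta_deg: float = 100.0

    def __post_init__(self):
        if len(self.values) != 20:
            raise ValueError("scale must cover the 20 canonical residues")
        if not 0 < self.delta_deg < 360:
            raise ValueError("rotation angle must lie in (0, 360) degrees")

    def with_angle(self, delta_deg: float) -> "HydrophobicityScale":
        return replace(self, delta_deg=delta_deg)


HM_SCALES: dict[str, HydrophobicityScale] = {
    # Eisenberg consensus scale (raw consensus values)
    "eisenberg-consensus": HydrophobicityScale(
        name="eisenberg-consensus",
        values={"A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
                "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
                "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
                "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08}),
    # Eisenberg normalized consensus scale (zero mean, unit spread)
    "eisenberg-norm": HydrophobicityScale(
        name="eisenberg-norm",
        values={"A": 0.25, "R": -1.80, "N": -0.64, "D": -0.72, "C": 0.04,
                "Q": -0.69, "E": -0.62, "G": 0.16, "H": -0.40, "I": 0.73,
                "L": 0.53, "K": -1.10, "M": 0.26, "F": 0.61, "P": -0.07,
                "S": -0.26, "T": -0.18, "W": 0.37, "Y": 0.02, "V": 0.54}),
}
DEFAULT_HM_SCALE = HM_SCALES["eisenberg-norm"]
DEFAULT_HM_WINDOW = 11


def net_charge(sequence: str, ph: float, pka: PkaSet = DEFAULT_PKA,
               c_term_amidated: bool = False) -> float:
    """Henderson-Hasselbalch net charge of a peptide at a given pH.

    Strictly decreasing in pH.  An amidated C-terminus carries no
    carboxylate and is excluded from the acidic groups.
    """
    positive = [pka.n_term]
    negative = [] if c_term_amidated else [pka.c_term]
    for residue in sequence:
        if residue in _BASIC:
            positive.append(pka.side_chain[residue])
        elif residue in _ACIDIC:
            negative.append(pka.side_chain[residue])
    charge = sum(1.0 / (1.0 + 10.0 ** (ph - p)) for p in positive)
    charge -= sum(1.0 / (1.0 + 10.0 ** (p - ph)) for p in negative)
    return charge


class IsoelectricPointUndefined(ValueError):
    """The net charge has no zero crossing on pH 0..14."""


def isoelectric_point(sequence: str, pka: PkaSet = DEFAULT_PKA,
                      c_term_amidated: bool = False,
                      tol: float = 1e-4) -> float:
    """pH at which the peptide's net charge is zero, by bisection.

    Raises :class:`IsoelectricPointUndefined` when the charge does not
    change sign on [0, 14] (e.g. an amidated peptide with no acidic
    residues stays positive at any pH).
    """
    lo, hi = 0.0, 14.0
    charge_lo = net_charge(sequence, lo, pka, c_term_amidated)
    charge_hi = net_charge(sequence, hi, pka, c_term_amidated)
    if charge_lo <= 0.0 or charge_hi >= 0.0:
        missing = "acidic" if charge_hi > 0.0 else "basic"
        raise IsoelectricPointUndefined(
            f"undefined isoelectric point: no titratable {missing} group "
            f"brings the net charge through zero on pH 0..14")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pka, c_term_amidated) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def segment_moment(sequence: str,
                   scale: HydrophobicityScale = DEFAULT_HM_SCALE) -> float:
    """Mean-vector hydrophobic moment of one contiguous segment.

    ``|sum_n h_n exp(i n delta)| / N`` with n = 0..N-1 and delta the
    scale's rotation angle.
    """
    if not sequence:
        raise SequenceError("cannot compute a moment of an empty sequence")
    delta = math.radians(scale.delta_deg)
    sin_sum = 0.0
    cos_sum = 0.0
    n_used = 0
    for n, residue in enumerate(sequence):
        try:
            h = scale.values[residue]
        except KeyError:
            raise SequenceError(
                f"residue {residue!r} missing from scale {scale.name!r}"
            ) from None
        sin_sum += h * math.sin(n * delta)
        cos_sum += h * math.cos(n * delta)
        n_used += 1
    return math.hypot(sin_sum, cos_sum) / n_used


def hydrophobic_moment(sequence: str,
                       scale: HydrophobicityScale = DEFAULT_HM_SCALE,
                       window: int | None = DEFAULT_HM_WINDOW,
                       reduce: str = "max") -> float:
    """Hydrophobic moment of a peptide.

    With ``window=None`` the whole-sequence mean-vector moment is
    returned.  Otherwise the per-residue moment is computed over every
    contiguous window of the given length (sequences shorter than the
    window are taken whole) and reduced by ``max`` (default) or
    ``mean``.
    """
    if reduce not in ("max", "mean"):
        raise ValueError(f"reduce must be 'max' or 'mean', got {reduce!r}")
    if window is None or len(sequence) <= window:
        return segment_moment(sequence, scale)
    if window < 2:
        raise ValueError(f"window must be at least 2, got {window}")
    moments = [segment_moment(sequence[i:i + window], scale)
               for i in range(len(sequence) - window + 1)]
    return max(moments) if reduce == "max" else sum(moments) / len(moments)


@dataclass(frozen=True)
class PhyschemResult:
    """Isoelectric point and hydrophobic moment with range verdicts."""

    ip: float
    hm: float
    ip_in_range: bool
    hm_in_range: bool
    passes: bool
    ip_range: tuple[float, float] = DEFAULT_IP_RANGE
    hm_range: tuple[float, float] = DEFAULT_HM_RANGE


def scaap_range_gate(ip: float, hm: float,
                     ip_range: tuple[float, float] = DEFAULT_IP_RANGE,
                     hm_range: tuple[float, float] = DEFAULT_HM_RANGE
                     ) -> PhyschemResult:
    """Inclusive interval tests on isoelectric point and hydrophobic moment."""
    if not (math.isfinite(ip) and math.isfinite(hm)):
        raise ValueError("isoelectric point and moment must be finite")
    ip_ok = ip_range[0] <= ip <= ip_range[1]
    hm_ok = hm_range[0] <= hm <= hm_range[1]
    return PhyschemResult(ip=ip, hm=hm, ip_in_range=ip_ok, hm_in_range=hm_ok,
                          passes=ip_ok and hm_ok, ip_range=ip_range,
                          hm_range=hm_range)


def compute_physchem(record: PeptideRecord,
                     pka: PkaSet = DEFAULT_PKA,
                     scale: HydrophobicityScale = DEFAULT_HM_SCALE,
                     window: int | None = DEFAULT_HM_WINDOW,
                     ip_range: tuple[float, float] = DEFAULT_IP_RANGE,
                     hm_range: tuple[float, float] = DEFAULT_HM_RANGE
                     ) -> PhyschemResult:
    """Compute both properties of a record and apply the SCAAP gate.

    The record's explicit ``amidated`` flag is honoured; a bare
    name-derived hint is logged but does not change the computation.
    """
    validate_sequence(record.sequence, record.id, min_length=1)
    if record.amidated_name_hint and not record.amidated:
        logger.info("record %s: name suggests C-terminal amidation; "
                    "computing with free termini (set amidated=True to "
                    "override)", record.id)
    ip = isoelectric_point(record.sequence, pka=pka,
                           c_term_amidated=record.amidated)
    hm = hydrophobic_moment(record.sequence, scale=scale, window=window)
    return scaap_range_gate(ip, hm, ip_range=ip_range, hm_range=hm_range)
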