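# Methods

## The polarity-index classifier

`polindex` screens peptides for SCAAP character (Selective Cationic
Amphipathic Antibacterial Peptides: short, strongly lytic to bacterial
membranes, non-toxic to mammalian cells) using a single sequence-level
property — the pattern of side-chain polarity transitions — backed by
two physicochemical gates.

The 20 canonical residues are partitioned into four side-chain polarity
groups, held in a fixed order that also indexes the matrix rows and
columns:

| index | group | residues |
|---|---|---|
| 1 | P+ basic hydrophilic | H K R |
| 2 | P− polar acidic | D E Y |
| 3 | N neutral polar | C G N Q S T |
| 4 | NP non-polar | A F I L M P V W |

A peptide of length *L* contributes its *L* − 1 overlapping residue
pairs to a 4×4 incidence matrix: pair (a, b) increments the cell at
row = group(a), col = group(b). Cells are addressed by their 1-based
row-major position 1..16. Pooling several peptides sums their raw
counts; pairs never span a boundary between two sequences. The counts
are also reported as a relative-frequency distribution scaled by a
weight factor (default 0.30). That scaling is strictly positive, so it
provably cannot change the rank order of the cells; it is retained in
outputs for fidelity and exposed as a configuration knob.

The **signature** of a matrix is the position set of its four largest
cells {M1..M4} plus the position of its smallest cell M16. A peptide is
SCAAP-like when its signature coincides with the signature of the
**template matrix**, pooled from the reference candidates whose
therapeutic index (ratio of the minimum inhibitory concentration against
mammalian vs. bacterial cells) is ≥ 1000 — two peptides, Cecropin-A and
the Cecropin/Melittin hybrid CA(1-8)M(1-18)NH2.

### Tie handling

Incidence counts are small integers, so ties are the rule, not the
exception. All ties — in top-4 selection and in minimum selection —
resolve in favour of the **higher position index**; M16 is chosen among
the twelve positions not consumed by the top four. This is the unique
simple total rule under which the pooled template reproduces the
reference signature {16, 4, 13, 15} with minimum position 10: the
template has a three-way tie at count 8 (positions 12, 13, 15) of which
the rule keeps 15 and 13, and five empty cells (3, 6, 8, 9, 10) of which
it picks 10. `Signature.tie_note` records whenever a tie touched a
selection boundary, and the classifier logs it.

### Comparison semantics

The top four are compared as an **unordered set**; the reference
signature is written in brace (set) notation and no deterministic
ordering rule reproduces its printed internal order (13 before 15 with
both at count 8), so order is not part of the contract. Two modes are
exposed:

* `strict` (default) — top-4 sets equal **and** M16 equal;
* `top4` — top-4 sets equal, M16 ignored. Useful because peptides with
  fewer than five empty cells can never place M16 at position 10.

### Pooling decision

The template pools its source peptides by summing raw pair counts, with
no per-peptide normalisation. Averaging per-peptide frequencies instead
changes the tie structure and cannot reproduce the reference signature;
summing is also the simplest reading of "the peptide used here is the
set of sequences".

## Physicochemical gates

A screened peptide must also pass two inclusive range tests:
isoelectric point (IP) in **[9.65, 11.80]** pH units and hydrophobic
moment (HM) in **[0.16, 0.57]** — the cationic, amphipathic corner of
property space.

### Isoelectric point

Net charge at pH *p* follows the Henderson–Hasselbalch model: each
basic group (N-terminus, K, R, H) contributes 1/(1+10^(p−pKa)), each
acidic group (C-terminus, D, E, C, Y) −1/(1+10^(pKa−p)). The charge is
strictly decreasing in *p*, so the pI is the unique zero on [0, 14]; it
is found by bisection to a default tolerance of 1e−4 pH units, leaving
a residual charge below 1e−3 for any realistic peptide.

The reference tables do not name a pKa set. The default is the
EMBOSS-style set (N-term 8.6, C-term 3.6, K 10.8, R 12.5, H 6.5, D 3.9,
E 4.1, C 8.5, Y 10.1), chosen because it reproduces the published
candidate pIs (11.2, 12.6, 10.8) within ±0.3; Lehninger- and
Bjellqvist-style sets are selectable by name, and the Bjellqvist set is
cross-checked in the test suite against Biopython's independent
ProtParam implementation (agreement ≤ 0.05 pH units on all seven
candidates). Cysteine is treated as titratable (reduced); no disulfide
detection. All termini are free by default; an explicit per-record
`amidated` flag removes the C-terminal carboxylate. Names ending in
"NH2" only set an informational hint — the published pI of
CA(1-8)M(1-18)NH2 (10.4) matches neither the free-termini (11.4) nor
the amidated calculation, so the discrepancy is logged, not silently
"corrected".

### Hydrophobic moment

The moment of a contiguous segment places residue hydrophobicities at
successive angular steps δ and takes the per-residue magnitude of their
vector sum:

    μH = |Σ_n h_n · exp(i n δ)| / N ,  n = 0..N−1,  δ = 100° (α-helix)

The source of the reference HM values names no scale, window or
aggregation, and no conventional variant reproduces all seven published
candidate values within ±0.10 (best worst-case ≈ 0.11 over a scan of
five standard scales × angles × windows). The package default is the
classic sliding-window procedure — **normalized Eisenberg consensus
scale, maximum μH over 11-residue windows, δ = 100°** — which came
closest overall in that calibration and reproduces the Cecropin-A
reference value within ±0.10 (computed 0.51 vs. published 0.44).
A whole-sequence mean (window = None), a `mean` window aggregation, the
raw consensus scale and any rotation angle remain configuration knobs.
For homogeneous sequences the segment moment reduces to the closed form
|h|·|sin(Nδ/2)/sin(δ/2)|/N, which the tests match to 1e−9.

### Gate caveat

Applied to the *published* IP/HM values of the 51-peptide screened
table, the stated ranges reject 18 rows, a superset of the six rows the
source itself marks as rejected — several unmarked rows carry printed
values outside the ranges (pI 9.50–9.55 or 11.90–13.45, HM 0.59–0.61).
The package applies the stated ranges uniformly and reports the
discrepancies per row rather than emulating the source's looser,
undocumented gate.

## Synthetic peptide generator

`generate_peptides` draws, per residue, first a polarity group from a
4-way categorical distribution (default uniform, order P+, P−, N, NP)
and then a residue uniformly within the group, so expected group
frequencies equal the weights regardless of unequal group sizes.
Lengths are uniform on a range (default 10–40 residues, the span of the
packaged reference peptides). Output is deterministic for a given seed
and always passes strict validation. The generator emulates
composition, not biology: real antimicrobial peptides have positional
structure (amphipathic periodicity, terminal motifs) that iid sampling
lacks, so generator-based tests establish counting correctness and
determinism, not real-data performance.

## Degenerate inputs and numerical choices

* Sequences are uppercased and whitespace-stripped on ingestion;
  non-canonical residues (X, B, Z, U, O, …) are a per-record error by
  default, or — in lenient mode — cause only the pairs containing them
  to be skipped, with a warning.
* Length-0/1 sequences have no pairs and are per-record errors; batch
  screening records the error and continues, never aborts.
* An empty matrix (zero pairs) has no signature; extracting one raises.
* A template threshold that rejects every candidate raises, listing the
  rejected therapeutic indices.
* A peptide whose charge has no zero crossing on pH 0–14 (e.g. an
  amidated all-basic peptide) has no pI; the error names the missing
  group class.
* Reports print IP and HM with two decimals, as in the reference
  tables; row order is input order.

## Scope and limitations

The signature match over the 51 published screened positives agrees
with the published identification for only a small fraction (2/51
strict, 6/51 top-4 mode; the test suite recomputes and reports these
rates rather than asserting them). Either the original implementation
differs from its description, or its weighting step was not
rank-neutral as described; with only the printed tables available, the
discrepancy is reported, not reverse-engineered. The database-scale
results (51/743 single-action identifications, 90 % double-blind
accuracy) depend on a November 2011 snapshot of the Antimicrobial
Peptide Database that is not redistributable; screening here runs on
user-supplied or synthetic FASTA. Problem sizes in the test suite
(1000 synthetic peptides for the oracle sweep, 3000 for the composition
check, 500 for determinism) keep the full suite in a few seconds while
leaving the statistical checks well-powered.
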