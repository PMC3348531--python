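# polindex

Polarity-index screening of **Selective Cationic Amphipathic
Antibacterial Peptides** (SCAAPs) — peptides under 60 residues that
lyse bacterial membranes while sparing mammalian cells (therapeutic
index > 75). Finding them among the thousands of catalogued
antimicrobial peptides is a needle-in-a-haystack problem; `polindex`
implements a deliberately minimal classifier that uses one
physicochemical property of the sequence: side-chain **polarity**.

## Method

The 20 amino acids fall into four polarity groups, in fixed order
P+ = {H,K,R}, P− = {D,E,Y}, N = {C,G,N,Q,S,T}, NP = {A,F,I,L,M,P,V,W}.
Every overlapping residue pair of a peptide increments one cell of a
4×4 transition matrix **P**[i, j] (row = group of the first residue,
column = group of the second; cells addressed 1..16 row-major). The
peptide's *signature* is the position set of its four most-populated
cells {M1..M4} plus its least-populated cell M16:

    signature(P) = { argmax₄ P, argmin P }

A peptide is called SCAAP-like when its signature coincides with the
signature of a template matrix **Q** pooled from reference peptides of
therapeutic index ≥ 1000 (Cecropin-A and the hybrid CA(1-8)M(1-18)NH2);
that template signature is {16, 4, 13, 15} with minimum position 10 —
dominated by nonpolar→nonpolar and basic↔nonpolar transitions, the
fingerprint of a cationic amphipathic peptide. Candidates are
additionally gated by isoelectric point (9.65 ≤ pI ≤ 11.80, bisection
on a Henderson–Hasselbalch charge model) and Eisenberg hydrophobic
moment (0.16 ≤ μH ≤ 0.57, 100° helical periodicity). See
`docs/methods.md` for the model details, tie rules and calibration
decisions.

## Worked example

Build the template from the packaged candidate table, export the
packaged 51-peptide screened table as FASTA, and screen it:

```sh
polindex build-template -o template.json
# template signature {16,4,15,13;10} from 2 peptide(s) -> template.json
polindex fixtures --which table2 -o candidates.fasta
polindex screen candidates.fasta --template template.json -o screen.tsv
```

`screen.tsv` holds one row per record (signature, pI, μH, range
verdicts, final verdict) plus a tallied summary:

```
id          length  top4         m16  tie_note  is_scaap  ip     hm    ip_in_range  hm_in_range  verdict  error
Cecropin-A  37      16,13,12,4   10   True      False     11.18  0.51  True         True         False
Melittin    26      16,12,15,11  14   True      False     12.55  0.37  False        True         False
Magainin 2  23      16,15,4,13   14   True      False     10.80  0.44  True         True         False
...
# total=7
# scaap=0
# physchem_pass=6
```

Reading the Cecropin-A row: its most-populated cell is 16 (NP→NP
transitions), its empty-cell minimum sits at 10, and its computed pI
(11.18) and moment (0.51) both pass the SCAAP ranges — but its own
top-4 set {16,13,12,4} differs from the pooled template's {16,4,13,15}
(a three-way count tie pulls in cell 12), so a single template peptide
does not match the two-peptide template signature. Melittin fails the
pI gate (12.55 > 11.80), consistent with its known hemolytic,
non-selective character.

Other entry points: `polindex classify` (signature match only),
`polindex physchem` (pI/μH table), `polindex generate --seed N`
(seeded synthetic peptides), `polindex fixtures` (packaged tables as
FASTA/TSV). All thresholds, ranges, pKa sets, hydrophobicity scales and
the comparison mode (`--mode strict|top4`) are flags or YAML config
keys. The same functionality is available as a library:

```python
from polindex import build_template, template_candidates, classify_peptide
template = build_template(template_candidates())   # TI >= 1000 filter
template.signature                                  # {16,4,15,13;10}
```

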