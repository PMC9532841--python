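# latamp

Rational design and assay reduction for amphipathic α-helical
antimicrobial peptides derived from latarcin-3a, a cytolytic peptide from
the venom of the spider *Lachesana tarabaevi*.

The package is aimed at peptide designers and microbiologists who want a
desk-reproducible version of a first-generation analog study: it computes
the physicochemical descriptors that steer the design, runs the
constrained substitution search that generates analogs of the parent's
helix core, verifies synthetic peptide identity from theoretical masses
and MALDI b/y fragment ladders, and reduces plate-format wet-lab readouts
(broth microdilution, crystal-violet biofilm, hemolysis, resazurin
viability) to their standard endpoints.

## The model

For a peptide of length *N* with per-residue hydrophobicities *h<sub>n</sub>*
(Fauchère–Pliška octanol/water scale by default) placed at successive
helical angles δ = 100°/residue, the descriptors are

- net charge `Z = (#K + #R) − (#D + #E)` (side chains, pH 7; histidine
  neutral; optionally +1 for the N-terminal amine),
- mean hydrophobicity `H = (1/N) Σ h_n`,
- hydrophobic percentage `H% = 100 · #{A,C,F,I,L,M,V,W} / N` (truncated),
- Eisenberg hydrophobic moment
  `μH = (1/N) · | Σ_n h_n · exp(i δ (n−1)) |`,

and the helical wheel places residue *n* at angle `(n−1)·δ mod 360`, with
the hydrophobic face defined as the half-plane centred on the μH vector.
Analog design extracts the parent's helix core (positions 5–17,
`MAKKLKEYMEKLK`), applies class-based substitutions (Met/Ala→Leu/Ile,
Glu→Lys, …) at any subset of positions, keeps candidates whose amino-acid
*composition* diverges from the parent by at most ~30% (a multiset
distance, insensitive to rearrangement) and that introduce no Pro/Gly,
and ranks them by a charge-first amphipathicity score. Assay endpoints
(MIC/MBC/MBIC) are called as the lowest tested concentration that
inhibits, monotone from the top of the dilution series; dose–response
curves are fitted with a four-parameter logistic to report EC50.

## Worked example

```
$ latamp describe --fasta peptides.fa
name     sequence               length  Z  H      H_pct  muH    M_avg   M_mono    MH_plus
Ltc-3a   SWKSMAKKLKEYMEKLKQRA   20      5  0.058  35     0.575  2484.02 2482.355  2483.362
Lt-MAP1  LAKKLKEYLEKLV          13      2  0.312  46     0.74   1574.97 1573.981  1574.988
Lt-MAP2  LIKKLKEYLKKLI          13      4  0.444  46     0.839  1630.13 1629.096  1630.103
Lt-MAP3  LAKKLAKYLKKAL          13      5  0.288  53     0.701  1487.94 1486.996  1488.004
```

Each row is one peptide: `Z` its side-chain net charge, `H` its mean
Fauchère–Pliška hydrophobicity, `H_pct` the share of hydrophobic
residues, `muH` the length-normalized hydrophobic moment (the analogs are
*more* amphipathic than the 0.575 of the parent), and the last three
columns the calculated average mass, monoisotopic mass and singly
protonated ion — e.g. the theoretical [M+H]+ of Lt-MAP3, 1488.004 Da,
matches its observed MALDI parental ion 1488.123 m/z within the 0.5 Da
tolerance.

The numbered drivers under `analysis/` run the full study pipeline and
write their tables under `results/`:

```
python analysis/01_describe_peptides.py   # descriptor table + wheel geometry
python analysis/02_design_analogs.py      # identity, feasibility, ranked candidates
python analysis/03_fragment_masses.py     # b/y ladders + parental-ion matching
python analysis/04_assay_recovery.py      # synthetic MIC / EC50 recovery
```

`04_assay_recovery.py`, for instance, reports that the MIC caller
recovers a true MIC of 64 µg/ml in 100% of 100 noisy synthetic plates and
that EC50 is recovered with ~4% median relative error over 200 noisy
dose–response curves.

## Layout

- `src/latamp/` — the library: `peptides` (sequence type, FASTA I/O),
  `scales` (hydrophobicity scales, mass tables), `descriptors`,
  `identity`, `design`, `fragments`, `assays`, `simulate` (seeded
  synthetic plates/spectra), `workflow` + `cli` (the `latamp` command).
- `analysis/` — narrative drivers reproducing the study's desk analyses.
- `docs/methods.md` — modelling assumptions, conventions and limitations.
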