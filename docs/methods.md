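# Methods

## Descriptor conventions

All descriptors operate on validated one-letter sequences over the 20
canonical amino acids; terminal chemistry is a flag (free N-terminal
amine always; C-terminus free acid by default, amide optional).

**Hydrophobicity scale.** The default is the Fauchère–Pliška
octanol/water partition scale, the convention used by the HeliQuest-style
wheel tools this package mirrors; it reproduces the study peptides'
printed mean hydrophobicities and moments exactly at 3 decimals. The
Eisenberg consensus scale ships as an alternative (`--scale
eisenberg-consensus`) but gives systematically different absolute values
and is not used in any reproduction.

**Net charge.** `side-chains` (default): +1 per Lys/Arg, −1 per Asp/Glu,
His neutral — the model under which the three analogs' printed charges
(+2/+4/+5) and the helix core's +3 are reproduced. `include-termini`
adds +1 for the protonated N-terminal amine; the −1 of a free-acid
C-terminus is behind a separate opt-in, because the database convention
that yields the parent's printed +6 counts the N-terminus only. No
pKa-based pH dependence is modelled.

**Hydrophobic percentage** counts {A, C, F, I, L, M, V, W} and truncates
toward zero (7/13 → 53), which is the printed convention (53, not 54).

**Hydrophobic moment.** μH = (1/N)·|Σ h_n e^{iδ(n−1)}| with δ = 100°
per residue (ideal α-helix, 3.6 residues/turn). δ is configurable for
3₁₀/π helices but all shipped numbers use 100°. The moment functions
return full precision; the bundled `describe()` rounds H and μH to the
3 decimals at which such tables are conventionally printed.

**Helical wheel.** Residue n at angle (n−1)·δ mod 360, counterclockwise
from the first residue; the hydrophobic face is the half-plane (±90°)
centred on the μH vector direction. The angular orientation is cosmetic
and does not affect μH.

## Analog design

The search space is defined by per-position substitution options: the
parent residue plus its rule class (defaults: M→L; A→L,I; E→K;
K→A,I,L,V; L→A), minus the helix guard (no Pro or Gly introductions —
both are helix breakers). Spaces up to 10⁶ candidates are enumerated
exhaustively (the default space over the 13-mer core is 6×10⁵);
larger spaces are sampled with a seeded generator and deduplicated, so
output is deterministic per seed in both regimes.

**Divergence cap.** The ~30% composition-difference constraint is a
multiset distance: 1 − (Σ_residue min(count_a, count_b))/N. A positional
(Hamming) reading is untenable — the most-modified published analog
differs at 7 of 13 positions (54%) yet was described as within the cap —
while its composition differs by 4 units (30.8%). Strict mode enforces
divergence ≤ 0.30 exactly (≤3 units at N=13); the default tolerant mode
admits one extra composition unit (≤4 at N=13), reflecting that the cap
was stated as approximate. Two of the three published analogs need the
tolerant mode.

**Score.** No explicit objective was published; the ranking here is this
package's operationalization of "raise the charge, keep moderate
hydrophobicity, reorganize the moment": score = 1·ΔZ + 1·ΔμH − penalty
for mean hydrophobicity outside [0.0, 0.5], ties broken by higher Z,
higher μH, lower divergence, then lexicographic sequence order. Because
ΔZ is integral and |ΔμH| < 1, charge dominates; under this score the
published analogs rank in their charge order (Lt-MAP3 > Lt-MAP2 >
Lt-MAP1). The weights and band are parameters, not fitted quantities.

## Identity

Equal-length pairs (the only case in the study: 13 vs 13) are compared
position-wise without gaps; identity = 100·matches/N, rounded half-up to
1 decimal. This yields 76.9 and 61.5 for the first two analogs. For the
third, position-wise counting gives 6/13 = 46.2 against a printed 46.6;
no per-column count over 13 positions can produce 46.6, so 46.2 is
reported as-is. Unequal lengths use a minimal global alignment (match
+1, mismatch 0, linear gap −1) with identity over alignment columns —
a general-use convenience whose scoring is this package's choice, not a
reimplementation of any specific server.

## Masses and fragments

Standard IUPAC average and monoisotopic residue masses; water 18.0153 /
18.01056 Da, proton 1.00728 Da; C-terminal amidation subtracts
0.98402 Da (monoisotopic) / 0.98476 Da (average). b_i = Σ residues 1..i
+ proton; y_j = Σ last j residues + water + proton; only singly charged,
unmodified b/y ions are produced (the MALDI LIFT annotation context), no
a-ions, neutral losses, or isotope envelopes. The identity
b_i + y_{N−i} = [M+H]+ + proton holds to 1e-6 Da and is property-tested.
Peak matching assigns each observed m/z to the nearest theoretical ion
within a tolerance (default 0.5 Da — observed parental ions in this
class of spectra deviate up to ~0.3 Da from theory) and reports b/y
ladder coverage. Average masses agree with an elemental-composition
oracle to within a few mDa; residual differences stem from
atomic-weight conventions, far below the 0.1 Da at which such tables
are printed.

## Assay reduction

**MIC/MBIC.** Growth fraction per concentration: g = (mean reading −
mean blank)/(mean growth control − mean blank), clamped to [0,1]. "No
significant growth" has no published numeric rule; it is
operationalized as g ≤ 0.10 (configurable). The endpoint is the lowest
tested concentration with g ≤ threshold *such that every higher tested
concentration also inhibits* — a monotone-from-the-top rule that
ignores isolated sub-threshold wells below a grown well (wells above a
skipped well still count; the call never interpolates between tested
concentrations). No inhibition anywhere → censored, serialized
`">128"`-style. MBC applies the same monotone rule to zero-colony
counts. Raising the threshold can only lower (never raise) the called
endpoint; this is property-tested.

**Hemolysis / viability.** Linear normalization between controls:
hemolysis % between PBS blank (0%) and Triton X-100 (100%), clamped to
[0,100]; viability % between medium blank and untreated control,
clamped below at 0 but allowed above 100 (metabolic readouts can exceed
control). The activity screen flags death ≥ 60% — the boundary is
inclusive at exactly 60. The dual-wavelength resazurin readout is
reduced to a single background-corrected signal; no published reduction
formula exists for the two-wavelength variant.

**Dose–response.** Four-parameter logistic r(c) = bottom +
(top−bottom)/(1+(EC50/c)^hill), least squares via bounded
Levenberg–Marquardt (trust-region reflective), initialised at the
geometric mean concentration with hill = 1. Either asymptote can be
fixed; fixing bottom = 0 and top = 100 is the recommended and default
analysis mode for responses that are already normalized percentages,
because with a 6-point dilution series the free 4-parameter problem is
weakly identified. Constant responses and non-convergence raise a
diagnostic error rather than returning silently.

## Synthetic data

Generators emulate each input with a deliberately minimal measurement
model: microdilution and crystal-violet plates are two-level (grown
wells at OD 0.50, inhibited/blank wells at OD 0.05 — typical
blank-corrected OD600 magnitudes for an 18 h broth culture) with
additive Gaussian noise truncated at zero, default sd 0.02 absorbance
units (realistic plate-reader replicate scatter that makes recovery
non-trivial but stable); dose–response curves are 4PL (bottom 0, top
100, hill 1.5) with additive noise in percentage points; synthetic
spectra are the theoretical b/y ladder with Bernoulli peak dropout and
Gaussian m/z jitter, parent ion always retained. All generators are
bit-reproducible per seed. What passing the round-trip experiments
shows is that the callers invert this well-behaved measurement model at
realistic noise — not that they are robust to growth kinetics, inoculum
effects, skipped-well artefacts, or plate gradients, none of which are
modelled.

Problem sizes used in the shipped experiments: 100 seeded plates for
MIC recovery and 200 seeded curves for EC50 recovery — large enough for
stable rates at the reported precision.

## Known limitations

- Descriptors assume a canonical, linear, monomeric peptide; no
  modified residues, cyclization, or disulfides.
- Helicity itself is asserted by construction (helix guard), not
  predicted; no structure modelling.
- The design score is a ranking heuristic, not an activity model; wet-lab
  measurements are the only ground truth for biological activity.
- Printed values known not to be reproducible under any consistent
  convention (the parent's +6 with the analogs' side-chain charges, the
  helix core's moment 0.699 vs recomputed 0.669, identity 46.6 vs 46.2,
  one analog's calculated mass at 1 decimal) are documented where they
  arise and are not fitted to.
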