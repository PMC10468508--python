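# Methods

## Scope and model of the data

`ffbench` evaluates conformational ensembles of a trimer of the 16-residue
R2-FUS-LC peptide (FUS low-complexity domain residues 50–65, sequence
YGQSSYSSYGQSQNTG) against two experimental fibril references: a compact
"U-shaped" conformation (multi-model NMR structure) and an extended
"L-shaped" conformation (cryo-EM). An ensemble is an ordered sequence of
snapshots; each snapshot holds the heavy atoms (hydrogens are read and
flagged but excluded from every distance and Rg computation) of three
equal-length peptides with 1-based residue numbering inside the selected
window. Multi-model PDB is the interchange format; binary trajectory
formats can be adapted to the same snapshot-stream contract without the
core depending on them. Coordinates are Å throughout.

Snapshot streaming assigns frame k (0-based) of a replica the time
(k+1)·Δt, so discarding an initial equilibration segment of D ns removes
exactly D/Δt frames; replicas are concatenated in replica order and
pooled, not averaged, by all downstream accumulators.

Altloc handling keeps the highest-occupancy conformer (ties: first
encountered). Residue windows are interpreted in the author numbering
carried by the file, which makes window selection idempotent.

## Radius-of-gyration scores

Rg is mass-weighted over heavy atoms (an unweighted flag exists for
sensitivity checks). The trimer Rg distribution is fitted with a
two-component univariate Gaussian mixture by EM (scikit-learn, full
covariance, `n_init = 10`, `tol = 1e-6`, seeded; components reported
sorted by ascending mean). The U/L reference scores are `1 / min_i |Z_i|`
with `Z_i = (Rg_ref − μ_i)/σ_i`; `|Z| < 1e-8` is treated as an exact hit
and capped at `1e8` — min–max normalisation maps the best score to 1
regardless of the cap's magnitude, so the cap only keeps the arithmetic
finite. The unfolded score divides the inter-quartile range of the
single-peptide Rg sample by the distance of its median from the Flory
prediction `R0·N^ν` (R0 = 2.54 Å, ν = 0.522, parameters optimised for
disordered proteins; 10.8 Å at N = 16), with the same cap for a median
exactly on the prediction. Percentiles use the linear-interpolation
convention. The U-shaped reference radius is recomputed as the mean trimer
Rg over the reference models rather than hard-coded.

## Contact-map scores

A contact is any heavy-atom pair within 5 Å *inclusive*; the boundary
matters only for constructed fixtures but is documented for determinism.
Eligible intra-peptide pairs satisfy |i−j| ≥ 2, giving N(N−1)/2 − (N−1)
pairs — 105 at N = 16, which fixes the reference marginal TP + FN at
100·(contacts/105)% independent of the ensemble. Ensemble contact
frequencies are computed per peptide, frequencies below 1% zeroed per
peptide, then averaged across the three peptides (filter before average,
in that order). Confusion matrices accumulate every (snapshot × peptide ×
pair) instance with replicas pooled; MCC uses the standard formula with
the convention that a degenerate marginal yields 0. Reference contacts are
classed side-chain/backbone (Bb = N, CA, C, O) by which atom classes
achieve a within-cutoff pair, and pairs with |i−j| > 5 are flagged as
medium-distance.

Inter-peptide analysis classifies each snapshot as monomer (no peptide
pair in contact), dimer (exactly one pair) or trimer (every peptide
touching another); the middle peptide is the one with the most
inter-peptide residue-pair contacts, ties to the lowest index. The
reference inter-peptide map is extracted middle → adjacent-edge from the
reference structure, and trajectory middle–edge maps are scored in that
same orientation. Contacts between the two edge peptides count as false
positives only; pairs involving a non-participating peptide (dimer's free
monomer, or all pairs of a monomeric snapshot) enter as all-negative
predictions so that every snapshot contributes to the denominator. This
last choice is a genuine open point — the alternative (dropping such
snapshots) changes only the denominator — and is recorded here and in the
output metadata.

## Secondary-structure scores

The built-in assigner is a deliberately simplified 3-state
Kabsch–Sander-style method: backbone hydrogen bonds by the electrostatic
energy `E = 0.084·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)·332 kcal/mol`
(bond when E < −0.5 kcal/mol, amide H reconstructed on the N–H bisector at
1.01 Å when absent, donors skipped for residues without a predecessor),
helices from two consecutive i→i+4 turns, strands from
parallel/antiparallel bridge patterns within or across peptides, all else
coil. It does not reproduce full 8-state DSSP fidelity (3₁₀/π helices,
isolated bridges, turns and bends all map to coil); a parser for external
DSSP output is provided, mapping H→H, E→E, everything else→C. Merging G/I
into H is configurable in principle but off by default since only
α-helix/β-strand/coil are scored.

Propensities pool the three peptides: `p_{i,ss} = count(i, ss)/(3·T)`,
normalised per residue so each row sums to 1. An alternative global
denominator (rows sum to 1/N) shifts every ensemble's log-likelihood by
the same additive constant `N·ln(1/N)` and therefore leaves the
min–max-normalised scores unchanged — this invariance is asserted in the
test suite, and the global variant is available behind a flag. The score
is `Σ_i ln max(p_{i,ref_i}, ε)` with ε = 1e-6: the floor must lie far
below any observable 1/T so that a never-observed reference state is
penalised distinctly, while keeping the sum finite. The log base is
likewise irrelevant after normalisation (also asserted). The U-shaped
reference labels are a per-residue majority vote over the reference
models, ties to coil; averaging per-model scores instead is a plausible
alternative not taken.

## Normalisation and combination

Raw scores are min–max rescaled across force fields,
`(S − min)/(max − min)`, with the minimum floored at 0.00001. The
plain range-division variant `S/(max − min)` is available behind a flag
but does not bound scores at 1 and does not reproduce the published
normalised columns, so the subtractive form is the default. Where a
measure has several references (U/L Rg plus unfolded; U/L SSP), the
normalised components are multiplied and the products re-normalised. The
final score multiplies the three measure scores *without* renormalising:
the published final column equals the bare products, and renormalisation
is again a flag. The floor (0.00001 rather than the also-quoted 0.0001)
follows the published table minima. The floor keeps a worst-in-one-measure
force field from zeroing out entirely, which matters because ranks are
taken on the product.

## Synthetic ensembles

The generator exists to exercise the estimators, not to imitate physics.
Snapshots mix three states: a compact β-hairpin trimer template (strands
1–7/10–16, type-I′ turn), an extended-strand template with one mid-chain
bend, and fresh self-avoiding random coils; templates are rotated into
their principal frame and stacked at 4.8 Å along the flattest axis to
mimic cross-β stacking (adjacent sheets touch, next-nearest mostly do
not). Peptides carry backbone N/CA/C/O plus a virtual Cβ for non-glycine
residues, built from ideal bond geometry by natural-extension-reference-
frame placement. Default ensemble parameters (200 snapshots, state
weights 0.4/0.3/0.3, 0.3 Å coordinate noise, 20 ps/frame) are chosen so a
mixed ensemble shows a clearly bimodal trimer-Rg distribution at a size
every test can afford.

Coils draw (φ, ψ) per residue from β/PPII/α basins (weights
0.45/0.35/0.20), reject self-clashes (CA pairs at sequence separation ≥ 3
under 4 Å) and accept only end-to-end CA distances within [1.6, 3.4]·Rg_FL
around the Gaussian-chain expectation √6·Rg_FL — this targets Flory
statistics by rejection rather than guaranteeing the exponent, so the
calibration test asserts the peptide median Rg within 20% of `R0·N^ν`.
Coil peptides are placed 40 Å apart (monomeric snapshots).

Direct statistical samplers (Gaussian-mixture Rg values, independent
per-cell secondary-structure labels, contact series with prescribed
per-pair sensitivity/specificity) provide closed-form expectations: the
mixture fit must recover its generating parameters, recovered propensity
scores must match the plug-in log-likelihood, and the accumulated MCC must
match the analytic confusion expectation at the given prevalence. One
global seed expands into named per-component child generators through
`numpy` seed sequences in a fixed documented order, so partial pipelines
are bitwise reproducible.

What passing these tests does **not** show: synthetic ensembles have no
side chains beyond Cβ, no sterics beyond coil self-avoidance, no
energetics, no kinetic correlation between frames, and template noise is
isotropic — conclusions about real force fields still require real
trajectories. The synthetic benchmark demonstrates that the estimators
and the scoring arithmetic are correct, not that any force field is.

## Published-table verification

The scoring layer is additionally validated against the published
thirteen-force-field benchmark tables embedded in `ffbench.published`:
MCC recomputed from the four published confusion matrices (within 0.005,
the two-decimal rounding of their entries), the normalised contact-map
column from the raw MCC column (within 1e-4), the combined Rg and SSP
scores from their printed component columns (within 5e-4), and the final
scores as bare three-component products to 3 significant figures, with
the implied ranking reproduced exactly.

## Numerical choices and degenerate inputs

Constant Rg samples are rejected for mixture fitting (a two-component fit
is undefined) and score 0 on the unfolded measure (zero IQR). Min–max
normalisation requires at least two distinct values and errors otherwise.
Confusion percentages must sum to 100 within 0.02 (the slack admits
published two-decimal-rounded matrices). The contact-map accumulation
raises on universe mismatch rather than silently reindexing. MCC ties and
middle-peptide ties break deterministically (degenerate marginal → 0;
lowest peptide index). Benchmark problem sizes in the tests and examples
(tens of snapshots per ensemble for geometric pipelines, 5 000–20 000
draws for the statistical samplers) are the package's default
desk-scale settings; all scale linearly if increased.

## Known limitations

* The 3-state assigner diverges from DSSP near chain termini and for
  irregular bridges; external DSSP output is preferred when available.
* Which reference model is "the" representative for the contact map is
  configurable (`reference_model_index`) because multi-model references
  do not single one out; counts can differ by model.
* The inter-peptide measure is implemented and tested but, as in the
  published benchmark, not folded into the final score.
* No uncertainty is attached to ranks; the scoring scheme is a point
  estimate by construction.
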