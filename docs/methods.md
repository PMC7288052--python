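# Methods

## Scope and model

The package analyses a single-position backbone-homologation scan of a
tetrapeptide amide. Its computational core is four models:

1. **Composition arithmetic.** A peptide's molecular formula is the sum of
   free amino-acid formulas minus one water per peptide bond, with the amide
   C-terminus obtained from the acid by −O, +N, +H. β²- and β³-homologues are
   compositionally identical: both add exactly one CH₂ to their α-residue's
   formula, so the class tag matters only for naming and stereo semantics
   (a deliberate design choice — the distinction between the two classes is
   where the side chain sits on the extra backbone carbon, not what atoms the
   residue contains). *m*-Tyr is a positional isomer of Tyr and shares its
   formula entry. Monoisotopic masses use principal-isotope masses
   (C 12.000000, H 1.00782503, N 14.0030740, O 15.9949146, S 31.97207117 Da);
   [M+H]⁺ adds the proton mass 1.00727646 Da. All mass targets are reported
   to 4 decimals, the precision of HR-MS "calcd" values.

2. **Displacement descriptor.** For a docked pose and a reference ligand pose
   expressed in the same receptor frame, the descriptor is the RMSD between a
   selected residue's atoms and the corresponding reference atoms.
   Correspondence is **positional** across the two selections (i-th name to
   i-th name), because the reference ligand's residue need not be chemically
   identical to the derivative's (an N-methylated phenylalanine ring pairs
   with a plain one). No Kabsch superposition is ever applied: the descriptor
   measures where the residue sits in the pocket, not how its conformation
   differs. Chemical equivalence under ring flips is handled by minimising
   over automorphisms: each declared symmetry group is an atom cycle whose
   generated automorphisms are the identity and the reversal about the cycle's
   first atom (for a phenyl ring bound through CG: CD1↔CD2, CE1↔CE2);
   independent groups compose. Ties between mappings are broken toward the
   lexicographically smallest permutation, making the reported mapping
   deterministic. The default residue-4 selection is the six aromatic ring
   carbons; broader selections (Cβ, backbone) are expressible through the same
   `ResidueSelection` type. Which atom set the original study used is not
   documented, so neither reading is asserted as "the" published one; the
   ring-only default is the minimal faithful choice.

3. **Affinity analytics.** IC50s are stored in nM and converted to molar
   inside pIC50 = −log₁₀(IC50). Replicate IC50s are averaged on the log scale
   (IC50s are conventionally log-normal). The descriptor–affinity relationship
   is ordinary least squares of pIC50 on RMSD with R² = 1 − SS_res/SS_tot;
   censored records (">1000 nM") are excluded by default, with an `at_bound`
   policy for sensitivity analysis — the published analysis does not state how
   censored compounds entered its correlation, so both policies are exposed
   and neither is silently chosen. Competition curves follow the one-site
   model y = bottom + (top−bottom)/(1 + 10^(log c − log IC50)) with unit Hill
   slope, fitted by Levenberg–Marquardt (`scipy.optimize.curve_fit`) with
   plateaus initialised from the data extremes and log IC50 from the
   half-drop point; the IC50 standard error comes from the covariance of
   log IC50 by the delta method. A flat curve (response span under 10% of
   scale) has no inflection and raises rather than returning an arbitrary
   IC50; a grossly non-monotonic curve (Spearman ρ > −0.5) is fitted but
   flagged.

4. **Decay kinetics.** Degradation is summarised by C(t) = C₀e^(−kt), fitted
   log-linearly — the simplest model consistent with half-life/percent-
   remaining summaries, robust at the 11-point scale of a plasma time course.
   C₀ is fitted rather than pinned to the first sample, so raw peak areas can
   be supplied and t0 noise is absorbed. Whether a decline exists at all is a
   one-sided t test on the slope (α = 0.05): a non-significant decline
   reports k = 0, T½ = ∞, model_ok = False and carries the information in the
   empirical remaining fraction; a significantly rising series is additionally
   flagged and no decay is forced. Classification: stable if C₉₆ₕ > 90%,
   labile if T½ < 6 h, else intermediate (thresholds configurable); for
   fits without an asserted model the observed remaining fraction stands in
   for C₉₆ₕ. Published half-lives may come from interpolation rather than a
   fitted model, so printed T½ values are treated as categories to reproduce,
   not exact fit targets.

## Synthetic data: what it emulates and what it does not

Docking output and wet-lab assays are replaced by seeded simulators whose
ground truth is known exactly:

- **Poses**: the reference ligand is an idealized four-residue peptide-like
  pose with an ideal planar phenyl ring (C–C 1.39 Å) at residue 4, centroid at
  a documented offset. Compound poses translate residue 4 rigidly by a
  prescribed magnitude along a seeded random direction — so the applied ring
  RMSD equals the magnitude exactly — optionally relabel the ring by the 180°
  flip (a pure bookkeeping change the descriptor must be blind to) and add
  isotropic Gaussian jitter. The truth table records the realised post-jitter
  displacement.
- **Affinities**: pIC50 = a − b·RMSD + N(0, σ²) with defaults a = 9 pIC50,
  b = 0.8 pIC50/Å, σ = 0.2 pIC50 over n = 11 compounds — an affinity span and
  noise level typical of a low-nanomolar parent series measured by radioligand
  competition.
- **Assays**: one-site curves on the 10⁻¹¹–10⁻⁵ M half-log ladder with
  additive noise (default scenario 3% of span, three replicates per
  determination, matching a triplicate competition assay); first-order decay
  on the 0, 1, 2, 3, 4, 5, 6, 12, 24, 48, 96 h sampling grid with 5%
  multiplicative log-normal noise.

One integer seed drives a named, independent generator stream per simulator
(pose/sar/assay/decay), so fixtures are reproducible and sub-simulations do
not perturb each other. Fixtures are written to disk in the public formats
(PDB, CSV) so the readers are exercised against real files.

What the simulators deliberately do **not** emulate: docking energetics and
pose multiplicity (scores, when present, are arbitrary labels), receptor
atoms, conformational change of the ligand (displacement is rigid),
assay-plate artefacts, and enzyme-mechanism kinetics beyond first order.
Passing tests therefore demonstrate that the *computations* — mass
bookkeeping, symmetry-aware displacement, regression and curve fitting —
are correct and recover known truth at realistic noise, not that any
particular docking protocol or biological dataset would reproduce a given
correlation. The published R² values (0.67 for the scan series, 0.60 for the
external validation set) depend on third-party docking runs against an
experimental receptor structure and are out of desk-reproducible scope;
they are context, not targets.

## Numerical choices and problem sizes

- Mass comparisons at 4 decimals (5·10⁻⁵ Da tolerance internally).
- PDB coordinates carry 3 decimals; round trips are checked at 10⁻³ Å.
- The exhaustive symmetry oracle is exercised on 1000 randomized 6-atom ring
  geometries; regression/assay recovery claims use 200 seeded repetitions
  each (n = 11 points or curves per repetition), sizes at which the whole
  suite runs in seconds while the binomial pass-fraction bounds (≥ 90%) are
  meaningful.
- Degenerate inputs are errors, not silent results: empty pose files,
  selections with absent atoms, constant-pIC50 regressions (undefined R²),
  flat competition curves, rising time courses.

## Known limitations

- The composition table covers the standard hydrophobic/aromatic residues
  plus *m*-Tyr; no post-translational modifications and no Cys (extend
  `FREE_AA_FORMULA` as needed).
- Symmetry handling covers ring-flip (order-2) automorphisms composed across
  groups — sufficient for phenyl/phenol rings; arbitrary permutation groups
  (e.g. tert-butyl three-fold rotors) are not generated.
- The one-site competition model fixes the Hill slope at 1 and does not fit
  ternary-complex or two-site models.
- Censoring is handled by exclusion/at-bound policies, not by likelihood-based
  censored regression.
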