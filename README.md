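# betascan

Analysis pipeline for a **β²-homo-amino-acid scan** of the µ-selective opioid
tetrapeptide **TAPP** (H-Tyr-D-Ala-Phe-Phe-NH₂). Replacing an α-residue by its
β²-homologue inserts one methylene unit into the backbone; scanning every
position with both (R)- and (S)-configurations — plus a *meta*-tyrosine
side-chain variant in position 1 — yields ten analogues whose receptor binding
and plasma stability probe the peptide's pharmacophore.

The package covers the desk-side computations of such a study, for medicinal
chemists and modellers who have docking poses and assay tables in hand:

- **Analogue enumeration and exact-mass bookkeeping** (`betascan.peptide`):
  formulas from free-amino-acid compositions, Σᵢ AAᵢ − (n−1)·H₂O with an amide
  C-terminus correction (−O, +N, +H); monoisotopic [M+H]⁺ masses for HR-MS
  verification.
- **Pose I/O in a fixed receptor frame** (`betascan.pose_io`): multi-model PDB
  and a PDBQT read subset; coordinates are never superposed or recentred.
- **Displacement descriptor** (`betascan.displacement`): the RMSD of a chosen
  residue's atoms against the corresponding atoms of a reference ligand pose,

  RMSD = min over ring automorphisms σ of √( (1/n) Σᵢ ‖pσ(i) − rᵢ‖² ),

  with the minimum taken over declared ring-flip symmetries (a phenyl ring's
  two chemically equivalent labelings) and **no** translational/rotational
  fitting — the quantity is physical displacement within the binding pocket.
- **Affinity analytics** (`betascan.pharmacology`): pIC50 = −log₁₀(IC50 [M]),
  fold changes, OLS regression pIC50 = a + b·RMSD with R² = 1 − SS_res/SS_tot,
  and one-site competition fitting
  y = bottom + (top − bottom)/(1 + 10^(log c − log IC50)).
- **Stability kinetics** (`betascan.stability`): log-linear first-order decay
  C(t) = C₀e^(−kt), T½ = ln2/k, percent remaining at 96 h, and the
  stable / intermediate / labile classification (stable: C₉₆ₕ > 90%; labile:
  T½ < 6 h).
- **Synthetic data with known ground truth** (`betascan.simulate`): seeded
  generators for receptor-frame poses with controlled displacement, linear
  descriptor–affinity datasets, competition curves (10⁻¹¹–10⁻⁵ M ladder) and
  decay time courses (0–96 h grid).

## Worked example

```python
from betascan.peptide import (TAPP, enumerate_scan, molecular_formula,
                              monoisotopic_mass, tapp_scan_spec)

formula = molecular_formula(TAPP)
print(formula, round(monoisotopic_mass(formula, "M+H"), 4))
for ana in enumerate_scan(TAPP, tapp_scan_spec())[:3]:
    print(ana.display_name, ana.formula, round(ana.mass_mh, 4))
```

prints

```
C30H35N5O5 546.2711
[(R)-β2hTyr1]-TAPP* C31H37N5O5 560.2867
[(S)-β2hTyr1]-TAPP* C31H37N5O5 560.2867
[(R)-β2h-m-Tyr1]-TAPP* C31H37N5O5 560.2867
```

i.e. the parent's protonated monoisotopic ion is 546.2711 Da, and every
single-position β²-homologue carries exactly one extra CH₂ (14.0157 Da,
[M+H]⁺ = 560.2867 Da). The asterisk marks analogues whose absolute
configuration is assigned indirectly from HPLC retention order.

The numbered drivers under `analysis/` run the full narrative — `01` the scan
enumeration, `02` synthetic pose generation and descriptor validation, `03`
the descriptor–affinity regression (slope −0.819 ± 0.042 pIC50/Å recovered
against a generating slope of −0.8, R² 0.977, negative-control mean R² 0.101),
`04` the assay analytics — writing their tables under `results/`.

A `betascan` CLI wraps the same steps (`betascan scan`, `betascan simulate`,
`betascan compute-rmsd`, `betascan correlate`, `betascan fit-stability`).

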