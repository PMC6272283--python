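# cptqsar

3D-QSAR (CoMFA) and probit bioassay statistics for camptothecin-derived
pesticides.

Camptothecin (CPT), a quinoline alkaloid from *Camptotheca acuminata*, is a
promising natural-product lead for acaricides and insecticides.  A series of
28 C-7 modified CPT derivatives (thiourea, urea and acylthiourea side chains
attached through a hydrazone linker) was assayed against the carmine spider
mite *Tetranychus cinnabarinus*, the pine wood nematode *Bursaphelenchus
xylophilus* and the cabbage aphid *Brevicoryne brassicae*, and the
structure–activity relationship against the mite was modelled with
comparative molecular field analysis (CoMFA).  This package reimplements
both computational stages of that study as an open, tested pipeline:

1. **Bioassay statistics** — dead/alive counts at five serial
   concentrations are corrected for natural mortality with Abbott's formula
   `p' = (p − p_c)/(1 − p_c)`, then a probit regression
   `Φ⁻¹(p') = α + β·log₁₀(dose)` is fitted by maximum likelihood; the median
   lethal concentration is `LC50 = 10^(−α/β)` with a delta-method 95%
   interval, and activities are expressed as `pLC50 = 3 − log₁₀(LC50/mM)`.
2. **CoMFA 3D-QSAR** — each derivative gets one MMFF94-minimized conformer
   with Gasteiger (PEOE) charges, is superposed onto the most active
   compound (**4d**) by a least-squares fit over the 28 shared scaffold
   atoms, and is sampled on a 2 Å grid with an sp³-carbon (+1 e) probe:
   steric Lennard-Jones energies `ε[(R/r)¹² − 2(R/r)⁶]` and electrostatic
   Coulomb energies `332·q·q_p/r²` (distance-dependent dielectric), both
   truncated at ±30 kcal/mol.  After minimum-sigma filtering and CoMFA
   block scaling, a NIPALS PLS1 model relates fields to pLC50; the number
   of latent components is chosen by leave-one-out `q² = 1 − PRESS/SS`,
   and the model is summarized by `r²`, `SEE = √(SSres/(n−c−1))`, external
   `r²pred` on 5 held-out compounds, per-field contributions, and
   stdev*coeff contour maps at the 80%/20% levels.

The 29 structures (SMILES reconstructed from the compound names and checked
against the published elemental-analysis formulas), the activity table and
the published experimental/predicted pLC50 table ship as checksummed
fixtures; a synthetic-data module generates field matrices with planted
linear signal and dose–mortality counts with known LC50 for statistical
validation of every estimator.

## Worked example

Reproduce the desk-checkable published statistics from the packaged tables:

```sh
$ cptqsar reproduce --out repro/
...
      quantity  printed  recomputed  match
     pLC50[4d]  5.11900     5.11900   True
           SEE  0.04100     0.04100   True
            r2  0.99100     0.99100   True
        r2pred  0.99300     0.99300   True
      lc50_min  0.00761     0.00761   True
...
32/34 quantities reproduced at printed precision
```

The two non-matching rows are compounds 4j and 5e, whose printed pLC50
values are internally inconsistent with the printed LC50 table (4j repeats
4a's value; 5e looks like a digit transposition).  Both tables are packaged
as printed and the discrepancy is flagged in a data-quality column.

Run the full structure-based analysis (about ten seconds):

```sh
$ cptqsar qsar --out results/
components=2 q2=-0.546 r2=0.642 SEE=0.228 r2pred=0.981
```

This prints the component count picked by leave-one-out cross-validation,
the cross-validated q², training r², standard error of estimate and the
external predictivity over the 5 test compounds, and writes the aligned
ensemble (SDF), the field matrix, the serialized PLS model, per-compound
predictions, the q² curve, and stdev*coeff contours (DX volumes, CSV and
PDB pseudo-atoms) to `results/`.  Note the q² of this reconstruction is
not comparable to the published 0.580: that number depends on a proprietary
force field, charge model and conformer search (see `docs/methods.md` for
the fidelity discussion), while the printed-table statistics above are
exactly reproduced.

Fit LC50s from raw dose–mortality counts:

```sh
$ cptqsar simulate bioassay --seed 3 --n-compounds 4 --out doses.csv
$ cptqsar bioassay --input doses.csv --out assay/
4 activity records written to assay/
```

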