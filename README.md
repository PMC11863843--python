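# irfg — functional-group detection from infrared spectra

`irfg` identifies which of 17 functional groups (alkane, methyl, alkene,
alkyne, alcohols, amines, nitriles, aromatics, alkyl halides, esters,
ketones, aldehydes, carboxylic acids, ether, acyl halides, amides, nitro)
are present in an organic molecule, directly from its infrared absorption
spectrum. It is aimed at lab software that wants automated spectrum
annotation — e.g. electronic lab notebooks ingesting JCAMP-DX files — and
at anyone studying how neural models read vibrational spectra.

The package ships the complete workflow:

* **JCAMP-DX I/O** for the uncompressed AFFN dialects, with unit
  normalization (micrometer axes → cm⁻¹, transmittance → absorbance via
  A = −log₁₀ T).
* **Preprocessing** onto a fixed 600–4000 cm⁻¹ grid (linear interpolation,
  per-spectrum min–max normalization, per-molecule deduplication, subset
  slicing).
* **SMARTS ground-truth labeling** from SMILES against a pinned 17-entry
  catalog whose ether pattern `[OD2]([#6;!$(C=O)])([#6;!$(C=O)])` keeps
  esters from being mislabeled as ethers.
* **The split two-head network.** An IR spectrum has a cluttered,
  molecule-specific fingerprint region and a cleaner functional-group
  region, so the model encodes them separately before fusing:

      ŷ = f_joint(h₁, h₂),  h₁ = f_FP(x_FP),  h₂ = f_FG(x_FG)

  with the split at 1800 cm⁻¹. Each head is dense(n→n)–batchnorm–ReLU–
  dropout(0.2), dense(n→256)–batchnorm–ReLU–dropout(0.3); the joint part is
  dense(512→512)–ReLU and a 17-unit logistic output. Training minimizes
  mean binary cross-entropy with Adam and linear learning-rate decay
  (50 epochs by default); presence is called at probability ≥ 0.5.
* **Evaluation protocols**: per-group molecular F1 = 2TP/(2TP+FP+FN) with
  mean ± sd over 5-fold cross-validation, perfect-match analysis and
  FPR/FNR bucketed by the number of true groups, and a 70-20-10 holdout.
* **Shapley-style attribution**: per-wavenumber importance maps per class,
  estimated by permutation sampling over 50 cm⁻¹ spectral segments.
* **A synthetic-spectrum generator** (Gaussian characteristic bands +
  fingerprint clutter + baseline drift + noise) so the entire pipeline is
  testable without any external dataset.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

Label a molecule (4-fluoroanisole) from its SMILES:

```sh
$ irfg label --smiles "COc1ccc(F)cc1"
id      smiles          alkane  methyl  alkene  alkyne  alcohols  amines  nitriles  aromatics  alkyl halides  esters  ketones  aldehydes  carboxylic acids  ether  acyl halides  amides  nitro
query   COc1ccc(F)cc1   0       1       0       0       0         0       0         1          1              0       0        0          0                 1      0             0       0
```

The four set bits — methyl, aromatics, alkyl halides, ether — are exactly
the groups in 4-fluoroanisole (the ring fluorine counts as a halide on
carbon; the methoxy oxygen is a plain ether because neither flanking carbon
is a carbonyl).

Train and evaluate on synthetic spectra, end to end:

```sh
irfg simulate --n 2000 --seed 7 --out synth/
irfg preprocess --manifest synth/manifest.tsv --out dataset.tsv --no-dedup
irfg train --dataset dataset.tsv --out model.npz --epochs 50 --seed 7
irfg evaluate --model model.npz --dataset dataset.tsv --report report.json
irfg explain --model model.npz --jcamp synth/synth-00000.jdx \
     --smiles "CC#N" --fg-class nitriles --out map.json --plot map.png
```

(`simulate` writes spectra without SMILES; add a SMILES column to the
manifest before `preprocess` if you want chemistry-derived labels rather
than the generator's own.)

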