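# Methods

## Problem

Infrared spectroscopy is often the cheapest structural probe available in a
synthesis lab, but reading functional groups off a spectrum is manual
expertise. `irfg` treats the task as supervised multi-label classification:
given an absorption spectrum on 600–4000 cm⁻¹, predict independent presence
bits for 17 functional groups (alkane, methyl, alkene, alkyne, alcohols,
amines, nitriles, aromatics, alkyl halides, esters, ketones, aldehydes,
carboxylic acids, ether, acyl halides, amides, nitro).

## Ground-truth labeling

Labels come from SMARTS substructure matching on the molecule's SMILES. The
catalog is pinned (order fixed, content-hashed); the ether pattern
`[OD2]([#6;!$(C=O)])([#6;!$(C=O)])` requires both oxygen neighbours to be
non-carbonyl carbons, so ester linkages do not spuriously set the ether bit.
Conventions worth knowing:

* *alkane* = sp3 carbon bonded only to C/H. A methoxy CH₃ is methyl but not
  alkane; a toluene CH₃ is both.
* *alkyl halides* = halogen on any carbon. This includes aryl halides
  (fluorobenzene) and the halogen of acyl halides; acetyl chloride therefore
  sets both halide bits.
* *alcohols* covers phenols but not carboxylic OH; *amines* excludes amide
  and nitro nitrogens. Aromaticity uses RDKit's default perception.

Model checkpoints embed the catalog hash and refuse to load under a
different catalog, since the output bits are only meaningful relative to
the catalog that produced the training labels.

## Preprocessing

`read → to_absorbance → linear interpolation onto the grid → clip negatives
→ per-spectrum min–max normalization → label`, in that fixed order. The
analysis grid is 600–4000 cm⁻¹ at 1 cm⁻¹ (3401 points; the step is a
config knob). Grid cells outside the measured range are set to 0, the
post-normalization baseline, to avoid extrapolation artifacts.
Transmittance is converted by A = −log₁₀(max(T, 10⁻⁶)); percent
transmittance is detected by max > 1.5, and unknown units are resolved by
the baseline heuristic (IR transmittance baselines sit near 1, absorbance
baselines near 0; median in between raises an error rather than guessing).
Duplicate measurements of one molecule keep the latest timestamp, ties
broken by larger record id. An optional automated screen drops spectra
whose median normalized intensity exceeds 0.5 (a crude saturated-baseline
flag); it is off by default and is a reproducible stand-in for manual
visual curation of noisy spectra.

The JCAMP-DX layer reads and writes the uncompressed AFFN dialects
(`(X++(Y..Y))` and `(XY..XY)`); ASDF-compressed payloads are rejected with
a distinct error rather than misread. Micrometer axes are converted via
ν = 10⁴/λ and descending axes are silently reordered.

## Model

The split network encodes the fingerprint region (≤ 1800 cm⁻¹, 1201 points
on the default grid) and the functional-group region (> 1800 cm⁻¹, 2200
points) with separate fully connected heads, then fuses them:

    y = f_joint(h₁, h₂),  h₁ = f_FP(x_FP),  h₂ = f_FG(x_FG)

Each head: dense(n→n) + batchnorm + ReLU + dropout 0.2, then dense(n→256) +
batchnorm + ReLU + dropout 0.3. The joint part concatenates the two 256-d
features, applies dense(512→512) + ReLU (no batchnorm, no dropout) and a
dense(512→17) output with logistic activation. Grid points exactly at the
boundary belong to the fingerprint side. Hidden activations are ReLU and
the output is logistic — standard choices for a BCE-trained multi-label
classifier. Initialization is Glorot-uniform from an explicit seed, so
parameters (and dropout masks, drawn from a separate seeded stream) are
bit-reproducible per platform.

The implementation is a small numpy layer stack with hand-written
backpropagation in float32. The Adam update runs as a single fused pass
(numba-jitted when available, numpy otherwise) because the input-sized
weight matrices make the optimizer step memory-bound; the input layers also
skip the unused gradient with respect to their inputs.

## Training and evaluation

Mean binary cross-entropy over the 17 outputs, Adam (β₁ = 0.9, β₂ = 0.999),
base learning rate 10⁻³ decayed linearly to 0 over the epochs
(lr_e = base·(1 − e/E)), batch size 32, 50 epochs by default. Non-finite
loss (or NaN gradients inside the optimizer) raises a divergence error
naming the epoch.

Metrics follow the molecular convention: per-group F1 = 2TP/(2TP+FP+FN)
over molecules; a group with TP = FP = FN = 0 is *undefined* and excluded
from macro averages instead of being imputed 0 (curated datasets genuinely
lack some groups, e.g. acyl halides, and 0-imputation would distort the
mean). Perfect match means all 17 bits correct; perfect-match ratios and
per-sample FPR/FNR are bucketed by the number of true groups, with
per-sample rates undefined when a sample has no true negatives (FPR) or no
true positives (FNR).

Protocols: plain (unstratified) 5-fold cross-validation with seeded
shuffling, each fold model trained with seed offset fold index; and a
70-20-10 holdout in which the 10 % test set is fixed first and all five
fold models from CV on the remaining 90 % are scored on it.

## Spectral attribution

Per-class importance maps are Shapley values over contiguous spectral
segments (default 50 cm⁻¹, i.e. 69 segments on the default grid — exact
per-point Shapley over 3401 inputs is intractable), estimated by
permutation sampling with the all-zero spectrum as the masked/baseline
state (the natural "no absorbance" reference after normalization; the
choice of background is a genuine free parameter of this family of
methods). Each sampled permutation's marginal contributions telescope to
f(x) − f(0), so completeness holds up to float error; the residual is
recorded on the map. Segment values are spread uniformly over their grid
points for plotting. Maps from models whose output barely depends on the
input are flagged `degenerate` rather than rejected. Estimates are
deterministic given seed and permutation count; the test suite checks them
against exact subset-enumeration Shapley values on ≤ 12-segment toys.

## Synthetic data

The generator emulates what the classifier needs from real IR data: each
present group adds Gaussian bands with centers drawn uniformly inside the
group's characteristic range (widths and relative intensities fixed per
band, ±30 % amplitude jitter), plus fingerprint-region clutter (up to 8
small random peaks below 1800 cm⁻¹), a smooth sinusoidal baseline drift
(amplitude 0.05) and white noise (sd 0.02), followed by the same min–max
normalization as the real pipeline. Label counts are uniform on 1–5 groups
per sample, matching the range that dominates curated IR datasets. The band
ranges for methyl, aromatics, C–F and ether C–O follow the standard
characteristic-absorption ranges; the remaining entries are
correlation-table fixture constants chosen once to make the 17 classes
mutually distinguishable (e.g. heavier-halide C–X stretch at 600–800 cm⁻¹
separating halides from ethers, the broad O–H width separating alcohols
from amines).

What it does *not* model: Lorentzian/Voigt line shapes, overtones and
combination bands, band shifts from conjugation or hydrogen bonding,
intensity physics, instrument artifacts, or correlated label structure.
A model that recovers groups from these spectra has demonstrated that the
architecture, losses, protocols and attribution machinery work end to end —
not that it reaches any particular accuracy on measured spectra.

## Problem sizes and numerical choices

End-to-end validation trains on 2 000 synthetic spectra and evaluates on
500 held-out spectra for three independent draws, and the attribution check
trains a 300-sample nitrile-only model for 15 epochs — sizes at which the
full protocol (50 epochs, batch 32) runs in minutes on a single CPU while
leaving headroom above the acceptance thresholds. Other constants:
transmittance floor 10⁻⁶ before the log; batchnorm ε = 10⁻⁵, momentum 0.1;
probability threshold 0.5 with ties counted as present; constant spectra
min–max-normalize to all zeros; k-fold remainders distributed one extra
sample to the leading folds.

## Known limitations

* The JCAMP reader covers the AFFN dialects only; SQZ/DIF/DUP compression
  is rejected (extension point, not silently wrong).
* The 16 non-ether SMARTS are pinned package conventions; other toolkits or
  catalogs draw group boundaries differently (notably alkane and aryl
  halides).
* Unstratified folds can starve very rare groups in small datasets; the F1
  undefined-group convention surfaces this rather than hiding it.
* Attribution is segment-resolution and baseline-dependent; it supports
  qualitative reading ("the model used the nitrile stretch"), not
  quantitative band assignment.
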