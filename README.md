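# memconnect

Membrane-connectivity digital analysis of HER2 immunohistochemistry, with
the full concordance toolkit used to validate such a scorer against
pathologist reads and FISH.

## The problem

HER2 status guides therapy in breast cancer. Conventional testing scores
DAB-stained IHC slides visually on the ordinal 0 / 1+ / 2+ / 3+ scale,
which is subject to observer variation precisely in the clinically
critical equivocal (2+) zone. Digital image analysis can replace the
visual read with a continuous, reproducible measurement. This package is
for image-analysis and biostatistics practitioners who want a transparent,
fully tested implementation of one such measurement — the *membrane
connectivity* estimate — together with the statistics needed to compare
any HER2 scorer against repeated visual evaluation and FISH.

## The statistic

A spot image is processed as:

1. **Stain separation.** Per-channel optical density
   `OD_c = −log10((I_c + 1)/255)` is decomposed onto hematoxylin and DAB
   unit vectors (Beer–Lambert / color deconvolution), giving a DAB density
   map.
2. **Membrane enhancement and segmentation.** A single-scale Hessian
   (Sato) ridge filter enhances thin curvilinear DAB structures; a global
   Otsu threshold on the positive ridge responses, combined with a DAB
   density floor, yields the binary membrane mask. The ROI is the tissue
   mask eroded by a 100-pixel edge margin, and a spot is analyzed only if
   the ROI area strictly exceeds 37,000 µm².
3. **Skeleton post-processing.** The mask is thinned to a 1-px skeleton;
   fragments separated by gaps ≤ `gap_px` are merged; fragments smaller
   than `min_fragment_px` are eliminated. The size `a_i` of a fragment is
   the number of pixels of its skeleton.
4. **Connectivity.** With low/high fragment-size cut-offs `c_low < c_high`,

       C = Σᵢ aᵢ·w(aᵢ) / Σᵢ aᵢ,   w(a) = clip((a − c_low)/(c_high − c_low), 0, 1)

   so C = 0 when no fragment exceeds `c_low` and C = 1 when every fragment
   exceeds `c_high`.
5. **Scoring.** HER2 score 0/1+ if C ≤ 0.12, 2+ if 0.12 < C ≤ 0.56,
   3+ if C > 0.56.

The concordance layer aggregates spots per patient (maximum over adequate
spots: VEmax, DAmax, ConnectMax), cross-tabulates raters into 3×3 ordinal
tables, and reports linearly weighted Cohen's kappa with an asymptotic 95%
CI, percent agreement, FISH positivity per category (HER2/CEP17 ratio
strictly > 2), and Pearson correlations on log scales. A synthetic
generator renders stained spots with known membrane ground truth and
simulates score/FISH cohorts, so the whole pipeline is testable without
any external data.

## Worked example

```bash
python examples/agreement_statistics.py
```

prints, from the bundled reference cross-tabulations:

```
comparison                n   kappa          95% CI   % agree
ve1_vs_ve2 (spot)       575    0.91    [0.88, 0.95]     96.0%
ve1_vs_da (spot)        575    0.86    [0.81, 0.90]     93.2%
ve2_vs_da (spot)        575    0.87    [0.82, 0.91]     93.4%
ve1_vs_ve2 (patient)    161    0.88    [0.81, 0.96]     94.4%
ve1_vs_da (patient)     161    0.80    [0.70, 0.89]     89.4%
ve2_vs_da (patient)     161    0.86    [0.79, 0.94]     92.5%
```

Kappa ≥ 0.81 reads as almost-perfect agreement: the digital analysis
agrees with either visual evaluation nearly as well as the pathologist
agrees with themself. `examples/score_synthetic_spot.py` runs the image
pipeline on a rendered spot (70% membrane completeness → connectivity
0.9371 → 3+), `examples/fish_concordance.py` reproduces the per-category
FISH-positive proportions from the bundled 54-patient cohort, and
`examples/simulate_cohort.py` generates a 575-spot cohort and recovers its
generating kappa and log-scale correlation.

Command-line equivalents: `memconnect score-spot IMAGE --mpp 0.25`,
`memconnect batch MANIFEST.csv --out results.csv`,
`memconnect concord spots.csv --fish fish.csv --out report/`,
`memconnect synth spot|cohort`, `memconnect report DIR`.

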