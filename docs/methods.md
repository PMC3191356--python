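# Methods

## Image model and stain separation

Brightfield H-DAB images are treated under the Beer–Lambert law: the
per-channel optical density of a pixel with 8-bit intensity `I_c` is
`OD_c = −log10((I_c + ε)/255)` with ε = 1 intensity unit guarding
`log(0)`. The OD vector is assumed to be a non-negative mixture of
hematoxylin and DAB unit vectors (Ruifrok–Johnston values by default,
hematoxylin (0.650, 0.704, 0.286), DAB (0.269, 0.568, 0.778), completed
by their cross product as residual axis). The mixture is inverted by
solving the 3×3 system per pixel; negative coefficients — noise outside
the physical cone of the basis — are clipped to zero, so a pure-white
pixel carries zero density in both stains.

The decomposition is the exact inverse of the forward renderer
(`od_to_rgb`) *within the unclipped dynamic range*: once a rendered
channel saturates to intensity 0 (per-channel OD beyond ≈ 2.4) the
density is unrecoverable, so round-trip tests cover OD pairs in
[0, 1.5]², which is clip-free under the default vectors. Real tissue
rarely exceeds OD ≈ 1.5 per stain.

No cross-scanner color normalization is attempted; the stain vectors are
configuration values.

## Membrane segmentation

Stained membranes appear as thin bright curvilinear ridges in the DAB
density plane. They are enhanced with a single-scale Sato
(Hessian-eigenvalue) ridge measure at `ridge_scale_um` (default 1.0 µm,
the order of membrane thickness; clamped to one pixel with a warning if
the scale falls below the pixel pitch). The measure is zero on constant
input, invariant to adding a constant density, translation-equivariant
away from borders, and prefers lines over isotropic blobs — the minimal
operator consistent with "detect curvilinear stained structures". The
operator sits behind a single function so it can be swapped.

Segmentation is a two-class (Otsu) threshold chosen from the histogram of
*positive* ridge responses, intersected with a DAB density floor
(`min_dab_od`, default 0.15 OD) that keeps chromogen-free ridges (e.g.
hematoxylin edges or noise ridges) out of the mask. Degenerate histograms
(constant or empty) yield an empty mask, which is meaningful: no
detectable membrane. Candidates are pixels with positive response rather
than positive DAB because on clean images the DAB-positive set is exactly
the membrane, and a bimodal split *within* the membrane values would
discard the dimmer half of the true structure; the positive-response set
always contains the background shoulder needed for a stable split.

## ROI and adequacy

Tissue is detected as pixels whose total OD exceeds `tissue_od_floor`
(default 0.1) after hole filling and removal of components smaller than
`min_speck_px` (default 100 px). The ROI erodes the tissue mask so that
every ROI pixel lies at least `margin_px` (default 100 px ≈ 25 µm at the
default 0.25 µm/px) from the nearest tissue edge, guarding against
edge-staining artifacts; the erosion uses the Euclidean distance
transform. A spot is analyzed only when the ROI area strictly exceeds
`min_roi_area_um2` (default 37,000 µm², about 5% of the ROI of an intact
1-mm spot: π·(500−25)² ≈ 7.09·10⁵ µm²). Spots flagged in the manifest as
manually excluded (inadequate tumour sample, DCIS) are never processed —
those exclusions are a visual-evaluation judgement, not an algorithm.

## Skeleton post-processing and connectivity

The membrane mask restricted to the ROI is thinned to a one-pixel
skeleton (topology-preserving thinning), labelled with 8-connectivity.
Fragments separated by end-to-end gaps of at most `gap_px` (default 3 px)
are merged by dilating the skeleton by ⌈gap_px/2⌉ and re-skeletonizing;
`gap_px = 0` is the identity. Fragments smaller than `min_fragment_px`
(default 10 px) are eliminated.

The fragment size `a` is its skeleton pixel count. Connectivity is the
size-weighted ramp

    C = Σ aᵢ·w(aᵢ) / Σ aᵢ,   w(a) = clip((a − c_low)/(c_high − c_low), 0, 1)

with defaults `c_low = 50`, `c_high = 500` skeleton pixels at 0.25 µm/px
(≈ 12.5 µm and 125 µm of membrane — below one cell perimeter versus
multi-cell chains). The two boundary behaviours (C = 0 when nothing
exceeds the low cut-off, C = 1 when everything exceeds the high one) are
fixed by the method's definition; the size-weighted linear ramp is this
package's interpolation between them — the simplest aggregation that is
continuous, non-decreasing in every fragment size, invariant to jointly
rescaling sizes and cut-offs, and never decreased by merging fragments.
An empty fragment set has C = 0. The HER2 score is 0/1+ for C ≤ 0.12,
2+ for 0.12 < C ≤ 0.56, 3+ for C > 0.56, boundaries belonging to the
lower category. The cut-offs and all post-processing parameters are
configuration keys recorded in every run log; they are deliberately not
tuned per dataset.

Because the statistic depends only on the fragment-size distribution, it
needs no cell segmentation and no tumour/non-tumour discrimination; the
only tissue requirement is a sufficient amount in the ROI.

## Agreement and FISH statistics

Spots aggregate per patient as the maximum over adequate spots (`max` is
the default; `mode` and `median` are available), requiring at least
`min_spots = 2` adequate spots. Rater pairs are cross-tabulated into 3×3
ordinal tables; agreement is Cohen's kappa with linear weights
`w_ij = 1 − |i−j|/2`, chance correction from marginal products, and the
large-sample (Fleiss–Cohen–Everitt) variance for the 95% CI (z = 1.96),
computed via statsmodels and cross-checked in tests against a direct
evaluation of the defining sums. Linear weights and the asymptotic CI
reproduce all six reference kappas to 2 decimals and all printed CIs
within ±0.02; quadratic weights do not (e.g. 0.95 instead of 0.91 on the
spot-level intra-observer table), which is why linear is the default.
Percent agreement is 100·trace/total.

FISH positivity is strict: amplified iff HER2/CEP17 > 2.0 (a ratio of
exactly 2.0 is negative). Polysomy (CEP17 > 3) and copy-number
amplification (HER2 > 6) flags are provided for the bubble-plot report.
Correlations between connectivity and FISH variables are Pearson on
(optionally) log-transformed values with two-sided t-test p-values;
non-positive values under a log are an input error, not silently dropped.

## Synthetic data

**Spot images.** Cells are discs of radius `cell_radius_um` (8 µm) placed
on a hexagonal lattice with 1-px clearance: 90% form a compact nest of
touching cells around a jittered centre, 10% (`scatter_fraction`) sit in
detached islets of 2–3 touching cells, emulating detached tumour nests.
Each cell carries a contiguous membrane arc covering a Beta-distributed
fraction of its perimeter (mean = `membrane_completeness`, concentration
10; degenerate at 0 and 1), rendered at `dab_intensity` (0.8 OD) with
thickness 1 µm, over a hematoxylin base (0.25 OD) with nuclei (+0.35 OD)
and Gaussian OD noise (SD 0.05) inside the tissue disc; the image is the
forward Beer–Lambert rendering, quantized to 8 bits. Defaults emulate a
1-mm core at 0.25 µm/px with 1200 cells (≈ 40% tumour-area fraction);
the unit tests and the acceptance script run 400-µm spots with 80 cells —
the same geometry at a smaller problem size. Generation is bit-for-bit
reproducible from (params, seed), and infeasible packings raise an error
suggesting fewer or smaller cells.

Contiguous arcs are the worst case for connectivity at a fixed stained
fraction, and the islet sizes matter: a detached *single* complete cell
is a ~200-px loop whose ramp weight (~0.33) drags the size-weighted mean
down more than its own shorter partial arc would, which can make C
non-monotone in completeness; islets of 2–3 cells produce fragments in
the size range where the ramp deficit shrinks as staining grows, keeping
the completeness→connectivity mapping strictly increasing. This mapping
is generator-specific: real tissue differs in cell-size dispersion,
membrane texture, stain variation and scanner characteristics, so passing
synthetic tests demonstrates correct mechanics of the pipeline, not
clinical performance.

**Cohorts.** Each patient has a latent HER2 category and 1–4 spots. By
default the cohort composition is fixed (`fix_composition`): category
counts and spots-per-patient counts are the largest-remainder rounding of
the target proportions (defaults: 85.2/4.3/10.4% categories; 16/15/55/91
patients with 1/2/3/4 spots → 575 spots, 161 patients with ≥ 2 spots),
randomly assigned — the emulated operating point is one fixed cohort, and
freeing the composition adds seed-to-seed variance unrelated to rater
behaviour (`fix_composition=False` gives fully multinomial draws). The
first visual read equals the latent category; the second read and the
digital score are drawn from row-stochastic confusion matrices whose
defaults are the row-normalized reference cross-tabulations — discordance
concentrated around 2+, no two-category flips. Spot connectivity is drawn
strictly inside the score band of the digital category (Beta shapes
(1, 4), (2, 2), (3, 1.5)), yielding the characteristic bimodal,
left-asymmetric ConnectMax distribution. FISH counts are lognormal:
log HER2 = µ_h + σ_h(ρ·z + √(1−ρ²)ε) with z the sample-standardized
log ConnectMax, so the generative log-scale correlation equals ρ
(default 0.67) exactly; CEP17 analogously with ρ = 0.39, and the ratio is
their quotient. Defaults: µ_h = log 4.5, σ_h = 0.75, µ_c = log 2.5,
σ_c = 0.30, chosen so negative patients centre near ratio ≈ 1.5 and
amplified patients near 4–6 with realistic copy numbers.

## Numerical choices and degenerate inputs

- Boundaries: score cut-points and the FISH/polysomy/amplification
  thresholds are strict exactly as defined above; the ROI area rule is a
  strict `>`.
- Empty inputs are meaningful where the science says so (empty membrane
  mask, empty fragment set → C = 0) and errors where they are not (empty
  contingency table, fewer than 3 correlation pairs, zero variance,
  degenerate marginals making chance agreement 1).
- Thinning tie-breaks are those of the underlying skeletonization
  algorithm, pinned by regression tests on programmatic fixtures.
- Batch analysis records a per-spot error row and continues; the CLI
  exits non-zero on configuration and input errors.
- Every run can be reproduced from its logged configuration
  (`run_log`), which records the full effective parameter set and library
  versions.

## Known limitations

- The stain model assumes H-DAB chemistry and a fixed stain basis; no
  support for other chromogens or cross-scanner normalization.
- The exact pre-processing, segmentation and post-processing operators of
  the commercial implementation of this method are not public; the
  operators here (Sato ridge, Otsu, dilation-based merging) are declared
  substitutes with the same contracts, and the fragment-size cut-offs are
  package defaults, not reverse-engineered values.
- Patient-level summaries assume the maximum-spot convention; it
  increases sensitivity on limited samples but a single false-positive
  spot can flip a patient.
- The asymptotic kappa CI is a large-sample approximation; for tables
  with very sparse categories a resampling CI would be preferable.
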