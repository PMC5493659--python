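# Methods

This note documents the models, conventions and numerical choices behind
`hyperphen`, and what the synthetic-data validation does and does not
demonstrate.

## Acquisition model and calibration

A push-broom line-scan camera sampling 400–1000 nm in 250 bands emits a
flat stream of unsigned integer samples. The stream layout is assumed to be
band-interleaved-by-line (BIL) with 16-bit little-endian samples; both are
configurable (`bsq`/`bip`, any integer or float dtype) since instrument
vendors differ and the original byte layout of any given system is rarely
documented. For the emulated geometry (1,004 cross-track pixels, 900 scan
lines) a scan is a 1,004 × 250 × 900 stream that reorganizes into 250
per-band images. Reorganization is a bijection: flattening the band images
in the stream's interleave order reproduces the payload byte for byte, and
this is tested as a property.

Reflectance is calibrated per pixel and band as

    r = (I − I_dark) / (I_ref − I_dark)

with dark-current and white-reference frames. Pixels where the reference
equals the dark frame are undefined and returned as NaN. Negative values
(sensor noise below dark current) are clipped at 0; values above 1.2 are
flagged with a warning but kept, since specular glints are informative for
quality control. The calibration is invariant under a common gain applied
to all three images. Repeated scans of the same plant can be averaged
upstream (`average_streams`) to improve the signal-to-noise ratio;
pre-averaged streams are equally accepted.

Band centers follow the linear mapping λ(i) = 400 + (i−1)·600/249 nm
(step ≈ 2.41 nm). All label checks agree with this mapping to the nearest
nanometre except a single 903-nm label that the mapping puts at 903.6 nm;
labels are therefore treated with a ±1 nm tolerance.

Cubes are stored as a plain-text ENVI header plus raw binary data (BSQ,
float64), written and parsed by a small reader/writer in `cube_io` — none
of the installed scientific libraries reads ENVI, and the format is a
dozen key/value lines. Wavelengths round-trip at full precision.

## Segmentation

The exact operator chain used on real installations is usually
instrument-specific; the rule implemented here is the standard one for
vegetation against an achromatic background: an NDVI-like ratio
(NIR−red)/(NIR+red) from the bands nearest 800 and 670 nm, an Otsu
threshold (plus an absolute NDVI floor of 0.2 so plant-free scenes yield an
empty mask rather than a split of the noise histogram), a 3×3 binary
opening, and removal of connected components under 50 pixels. Disconnected
plant parts above the size floor are all retained. The projected area S is
the plant pixel count; with two imaging angles (0° and 90°) indices are
computed per view and averaged, S included. The vegetation ratio makes the
mask invariant to a global intensity gain. On generator cubes the rule
recovers the stored truth masks at Jaccard ≥ 0.99 (the residual disagreement
is boundary pixels shaved by the opening).

## The index catalog

Eight families, 1,540 indices, names fixed by a versioned registry:

| family | size | definition |
|---|---|---|
| T, A | 250 + 250 | per-band sum over plant pixels; A = T/S |
| dT, dA | 250 + 250 | first derivative w.r.t. wavelength |
| ddT, ddA | 250 + 250 | second derivative |
| CPT, CPA | 20 + 20 | characteristic features of the T and A spectra |

Derivatives are taken per nanometre, not per band index, so values are
physical and comparable across spectral resolutions, using central
differences at interior bands and one-sided second-order stencils at the
two ends. Keeping the full 250-band length for the derivative families is
what makes the six band-wise families total 1,500 and the catalog exactly
1,540.

The 20 characteristic slots are standard vegetation-spectroscopy features:
position, amplitude (max first derivative) and area (trapezoidal integral
of the first derivative) for the blue (490–530 nm), yellow (560–640 nm)
and red (680–760 nm) edges; green-peak position/height (510–560 nm);
red-valley position and depth below the chord joining the 640/700-nm
endpoints; NIR plateau mean (780–1000 nm); visible mean (400–760 nm); and
five ratio / normalized-difference combinations of these. Slot 9 is pinned
to the red-edge area. CPT is computed strictly from the T spectrum and CPA
from the A spectrum; the registry is a single table in
`spectral_indices.py` so slots can be re-bound without touching consumers.
Ratio slots return NaN on degenerate (zero-denominator) spectra rather
than raising.

## Trait models

Stepwise selection uses forward entry at α_enter = 0.05 and backward
removal at α_remove = 0.10 — the classic defaults. Entry is by the
smallest partial-F p-value, computed by residualizing candidates and the
response against the current model (one QR per step, so screening all
1,541 candidates is vectorized); ties break on the lexicographically
smallest feature name, making the procedure deterministic and independent
of column order. Candidates whose residual variance falls below 1e-8 of
their raw variance are treated as collinear and skipped; zero-variance
candidates are excluded up front. A visited-set guard makes entry/removal
cycles terminate.

Cross-validation assigns folds by a seeded uniform permutation split into
k near-equal parts, refitting the stepwise model per training split.
Reported are per-fold held-out R², per-fold MAPE, and the SD of per-sample
absolute percentage errors (population SD, ddof = 0, matching the 1/n in
the error definitions; "SD_APE" is taken at its name — the spread of the
APE values whose mean is the MAPE). Held-out samples with Y = 0 are
excluded from percentage errors with a warning. MAPE is scale-invariant,
which the suite checks as a property.

The correlation screen tallies |Pearson r| > 0.3 per wavelength —
absolute, not signed, since negatively correlated indices are equally
informative; band-wise features count at their band center and
characteristic features at their window center (a registry attribute).
Stage/subspecies classification selects features stepwise by the partial F
of the Wilks' Λ ratio and evaluates a linear discriminant with stratified
k-fold cross-validation; candidates with singular within-class scatter are
skipped.

Prediction accuracy on real crop panels is dataset-specific and no claim
about it is made here; the synthetic experiment only demonstrates that the
machinery recovers planted relationships.

## Genetic analyses

Panel filters: SNPs are oriented to the minor allele, then kept when
MAF ≥ 0.05 and at least 6 accessions carry the minor allele. The GRM is
K = ZZ'/m on column-standardized, mean-imputed dosages (monomorphic SNPs
excluded), giving a symmetric PSD matrix with diagonal mean ≈ 1.

Bivariate REML: the two-trait model has genetic covariance structured by
the GRM and a *diagonal* residual covariance (residuals independent
between traits — the generator's regime; a residual covariance term as in
general mixed-model software is a known extension not implemented here).
Each trait's only fixed effect is an intercept; traits are standardized
internally. A single eigendecomposition of the GRM rotates the model into
n independent 2×2 blocks, making every likelihood, score and
average-information quantity O(n). Maximisation starts from a moment-based
point (half the phenotypic variance genetic, genetic covariance at half
the phenotypic correlation) and takes average-information steps with
step-halving; if that stalls, a Nelder–Mead search on the exact restricted
likelihood in an unconstrained parameterisation (log variances, atanh
correlation) finishes. Convergence is a restricted log-likelihood change
below 1e-6; variance components are floored at 1e-8 and the genetic
correlation is confined inside ±1, so boundary cases (e.g. a trait paired
with itself) return |r_g| → 1 cleanly. Standard errors come from the
inverse average-information matrix by the delta method. At the validated
design point (n = 500, 2,000 SNPs, h² = 0.5 both traits, r_g = 0.6) the
mean estimates over 20 seeds sit within ±0.1 of truth; single-replicate
sampling SD is ≈ 0.12, consistent with the usual GRM-REML information
bound ≈ √(2/(n²·var(K_offdiag))).

Hyper-traits: an index qualifies when |r_p| ≥ 0.5 with the agronomic
trait, |r_g| ≥ 0.5 and its own h² ≥ 0.5 — absolute correlations, since
strongly negative proxies pass by magnitude.

Association scan: per-SNP slope t-tests on mean-imputed dosages —
deliberately structure-naive plumbing so clumping and locus definition can
be exercised end to end; P-values are floored at the smallest positive
double so they stay in (0, 1].

Thresholds: suggestive = 1/N and significant = 0.05/N for an externally
estimated effective SNP number N (its estimation is out of scope), so
significant/suggestive = 0.05 identically.

LD clumping: greedy over SNPs below the suggestive threshold in ascending
P order; each lead absorbs all remaining candidates with r² > 0.25 to it
(composite r²: squared correlation of mean-imputed dosages — the common
summary-statistic practice when the phasing tool is unspecified); leads
are then dropped unless ≥ 5 SNPs at P < 10⁻⁴ are in LD (r² > 0.25) with
them. Output is invariant to the input row order, checked against a
loop-based oracle.

Loci: associated SNPs whose adjacent distance is under 300 kb merge into
one locus (single linkage along each chromosome), so distinct loci are
≥ 300 kb apart, every input SNP belongs to exactly one locus, and the lead
SNP is the lowest-P member with position as tie-break. Merging is applied
to clumped leads by default; a switch allows merging all suggestive SNPs
instead, since both conventions exist in practice. Candidate windows take
all annotated genes overlapping ±100 kb of a lead SNP from a GFF3 file.
Haplotype contrasts group accessions by their exact dosage string over the
chosen significant SNPs, drop groups under 30 accessions, and compare the
two largest with a Welch t-test.

## Synthetic data

The imaging generator is a shape model, not radiative transfer: plant
reflectance is base + Gaussian green peak (550 nm) − Gaussian chlorophyll
absorption (680 nm) + logistic red edge rising to a NIR plateau. The
latent chlorophyll variable (0–1) deepens the absorption from 0.02 to
0.065, shifts the red-edge inflection linearly from 700 to 720 nm and
damps the green peak; latent biomass scales the plateau from 0.40 to 0.65
and the plant radius. The background is spectrally flat (0.25), per-pixel
noise is Gaussian (SD 0.01 by default), and the scene is inverted through
the calibration equation (dark ≈ 100 counts with mild per-band structure,
white ≈ dark + 2,200–3,200 counts) and quantized to the stream dtype.
These defaults give vegetation/background NDVI contrast of ≈ 0.85 vs 0,
comfortably bimodal, which is what real pot-grown scenes in a darkroom
look like; what they do *not* emulate is specular glint, pot-rim
reflections, leaf-angle effects, within-plant chlorophyll gradients or
sensor smile, so segmentation and recovery results on generator cubes are
upper bounds on real-data performance. Growth stages differ in their
latent means (chlorophyll 0.75/0.50/0.25 and biomass 0.35/0.60/0.85 for
tillering/heading/ripening, SD 0.08), i.e. ≈ 5-nm red-edge shifts between
stages.

The genetic generator draws binomial dosages at uniform MAFs (0.05–0.5)
over 12 chromosomes, optionally in linkage blocks (SNPs in a block copy a
base column with a per-accession resampling rate, giving within-block
r ≈ 1 − resample rate). Per-SNP effect pairs are bivariate normal with
correlation r_g; optional QTLs carry a configured share of the genetic
variance. Genetic values are rescaled so the realized variance explained
equals the configured h² exactly, and residuals are independent between
traits — the model the REML estimator assumes, which is the point: the
recovery tests are well-specified-model calibration checks, not robustness
studies. No epistasis, dominance, G×E or population structure is
simulated, which is also why the naive association scan is adequate
plumbing here.

Identical seeds give bit-identical outputs; every artifact carries its
ground truth (masks, spectra, genetic values, QTL effects) so downstream
tests never re-derive it.

## Problem sizes in the validation runs

The suite and the acceptance script run everything at desk scale, chosen
to make the statistical checks informative: 80×80 cubes with the full 250
bands (50 seeds for mask recovery), 30–36-plant panels through the full
imaging pipeline for modeling and classification, 200–600-SNP LD panels
for clumping against brute-force oracles, 1,000 random instances for
locus-set invariants, and 20 replicates of n = 500 / 2,000 SNPs for REML
recovery. One full-size 1,004 × 250 × 900 stream is reorganized to pin the
acquisition geometry.

## Known limitations

* The 20 characteristic slots follow standard spectroscopy definitions;
  installations with their own feature tables should re-bind the registry.
* The REML residual covariance is diagonal; traits with shared
  measurement error will push its estimate of r_g toward the phenotypic
  correlation.
* The association scan ignores kinship and structure by design.
* Haplotype groups use exact dosage-string identity, which fragments under
  genotyping error; real panels usually collapse to major haplotypes
  first.
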