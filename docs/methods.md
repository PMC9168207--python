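# Methods

This note documents the models, parameter choices and numerical conventions
behind `echocad`, and what the synthetic experiments do and do not show.

## Problem setting

The pipeline is a binary texture classifier for apical 4-chamber
echocardiogram stills: normal hearts versus hearts with hypertension-induced
structural change. Hypertensive remodeling thickens the myocardium and
alters its fine-grained speckle texture before overt hypertrophy; the
working hypothesis is that multi-resolution texture statistics capture these
changes. The reference study size — 51 normal and 61 HTN images — is used
as the default dataset shape throughout.

## Preprocessing

Ultrasound frames carry burned-in annotations outside the imaging sector.
The annotation mask flags (i) every pixel outside the largest connected
foreground component (the sector, found by thresholding the 5×5
median-filtered frame at 0.02, filling holes, and dilating 2 px to undo the
median filter's boundary erosion), and (ii) bright components (≥ 0.9 of the
frame maximum) that are small (< 2000 px) or touch the outer 5% border band.
The sector interior is never flagged. Flagged pixels are zeroed, CLAHE
(clip limit 0.01, 8×8 tiles, 256 bins — the ubiquitous defaults) enhances
contrast, and the sector bounding box is cropped and bilinearly resampled to
512×512. The pinned stage order is mask → CLAHE → crop → resize; the whole
chain is deterministic. A genuinely degenerate (constant) image is returned
unchanged by CLAHE, since equalizing a one-bin histogram is the identity.

## Feature extractors

All six extractors share one summarization convention: decompose into
sub-bands, take absolute coefficient values, block-average to a small fixed
grid, concatenate coarse → fine with ascending orientation. Decomposition
depths and direction counts are pinned so the feature lengths are exact
contracts (2560 / 4096 / 9216 / 15872 / 8192 / 512); each is a config
default and can be overridden, in which case the lengths change
accordingly.

* **DWT** — 3-level separable db4 with periodization: 10 sub-bands of exact
  dyadic sizes, each pooled to 16×16. Orthonormal, so Parseval holds
  exactly; a constant c maps to approximation features c·2³ (per-level 2-D
  scaling gain 2) and zero detail features.
* **Contourlet** — a Laplacian pyramid whose reduce/expand pair uses the
  orthonormal db4 scaling filter with the exact adjoint as expansion. This
  makes the pyramid a tight frame: analysis loses no energy, collapse
  reconstructs bit-near-exactly, and constants reproduce without leakage
  into band-pass levels. Each band-pass level passes through a
  frequency-domain directional filter bank: raised-cosine (Meyer-type)
  windows in the angle-modulo-π coordinate forming an exact partition of
  unity (4, 4, 8 directions fine → coarse). The low-pass is excluded from
  the features.
* **Dual-tree complex wavelet** — two parallel orthonormal trees (Farras
  nearly-symmetric first stage; Kingsbury Q-shift 10-tap deeper stages,
  tree B the time reverse of tree A) filtered circularly via FFT. The four
  row/column tree combinations combine into 6 oriented complex sub-bands per
  level whose magnitudes are approximately shift-invariant; a 1-D
  analyticity probe of the implemented cascade shows 99.2% one-sided
  spectral energy. The published 8-decimal Q-shift coefficients are
  re-balanced (even/odd tap sums forced to √2/2) so the lowpass sums to
  exactly √2 and the quadrature-mirror highpass to exactly 0, making
  constant images map to exactly zero detail features. Real and imaginary
  parts are pooled separately (36 × 256 features).
* **Shearlet** — a cone-adapted frequency-domain system: Meyer radial bands
  in t = log₂(8r) under the max-norm radius, angular raised-cosine windows
  in the shear coordinate saturating at the cone edges, hard cone split
  along the diagonals. Squared magnitudes sum to exactly 1 (tight frame);
  1 + 3 scales × 2 cones × 5 shears = 31 filters, each map pooled to 16×32.
  Boundary shearlets are confined to their cone (zero out-of-cone energy)
  rather than glued across the diagonal; this sacrifices frequency-domain
  smoothness at the seam, which is irrelevant for energy-pooling features.
* **2-D CWT** — scale-normalized Laplacian-of-Gaussian (Mexican hat)
  responses at 8 dyadic scales via FFT. Scale normalization (σ²∇²G) makes
  the response magnitude scale-invariant, so the energy-maximizing scale
  matches the structure size (verified: a σ = 8 blob peaks within one
  dyadic step of 8).
* **EWT** — per image row: the largest local maxima of the FFT magnitude
  spectrum (up to 4) define band boundaries at peak midpoints; smooth
  Meyer-type steps with transition half-width half the distance to the
  nearest neighbouring edge form an exact partition of unity, so modes sum
  to the signal to machine precision. The feature is the lag-1 correntropy
  of the highest-frequency mode, V = mean exp(−Δ²/2σ²) with σ = 1 after
  z-scoring (constant bands return V = 1). Rough bands give small V, smooth
  bands V ≈ 1.

The curvelet slot exists in the registry but is deliberately not
implemented.

## LSDA

Locality sensitive discriminant analysis builds kNN graphs (k = 5,
Euclidean, self-excluded, distance ties broken by sample index,
OR-symmetrized) split by label agreement into a within-class adjacency Ww
and between-class adjacency Wb, then solves

    Xᵀ(α·Lb + (1−α)·Ww)X a = λ (XᵀDwX + ε·I) a

with α = 0.5, ε = 1e−6, Lb = Db − Wb, keeping the r = 30 eigenvectors of
largest λ (columns orthonormalized by QR, sign-fixed by making each
column's largest-magnitude entry positive). Columns of X are standardized
with the training statistics, which are stored and re-applied at transform
time, so train/test separation is leakage-free. For wide data the problem is
solved in the sample span (whitened dual basis); this is algebraically
identical to the primal problem restricted to that span and is verified to
agree to 1e−8 on small instances. The `between='adjacency'` option selects
the published variant that uses Wb instead of Lb in the objective.

**Conditioning in the overcomplete regime.** When the feature dimension
reaches the sample count, the eigenproblem admits directions that exactly
collapse a training class to a single value. If the classes are so well
separated that Wb has no edges (exactly the situation on these phantoms),
such directions attain the Rayleigh-quotient supremum and fill the leading
eigenvectors. They can transfer poorly: a downstream axis threshold
calibrated on a zero-width training class has no margin, which made the
decision-tree pathway seed-unstable (observed 77–100% across seeds) while
margin- and covariance-based classifiers were unaffected. Following the
standard practice for graph-embedding discriminants, LSDA therefore applies
a PCA pre-projection (to `n_pca` = r dimensions by default) whenever
d ≥ n, computed on the standardized features inside `fit`. Larger ridge
values and per-fold t-ranking were evaluated and do not remove the
degeneracy; the PCA stage does, and with it the criterion pipeline is stable
at 100% across all tested dataset/CV seed combinations. Well-posed inputs
(d < n) are never PCA-projected. `n_pca=None` disables the stage.

Whether reduction is fitted once on all data or per training fold is a
protocol choice: the default is per-fold (leakage-free); `paper_mode` in the
pipeline config reproduces the whole-dataset variant for comparison with
reported whole-dataset feature statistics.

## Ranking, classifiers, validation

Features are ranked by |t| from Welch's unequal-variance two-sample test
with Welch–Satterthwaite degrees of freedom (the unequal-variance form
reproduces the reference per-feature t statistics from their printed
per-class moments to within the 4-decimal rounding of those inputs; ties
broken by ascending index; a feature identical in both classes ranks last
with t = 0). Nine classifiers are exposed: CART/Gini decision tree
(unlimited depth), linear and quadratic Gaussian discriminants (singular
quadratic covariances are ridge-repaired with a warning), SVMs with
polynomial kernels of degree 1–3 (C = 1, coef0 = 1, gamma = 'scale') and
RBF (γ = 1/(r·var)), kNN (k = 5, clamped to the training size), and a
Parzen-window Gaussian-kernel density classifier (σ = 0.1 on standardized
features) as the probabilistic neural network.

Cross-validation is stratified 10-fold from a seeded shuffle (default seed
17), with fold-internal standardization and (when a reducer is supplied)
fold-internal reduction. Confusion counts are pooled over folds; accuracy,
PPV, sensitivity and specificity are reported in percent with HTN as the
positive class; undefined ratios are NaN with a warning. Incremental
selection evaluates the first k ranked features for k = 1..max and returns
the smallest k attaining the maximal accuracy.

## Synthetic phantoms

The generator emulates the geometry and texture statistics of apical
4-chamber stills, not ultrasound physics: a 90° sector fan (≈ 75% of the
frame), four elliptical blood pools (ventricles apical, atria basal) with
per-seed jitter, myocardial wall bands of class-dependent thickness drawn
per image (normal 8 ± 1 px, HTN 14 ± 1.5 px), and multiplicative speckle
formed as the magnitude of a Gaussian-smoothed complex Gaussian field —
the fully-developed-speckle model, giving exactly Rayleigh marginals
(verified by KS distance < 0.05 on > 10⁴ wall pixels). The speckle
correlation length is also class-dependent (2 px vs 3 px) so texture-only
features carry class signal. Images are normalized by their maximum,
preserving the Rayleigh shape up to scale, and an optional white text block
is stamped in the top-left corner with its ground-truth mask and an
overlay-free twin retained.

Not modelled: beamforming, attenuation, shadowing, anatomical variability
beyond the parameterized layout, cine loops. Passing the end-to-end tests
therefore shows that the pipeline recovers a geometric + textural class
contrast of realistic magnitude under Rayleigh speckle — not that it
attains any particular accuracy on clinical images.

With the class effect removed (`null_effect_config`), the same pipeline
scores at chance, and with permuted labels the leakage-free protocol stays
within chance ± a few points over 20 permutations — the discrimination is
not an artifact of the protocol.

## Problem sizes and numerical conventions

The default experiment uses the full 51 + 61 dataset at 512×512; the test
suite runs it once and shares it across tests (about three minutes
end-to-end). Tolerances: partition-of-unity and tight-frame identities hold
to ~1e−15 and are tested at 1e−6; Parseval at 1e−9; LSDA primal/dual
agreement at 1e−8. All FFT filtering uses periodic boundaries; all
randomness flows through explicit integer seeds (per-record seeds derived
from a master `SeedSequence`); repeated runs are bit-identical.

## Known limitations

* The mask heuristic presumes the sector is the dominant bright structure;
  frames whose annotations merge with the sector are cleaned only by the
  outside-sector rule.
* The contourlet/shearlet/EWT systems are frequency-domain constructions
  chosen for exact invertibility and stable feature ordering; they are one
  consistent realization of the printed feature counts, not a claim about
  any particular legacy implementation.
* With `paper_mode` (whole-dataset reduction) the cross-validated accuracies
  are optimistically biased; it exists for comparability only.
* DICOM input is limited to single-frame secondary captures.
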