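# Methods

## Problem and pipeline

Glioblastoma presents on structural MRI as a composite lesion: a necrotic
core, a contrast-enhancing rim (bright on post-contrast T1w but not on
pre-contrast T1w), solid non-enhancing tumor, and a peritumoral edema halo
(edema and necrosis hyperintense on T2w/FLAIR). The package segments these
four compartments plus unaffected tissue from the four co-acquired
channels, then derives the clinically used quantities: compound-region
volumes (CETV = {enhancing}, TV = {necrosis, non-enhancing, enhancing},
TV+ = TV ∪ {edema}; CETV ⊂ TV ⊂ TV+ by construction), bidimensional
RANO/WHO diameters and SPD, and agreement statistics against a reference
segmentation.

The pipeline is: preprocessing → per-voxel features → decision-forest
posteriors → CRF regularization → measurement. All grids are (x, y, z)
arrays with z inferior→superior, so axial slices are fixed-z planes; voxel
indices are 0-based and physical position = index × spacing. This
orientation convention is the package's own choice (RANO measurements are
axial, so the axial axis must be pinned).

## Preprocessing

- **Reference grid**: the post-contrast T1w channel, because enhancement —
  hence CETV and the RANO diameters — is read on it. The other three
  channels are rigidly resampled onto it.
- **Rigid registration**: 6-DOF (intrinsic xyz Euler angles + translation,
  rotation center at the volume's physical center). The similarity
  objective is normalized cross-correlation over the voxels where the
  resampled moving image lies inside its field of view, which makes the
  estimate exactly invariant to positive affine intensity rescaling of
  either image. Optimization is Powell from two starts — identity, and the
  translation proposed by phase cross-correlation when the grids are
  commensurate — on a stride-2 subsampled grid for speed; the best final
  objective wins. The enforced contract (tested) is recovery of known
  translations within 0.5 voxel per axis and ≥ 90 % MSE reduction; NCC was
  chosen over a mutual-information objective because the phantom channels
  that exercise the code are mono-contrast per comparison.
- **Skull stripping**: Otsu threshold on T1w, morphological closing
  (ball radius 2 voxels), hole filling, largest 26-connected component.
  This is a deliberately simple, fully specified procedure that assumes a
  dark exterior; it is validated against the phantom's analytic brain
  ellipsoid (≥ 95 % coverage, ≤ 1 voxel dilation), not against clinical
  skull anatomy.
- **Normalization**: per-channel z-score inside the brain mask, zeros
  outside. This removes scanner scale so the classifier and the fixed
  phantom intensity table transfer across noise/bias settings; a constant
  channel is an error, not silently passed through.

## Features (72 by default)

Per in-mask voxel: (a) the 4 channel intensities; (b) per modality ×
patch radius ∈ {1, 2} voxels, first-order statistics {mean, variance,
skewness, kurtosis, energy, entropy} with windows clipped to the mask
(statistics over the available in-mask voxels); (c) per modality,
central-difference gradient magnitude (scaled by spacing) and its patch
mean; (d) per modality × scale ∈ {2, 4} mm, |I(v) − I(mirror v)| after
Gaussian smoothing at that scale, mirrored across the mid-sagittal plane;
(e) location: coordinates normalized to the brain bounding box and
distance (mm) to the brain centroid.

Numerical choices: energy is the patch mean of squared intensities;
entropy uses a fixed 32-bin histogram over the channel's in-mask range
(bounded by log₂ 32; entropy of a constant patch defined as 0); a
cancellation floor (var < 1e-12·(1+E[I²]) ⇒ 0) keeps variance, skewness
and kurtosis exactly zero on constant patches. The mid-sagittal plane is
the sagittal plane through the mask centroid — a documented simplification
appropriate for centered heads/phantoms, not a reflection-symmetry
optimization. Channels are masked before any filtering, so no feature
depends on intensities outside the brain mask (this is a tested
invariant). Feature ordering is deterministic, and the classifier refuses
feature matrices whose name registry does not match training.

## Classifier and CRF

The forest is a scikit-learn RandomForestClassifier: 50 trees, max depth
20, min leaf 5, √d features per split, mandatory seed; the out-of-bag
accuracy is reported as the training estimate. Training voxels are capped
per class per subject (default 2000, seeded subsampling) — full-volume
training adds cost without accuracy on these phantoms. Posteriors are the
mean of tree votes, embedded into the full 5-class simplex (rows sum to 1).

Regularization minimizes the contrast-sensitive Potts energy (unary
−log(p+ε), ε = 1e-9; pairwise λ·exp(−‖ΔI‖²/2σ²) on unequal neighbor
labels, ‖ΔI‖ the 4-channel Euclidean distance in z-score units) by
iterated conditional modes: fixed raster sweep order, initialization at
the per-voxel argmax, ties broken toward the lowest class code, stop at a
fixpoint or `max_sweeps`. ICM is deterministic and monotone, and on tiny
grids its energies are verified against exhaustive enumeration; global
optimality (graph cuts) is deliberately out of scope. Defaults λ = 1,
σ = 1, 6-neighborhood: with z-scored channels, σ = 1 puts the pairwise
weight near 1 inside homogeneous compartments and near 0 across strong
edges. The CRF regularizes labels only; posteriors are not re-estimated.

## RANO bidimensional measurement

Lesions are 3D 26-connected components of the measured compartment
(default: enhancing only; an enhancing+necrosis mode exists because both
readings of "contrast-enhancing lesion" occur in practice). Per axial
slice, d1 is the maximum pairwise distance between in-plane voxel centers;
d2 the maximum over pairs within ±5° of perpendicular to the d1 segment
(tolerance configurable); the reported slice maximizes d1 (ties → lowest
z; a max-product rule is available). Diameters are voxel-center to
voxel-center, so a single-voxel slice has d1 = 0 — unambiguous and
oracle-checkable. Lesions with maximal axial diameter < 10 mm (default)
are flagged non-measurable and excluded from SPD. Slices with more than
1500 lesion pixels restrict the pair search to boundary pixels; all tested
sizes use the exact all-pairs path.

## Agreement metrics and statistics

Dice, PPV and sensitivity are computed with integer counts before the
final division. Conventions: Dice(∅, ∅) = 1 and 0 when exactly one mask is
empty (phantoms may lack a compartment); undefined PPV/sensitivity are NaN
("missing"), never 0; relative volume error is signed with positive =
oversegmentation. Wilcoxon signed rank drops zero differences and uses the
exact sign-flip null (2ⁿ enumeration, midranks for ties) for n ≤ 12, else
the tie-corrected normal approximation; two-sided p = min(1, 2·min tail).
Spearman ρ is Pearson on midranks with an exact permutation p (all n!
orderings) for n ≤ 8, else the t approximation. Friedman and
Kruskal–Wallis use scipy's tie-corrected chi-square statistics, with the
fully-tied Friedman case defined as statistic 0, p = 1. Cohen's κ is
evaluated on the union of both tumor extents dilated by 1 voxel —
whole-brain κ would be dominated by background agreement, and the support
choice is therefore explicit and configurable.

## Synthetic phantoms

A phantom is an ellipsoidal brain (semi-axes 0.42 × grid size) in a dark
exterior, with one tumor of four nested concentric spheres (default radii
4 / 7 / 9 / 12 mm for core/rim/margin/halo, tumor center offset a few
voxels from the brain center). The intensity table encodes only ordinal
contrasts, in arbitrary units with brain tissue at 100: enhancing 185 on
T1wGd (bright) vs ~90 elsewhere; necrosis 55 on T1w/T1wGd (no enhancement)
and 160–165 on T2w/FLAIR; edema 150/175 on T2w/FLAIR; non-enhancing
intermediate (128–130); exterior 10. Absolute values are meaningless by
design — normalization must remove them. Degradations: additive zero-mean
Gaussian noise (default SD 10, i.e. 10 % of the brain mean — a moderate
clinical-range SNR) and an optional multiplicative bias field
1 + a·P(u), P a seeded quadratic polynomial in [−1, 1]³ coordinates scaled
to max |P| = 1. Cohorts jitter radii (±1 mm), tumor center (±2 voxels) and
class means (±5 units) uniformly, each phantom with its own derived noise
seed; zero-width jitter reproduces the template exactly.

What the phantom does **not** emulate: real brain anatomy and tissue
heterogeneity, infiltrative (non-spherical, disconnected) tumor growth,
partial-volume mixing, Rician noise statistics, skull/scalp signal, and
cross-channel misregistration beyond what the registration tests inject.
Consequently, near-perfect phantom recovery demonstrates that the
implementation is correct and self-consistent — not that clinical accuracy
would match; the separations in the intensity table make the voxel
classification problem much easier than clinical glioblastoma.

## Experiment and problem sizes

The standard validation run trains on 12 phantoms and segments 6 held-out
phantoms at 48³ voxels, 1 mm isotropic, noise SD 10 — sizes chosen so the
whole experiment, including forest training, runs in about a minute on one
CPU while every stage still operates on genuinely 3D multi-compartment
data. Reported aggregates are median/mean/SD of Dice per compound region
plus median absolute and relative volume errors, mirroring how multi-region
segmentation studies tabulate results. Determinism: every stage derives
its seed from the global seed and the stage name (CRC32 mixing), so a run
is a pure function of its configuration.

## Known limitations

- ICM finds local energy minima only; with large λ it can lag behind
  graph-cut solutions.
- The mid-sagittal plane estimate assumes roughly centered, unrotated
  heads.
- Skull stripping presumes a dark exterior (as after defacing/phantoms);
  it is not a clinical brain extractor.
- The exact-permutation statistics are O(2ⁿ)/O(n!) and intentionally
  capped at n = 12 / n = 8.
- DICOM ingestion, deformable registration, longitudinal RANO response
  categories and GPU inference are out of scope.
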