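# Methods

## Problem and approach

Quantifying amyloid burden from brain PET requires carrying each scan
into a standard template space so that predefined volumes of interest
(VOIs) apply, or segmenting each subject's anatomy individually. Both
conventional routes need a structural MRI of the same subject. `petnorm`
implements an MRI-less route: a cascade of small 3-D encoder–decoder
networks predicts a dense displacement field directly from an
affine-registered PET volume. MRI is used only *during training*, inside
the loss — the trained model normalizes PET alone.

The pipeline is, in order:

1. **Affine registration** of the individual PET to the template grid
   (12 parameters, global normalized cross-correlation, multiresolution
   Nelder–Mead simplex, centroid initialization). The registration target
   is an *average amyloid PET template* (mean of the positive and
   negative uptake patterns), not the T1 template: a same-modality target
   is essential because an amyloid-positive cortex is bright where T1
   gray matter is dark, and registering positive scans to T1 contrast
   produces a systematic, status-dependent scale and translation bias.
2. **Cascade prediction**: stage 1 maps the affine-registered PET to a
   displacement field; each further stage sees the PET warped by the
   accumulated field concatenated with the original PET and predicts a
   refinement, merged by field composition
   `w(x) = u_new(x) + u_acc(x + u_new(x))`.
3. **Pull-warp** of the PET by the composed field onto the template.
4. **Quantification**: mean uptake over six composite VOIs (global
   cerebral cortex, frontal, posterior cingulate–precuneus, lateral
   parietal, lateral temporal, medial temporal) divided by mean
   cerebellar gray-matter uptake gives SUVR; global SUVR > 1.5 classifies
   a scan amyloid-positive (a tie is negative).
5. **Agreement statistics** between two SUVR methods: per-region OLS
   (slope, intercept, R²), ICC(3,1) (two-way mixed, single measure,
   consistency — invariant to a fixed between-method offset), and
   Bland–Altman bias with 1.96·SD limits of agreement.

## Conventions

* All fields are *pull* displacements in voxel units on 0-based indices:
  a warped image reads its source at `x + u(x)`. Samples outside the
  source grid read 0 (PET background is air); interpolation extends into
  that zero padding (`grid-constant` semantics), which keeps the warp a
  linear operator in the image.
* Labels are warped by nearest neighbour only; label identity is never
  averaged.
* The world affine is carried through NIfTI I/O but all computation is
  voxel-space on a common grid; displacement fields are stored as 4-D
  NIfTI with the vector component last.
* Whether fields live in voxel or mm units was an open choice; voxel
  units were chosen so network outputs are grid-scale-free.

## Training objective

For a predicted field `u` applied to the co-registered MR `M` and GM
segment `G` of a training subject:

```
L = NCC_w(warp(M, u), T_mr) + β · Dice_s(warp(G, u), T_gm) + λ · R(u)
```

* **Windowed NCC** (window `w = 9` voxels, odd, clipped to the grid):
  signed local correlation from sliding box sums, averaged over voxels
  whose full window fits inside the grid; loss = 1 − mean correlation,
  range [0, 2]. Local variances are floored at `ε = 1e−5`, so locally
  constant patches contribute correlation 0 (loss 1) rather than noise.
  Inside the training objective three refinements are applied, each a
  standard registration practice and each exposed in `CascadeConfig`:
  * the mean is restricted to windows overlapping the template head —
    background air has undefined, field-independent correlation and
    would otherwise dilute the similarity and its gradient;
  * both images are pre-smoothed (σ = 1 voxel) before the similarity.
    The moving image is blurred by resampling while the template is
    not; without equalizing blur a dense field can lower the loss by
    "deconvolving" that blur instead of recovering correspondence (we
    observed exactly this failure: near-perfect correlation with fields
    far from the truth);
  * a half-resolution similarity term (window 5) is averaged in, giving
    larger capture range and better-conditioned gradients early in
    training.
* **Soft Dice** with smoothing 1 on probabilistic GM in [0, 1];
  differentiable and defined for empty masks. Note that soft Dice of a
  probabilistic map against itself is not 0; the term still attains its
  minimum at alignment.
* **Smoothness** `R(u)`: *mean* squared forward-difference gradient over
  all components and axes. Dense-field training folds without it.
  λ = 1 by default: because the term is a mean (not a sum over voxels),
  order-one weights are the natural scale; much smaller values leave
  visible folding, much larger ones bias the field toward zero.
* β = 1 by default; both weights are calibration choices for fold-free
  recovery on phantoms, not fixed by the method.

The final convolution of every stage is zero-initialized, so an
untrained cascade predicts the zero field exactly and the whole pipeline
degenerates to the affine resampling — a property the tests pin down
bit-exactly.

## Architecture and optimization

Each stage is a U-net-style encoder–decoder with `levels = 3` resolution
levels and `base_channels = 6` at the first level (doubled per level),
3×3×3 convolutions with leaky-ReLU (slope 0.2), 2× average pooling down
and nearest-neighbour upsampling with skip concatenation up. The first
convolution always runs at full resolution, so fine image structure is
encoded into features before any pooling; with the default
`field_resolution = 2` the decoder stops at half resolution and the
3-channel field is upsampled trilinearly to the full grid (the target
deformations are smooth, so a half-resolution field loses little
accuracy while cutting convolution cost several-fold). Two stages by
default; stage inputs are PET alone (stage 1) and warped-PET ⊕ PET
(later stages); gradients flow through the field composition into all
stages jointly.

The network and its training loop are implemented directly over numpy
with a small reverse-mode differentiation tape (`petnorm._autodiff`)
providing exactly the operators the model needs (convolution, pooling,
trilinear grid sampling differentiable in both source and coordinates,
sliding box sums, forward differences). Every operator's gradient is
verified against central finite differences in the test suite, including
the fully assembled objective differentiated through the warp.

Optimization is Adam (base learning rate 4·10⁻³, batch size 1, 30
epochs) with global-norm gradient clipping (1.0), a short linear warmup
followed by cosine decay, and a 2× learning-rate multiplier on the
field-producing layers (which start at zero and otherwise ramp slowly).
The parameter state of the best epoch-mean loss is kept. On-the-fly
augmentation draws, per sample and epoch, a small affine (±3°, ±1.5
voxels, ±3% scale), an elastic perturbation (Gaussian-smoothed noise,
σ = 4 voxels, amplitude up to 1.5 voxels) applied identically to
PET/MR/GM, and a ±10% intensity scale on PET only.

Problem sizes were chosen for single-CPU work: 48³ grids, 20 training
subjects, 30 epochs train in roughly ten minutes; the architecture
defaults above are sized to that budget.

## Synthetic phantom model

`petnorm.phantom` generates the study conditions: a procedural brain
template (ellipsoidal cortex shell, WM interior, paired CSF ventricles,
two subcortical nuclei, inferior cerebellar blobs) with T1-like mean
intensities (CSF 0.2 < GM 0.6 < WM 1.0), and individual subjects derived
from it by a known ground-truth mapping

```
g(x) = M (x + u_vent ∘ u_rand (x)) + t
```

composed of a ventricular radial expansion (factor `ventricle_scale`,
cosine-tapered — the hydrocephalus-like stress case that defeats
template registration with limited deformation models), a smooth random
field (Gaussian-smoothed white noise, σ = 4 voxels, rescaled to a
maximum magnitude `deform_amplitude`, redrawn until fold-free), and a
random small pose (default ±5°, ±2 voxels, ±5% scale). Every
individual-space volume is pulled from template space through `g` in a
single interpolation pass.

The template carries a deterministic multi-scale multiplicative
intensity texture (12% rms at σ = 1.5 voxels plus 5% at σ = 5), shared
by the MR and PET constructions. This is not cosmetic: real images have
dense anatomical structure everywhere, and without it the ground-truth
deformation is fundamentally unidentifiable from the data — only tissue
boundaries would constrain the loss, and boundary matching cannot
observe motion tangential to the boundary.

PET uptake per tissue is piecewise constant before texturing and
warping: CSF 0.1, WM 1.0, cerebellar GM 0.6, and cortical GM 0.6
(negative) or 1.3 (positive; subcortical GM 0.9). The ratios put a
noise-free positive phantom's global cortical SUVR at 1.3/0.6 ≈ 2.167
and a negative one at 1.0 — both far from the 1.5 threshold, making
classification checks unambiguous. (`pet_from_labels` builds the exact
untextured construction whose SUVR is analytic; the textured template
PET used for subjects multiplies it by `1 + texture`.) Optional
spherical lesions are punched out at CSF intensity (rejected if they
leave the brain); Gaussian noise (fraction of cortical uptake) is added
last and clipped at 0.

Default study conditions: 48³ grids, 20 training subjects, deformation
amplitude 3 voxels, ventricle scale uniform in [1.0, 1.6], noise 5% of
cortical uptake, half positive.

What the phantom does **not** emulate: scanner physics (PSF, scatter,
reconstruction noise texture), partial-volume effects, inter-subject
anatomical topology differences, multi-tracer kinetics, or true
PET–MR intensity relationships (phantom PET and MR share one texture
and are positively correlated by construction, which is why a
single-modality global-NCC affine stage suffices here; real
PET-to-template registration would need a tracer-specific template or a
multimodal metric). Passing tests therefore demonstrate that the
method's machinery — losses, geometry, training dynamics,
quantification — behaves correctly, not that trained weights transfer
to clinical scans.

## Evaluation design

`run_phantom_study` mirrors a two-arm validation: the *network arm*
(affine + predicted field + warp, PET only, no access to ground truth)
against a *reference arm* that evaluates the composite atlas in each
subject's individual space through the phantom's exact generation
mapping — the stand-in for individual-space MRI parcellation, which is
exact here. Per-region agreement (slope, intercept, R², ICC, bias, 95%
limits) is tabulated with the reference arm as x. The held-out cohort
can be generated noise-free (`test_noise_sd = 0`) so that deformation
recovery is measured against clean ground truth.

Diagnostics computed on held-out subjects:

* **GM Dice**: the subject's GM segment carried to template space by the
  estimated transform (affine-only vs. with field), thresholded at 0.5,
  against the template GM mask.
* **Endpoint error**: mean distance, over template brain voxels, between
  the estimated template→individual map `x ↦ M_reg(x + u(x)) + t_reg`
  and the numerical inverse of `g` (fixed-point inversion of the
  displacement field). Reported as a ratio to the zero-field
  (affine-only) error; below 1 means the network recovers deformation
  beyond the affine.
* **Fold fraction**: share of interior voxels with non-positive Jacobian
  determinant of the predicted map (central differences, one-sided at
  boundaries).

A caveat worth stating plainly: after the 12-parameter affine stage the
remaining true deformation on these phantoms averages about one voxel,
and direct per-image optimization of the training objective (a bound on
what any predictor of this objective can achieve) converges to roughly
half of that residual — sub-voxel correspondence beyond that point is
only weakly identifiable from the images. The amortized network, trained
for 600 gradient updates (20 subjects × 30 epochs, batch 1), recovers a
more modest fraction on held-out subjects; registration networks of this
family typically need orders of magnitude more updates to approach the
per-image bound. The study report exposes all three numbers (zero-field
error, network error, their ratio) so this gap is visible rather than
hidden.

The atlas used on phantoms is geometric: the cortical shell is
partitioned exhaustively into four lobar sectors by nearest-anchor
assignment in normalized (|x|, y, z) direction space (lateral composites
are bilateral, hence |x|), subcortical nuclei stand in for the medial
temporal composite, cerebellar GM is the reference, and the global
composite is the union of the cortical sectors. The label→composite
grouping ships as editable JSON.

## Numerical choices and degenerate inputs

* Zero fields and exact identity affines short-circuit to bit-exact
  copies; the identity guarantee does not depend on interpolator
  rounding.
* NCC variance floor 1e−5; Dice smoothing 1; window means over
  valid-window voxels only.
* Affine similarity is global (unwindowed) NCC — smooth and
  basin-friendly for linear alignment; windowed NCC is deliberately
  reserved for the deformable stage. If simplex refinement ever scores
  below the centroid initialization, the initialization is returned and
  the result marked unconverged.
* Ties at the 1.5 positivity threshold classify negative.
* Regional means are unweighted voxel means.
* Constant volumes are rejected where a statistic would be undefined
  (registration similarity, regression x-variance, all-identical ICC).
* Fixed-point field inversion assumes non-folding fields (guaranteed by
  the phantom's resampling rule) and runs 20 iterations.
* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; identically-seeded runs are byte-identical,
  including written NIfTI and CSV outputs (uncompressed `.nii` is used
  by the study driver so file bytes are reproducible).

## Known limitations

* The affine stage is single-modality NCC against an average-uptake PET
  template; multimodal (e.g. mutual-information) registration is not
  implemented. The stage is declared replaceable behind
  `register_affine`.
* Training at desk scale (tens of subjects, tens of epochs, 48³ grids)
  demonstrates that the objective drives fold-free alignment and
  improves gray-matter overlap on held-out subjects; it does not reach
  the per-image identifiability bound on deformation recovery (see the
  caveat above), and clinical-scale accuracy claims would require real
  multicenter cohorts.
* The ICC variant is fixed to consistency ICC(3,1) (the choice matching
  a "consistency of quantification" question); absolute-agreement
  variants are not exposed.
* Diffeomorphic (velocity-field) parameterizations and B-spline
  transforms are out of scope; fold-freedom is encouraged by the
  smoothness penalty and monitored, not guaranteed.
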