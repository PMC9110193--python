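# Methods

## The model

Dynamic CT perfusion tracks an iodine bolus through brain tissue. For a
voxel with time–density curve `TDC(t)` (HU above baseline) and an arterial
input function `AIF(t)` measured in a feeding artery, the indicator-dilution
model is

    TDC(t) = (AIF ⊛ k)(t),        k(t) = F · R(t)

where `R(t)` is the residue function (fraction of tracer still in the voxel
`t` seconds after an idealised instantaneous arterial bolus, `R(0) = 1`,
non-increasing) and `F` is perfusion. We store `k` as a tissue fraction per
second; the clinical maps follow as

    CBF = 6000 · max_t k(t)      [mL/100 g/min]
    CBV = 100 · dt · Σ_t k(t)    [mL/100 g]
    MTT = 60 · CBV / CBF         [s]      (central volume theorem)
    TTP = dt · (argmax_t TDC − t₀)  [s]

The constants 6000 and 100 assume tissue density 1 g/mL; an absolute
calibration (density 1.04 g/mL, hematocrit correction) can be supplied
through `ConversionConstants`. Maps are relative by default because no
calibration data accompany a phantom.

Discretisation uses the rectangle rule on a uniform grid (`dt` seconds per
frame): the convolution becomes multiplication by a circulant matrix `N`
built from the dt-scaled AIF samples, zero-padded by a factor of 2 so the
circulant (cyclic) convolution reproduces the causal linear convolution
without wrap-around — the standard block-circulant, delay-insensitive
formulation. Non-uniform sampling is rejected rather than resampled.

## Inverse solvers

**bSVD.** The baseline inverts the padded circulant operator through its
SVD, zeroing singular values below `truncation_fraction · σ_max`
(default 0.15, the common literature choice; 0 gives the exact inverse).
Truncation controls noise amplification at the cost of a systematic
amplitude underestimation — sharp residue onsets live in the discarded
components — which is the visual "noise artifact vs over-smoothing"
trade-off the plug-and-play solver is designed to improve on.

**ADMM / plug-and-play.** The regularised problem
`min_U ‖NU − D‖²/2 + α·E(U)` is split into a fidelity update (U), a
regularisation/denoising update (Z) and a scaled multiplier (λ). The
classical step uses the explicit regulariser gradient; the plug-and-play
step replaces it with a denoiser residual `Res(Z)` and merges the step
size and penalty into a single per-iteration parameter `χ̃ = b_su·χ`:

    U ← (1 − χ̃ₙ) U + χ̃ₙ (Z − λ) − b̃ₛᵤ,ₙ Nᵀ(NU − D)
    Z ← (1 − χ̃ₙ) Z + χ̃ₙ (U + λ) − α̃ · Res(Z)
    λ ← λ + κₙ (U − Z)

All per-iteration parameters are schedules of length `n_iter` (default 12
unrolled steps), so they can be tuned or learned per stage; defaults are
constant: `χ̃ = 0.25`, `κ = 0.5`, `α̃ = 1`, and `b̃ₛᵤ = 0.9/σ_max²`
(`ADMMConfig.for_operator`), the largest step that keeps the explicit
fidelity gradient stable for every singular component. `b_su` and `b_sz`
are exposed as independent parameters with equal defaults.

Design choices the update equations leave open:

- **Warm start.** U and Z are initialised from the truncated bSVD
  solution. Twelve explicit gradient-form iterations from a zero start
  cannot reach data consistency (components with σᵢ ≪ σ_max converge at
  rate `b̃σᵢ²` per step); refining the baseline solution makes the
  unrolled scheme a denoising/consistency trade-off, which is how
  unrolled perfusion networks are normally run.
- **Output.** The solver returns the denoised iterate Z (U and Z agree at
  convergence; the `gap_norms` diagnostic logs ‖U − Z‖ per iteration).
- **Unobserved tail.** The padded data vector keeps zeros beyond the
  acquired frames, the same convention bSVD uses.

**Denoisers.** `Res(Z)` operates on 2D spatial frames of the residue at
each time index (batched over slices and frames):

- `tv`: Chambolle total variation per frame. With no explicit weight the
  weight adapts per call to `1.5 ×` the wavelet-estimated noise sd of the
  frame stack, so smoothing tracks the iterate's actual noise level.
- `gaussian`: fixed-σ Gaussian smoothing (reference/simplest prior).
- `residual_cnn`: a compact numpy residual network — 3×3 convolutions,
  15 filters, 7 residual blocks (conv–ReLU–conv with skip), a 1-channel
  head and tail — predicting the noise residual DnCNN-style. The tail
  convolution is zero-initialised so the untrained network is the
  identity denoiser; with a randomly initialised tail the 12-step
  unrolled loop visibly diverges. Frames are standardised by a single
  global scale stored with the weights. Training: Adam (lr 1e-3, batch
  16) on the MSE of `(noisy − predicted residual)` against clean patches;
  the published table value "initial learning rate 4500" is recorded in
  `DenoiserSpec.published_initial_learning_rate` for provenance but is
  not usable as a gradient step. Training pairs come from the phantom:
  clean ground-truth residue frames against either additive-noise
  corruptions or truncated-bSVD reconstructions of the noisy series (the
  noise actually seen inside the solver; the default). Weights serialise
  to one JSON file with an architecture header. A `residual_cnn` request
  without weights falls back to TV with a warning.

## The digital phantom

A mirror-symmetric elliptical brain (grey-matter ring, white-matter
interior, air outside) of 64×64×4 voxels at 2×2×5 mm, 40 frames at
dt = 1 s. An ischemic lesion — concentric discs, core radius 6 voxels
inside penumbra radius 12, cylindrical through the slices — sits in one
hemisphere. Tissue classes (literature-standard values):

| class        | CBF (mL/100 g/min) | MTT (s) | arrival delay (s) |
|--------------|-----|----|---|
| gray matter  | 60  | 4  | 0 |
| white matter | 25  | 5  | 0 |
| penumbra     | 20  | 10 | 3 |
| core         | 8   | 14 | 5 |

Residues are exponential, `R(t) = exp(−t/MTT)`, shifted by the arrival
delay: ischemic tissue fills late through collaterals, and without the
delay the TTP prolongation of the lesion (~2 s from MTT alone) would sit
below the 4 s hypoperfusion threshold the segmentation uses. The AIF is a
peak-normalised gamma variate (arrival 5 s, α = 3, β = 1.5 s, peak
300 HU — a first-pass bolus of realistic height and width). Curves get a
flat 40 HU baseline and additive Gaussian noise (default σ = 5 HU,
emulating low-dose acquisition; tissue peak enhancements are ~2–9 HU, so
this is a deliberately harsh regime).

**Grid-consistent ground truth.** The exported truth maps are the values a
perfect deconvolution on this grid would recover: CBF equals the class CBF
exactly (since `R(0) = 1`), CBV is the rectangle-rule sum of the sampled
residue, and MTT = 60·CBV/CBF, so the central volume identity is exact by
construction. (The rectangle rule overestimates the continuous integral of
an exponential by ≈ dt/2 s of MTT; defining truth on the grid keeps
recovery tests about the solver, not about quadrature conventions.) The
class MTT in the table is the generative parameter of the exponential.

What the phantom does **not** emulate: photon/sinogram (Poisson) noise,
motion, beam hardening, partial-volume mixing, anatomical texture,
patient-specific AIF shapes, or bolus dispersion. Tests passing on it show
correctness of the algorithms under the stated model, not clinical
performance.

## Lesion analysis

The contralateral hemisphere is the healthy reference ("mirror
technique"): a mask is reflected across the midline plane (default: the
geometric volume centre; reflection index `round(2m − x)`), and per-voxel
references are the median TTP and CBF of contralateral brain tissue.
Hypoperfusion is a TTP delay > 4 s; core additionally requires
CBF < 0.3 × the contralateral median; penumbra is hypoperfused minus
core — common clinical threshold conventions. ROI tables report mean ± sd
of all four parameters and volumes in mL (voxel count × voxel volume).

## Metrics

PSNR and NMSE wrap scikit-image (`10·log₁₀(range²/MSE)`, flagged infinite
on identical inputs; `‖t − r‖²/‖r‖²`). FSIM is implemented from its
published formulation: phase congruency from a 4-scale × 4-orientation
log-Gabor bank (min wavelength 6, multiplier 2, σ_onf 0.55) with the
median-based noise-energy threshold, Scharr gradient magnitudes, and the
similarity product weighted by pointwise maximum phase congruency, with
T1 = 0.85 and T2 = 160 on a 0–255 scale; inputs are rescaled to that
range from `data_range`. Images below 16×16 are rejected; featureless
(constant) pairs fall back to the unweighted similarity mean. The test
suite cross-checks against an independent transcription of the published
reference algorithm.

For 3D maps, metrics are computed per axial slice and averaged;
`data_range` defaults to the ground-truth max − min per map. The
comparison harness replicates the phantom over noise seeds (derived
deterministically from one master seed), zero-fills undefined MTT voxels,
and reports mean ± sd per method × map × metric, flagging failed methods
without aborting the run.

## Numerical conventions and degenerate inputs

- `argmax` ties take the first index (numpy convention) for CBF and TTP.
- CBF = 0 voxels get MTT = NaN plus a validity flag, never an exception.
- Baseline estimation averages the first 4 frames by default.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); solvers are deterministic, bitwise
  reproducible single-threaded.
- Problem sizes used by the test-suite and the acceptance script — the
  default 64×64×4×40 phantom, 10 noise replicates for method comparison,
  200 patches × 20 epochs for denoiser training — are the package's
  desk-scale defaults; all scale up through `PhantomSpec` and function
  arguments.

## Known limitations

- On a finite acquisition window the *exact* (zero-truncation) circulant
  inverse is reliable only for residues whose convolution tail dies inside
  the window; delayed, long-MTT lesion curves violate this and their exact
  inverse is badly inflated by the forced-zero data tail. Practical
  reconstructions (truncation > 0, the PnP solvers) do not suffer from
  this, which is why lesion segmentation operates on the
  default-truncation reconstruction.
- Truncated-SVD-style recovery underestimates CBF amplitude in a
  shape-dependent way (sharper residues lose more), which narrows the
  recovered contrast between classes of similar CBF. At the default 5 HU
  noise the per-voxel matched-filter discriminability between adjacent
  tissue classes is only d′ ≈ 1.1–1.7, so voxelwise class separation is
  information-limited: no per-voxel decision rule can exceed roughly
  70–80% accuracy for the closest class pairs without spatial pooling,
  and the spatially regularised solvers recover the class rank in the
  mean but not for ≳95% of individual voxels.
- The bundled residual CNN is trained briefly on CPU-scale data; with the
  default 200-patch/20-epoch budget it stabilises the loss but does not
  outperform the adaptive TV prior. It is the architecture vehicle, not a
  state-of-the-art denoiser.
- FSIM has no installed third-party implementation to compare against;
  the oracle used in tests is an independent transcription of the
  published algorithm.
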