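# ctpdeconv

Deconvolution of dynamic CT-perfusion (CTP) series for acute-stroke
imaging: a block-circulant indicator-dilution forward model, the
truncated-SVD baseline (bSVD), classical ADMM, and an adaptive
plug-and-play unrolled ADMM with pluggable denoisers (adaptive total
variation or a compact trainable residual CNN), plus hemodynamic map
computation (CBF, CBV, MTT, TTP), mirror-ROI core/penumbra analysis, and
a PSNR/NMSE/FSIM evaluation harness. Everything is testable against a
built-in digital brain-perfusion phantom with known ground truth, so the
package is usable end-to-end without patient data.

It is written for medical-imaging researchers who want a transparent,
scriptable CTP reconstruction pipeline — the NIfTI-in/NIfTI-out kind of
tool you drive from a shell or a notebook.

## The model

A tissue voxel's time–density curve is the convolution of the arterial
input function with the voxel's flow-scaled residue function
`k(t) = F·R(t)`:

```
TDC(t) = (AIF ⊛ k)(t)
```

Discretised on a uniform grid, the convolution is multiplication by a
zero-padded block-circulant matrix `N` built from the AIF; deconvolution
recovers `k` per voxel, and the maps follow as CBF = 6000·max k,
CBV = 100·dt·Σk, MTT = 60·CBV/CBF (central volume theorem), and TTP from
the curve peak. The regularised inverse problem

```
min_U ‖N U − D‖²/2 + α·E(U)
```

is solved by ADMM; the plug-and-play variant merges the step size and
penalty into one per-iteration parameter χ̃ and replaces the regulariser
gradient by a denoiser residual:

```
U ← (1 − χ̃ₙ)U + χ̃ₙ(Z − λ) − b̃ₛᵤ,ₙ·Nᵀ(NU − D)
Z ← (1 − χ̃ₙ)Z + χ̃ₙ(U + λ) − α̃·Res(Z)
λ ← λ + κₙ(U − Z)
```

run as a fixed 12-step unrolled scheme warm-started from bSVD. The
learned denoiser is a 7-residual-block, 15-filter, 3×3 CNN predicting the
noise residual of each spatial frame. See `docs/methods.md` for the full
account, parameter defaults, and limitations.

## Worked example

```python
import dataclasses
from ctpdeconv import (PhantomSpec, synthesize_phantom, estimate_baseline,
                       deconvolve, compute_maps, psnr, nmse, fsim)

spec = PhantomSpec()                      # 64x64x4, 40 frames, sigma = 5 HU
series, aif, truth = synthesize_phantom(spec)
sub = estimate_baseline(series)

for method in ("bsvd", "admm_tv"):
    maps = compute_maps(deconvolve(sub, aif, method=method).residue, sub)
    rng = truth.cbf.max() - truth.cbf.min()
    print(method,
          f"PSNR={psnr(truth.cbf[:, :, 0], maps.cbf[:, :, 0], rng):.2f} dB",
          f"NMSE={nmse(truth.cbf[:, :, 0], maps.cbf[:, :, 0]):.3f}",
          f"FSIM={fsim(truth.cbf[:, :, 0], maps.cbf[:, :, 0], rng):.3f}")
```

prints (one axial CBF slice vs ground truth at the default phantom seed;
averaged over 10 noise seeds the package reports PSNR 5.7 → 13.3 dB,
NMSE 0.76 → 0.13, FSIM 0.22 → 0.41 going from bSVD to the plug-and-play
solver):

```
bsvd PSNR=5.69 dB NMSE=0.769 FSIM=0.216
admm_tv PSNR=13.28 dB NMSE=0.134 FSIM=0.418
```

Higher PSNR/FSIM and lower NMSE mean the reconstructed perfusion map is
closer to the true one: the denoising prior suppresses the heavy noise
amplification of the truncated-SVD inverse on low-dose data.

The same pipeline from the shell:

```
ctpdeconv simulate --seed 1 --out phantom/
ctpdeconv deconvolve --series phantom/series.nii.gz --aif phantom/aif.csv \
                     --method admm-tv --out recon/
ctpdeconv report --cbf recon/cbf.nii.gz --cbv recon/cbv.nii.gz \
                 --mtt recon/mtt.nii.gz --ttp recon/ttp.nii.gz --out lesion/
```

`lesion/roi_stats.csv` then holds mean ± sd of CBF/CBV/MTT/TTP for the
segmented infarct core and penumbra and their mirror references, with
volumes in mL. `ctpdeconv train` fits the residual-CNN denoiser on
phantom patch pairs and `ctpdeconv evaluate` produces the method-comparison
metric table.

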