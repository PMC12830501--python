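# gaprc

Tissue-dependent, spatially-variant positron range correction (PRC) for
Gallium-68 PET, with everything needed to study it without patient data:
per-tissue positron-range kernels from Monte Carlo transport, CT-driven
tissue masks, the correction operator embedded in the projection steps of
OSEM reconstruction, a synthetic torso phantom with artificial lesions
inserted in the sinogram domain, and the lesion quantification and paired
statistics used to evaluate the method.

## The problem

⁶⁸Ga emits energetic positrons (endpoint 1.9 MeV) that travel several
millimetres before annihilating — up to ~9 mm in water and ~32 mm in lung —
blurring PET images in a tissue-dependent way. A *tissue-independent* PRC
deconvolves one water kernel everywhere; it overcorrects bone and
undercorrects lung. The *tissue-dependent, spatially-variant* (TDSV)
correction applies a per-tissue kernel through binary CT-derived masks
inside each image update:

```
img_PRC = Σᵢ (img ⊗ Kernelᵢ) ⊙ Maskᵢ ,      i ∈ {lung, water, bone}
```

where `⊗` is 3D convolution, `⊙` the element-wise product, and the masks
come from nearest-neighbour classification of the CT in Hounsfield units
(references: water 3 HU, lung −695 HU, bone 1226 HU). The correction is
applied in both the forward and the backward projection step of ordered
subset expectation maximization (OSEM); reconstruction behaves like a
statsmodels fit: `OSEM(sinogram, system_model, config).fit()` returns an
`OSEMResults` with the image, the Poisson log-likelihood trace and a
`summary()`.

Kernels are generated by condensed-history Monte Carlo: kinetic energies
sampled from the allowed Fermi β⁺ spectrum with Coulomb correction, CSDA
slowing-down in density-scaled water, Gaussian multiple scattering, and
voxelisation of the annihilation displacements on the PET grid
(2.73 × 2.73 × 2.80 mm³) with normalisation to unit sum.

## Worked example

```python
import numpy as np
from gaprc import make_default_kernels, radial_profile

kernels = make_default_kernels(n=200_000, seed=20220901)
for name in ("water", "lung", "bone"):
    k = kernels[name]
    prof = radial_profile(k)
    c = k.weights[k.half_width]
    cdf5 = np.interp(5.0, prof["radius_mm"], prof["cdf"])
    print(f"{name:6s} {k.shape[0]:2d}x{k.shape[1]}x{k.shape[2]}  "
          f"central-voxel fraction {c:5.3f}   within 5 mm {100*cdf5:5.1f}%")
```

prints

```
water   7x7x7  central-voxel fraction 0.296   within 5 mm  90.5%
lung   25x25x25  central-voxel fraction 0.049   within 5 mm  21.8%
bone    5x5x5  central-voxel fraction 0.628   within 5 mm 100.0%
```

The kernel extents follow from the maximum positron range per tissue
(water 8.8 mm, lung 32.3 mm, bone 4.5 mm) divided by the voxel pitch: in
water 30% of annihilations stay in the decay voxel and 90% within 5 mm,
while in lung the distribution is so dispersed that only 5% annihilate in
the decay voxel — which is why a single water kernel cannot correct lung
lesions.

The end-to-end study (phantom → acquisition → lesion insertion → four
reconstruction variants → metrics → statistics) runs with

```bash
gaprc experiment --seed 1 --out runs/demo
```

and writes `measurements.csv` (one row per lesion × reconstruction),
`noise.csv` (half-split SD in liver and lung), `changes.csv` (paired
percentage changes with Wilcoxon/Bonferroni inference), the reconstructed
volumes, and a manifest with every seed and kernel hash. Other subcommands
(`kernels`, `phantom`, `simulate`, `reconstruct`, `evaluate`, `stats`)
expose the individual stages.

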