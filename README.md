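# cestpvc

Partial-volume-corrected quantitative CEST (amide proton transfer) analysis.

APT CEST imaging measures the exchange of amide protons (resonating at
+3.5 ppm from water) with tissue water by saturating at a series of
frequency offsets and recording the water signal loss — the z-spectrum.
In ischemic stroke the APT signal of the ischemic core is reduced, making it
a candidate pH-weighted marker. At clinical resolution, however, many voxels
at tissue boundaries contain a substantial cerebrospinal-fluid (CSF)
fraction; CSF carries no amide pool, so it dilutes the apparent APT effect
and corrupts quantification exactly where stroke lesions border enlarged
ventricles and sulci.

`cestpvc` implements both the standard and the corrected analysis for
researchers working with multi-pool model-based CEST quantification:

* a continuous-wave multi-pool **Bloch-McConnell forward model**
  (`dM/dt = A M + b`, solved exactly by eigendecomposition), plus the
  power-equivalent CW amplitude of pulsed saturation trains;
* the **partial-volume mixture**
  `S_total(w) = (1 - [tissue]) S_CSF(w) + [tissue] S_tissue(w)`,
  where `[tissue]` is the voxel's tissue partial-volume estimate (PVE) from
  an upstream GM+WM segmentation, `S_tissue` is a 4-pool tissue spectrum
  (water, amide, semisolid MT, NOE) and `S_CSF` a 1-pool CSF spectrum whose
  concentration is pinned to the tissue water signal by a ratio
  (default 0.53), itself estimable from unsaturated images;
* voxelwise **MAP fitting** with Gaussian priors on transformed parameters,
  a Laplace posterior, a free per-voxel B0 shift, and the interpretability
  rule that voxels with tissue PVE < 0.5 receive a CSF-only fit and are
  excluded from APT analysis;
* **APTR\*** quantification: `(S_w - S_w+a) / S0` at +3.5 ppm from the
  fitted spectra without and with the amide pool — for the corrected model,
  tissue-compartment spectra only, undiluted by CSF;
* the **robustness statistics** used to compare the two measures:
  coefficient-of-variation repeatability, spatial variability,
  ischemic-core contrast-to-noise ratio, and APTR\* variability across
  CSF-fraction bins;
* a **digital stroke phantom** with known ground truth (tissue/CSF partial
  volume structure, a lesion with 30% amide reduction, a smooth B0 field,
  seeded noise) that exercises the full pipeline.

## Worked example

Fit both models to a mixed tissue/CSF voxel (60% tissue) and quantify:

```python
import numpy as np
from cestpvc import (CompartmentModel, PriorSpec, ZSpectrum,
                     aptr_star, fit_voxel, pvc_spectrum)
from cestpvc.params import default_protocol

protocol = default_protocol()          # 0.55 uT, 2 s, 33 offsets, 3 T
model = CompartmentModel()             # 4-pool tissue + 1-pool CSF, ratio 0.53
priors = PriorSpec()

# synthesize a noiseless boundary voxel: 60% tissue, 40% CSF
voxel = pvc_spectrum(model, pve=0.6, protocol=protocol)
data = ZSpectrum(np.array(protocol.offsets), voxel.signal, 1.0)

fit4 = fit_voxel(data, "four_pool", model, priors, protocol=protocol)
fitp = fit_voxel(data, "pvc", model, priors, protocol=protocol, pve=0.6)

print(f"4-pool APTR* : {aptr_star(fit4, protocol, model):.5f}")
print(f"PVC APTR*    : {aptr_star(fitp, protocol, model):.5f}")
print(f"amide m0 (pvc fit): {fitp.estimates['amide_m0']:.2e}")
```

Output:

```
4-pool APTR* : 0.01011
PVC APTR*    : 0.01465
amide m0 (pvc fit): 6.50e-04
```

The uncorrected 4-pool analysis reports a diluted APT effect (0.01011),
while the corrected fit recovers the true tissue value (0.01465, the same
number a pure-tissue voxel gives) and the exact amide concentration the
spectrum was built with — the dilution-and-correction mechanism in one
voxel.

## Command line

The pipeline runs from a shell on NIfTI volumes plus a plain-text offset
list (one ppm per line, in volume order):

```sh
cestpvc phantom --out phantom/                      # synthetic dataset + truth
cestpvc fit --data phantom/cest.nii.gz --offsets phantom/offsets.txt \
    --protocol phantom/protocol.yaml --pve phantom/tissue_pve.nii.gz \
    --s0 phantom/s0.nii.gz --model pvc --out fits/  # parameter maps
cestpvc quantify --fits fits/ --pve phantom/tissue_pve.nii.gz \
    --out aptr.nii.gz                               # APTR* map + PVE masks
cestpvc stats --aptr aptr.nii.gz --pve phantom/tissue_pve.nii.gz \
    --csf-pve phantom/csf_pve.nii.gz --core phantom/mask_core.nii.gz \
    --contra phantom/mask_contralateral.nii.gz --out stats.csv
cestpvc ratio --s0 phantom/s0.nii.gz --tissue-pve phantom/tissue_pve.nii.gz \
    --csf-pve phantom/csf_pve.nii.gz --out ratio.json
```

Reruns with the same seed reproduce all outputs bit-identically; every
output directory carries a manifest with the configuration hash and seed.

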