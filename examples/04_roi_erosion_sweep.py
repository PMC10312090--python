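"""CSF-distance ROI erosion and the contamination sweep.

Erodes the phantom's tissue ROIs with the two-stage rule (1 mm isotropic,
then >=1 mm in-plane / >=5 mm through-plane from any CSF voxel), then runs
the progressive through-plane sweep on a thin-slice slab phantom whose
cortical rim is contaminated by slice-direction partial volume with CSF:
mean cortical CSFF falls monotonically as the erosion deepens.
"""

import numpy as np
from scipy import ndimage

import cswater as cw
from cswater.relaxometry import WFMaps

labels = cw.build_label_volume(shape=(32, 32, 16), seed=7)
rois = cw.erode_rois(labels, cw.ErosionSpec())
for name, mask in rois.masks.items():
    src = (labels.labels == {"cerebral_wm": 1, "cortex": 2, "deep_gm": 3}[name]).sum()
    print(f"{name:12s}: {src:5d} voxels -> {int(mask.sum()):5d} after erosion")

# slab phantom, 0.8 mm slices so every through-plane level bites
slab = np.zeros((10, 10, 30), dtype=np.int16)
slab[:, :, :4] = 5          # subarachnoid CSF
slab[:, :, 4:] = 2          # cortex
lab = cw.LabelVolume(slab, voxel_size=(1.3, 1.3, 0.8))
dz = ndimage.distance_transform_edt(slab != 5, sampling=(1e9, 1e9, 0.8))
csff = 0.04 + 0.5 * np.exp(-dz / 2.0)            # contaminated rim
maps = WFMaps(mwf=np.full(slab.shape, 0.05), iewf=0.91 - csff + 0.04,
              csff=csff, defined=slab == 2)
print()
print(cw.erosion_sweep(lab, maps).to_string(index=False))
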