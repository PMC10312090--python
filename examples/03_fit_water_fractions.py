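"""Fit the three-pool model and recover water-fraction maps.

Fits a single noiseless white-matter voxel (exact recovery) and then a
small noisy phantom with and without the Laplacian spatial constraint,
printing the mean CSFF error of each — the spatially regularized fit is
markedly less biased at realistic SNR.
"""

import numpy as np

import cswater as cw

TE = np.array(cw.DEFAULT_TE_MS)
truth = cw.default_tissue_truth()

# single noiseless voxel: exact round trip
s = sum(a * np.exp(-TE / t) for a, t in zip(truth.amplitudes[1], truth.t2s[1]))
pools, resid, converged = cw.fit_voxel(s, TE)
print("fitted amplitudes:", np.round(pools.amplitudes, 2))
print("fitted T2s (ms):  ", np.round(pools.t2s, 1))
print("water fractions:  ", np.round(cw.compute_wf(pools), 4), "(truth 0.10/0.85/0.05)")

# uniform noisy phantom: independent vs spatially regularized fits
labels = cw.LabelVolume(np.ones((6, 6, 3), dtype=np.int16), voxel_size=(1.3, 1.3, 5.0))
clean = cw.forward_signal(truth, labels)
nm = cw.NoiseModel(sigma=10.0, n_coils=32)   # first-echo SNR 100
noisy = cw.add_ncchi_noise(clean, nm, seed=0)
corrected = cw.correct_magnitude(noisy, cw.build_correction_table(nm))
mask = np.ones(clean.shape, bool)
for lam in (0.0, 100.0):
    fit = cw.fit_volume(corrected, mask, config=cw.FitConfig(lambda_laplacian=lam))
    bias = np.nanmean(fit.wf.csff[mask]) - 0.05
    print(f"lambda={lam:5.0f}: mean CSFF bias {bias:+.4f} over {mask.sum()} voxels")
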