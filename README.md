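# cswater — multi-compartment T2 relaxometry of brain water

`cswater` maps six-echo T2-prepared brain MRI magnitudes to voxelwise
water-fraction maps of three tissue water pools — myelin water (MWF,
T2 ≈ 5–20 ms), intra/extra-cellular water (IEWF, T2 ≈ 20–200 ms) and
CSF-like water (CSFF, T2 ≈ 200–2000 ms) — and carries the analysis through
to cohort-level ageing statistics. The parenchymal CSF fraction is of
particular interest as a candidate marker of the subvoxel CSF space
(e.g. microscopic perivascular-space dilation) in the ageing brain.

It is written for quantitative-MRI researchers who want a tested,
reproducible implementation of this pipeline: every stage can run on a
built-in digital phantom and synthetic cohort, so the whole chain is
verifiable without scanner data.

## The model

Each voxel's magnitude decay over the T2-prep schedule
TE ∈ {0, 7.5, 17.5, 67.5, 147.5, 307.5} ms is

S(TE) = A_MW·e^(−TE/T2_MW) + A_IEW·e^(−TE/T2_IEW) + A_CSF·e^(−TE/T2_CSF),

fitted per voxel by box-constrained L-BFGS (T2 bounds [5,20], [20,200],
[200,2000] ms; amplitudes ≥ 0) from a deterministic initialization, with
an optional Laplacian spatial smoothness penalty; water fractions are the
amplitude ratios to the total. Around the fit sit:

- **Noise correction** — sum-of-squares coil combination makes magnitudes
  non-central chi distributed; σ is estimated from background air and the
  exact first moment E[M|A] = σ√2·Γ(n+½)/Γ(n)·₁F₁(−½; n; −A²/2σ²) is
  tabulated and inverted per voxel.
- **ROI erosion** — tissue ROIs are eroded 1 mm isotropically and then to
  ≥1 mm in-plane / ≥5 mm through-plane clearance from ventricular and
  subarachnoid CSF to suppress partial-volume contamination.
- **Statistics** — per regional outcome, nested OLS models
  WF = β₀+β₁Age+β₂Sex+β₃Volume (+β·Age²) compared by ANOVA F-test,
  Benjamini–Hochberg FDR over the nine age p-values, Bland–Altman
  repeatability, and Spearman correlation between ventricle volume and
  regional CSFF.

## Worked example

```bash
python examples/05_age_trends_stats.py
```

simulates a 60-subject cohort (ages 20–80) with the default trends and
runs the full nine-outcome analysis:

```
         outcome model    age_p  age_p_fdr
 cerebral_wm:mwf    LM 0.427242   0.549311
cerebral_wm:iewf    LM 0.497093   0.559230
cerebral_wm:csff    LM 0.848476   0.848476
      cortex:mwf    LM 0.410872   0.549311
     cortex:iewf    QM 0.000205   0.000922
     cortex:csff    QM 0.000004   0.000032
     deep_gm:mwf    LM 0.087814   0.197582
    deep_gm:iewf    LM 0.231705   0.417068
    deep_gm:csff    QM 0.022295   0.066885

ventricle volume vs WM CSFF: Spearman rho = 0.45 (p = 0.00027)
V_CSF: cortex 3.3%, WM 3.5%
IEW content 0.90 -> 0.76 g/mL: IEWF -1.6 pp, CSFF +0.8 pp
```

Each row selects the linear (LM) or quadratic (QM) age model for one
(region, water-fraction) outcome; `age_p` is the reported age p-value
(ANOVA p of the Age² term under QM, Wald p of Age under LM) and
`age_p_fdr` its BH-adjusted value. The generated cohort encodes a
U-shaped cortical CSFF trend, and the analysis correctly selects QM for
`cortex:csff` at high significance. The last lines show the volume-
fraction conversions: scaling CSFF by tissue water content gives the CSF
volume fraction (3.3% cortex, 3.5% WM), and reducing intra/extra-cellular
water content from 0.90 to 0.76 g/mL shifts IEWF by −1.6 and CSFF by only
+0.8 percentage points — relative fractions understate absolute water
loss.

The other examples walk the imaging chain: phantom and forward signal
(`01`), noise estimation and bias correction (`02`), water-fraction
fitting with and without the spatial constraint (`03`), ROI erosion and
the CSF-contamination sweep (`04`), and the end-to-end pipeline with
NIfTI/CSV artifacts and a provenance manifest (`06`). The `cswater` CLI
(`simulate`, `correct`, `fit`, `roi`, `stats`, `run`) exposes the same
stages for shell use.

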