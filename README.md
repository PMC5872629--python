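# gfadwi

Diffusion-MRI analysis of motor-area white matter for pre/post
rehabilitation studies, built around the generalized fractional
anisotropy (GFA) of per-direction ADC profiles.

Clinical DTI studies of stroke rehabilitation ask whether white matter
under the motor cortices (Brodmann areas 4 and 6) changes over a course
of treatment, and whether that change tracks motor recovery.  Tensor
fractional anisotropy (FA) is the standard readout, but FA drops
wherever fiber populations cross, which can mask genuine change.  GFA
summarizes the *directional* ADC profile instead and holds up at
crossings.  This package provides the full analysis chain — and, because
clinical DWI datasets of this kind are rarely shared, a synthetic data
module (multi-tensor phantoms and pre/post cohorts with planted effects)
so every stage is testable end to end.

## The quantities

For an acquisition with `n_s` motion-probing-gradient axes and b-value
`b`, the per-axis apparent diffusion coefficient at a voxel is

    Psi(u_i) = -ln(S_i / S0) / b,    i = 1 .. n_s

and GFA is the sample standard deviation of the profile over its root
mean square:

    GFA = std(Psi) / rms(Psi)
        = sqrt( n_s * sum_i (Psi_i - <Psi>)^2 / ((n_s - 1) * sum_i Psi_i^2) )

which lies in [0, 1] for nonnegative profiles (0 = isotropic, 1 = all
diffusion on one axis).  Tensor FA comes from the log-linear
least-squares tensor fit,

    FA = sqrt(1/2) * sqrt((l1-l2)^2 + (l2-l3)^2 + (l3-l1)^2) / sqrt(l1^2+l2^2+l3^2).

Motor outcomes follow the standard stroke-rehabilitation summaries:
Fugl-Meyer assessment (FMA, 0–66) and the Wolf Motor Function Test
(WMFT) over 15 timed tasks, as mean performance rate (60/time, rate 0
beyond the 120 s cap) and log performance time (lpt = ln of the mean
capped time).  Pre/post changes are tested with the Wilcoxon
signed-rank test; associations between changes use Spearman's rho.

## Worked example

```python
import numpy as np
from gfadwi import (
    make_scheme, build_phantom, metric_map, RoiMask, roi_means,
    CohortSpec, simulate_cohort, analyze_cohort,
)

# 21-axis, b = 1000 s/mm^2 phantom with four motor-area ROI blocks
scheme = make_scheme(21, 1000.0)
dwi, truth = build_phantom((16, 16, 4), scheme, sigma=0.0)
fa = metric_map(dwi, "FA", mask=truth.labels > 0)
mask = RoiMask(truth.labels, truth.label_table, truth.affine)
print(roi_means(fa, mask))

# 36-subject pre/post cohort with planted GFA increase and a planted
# negative correlation between lesioned-BA4 GFA change and lpt change
report = analyze_cohort(simulate_cohort(CohortSpec(), seed=1))
row = report.roi_table.set_index("roi").loc["BA4_lesioned"]
print(f"GFA {row.gfa_pre_mean:.3f} -> {row.gfa_post_mean:.3f}, "
      f"p = {row.gfa_p:.4f}, rho(dGFA, dlpt) = {row.rho_gfa_lpt:.3f}")
```

prints

```
               roi      mean  n_voxels
0     BA4_lesioned  0.870388       144
1  BA4_nonlesioned  0.870388       144
2     BA6_lesioned  0.500694       144
3  BA6_nonlesioned  0.870388       144
GFA 0.181 -> 0.186, p = 0.0000, rho(dGFA, dlpt) = -0.238
```

The three single-fiber blocks sit at the closed-form FA of a
(1.7, 0.2, 0.2)·10⁻³ mm²/s tensor, 0.870388; the crossing-fiber block
(lesioned BA6) drops to 0.50 — the fiber-intersection effect that
motivates GFA.  In the cohort, the planted pre→post GFA shift in
lesioned BA4 is detected and the change anti-correlates with the WMFT
log performance time change (any single 36-subject draw scatters around
the planted rank correlation of −0.363).

The same chain is available from the shell:

```sh
gfadwi demo --seed 1 --out runs/demo
```

## Layout

| module        | contents                                                  |
|---------------|-----------------------------------------------------------|
| `scheme`      | gradient schemes (quasi-uniform direction layouts)        |
| `synthetic`   | multi-tensor phantoms, Rician noise, ROI blocks           |
| `cohort`      | pre/post cohort simulator with planted effects            |
| `metrics`     | ADC profiles, GFA, tensor fit, FA, MD, metric maps        |
| `roi`         | FWHM Gaussian smoothing, label-wise ROI means             |
| `scores`      | FMA / WMFT representations and CSV I/O                    |
| `stats`       | Wilcoxon signed-rank, Spearman, cohort report             |
| `pipeline`    | seeded end-to-end runs with plain-format artifacts        |
| `cli`         | `gfadwi` command (`phantom`, `maps`, `roi`, `scores`, `analyze`, `demo`) |

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
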