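# brightpath

Image-based planning tools for transcranial magnetic stimulation (TMS)
trials, plus the trial's statistical power calculators. The package is
aimed at imaging methodologists who need a transparent, testable
implementation of each step between a preprocessed resting-state scan
and a deliverable coil pose:

* **Connectivity-guided target** (for individualized iTBS): the voxel of
  the left middle frontal gyrus where outgoing effective connectivity
  from the right anterior insula peaks. Effective connectivity is the
  signed coefficient b of the bivariate first-order Granger model on
  standardized series, y_t = c + a·y_{t−1} + b·x_{t−1} + e, computed
  voxelwise, z-scored across the search mask, thresholded at z > 1.96
  and clustered (26-connectivity); the target is the global-maximum
  voxel. Supporting steps — ICA-component-to-template matching, WM/CSF
  nuisance regression, 0.01 Hz high-pass, nuisance-mask
  binarization/erosion — are included.
* **Standard rTMS target**: the brain voxel nearest the F3 scalp
  position (MNI −49, 51, 40 mm).
* **Coil-pose geometry**: a head-fixed NLR frame built from the nasion
  and preauricular fiducials (origin = orthogonal projection of the
  nasion onto the interaural line; x→nasion, y→left ear, z→vertex),
  a least-squares rigid fit into that frame, projection of the brain
  target to the nearest scalp-mesh vertex, and a coil rotation whose
  z-axis is the outward surface normal and whose y-axis projects onto
  the NLR xy-plane at exactly 45° to the midsagittal axis — exported as
  a scalar-first unit quaternion.
* **BOLD motion QC**: Power-convention framewise displacement with the
  trial's gates (any FD > 3 mm, or mean FD > 1 mm, fails).
* **MEGA-PRESS preprocessing**: ON/OFF splitting, water-phase
  eddy-current correction, time-domain spectral registration to the mean
  OFF spectrum, choline-window outlier rejection (mean + 3 sd), ON−OFF
  differencing, and the water-linewidth (< 13 Hz) and OFF-SNR QC gates.
* **Power calculators**: two-arm power for a difference δ in the mean of
  k correlated follow-ups with ANCOVA baseline adjustment and dropout,
  se = sd_adj·√(2/n_arm), power = Φ(δ/se − z_c); and Fisher-z correlation
  power, Φ(|atanh ρ1 − atanh ρ0|·√(n−3) − z_c), with its inversion for
  the minimum detectable |ρ|.

Every stage is exercised end-to-end on synthetic fixtures with known
ground truth (`brightpath.synthetic_fixtures`), so nothing needs to be
downloaded. See `docs/methods.md` for model details, conventions and
limitations.

## Worked example

Plant a known causal path in a synthetic BOLD volume and recover it:

```python
import brightpath as bp

fx = bp.make_var_bold()          # seed sphere drives one frontal voxel
target, _ = bp.run_cgitbs_pipeline(
    fx.bold, fx.components, fx.template, fx.lmfg, fx.rai,
    wm=fx.wm, csf=fx.csf)
print(target.voxel_index, target.world_mm, round(target.peak_z, 2))
```

prints

```
(6, 17, 12) (18.0, 51.0, 36.0) 6.21
```

— the planted voxel (`fx.true_target_voxel`), its position in mm, and
its connectivity z-score, 6.2 standard deviations above the mask mean.
Adding a head mesh and fiducial landmarks (`mesh=`, `landmarks=`)
extends the run through the NLR geometry and returns a full coil-pose
plan; `bp.export_plan` writes it as versioned JSON.

The calculators are also available from the shell:

```sh
$ brightpath power trial --n 266
{"power": 0.8928215617384413, "power_percent": 89.3}
$ brightpath power corr --n 120 --rho0 0.2 --rho1 0.5
{"power": 0.9631766969863893, "power_percent": 96.3}
```

i.e. 89.3% power for the primary analysis at the stated design
(δ = 3 HDRS-17 points, SD 8, follow-up correlation 0.7, baseline
correlation 0.27, 20% dropout), and 96.3% power to distinguish a 0.5
from a 0.2 correlation at n = 120. The umbrella CLI also exposes
`target`, `pose`, `qc`, `mrs` and `fixtures` subcommands; exit codes are
0 (ok), 2 (QC failure), 3 (input error).

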