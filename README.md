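# discsaxs

Analysis of in-situ small-angle X-ray scattering (SAXS) collected during
whole intervertebral-disc compression, together with a forward simulator of
the fiber-diffraction detector images. The package is aimed at researchers
studying how annulus fibrosus collagen accommodates disc-level loading — in
particular, how the nanoscale deformation mechanisms differ between healthy
and diabetic tissue, where advanced glycation end products (AGEs) stiffen
the collagen network.

## What it measures

The annulus fibrosus winds around the disc in alternating left- and
right-handed collagen sheets, so its diffraction pattern shows two arc
families mirrored about the loading axis. From each detector exposure the
package extracts:

* **Interlamellar fiber angle** — the two arcs' azimuthal intensities are fit
  with wrapped Gaussians; the angle is the difference of the fitted centers
  (`≈ 97°` unloaded), a relative measure that is invariant to rigid sample
  tilt.
* **Collagen fibril strain** — the meridional collagen reflection is fit in
  10°-wide sectors with an exponentially modified Gaussian (EMG); the
  d-period follows from the peak position, *d* = 2π·n/*q*, and fibril strain
  is the relative change of *d* against the same specimen's unloaded frame:
  ε_f = 100·(d − d₀)/d₀.
* **d-period dispersion** — the numerically computed FWHM of the fitted
  radial peak, which broadens when fibrils slide or delaminate.
* **Degree of alignment** — a 0–1 concentration statistic of the azimuthal
  intensity (1 = all intensity at one orientation, 0 = isotropic), computed
  from sorted cumulative intensity fractions.
* **Macroscale stress and strain** — axial stress from the load cell and the
  radiograph-derived circular cross-section, applied compressive strain from
  speckle images via strip-wise 1D digital image correlation (normalized
  cross-correlation with sub-pixel refinement and a second warp-corrected
  pass).

Per-specimen trajectories of these outcomes versus applied strain are
aggregated into group means and a diabetic-minus-lean difference curve with
a 95% confidence band from a specimen-level bootstrap.

Because the study's raw detector frames are not retrievable by accession,
every stage is validated against the built-in forward model
(`discsaxs.simulate`): parametric two-arc patterns with Poisson counting
noise, rendered from ground-truth trajectories whose endpoints match the
published group outcomes (lean: +26° angle increase and 2.0% fibril strain
at 10% applied compression; diabetic: +18° and 1.4%, with FWHM broadening
above 4% and alignment loss above 8%).

## Worked example

```python
import numpy as np
from discsaxs import (
    analyze_series, make_cohort, simulate_series, summarize_specimen,
)

spec = make_cohort("lean", 1, base_seed=1)[0]          # one simulated disc
images, truth = simulate_series(spec)                  # 15 exposures, 0–10%
df = analyze_series(images, truth["applied_strain_pct"].to_numpy(),
                    specimen_id=spec.specimen_id, group=spec.group)
print(summarize_specimen(df))
```

prints (numbers from an actual run):

```
{'specimen_id': 'lean_01', 'group': 'lean', 'eval_strain_pct': 10.0,
 'partial': False, 'angle_increase_deg': 25.76, 'fibril_strain_pct': 1.973,
 'transfer_fraction_pct': 19.73, 'angular_rate_deg_per_pct': 2.576}
```

i.e. over 10% applied compression this disc's interlamellar angle opened by
25.8° (≈2.6° per percent applied strain) and its collagen fibrils stretched
by 1.97%, so about 20% of the tissue-level strain was transferred to the
fibrils — recovering the ground truth of the lean preset (26°, 2.0%, 20%)
within the counting-noise tolerance.

The same flow is available from the shell:

```bash
discsaxs simulate --preset lean --n-specimens 7 --seed 1 --out runs/sim
discsaxs analyze --input-dir runs/sim --out runs/analysis
discsaxs summarize --measurements runs/analysis/measurements.csv --out runs/summary
# or all three stages with a manifest:
discsaxs full --out runs/full --n-lean 7 --n-diabetic 6 --seed 1
```

## Layout

| module | contents |
| --- | --- |
| `discsaxs.geometry` | detector geometry, pixel→(q, φ) maps, cake binning, TIFF + JSON-sidecar I/O |
| `discsaxs.emg` | exponentially modified Gaussian peak shape (mode, FWHM, width solving) |
| `discsaxs.azimuthal` | azimuthal profiles, two-arc fitting, interlamellar angle, alignment statistic |
| `discsaxs.radial` | sector integration, EMG peak fits, d-period, fibril strain, FWHM |
| `discsaxs.mechanics` | 1D speckle DIC, stress from load, exposure synchronization |
| `discsaxs.simulate` | forward model: pattern renderer, series/speckle/load-trace simulation, presets |
| `discsaxs.trajectories` | specimen summaries, group difference curves with bootstrap bands |
| `discsaxs.pipeline`, `discsaxs.cli` | per-frame orchestration and the `discsaxs` command |

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
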