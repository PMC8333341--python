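# tensionmap

Per-pixel mapping of molecular force orientation and magnitude from
polarization-modulated structured-illumination acquisitions.

A striped SIM excitation pattern is linearly polarized along the stripe
orientation, so a standard three-orientation acquisition samples each pixel
at three excitation polarization angles spaced 60 degrees apart.  For
surface-anchored tension probes whose fluorophore dipole is perpendicular
to the force axis, the pixel intensity follows
`I(alpha) = A sin^2(alpha - phi) + c`, and the three samples determine the
in-plane force angle `phi` (axial, modulo 180 degrees), the tilt angle
`theta`, and the peak intensity `I_max = A + c` in closed form.

## What is in the package

| module | purpose |
| --- | --- |
| `tensionmap.orientation` | forward dipole-intensity model, exact three-point sinusoid fit (second-harmonic demodulation), tilt-angle inversion, per-image fitting, polarization-response metric |
| `tensionmap.preprocess` | raw montage correction: camera baseline, rolling-ball illumination profile, montage percentile subtraction, phase averaging into a polarization triplet |
| `tensionmap.synthetic` | ground-truth scene generators (platelet ring + lobes, bead phantom, uniform) and raw montage / timelapse renderers with stripes, shot noise, photobleaching and stage drift |
| `tensionmap.errorsim` | Monte Carlo characterization of random and systematic errors of `phi` and `theta` versus true orientation and photon budget; uniformity histograms |
| `tensionmap.timelapse` | drift and photobleach correction, tension area `T(t)`, alignment parameter `R(t)`, kinetic curve fits (simulated annealing + local refinement), cohort statistics, linescan edge widths |
| `tensionmap.render` | dipole-map and HSV/jet colormap display styles |
| `tensionmap.circular` | axial (doubled-angle) circular statistics |
| `tensionmap.io` | TIFF + JSON-sidecar serialization |
| `tensionmap.cli` | `tensionmap` command-line front end |

## CLI

```sh
# generate a synthetic platelet acquisition (raw montage TIFF + JSON sidecar)
tensionmap simulate-scene --kind platelet --seed 1 --out scene.tif

# correct + phase-average into a polarization triplet, then fit
tensionmap preprocess --input scene.tif --out triplet.tif
tensionmap fit --input triplet.tif --out map.tif --csv map.csv

# render the orientation map
tensionmap render --input map.tif --style colormap-phi --out map.png

# Monte Carlo error surface
tensionmap error-sim --imax 1000 --reps 5000 --seed 1 --out errors.csv

# synthetic timelapse and its quantification
tensionmap simulate-timelapse --seed 1 --out-dir tl/
tensionmap timelapse --input-dir tl/ --out-dir tl_out/
```

Exit codes: 0 ok, 2 config error, 3 data error.  Every subcommand writes a
JSON run log (parameters, seeds, version) next to its outputs.

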