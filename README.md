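# optoflow

Quantitative analysis of optically patterned microtubule–kinesin active
fluids.

Microtubule networks driven by light-switchable kinesin clusters behave
as an extensile active fluid whose stress can be turned on and off, and
confined to illuminated regions, in real time. `optoflow` implements the
measurement chain for such experiments on fluorescence time-lapse data,
together with a seeded synthetic-microscopy generator so that every
stage can be exercised and validated without experimental data. It is a
Python library first (see `examples/`), with a thin `optoflow` CLI for
shell-driven runs.

## What it computes

- **PIV flow fields and speed traces** (`flowfield`): windowed
  normalized cross-correlation between consecutive frames with
  three-point Gaussian sub-pixel refinement, normalized-median outlier
  replacement, the mean network speed ⟨|v|⟩(t), and Pearson correlation
  between velocity fields.
- **Photoswitching kinetics** (`kinetics`): cycle segmentation from the
  illumination schedule; activation fits
  ⟨|v(t)|⟩ = v_max (1 − e^(−t/τ_on)); deactivation fits of the
  normalized logistic decay v̂(t) = 2/(1 + e^(t/τ_off)); per-cycle
  plateau/dark-speed summaries; the intensity–speed response and its
  saturation intensity.
- **Bend-angle analysis** (`orientation`): structure-tensor orientation
  fields with coherence masking, the mean in-plane deviation angle
  ⟨θ⟩(t) from the initial alignment, its activated growth rate γ̇, and
  the post-deactivation relaxation fit
  ⟨θ⟩(t) = e^(−t/τ) γ̇ t + C e^(−t/r)
  with γ̇ held fixed (τ: motor-cluster unbinding time; r: elastic
  relaxation time of the passive network).
- **Strain mapping** (`strainmap`): Eulerian accumulation of PIV
  displacement fields, region-averaged cumulative normal strains
  γ_xx(t), γ_yy(t), a normalized region-fluorescence flux proxy,
  quiescent / sliding / buckling regime classification (buckling when
  Δγ_yy > 0.5% over the activation window), and the threshold-intensity
  rule.
- **Confinement-dependent instability threshold** (`stability`): the
  geometric activity bound for an activated L × W × H region,

      α_eff = π² L² (1/L² + 1/W² + 1/H²)²,  1/L² > 1/W² + 1/H²
            = 4π² (1/W² + 1/H²),            otherwise,

  the origin-constrained fit of threshold intensity I* = a·α_eff, the
  saturated-branch prediction, and the phenomenological 1/L² + C
  comparison fit.
- **Synthetic microscopy** (`synthgen`): seeded aligned filament
  textures, advection by programmed flows (uniform, affine extension,
  shear, growing bend mode, divergence-free turbulence) gated by an
  illumination schedule, model speed/angle traces, and
  threshold-intensity datasets — all bit-reproducible per seed.

## Worked example

```sh
python examples/photoswitching_kinetics.py
```

```
plateau speed : 1.183 um/s   (programmed 1.2)
tau_on        : 7.31 s     (programmed 8)
tau_off       : 14.24 s    (programmed 13)
```

A synthetic light cycle (2 min on at 1 µW/mm², then dark) is generated
with the non-processive-motor parameters plus 10% measurement noise;
refitting recovers the plateau speed and both switching time constants.
The other example scripts cover PIV speed measurement
(`piv_speed_trace.py`), bend-angle growth and relaxation
(`bend_instability.py`), strain regimes (`strain_regimes.py`) and the
confinement threshold fit (`confinement_threshold.py`).

The same stages are available from the shell, e.g.

```sh
optoflow simulate --seed 2 --out run/ --shape 192 192 --speed 1 --n-frames 8
optoflow piv run/sequence.tif --schedule run/schedule.yaml --out run/trace.csv
```

## Conventions

Row index is y (downward), column index is x (rightward); x is the
initial filament-alignment direction; angles are measured from +x with
the nematic identification θ ≡ θ ± π. Times are seconds, lengths
micrometres, intensities µW/mm² at every module boundary.
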