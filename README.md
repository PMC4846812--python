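# batwake

Wake analysis for flapping animal flight from time-resolved, transverse-plane
stereo PIV. Given sequences of three-component velocity vector fields measured
on a fixed plane behind a flying animal (plus flight speed *U*, frame rate
*f<sub>L</sub>*, air density *ρ* and body mass *m*), `batwake`:

1. **validates and repairs** the vector fields (normalized median outlier
   test, median replacement, hole filling by interpolation);
2. **reconstructs the pseudo-3D wake** under the frozen-flow hypothesis
   (frames stacked at out-of-plane spacing *U/f<sub>L</sub>*, resampled with
   tricubic splines to an isotropic dx = dy = dz grid, Gaussian-smoothed
   with a 5×5×5 kernel);
3. **identifies vortex structures** as connected regions of positive
   Q-criterion, Q = ½(‖Ω‖² − ‖S‖²), above a threshold, and characterizes
   each one (volume, circulation of the dominant cross-section, upwash vs
   downwash sense);
4. **estimates weight support** from the spanwise first moment of streamwise
   vorticity (Trefftz-plane / vorticity-moment estimate),

   F = 2 ρ U Σ<sub>y&gt;y₀</sub> ω<sub>x</sub>(y, z) (y − y₀) dy dz,

   integrated over one semi-span about the body symmetry plane y₀ and
   doubled, averaged per wingbeat and expressed as a percentage of *m g*;
   sequences outside ±20 % of full support fail the capture-quality filter.

Since raw flight recordings are rarely shareable, the package ships a
**synthetic wake generator**: closed vortex filaments (tip/root loop pairs,
trailing pairs, rings, reversed loops) with Lamb–Oseen cores, advected
rigidly at *U* and sampled onto PIV-like frames with Gaussian noise,
spurious vectors and data holes. Filament wakes have closed-form induced
velocity, vorticity and vertical impulse (ρ Γ A per loop), so every stage —
from outlier rejection to the force integral — is testable against analytic
ground truth.

Intended users: experimentalists in animal flight and comparative
biomechanics post-processing wind-tunnel PIV of birds, bats or insects, and
anyone needing a transparent, tested reference implementation of
vorticity-moment lift estimation on stacked PIV planes.

## Worked example

A wake tuned so each wingbeat carries exactly one body weight of impulse,
sampled at 640 Hz with realistic measurement noise (velocity noise sd of
1 % of *U*, 2 % spurious vectors), repaired and measured:

```python
import numpy as np
from batwake import SequenceMeta
from batwake.synthetic import NoiseSpec, build_scenario, sample_plane_sequence
from batwake.preprocess import preprocess_sequence
from batwake.forces import sequence_weight_support, filter_sequences

meta = SequenceMeta(U=4.0, mass=0.009)          # 9 g animal at cruise speed
wake = build_scenario("cruise_wingbeat", dict(U=4.0, mass=0.009))
noise = NoiseSpec(velocity_noise_sd=0.04, spurious_fraction=0.02, rng_seed=1)
frames = sample_plane_sequence(wake, meta, noise, n_frames=116)
frames, stats = preprocess_sequence(frames)      # outlier rejection + repair
record = sequence_weight_support(frames, meta)   # forces, wingbeats, % support
print(record.summary())
for k, pct in enumerate(record.weight_support_pct):
    print(f"  wingbeat {k}: frames {record.wingbeat_bounds[k]}, "
          f"mean force {record.wingbeat_mean_force[k]:.4f} N, support {pct:.1f}%")
print(f"kept by +/-20% filter: {len(filter_sequences([record]))} of 1")
```

prints

```
weight support 99.2% (accepted; 2 wingbeats)
  wingbeat 0: frames (0, 58), mean force 0.0874 N, support 99.0%
  wingbeat 1: frames (58, 116), mean force 0.0878 N, support 99.5%
kept by +/-20% filter: 1 of 1
```

The 9 g animal weighs 0.0883 N; the estimator reads the wake's mean vertical
force to within about 1 % of that, the residual coming from grid
discretization and the repaired measurement noise. The wingbeat boundaries
(58 frames ≈ 11 Hz at 640 Hz) are found automatically from the periodicity
of the momentary force series.

The same pipeline runs from the shell:

```bash
batwake pipeline --scenario cruise_wingbeat --speed 4 --seed 1 --frames 116 --out run/
# run/forces.csv, run/structures.csv, run/volume.vtk, run/config.yaml
batwake report --forces-csv run/forces.csv
```

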