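# excitube

Exciton spectroscopy and self-assembly kinetics of double-walled dye
nanotubes.

Amphiphilic cyanine dyes such as C8S3 self-assemble into double-walled
nanotubes (inner diameter ≈ 6.9 nm, outer ≈ 13.5 nm) whose walls are
excitonically coupled J-aggregates.  When the outer wall (OW) is
selectively dissolved and allowed to recover on the surviving inner
wall (IW), it regrows as a *patchwork*: locally ordered patches of
molecules with mutually random orientations that only later align into
one global domain.  This package provides the complete analysis chain
used to study that process on simulated data:

- **synthetic geometry** — planar brickwork lattices rolled into
  cylinders, patchwork outer walls, and a seeded stochastic toy model of
  the recovery (adsorption, patch nucleation, whole-patch reorientation);
- **exciton spectra** — the Frenkel Hamiltonian with Gaussian diagonal
  disorder and extended-dipole couplings, disorder-averaged polarized
  absorption, linear dichroism (LD) and reduced linear dichroism (LD_r);
- **observables** — band-averaged OD/LD/LD_r time series and peak
  positions;
- **patches** — DBSCAN identification of patches from regularized
  positions plus dipole orientations (eps = 0.2, ≥ 2 points);
- **kinetics** — ordered vs delayed-ordering rate-equation models,
  fitted jointly to OD and LD series, statsmodels-style
  (`RecoveryKinetics(...).fit().summary()`).

## Model

Each molecule *n* at position r⃗_n carries a unit transition dipole
d⃗_n of magnitude μ = q·l (q = 0.34 e, l = 7 Å, μ = 11.4 D).  The
one-exciton Hamiltonian (cm⁻¹) is

    H_nn = ν̃_n − δ,   H_nm = J_nm   (n ≠ m),

with ν̃_n ~ 𝒩(ν̃₀ = 19 498, σ = 231), gas-to-crystal shift δ = 350, and
extended-dipole couplings

    J_nm = α (μ/l)² Σ_{s,s'=±1} s·s′ / | r⃗_n + s(l/2)d⃗_n − r⃗_m − s′(l/2)d⃗_m |,

α = 5.04 × 10³ cm⁻¹ Å³ D⁻².  Polarized absorption is the average over
disorder realizations of the stick spectrum Σ_k |⟨g|ê·μ̂|k⟩|² broadened
by a zero-mean Gaussian lineshape (σ = 75 cm⁻¹).  For a flow-aligned
tube, LD = A∥ − A⊥, A_iso = (A∥ + 2A⊥)/3 and LD_r = LD/A_iso, which is
3 for perfectly axial transitions and 0 for isotropic ones.

Outer-wall recovery is described by OD(t) = od_base + od_amp(1 −
e^(−k_ads t)) in both rate models; the *ordered* model takes LD ∝ OD,
while the *disordered* model routes adsorbed molecules through a
transient disordered state that orders at a second rate k_ord, delaying
LD and making LD_r dip before it recovers.

## Worked example

```python
import numpy as np
from excitube import (
    AssemblySimParams, ExcitonParams, LatticeSpec, TubeSpec,
    full_spectrum, rolled_wall, simulate_assembly,
)
from excitube.dichroism import BandWindow, find_peak, timeseries
from excitube.kinetics import fit_model

lattice = LatticeSpec.brickwork()
tube = TubeSpec(length=6.0)
iw = rolled_wall(lattice, tube.radius_iw, tube.length, tube.axis, "IW")

spec = full_spectrum(iw, ExcitonParams(n_realizations=100, seed=0))
peak, _ = find_peak(spec.grid, spec.a_par)
print(f"inner wall: {len(iw)} molecules, parallel-polarized peak at {peak:.0f} cm^-1")

frames = simulate_assembly(
    iw, tube, lattice,
    AssemblySimParams(adsorption_rate=0.08, patch_reorientation_rate=0.3,
                      n_steps=40, seed=11),
)
points = timeseries(frames, ExcitonParams(n_realizations=40, seed=5),
                    BandWindow(15324, 18550),
                    grid=np.arange(14000.0, 21000.0, 4.0), seed=5)
for tag in ("ordered", "disordered"):
    print(f"{tag:>10s} model: sse = {fit_model(points, tag).sse:.4f}")
```

prints

```
inner wall: 100 molecules, parallel-polarized peak at 16776 cm^-1
   ordered model: sse = 4.9860
disordered model: sse = 2.1689
```

The inner-wall band is strongly red-shifted from the 19 148 cm⁻¹
monomer position (J-aggregate behaviour), and the delayed-ordering
model fits the recovery series roughly twice as well as immediate
ordering — the spectroscopic signature of patchwork growth.

A full run (frames → spectra → time series → patches → both fits, with
a reproducibility manifest) is one command:

```
excitube pipeline --config examples/demo.yaml
```

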