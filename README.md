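# ciliaflow

Two-dimensional immersed-boundary lattice-Boltzmann (IB-LBM) simulation of
**mucociliary clearance** — the transport of airway mucus by coordinated
ciliary beating.

The airway surface liquid is modelled as two layers in a periodic channel:
a watery Newtonian **periciliary liquid (PCL)** in which an array of
node-spring cilia beats, and a viscoelastic **mucus layer (ML)** above it,
separated by a virtual elastic membrane.  The fluid is solved by a D2Q9
BGK lattice-Boltzmann method with Guo forcing; the mucus follows the
Oldroyd-B law, σ = 2η_N D + σ_E with σ_E + λ ∇σ_E = 2η_E D (upper-convected
derivative); cilia, membrane and rigid particles couple to the lattice
through regularized-delta (Peskin) kernels.  Each cilium is dragged
through penalty springs, F_c = K_sl (Y − X), by a prescribed-motion
*virtual cilium* whose two-stroke beat (straight effective stroke, curled
recovery stroke) is generated from a tangent-angle profile.  Passive
tracepoints in the ML measure the mean transport speed; rigid discs seeded
in the PCL probe particle capture.

Intended users: researchers studying ciliary propulsion, airway-surface
liquid mechanics, or fluid–structure interaction methods who want a small,
fully scriptable 2D model with measurable transport output.

## Worked example

Measure the reference transport speed: beat amplitude regulated so that
the case with cilium spacing 0.55 L, phase difference 0.02 T, PCL depth
6.2 μm, ML thickness 4 μm, viscosity ratio 40 and a 20 Hz beat moves the
mucus layer at about 42 μm/s:

```python
from ciliaflow.reference import reference_config
from ciliaflow.simulation import run_simulation

res = run_simulation(reference_config(seed=1).replace(total_periods=6.0))
print(f"mean ML speed : {res.v_ml_um_s:.2f} um/s")
print(f"max strain    : {res.max_strain_pct:.3f} %")
print(f"per-period    : {res.per_period_v_um_s.round(1)}")
```

prints (half resolution, dx = 0.2 μm, 20 000 steps per beat period):

```
mean ML speed : 42.38 um/s
max strain    : 2.324 %
per-period    : [29.  42.2 42.2 42.3 42.4 42.5]
```

The first period ramps the beat up from rest; the flow is fully developed
from the second period on, and the reported speed is the tracer-mean over
the final three beat periods.  The strain figure is the largest relative
stretch of any cilium segment; it is concentrated in the tip segments,
where at this resolution the cilium tip lies within one spreading-kernel
width of the membrane (see the limitations section of the methods note).

Other entry points:

```bash
ciliaflow validate poiseuille      # viscoelastic channel benchmark vs closed form
ciliaflow run config.yaml          # a single configured simulation
ciliaflow sweep thickness          # ML-thickness / density / phase sweeps
ciliaflow particles --y0 4.5       # particle-migration run
ciliaflow calibrate                # re-run the amplitude regulation
```

Sweeps produce tidy CSV tables (one row per run) from which the
thickness/density/phase figures can be regenerated.

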