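"""Reference configurations of the mucociliary-clearance study.

The beat amplitude is regulated so that the reference case (cilium spacing
0.55 L, phase difference 0.02 T, PCL depth 6.2 um, ML thickness 4 um,
ML:PCL viscosity ratio 40, 20 Hz beat) transports the mucus layer at about
42 um/s.  The calibrated values below were obtained with
:func:`ciliaflow.simulation.calibrate_amplitude` at the two resolutions the
package runs at, and serve as the starting point when the calibration is
re-run; re-calibration from these values converges in one or two short
runs.

* ``half`` resolution (dx = 0.2 um, 20000 steps per beat period) is the
  measurement configuration for the transport-speed and cilium-strain
  reference numbers;
* ``quarter`` resolution (dx = 0.4 um, 5000 steps per beat period) is the
  screening configuration used by the parameter sweeps and the
  particle-migration study.
"""

from __future__ import annotations

from .config import SimulationConfig

__all__ = ["REFERENCE_AMPLITUDE_HALF", "REFERENCE_AMPLITUDE_QUARTER",
           "reference_config", "trend_config", "TARGET_ML_SPEED_UM_S"]

#: transport-speed target of the amplitude regulation, um/s
TARGET_ML_SPEED_UM_S = 42.0

#: calibrated root-sweep half-angle (radians) at half resolution
REFERENCE_AMPLITUDE_HALF = 0.0984

#: calibrated root-sweep half-angle (radians) at quarter resolution
REFERENCE_AMPLITUDE_QUARTER = 0.230


def reference_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The half-resolution reference case (transport / strain measurements)."""
    base = dict(dx_um=0.2, steps_per_period=20000,
                amplitude=REFERENCE_AMPLITUDE_HALF, seed=seed)
    base.update(overrides)
    return SimulationConfig(**base)


def trend_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The quarter-resolution screening case (sweeps, particle study)."""
    base = dict(dx_um=0.4, amplitude=REFERENCE_AMPLITUDE_QUARTER, seed=seed)
    base.update(overrides)
    return SimulationConfig(**base)
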