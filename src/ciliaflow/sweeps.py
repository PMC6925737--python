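"""Parameter studies: mucus thickness, cilia density, phase difference, particles.

Each sweep runs one simulation per parameter combination and collects the
mean mucus-layer velocity (or particle-migration summary) into a tidy
pandas DataFrame; per-run failures are recorded and the sweep continues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ParticleSpec, SimulationConfig
from .simulation import RunResult, particle_capture_stop, run_simulation

__all__ = ["sweep_thickness", "sweep_density", "sweep_phase", "particle_study",
           "density_linear_fit", "classify_migration"]


def _run_cell(cfg: SimulationConfig, **cell) -> dict:
    try:
        res = run_simulation(cfg)
        return {**cell, "v_ml_um_s": res.v_ml_um_s,
                "max_strain_pct": res.max_strain_pct, "error": ""}
    except Exception as exc:  # per-run failure: record, keep sweeping
        return {**cell, "v_ml_um_s": np.nan, "max_strain_pct": np.nan,
                "error": f"{type(exc).__name__}: {exc}"}


def sweep_thickness(base: SimulationConfig, thicknesses_um,
                    spacings_L=(0.55,)) -> pd.DataFrame:
    """Mean ML velocity across mucus-layer thicknesses (per cilia spacing)."""
    rows = []
    for sp in spacings_L:
        for th in thicknesses_um:
            cfg = base.replace(ml_thickness_um=float(th), spacing_L=float(sp))
            rows.append(_run_cell(cfg, ml_thickness_um=th, spacing_L=sp))
    return pd.DataFrame(rows)


def sweep_density(base: SimulationConfig, spacings_L,
                  thicknesses_um=(4.0,)) -> pd.DataFrame:
    """Mean ML velocity across cilia spacings (density = 1/spacing)."""
    rows = []
    for th in thicknesses_um:
        for sp in spacings_L:
            cfg = base.replace(spacing_L=float(sp), ml_thickness_um=float(th))
            rows.append(_run_cell(cfg, spacing_L=sp, ml_thickness_um=th,
                                  density=1.0 / sp))
    return pd.DataFrame(rows)


def density_linear_fit(table: pd.DataFrame) -> dict:
    """Least-squares line of v_ML against cilia density 1/spacing, with R^2."""
    t = table.dropna(subset=["v_ml_um_s"])
    x = t["density"].to_numpy()
    y = t["v_ml_um_s"].to_numpy()
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return {"slope": float(slope), "intercept": float(intercept), "r2": r2}


def sweep_phase(base: SimulationConfig, phase_diffs_T,
                spacings_L=(0.55,)) -> pd.DataFrame:
    """Mean ML velocity across adjacent-cilia phase differences."""
    rows = []
    for sp in spacings_L:
        for ph in phase_diffs_T:
            cfg = base.replace(phase_diff_T=float(ph), spacing_L=float(sp))
            rows.append(_run_cell(cfg, phase_diff_T=ph, spacing_L=sp))
    return pd.DataFrame(rows)


def classify_migration(res: RunResult, top_um: float = 5.5) -> dict:
    """Classify a particle run: did the mean height reach the cilia-tip region?

    ``top_um`` is the cilium length; "reached top" means the mean particle
    height attained ``y >= top_um`` at some time, and the crossing time (in
    beat periods) is reported.
    """
    t = res.particle_times_T
    ybar = res.particle_mean_y_um
    if t is None:
        raise ValueError("run has no particle log")
    above = np.nonzero(ybar >= top_um)[0]
    if above.size:
        return {"reached_top": True, "crossing_time_T": float(t[above[0]]),
                "final_y_um": float(ybar[-1])}
    return {"reached_top": False, "crossing_time_T": np.nan,
            "final_y_um": float(ybar[-1])}


def particle_study(base: SimulationConfig, diameters_um, y0s_um,
                   n_particles: int = 20, periods: float = 20.0,
                   top_um: float = 5.5, stop_at_capture: bool = True
                   ) -> pd.DataFrame:
    """Particle-migration study over (diameter, initial height) combinations.

    With ``stop_at_capture`` a run ends as soon as the mean particle height
    reaches the cilia-tip region (the crossing time is the measurement;
    confined runs still go the full duration).
    """
    rows = []
    for d in diameters_um:
        for y0 in y0s_um:
            cfg = base.replace(
                particles=ParticleSpec(n=n_particles, diameter_um=float(d),
                                       y0_um=float(y0)),
                total_periods=float(periods))
            stop = (particle_capture_stop(top_um / base.dx_um - 0.5)
                    if stop_at_capture else None)
            try:
                res = run_simulation(cfg, stop_when=stop)
                cls = classify_migration(res, top_um)
                rows.append({"diameter_um": d, "y0_um": y0, **cls, "error": ""})
            except Exception as exc:
                rows.append({"diameter_um": d, "y0_um": y0, "reached_top": None,
                             "crossing_time_T": np.nan, "final_y_um": np.nan,
                             "error": f"{type(exc).__name__}: {exc}"})
    return pd.DataFrame(rows)
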