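"""Standard study conditions for synthetic cohorts.

These builders pin down the cohorts used for parameter-recovery
validation: heated cells with plateau deltaT drawn uniformly over a
range spanning the line's 50% point, logistic width 1 degC, 100
unheated control cells for the fluctuation threshold, and a thermometer
sheet covering the cells' distances.  The deltaT range and laser power
are matched to each line so the 50% crossing is well inside the sampled
range.
"""

from __future__ import annotations

from dataclasses import replace

from .datatypes import HeatPulseProtocol
from .pipeline import RunConfig, RunReport, run_pipeline_on_cohort
from .simulate import SimConfig, mutant_preset, simulate_cohort

__all__ = ["recovery_config", "run_recovery", "DEFAULT_RANGES"]

# deltaT sampling range (degC) and laser power (mW) per base temperature
# scenario; ranges span the published 50% points with margin.
DEFAULT_RANGES = {
    36.0: ((0.0, 15.0), 25.6),
    24.0: ((0.0, 20.0), 51.2),
}


def recovery_config(
    mutant_name: str = "WT",
    t0_c: float = 36.0,
    seed: int = 0,
    *,
    n_cells: int = 1000,
    n_unheated: int = 100,
    deltaT_range=None,
    laser_power_mw: float | None = None,
    dtth_true_c: float | None = None,
) -> SimConfig:
    """Cohort configuration for dT_th parameter recovery."""
    rng_default, power_default = DEFAULT_RANGES[float(t0_c)]
    mut = mutant_preset(mutant_name, t0_c)
    if dtth_true_c is not None:
        mut = replace(mut, dtth_true_c=dtth_true_c)
    protocol = HeatPulseProtocol(
        t_start=10.0, duration=2.0,
        laser_power_mw=laser_power_mw or power_default, t0_c=t0_c)
    return SimConfig(
        seed=seed,
        n_cells=n_cells,
        n_unheated=n_unheated,
        deltaT_range_c=deltaT_range or rng_default,
        protocol=protocol,
        mutant=mut,
    )


def run_recovery(sim_cfg: SimConfig, *, n_boot: int = 0) -> tuple[RunReport, float]:
    """Simulate a cohort, run the full pipeline, return (report, truth)."""
    data = simulate_cohort(sim_cfg)
    run_cfg = RunConfig(
        protocol=sim_cfg.protocol,
        i_back=sim_cfg.i_back,
        n_boot=n_boot,
        seed=sim_cfg.seed,
    )
    report = run_pipeline_on_cohort(data, run_cfg)
    return report, sim_cfg.mutant.dtth_true_c
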