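"""Validation experiments run on the synthetic study system.

These are the package's own calibration/recovery checks: they generate a
study with a known embedded covariate effect, push it through the full
pipeline (biomass, topography, diversity, driver selection) and ask
whether the effect is recovered. Problem sizes are chosen so a single
replicate runs in about a second: a 120-quadrat plot (the default grid),
a 40-species pool, two censuses, ~60 stems per quadrat and 99 null-model
iterations.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .pipeline import PipelineConfig, compute_results
from .simulate import SimulationConfig, simulate_study


def recovery_replicate(seed: int, covariate: str = "cMPD", effect: float = 0.5,
                       noise_sd: float = 1.0) -> tuple[bool, float]:
    """One embedded-effect recovery replicate.

    Simulates a study in which quadrat ΔAGB is ``effect`` x ``covariate``
    plus Gaussian noise, runs the whole-plot driver analysis, and reports
    (covariate selected by the lowest-AIC model?, its fitted coefficient
    — NaN when not selected).
    """
    cfg = SimulationConfig(seed=seed, n_species=40, initial_stems_mean=60, n_censuses=2,
                           embedded_effects=((covariate, effect),), noise_sd=noise_sd,
                           null_iterations=99)
    study = simulate_study(cfg)
    pc = PipelineConfig(null_iterations=99, seed=seed, strata=("whole",))
    res = compute_results(study.censuses, study.species_pool,
                          study.landscape.corner_elevations,
                          study.landscape.frame["habitat"], pc)
    (cell,) = res["drivers"]
    if covariate in cell.model.predictors:
        return True, float(cell.model.coefficients.at[covariate, "coef"])
    return False, float("nan")


def recovery_rate(n_replicates: int, base_seed: int = 0, covariate: str = "cMPD",
                  effect: float = 0.5, noise_sd: float = 1.0) -> float:
    """Fraction of replicates in which the embedded effect is selected
    with the correct (positive) sign."""
    seeds = np.random.SeedSequence(base_seed).generate_state(n_replicates) % (2**31)
    hits = 0
    for s in seeds:
        selected, coef = recovery_replicate(int(s), covariate, effect, noise_sd)
        if selected and np.sign(coef) == np.sign(effect):
            hits += 1
    return hits / n_replicates
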