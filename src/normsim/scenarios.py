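"""What-if scenarios, adherence sampling, comparison metrics, bootstrap CIs.

Scenario presets mirror the study's interface: a slider choosing how much
each child's ideal BMI is driven by knowledge of a healthy BMI versus the
(possibly unhealthy) social norm, and school-based behaviour buttons adding
one hour of exercise (+0.175 PAL) and/or removing one snack (-200 kcal/day)
for one in four children.

* ``do_nothing``                — ideal 100% social norm, no behaviour change
* ``individual_intervention``   — ideal 50% norm / 50% healthy-BMI knowledge
* ``combined_intervention``     — ideal 100% healthy-BMI knowledge
* ``behaviour_change``          — norm-driven ideal plus the school buttons

The headline comparison metric is the *effectiveness diminishment*: the
percentage of the combined intervention's median-BMI improvement that is
lost when the unhealthy social norm keeps half its influence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .core import (
    InterventionAssignment,
    ModelParams,
    Population,
    Trajectory,
    simulate,
)


class UndefinedMetricError(ValueError):
    """The diminishment metric needs a strictly positive combined effect."""


@dataclass(frozen=True)
class InterventionSpec:
    """School-based behavioural intervention: activity and intake deltas
    applied to a random adherent subset of children for the whole run."""

    delta_pal: float = 0.0  # PAL units, >= 0
    delta_kcal: float = 0.0  # kcal/day, <= 0
    adherence_fraction: float = 0.25
    label: str = "intervention"

    def __post_init__(self) -> None:
        if not 0.0 <= self.adherence_fraction <= 1.0:
            raise ValueError("adherence_fraction must lie in [0, 1]")
        if self.delta_pal < 0:
            raise ValueError("delta_pal must be >= 0")
        if self.delta_kcal > 0:
            raise ValueError("delta_kcal must be <= 0")


@dataclass
class ScenarioConfig:
    w_hb: float = 0.5
    intervention: Optional[InterventionSpec] = None
    months: int = 36
    seed: int = 0
    bootstrap_reps: int = 1000
    label: str = "scenario"

    def __post_init__(self) -> None:
        if self.months < 0:
            raise ValueError("months must be >= 0")
        if self.bootstrap_reps < 0:
            raise ValueError("bootstrap_reps must be >= 0")


@dataclass
class ScenarioResult:
    label: str
    trajectory: Trajectory
    delta_bmi: float  # baseline minus final median BMI (positive = improvement)
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


#: Low / medium / high intensity school buttons plus "no school-based
#: intervention"; only the combined button is a named scenario preset.
INTERVENTION_BUTTONS: dict[str, Optional[InterventionSpec]] = {
    "no_school_intervention": None,
    "exercise_only": InterventionSpec(0.175, 0.0, 0.25, "1 extra hour of exercise"),
    "snack_only": InterventionSpec(0.0, -200.0, 0.25, "1 less snack"),
    "exercise_and_snack": InterventionSpec(
        0.175, -200.0, 0.25, "1 extra hour of exercise + 1 less snack"
    ),
}

_PRESETS: dict[str, ScenarioConfig] = {
    "do_nothing": ScenarioConfig(w_hb=0.0, intervention=None, label="do_nothing"),
    "individual_intervention": ScenarioConfig(
        w_hb=0.5, intervention=None, label="individual_intervention"
    ),
    "combined_intervention": ScenarioConfig(
        w_hb=1.0, intervention=None, label="combined_intervention"
    ),
    "behaviour_change": ScenarioConfig(
        w_hb=0.0,
        intervention=INTERVENTION_BUTTONS["exercise_and_snack"],
        label="behaviour_change",
    ),
}


def preset(name: str) -> ScenarioConfig:
    """A fresh copy of one of the named what-if scenarios."""
    if name not in _PRESETS:
        raise KeyError(
            f"unknown scenario {name!r}; available presets: {sorted(_PRESETS)}"
        )
    return replace(_PRESETS[name])


def assign_adherence(n: int, fraction: float, seed) -> np.ndarray:
    """Boolean adherence flags: exactly round(fraction * n) children,
    chosen uniformly without replacement; fixed for the whole run."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    k = int(round(fraction * n))
    mask = np.zeros(n, dtype=bool)
    mask[rng.choice(n, size=k, replace=False)] = True
    return mask


def _simulate_scenario(
    pop: Population,
    config: ScenarioConfig,
    params: ModelParams,
    seed,
) -> Trajectory:
    run_params = replace(params, w_hb=config.w_hb)
    assignment = None
    if config.intervention is not None:
        mask = assign_adherence(len(pop), config.intervention.adherence_fraction, seed)
        assignment = InterventionAssignment(
            delta_pal=config.intervention.delta_pal,
            delta_kcal=config.intervention.delta_kcal,
            mask=mask,
        )
    return simulate(pop, run_params, config.months, intervention=assignment)


def run_scenario(
    pop: Population,
    config: ScenarioConfig,
    params: Optional[ModelParams] = None,
) -> ScenarioResult:
    """Simulate one scenario; attach a bootstrap CI when reps > 0.

    ``delta_bmi`` is the baseline median minus the final median, so a
    positive value means the group's median BMI improved (fell).
    """
    params = params or ModelParams()
    ss = np.random.SeedSequence(config.seed)
    adh_seed, boot_seed = ss.spawn(2)
    traj = _simulate_scenario(pop, config, params, adh_seed)
    delta = float(traj.median_bmi[0] - traj.median_bmi[-1])
    ci_low = ci_high = None
    if config.bootstrap_reps > 0:
        ci_low, ci_high = bootstrap_ci(
            pop, config, params, reps=config.bootstrap_reps, seed=boot_seed
        )
    return ScenarioResult(
        label=config.label, trajectory=traj, delta_bmi=delta,
        ci_low=ci_low, ci_high=ci_high,
    )


def bootstrap_ci(
    pop: Population,
    config: ScenarioConfig,
    params: Optional[ModelParams] = None,
    reps: int = 1000,
    seed=0,
) -> tuple[float, float]:
    """95% percentile bootstrap for delta_bmi, resampling children.

    Children are resampled with replacement (same n); adherence, being part
    of the scenario rather than the data, is resampled inside every
    replicate.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    params = params or ModelParams()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    n = len(pop)
    deltas = np.empty(reps)
    for r in range(reps):
        idx = rng.integers(0, n, size=n)
        traj = _simulate_scenario(pop.take(idx), config, params, rng.integers(2**31))
        deltas[r] = traj.median_bmi[0] - traj.median_bmi[-1]
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    return float(lo), float(hi)


def effectiveness_diminishment(delta_individual: float, delta_combined: float) -> float:
    """Percent of the combined intervention's effect lost to the norm.

    100 * (1 - delta_individual / delta_combined); requires a strictly
    positive combined effect (an unhealthy norm that the combined scenario
    actually corrects).
    """
    if delta_combined <= 0:
        raise UndefinedMetricError(
            "effectiveness diminishment is undefined: combined-intervention "
            f"effect is {delta_combined:.4g} (needs to be > 0)"
        )
    return 100.0 * (1.0 - delta_individual / delta_combined)


def compare_interventions(
    populations: dict[str, Population],
    months: int = 36,
    params: Optional[ModelParams] = None,
    reps: int = 0,
    seed: int = 0,
) -> dict[str, dict]:
    """Individual vs combined scenario per community, plus the average
    effectiveness diminishment with equal community weights."""
    params = params or ModelParams()
    out: dict[str, dict] = {}
    dims = []
    for i, (name, pop) in enumerate(sorted(populations.items())):
        res = {}
        for scen in ("individual_intervention", "combined_intervention"):
            cfg = preset(scen)
            cfg.months = months
            cfg.seed = seed * 1000 + i
            cfg.bootstrap_reps = reps
            res[scen] = run_scenario(pop, cfg, params)
        dim = effectiveness_diminishment(
            res["individual_intervention"].delta_bmi,
            res["combined_intervention"].delta_bmi,
        )
        res["diminishment_pct"] = dim
        dims.append(dim)
        out[name] = res
    out["average_diminishment_pct"] = float(np.mean(dims))
    return out
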