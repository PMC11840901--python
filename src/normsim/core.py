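"""Discrete-time energy-balance model of childhood BMI coupled to a social norm.

The model advances a group of children in monthly steps. Each child carries a
fixed baseline (gender, age, height, baseline activity level and energy
intake, sociocultural ideal BMI, knowledge of a healthy BMI) and a dynamic
state (weight, BMI, basal metabolic rate, activity level, energy intake and
expenditure, perceived norm). The group is a norm-sharing unit: every month
the group-median BMI feeds back into each child's perceived norm, which pulls
their individual ideal BMI and hence their behaviour.

One month, for every child synchronously from the common current state:

1.  individual ideal BMI  = w_hb * healthy_BMI + (1 - w_hb) * norm
2.  discrepancy           = BMI - individual ideal BMI
3.  PAL'   = PAL0  + intent_pab * discrepancy  (+ intervention delta)
4.  TDEI'  = TDEI0 + intent_eb  * discrepancy  (+ intervention delta)
5.  TDEE'  = BMR * PAL'
6.  W'     = W + (TDEI' - TDEE') * days_per_month / kcal_per_kg
7.  BMI'   = W' / height0^2                    (height frozen at baseline)
8.  BMR'   = child-specific linear function of W' (gender x age bracket)
9.  median' = median of all BMI'
10. norm'  = (median' + SCIB) / 2              (SCIB frozen at baseline)

With the default constants the weight increment is exactly
73 * (TDEI - TDEE) / 18480 kg per month (365 days / 12 months / 7700 kcal
per kg of body weight).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

Gender = Literal["boy", "girl"]

#: Child basal-metabolic-rate coefficients (kcal/day per kg, kcal/day),
#: keyed by gender and baseline-age bracket.
BMR_COEFFICIENTS: dict[tuple[str, str], tuple[float, float]] = {
    ("boy", "3-9"): (22.706, 504.3),
    ("boy", "10-18"): (17.686, 658.2),
    ("girl", "3-9"): (20.315, 485.9),
    ("girl", "10-18"): (13.384, 692.6),
}


class InvalidParameterError(ValueError):
    """A model parameter is outside its admissible range."""


class SimulationDivergenceError(RuntimeError):
    """A child's weight left the physically meaningful range."""


class UnsupportedAgeError(ValueError):
    """Age outside the 3-18 range covered by the child BMR equations."""


# ---------------------------------------------------------------------------
# Parameters and per-child record types
# ---------------------------------------------------------------------------


@dataclass
class ModelParams:
    """Tunable constants of the energy-balance / social-norm model.

    Parameters
    ----------
    intent_pab : float
        Intent to change physical-activity behaviour: PAL units gained per
        kg/m^2 of positive discrepancy between BMI and individual ideal BMI.
    intent_eb : float
        Intent to change eating behaviour: kcal/day added per kg/m^2 of
        discrepancy. Negative by sign convention (a child above their ideal
        eats less).
    kcal_per_kg : float
        Energy content of one kg of body-weight change (7700 kcal/kg).
    days_per_month : float
        Days per model month (365/12).
    w_hb : float
        Weight of healthy-BMI knowledge in the individual ideal BMI, in
        [0, 1]; the perceived social norm carries the complement.
    pal_floor, tdei_floor : float
        Behavioural floors preventing unphysical divergence under extreme
        discrepancies; floor events are counted on the trajectory.
    """

    intent_pab: float = 0.05
    intent_eb: float = -50.0
    kcal_per_kg: float = 7700.0
    days_per_month: float = 365.0 / 12.0
    w_hb: float = 0.5
    pal_floor: float = 1.0
    tdei_floor: float = 500.0

    def __post_init__(self) -> None:
        if self.intent_pab < 0:
            raise InvalidParameterError("intent_pab must be >= 0")
        if self.intent_eb > 0:
            raise InvalidParameterError("intent_eb must be <= 0")
        if not 0.0 <= self.w_hb <= 1.0:
            raise InvalidParameterError(f"w_hb must lie in [0, 1], got {self.w_hb}")
        if self.kcal_per_kg <= 0:
            raise InvalidParameterError("kcal_per_kg must be positive")


@dataclass(frozen=True)
class ChildBaseline:
    """Immutable per-child attributes fixed at month 0."""

    id: str
    gender: Gender
    age0: int
    height0: float
    pal0: float
    tdei0: float
    scib: float
    healthy_bmi: float

    def __post_init__(self) -> None:
        if self.height0 <= 0:
            raise InvalidParameterError(f"{self.id}: height0 must be positive")
        if self.tdei0 <= 0:
            raise InvalidParameterError(f"{self.id}: tdei0 must be positive")
        if not 10 <= self.scib <= 40:
            raise InvalidParameterError(f"{self.id}: scib {self.scib} outside [10, 40]")
        if not 10 <= self.healthy_bmi <= 30:
            raise InvalidParameterError(
                f"{self.id}: healthy_bmi {self.healthy_bmi} outside [10, 30]"
            )


@dataclass
class ChildState:
    """Per-child dynamic state at one month."""

    weight: float
    bmi: float
    bmr: float
    pal: float
    tdei: float
    tdee: float
    norm: float
    iib: float = float("nan")
    discrepancy: float = float("nan")


# ---------------------------------------------------------------------------
# Columnar population container
# ---------------------------------------------------------------------------


@dataclass
class Population:
    """Columnar container of child baselines (one entry per child).

    The simulator operates on this array view for speed; individual
    :class:`ChildBaseline` records can be reconstructed with
    :meth:`children` for inspection or small-scale work.
    """

    ids: np.ndarray
    community: np.ndarray
    gender: np.ndarray
    age0: np.ndarray
    height0: np.ndarray
    weight0: np.ndarray
    pal0: np.ndarray
    tdei0: np.ndarray
    scib: np.ndarray
    healthy_bmi: np.ndarray
    perception: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = len(self.ids)
        for name in (
            "community",
            "gender",
            "age0",
            "height0",
            "weight0",
            "pal0",
            "tdei0",
            "scib",
            "healthy_bmi",
        ):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"column {name!r} has shape {arr.shape}, expected ({n},)")
            setattr(self, name, arr)
        self.ids = np.asarray(self.ids)
        if n == 0:
            raise ValueError("population must contain at least one child")

    def __len__(self) -> int:
        return len(self.ids)

    def take(self, index: np.ndarray) -> "Population":
        """Reindex (e.g. a bootstrap resample); ids are kept as-is."""
        kw = {}
        for name in (
            "ids",
            "community",
            "gender",
            "age0",
            "height0",
            "weight0",
            "pal0",
            "tdei0",
            "scib",
            "healthy_bmi",
        ):
            kw[name] = getattr(self, name)[index]
        if self.perception is not None:
            kw["perception"] = self.perception[index]
        return Population(**kw)

    def children(self) -> Iterator[ChildBaseline]:
        for i in range(len(self)):
            yield ChildBaseline(
                id=str(self.ids[i]),
                gender=str(self.gender[i]),  # type: ignore[arg-type]
                age0=int(self.age0[i]),
                height0=float(self.height0[i]),
                pal0=float(self.pal0[i]),
                tdei0=float(self.tdei0[i]),
                scib=float(self.scib[i]),
                healthy_bmi=float(self.healthy_bmi[i]),
            )

    @classmethod
    def from_children(
        cls,
        baselines: Sequence[ChildBaseline],
        weights: Sequence[float],
        community: str = "group",
    ) -> "Population":
        """Build a population from per-child records and baseline weights."""
        return cls(
            ids=np.array([c.id for c in baselines]),
            community=np.array([community] * len(baselines)),
            gender=np.array([c.gender for c in baselines]),
            age0=np.array([c.age0 for c in baselines], dtype=int),
            height0=np.array([c.height0 for c in baselines], dtype=float),
            weight0=np.asarray(weights, dtype=float),
            pal0=np.array([c.pal0 for c in baselines], dtype=float),
            tdei0=np.array([c.tdei0 for c in baselines], dtype=float),
            scib=np.array([c.scib for c in baselines], dtype=float),
            healthy_bmi=np.array([c.healthy_bmi for c in baselines], dtype=float),
        )


@dataclass
class StateArrays:
    """Synchronous group state at one month (arrays over children)."""

    weight: np.ndarray
    bmi: np.ndarray
    bmr: np.ndarray
    pal: np.ndarray
    tdei: np.ndarray
    tdee: np.ndarray
    norm: np.ndarray
    iib: np.ndarray
    discrepancy: np.ndarray

    def child_state(self, i: int) -> ChildState:
        return ChildState(
            weight=float(self.weight[i]),
            bmi=float(self.bmi[i]),
            bmr=float(self.bmr[i]),
            pal=float(self.pal[i]),
            tdei=float(self.tdei[i]),
            tdee=float(self.tdee[i]),
            norm=float(self.norm[i]),
            iib=float(self.iib[i]),
            discrepancy=float(self.discrepancy[i]),
        )


@dataclass
class GroupState:
    """State of one norm-sharing group at month ``month``."""

    state: StateArrays
    median_bmi: float
    month: int


@dataclass
class InterventionAssignment:
    """Fixed per-run behavioural intervention deltas and who receives them."""

    delta_pal: float
    delta_kcal: float
    mask: np.ndarray  # boolean, one entry per child

    def pal_deltas(self, n: int) -> np.ndarray:
        return np.where(self.mask, self.delta_pal, 0.0)

    def kcal_deltas(self, n: int) -> np.ndarray:
        return np.where(self.mask, self.delta_kcal, 0.0)


@dataclass
class Trajectory:
    """Month-indexed group-median BMI series (index 0 = baseline)."""

    median_bmi: np.ndarray
    history: Optional[list[GroupState]] = None
    pal_floor_events: int = 0
    tdei_floor_events: int = 0

    @property
    def months(self) -> int:
        return len(self.median_bmi) - 1


# ---------------------------------------------------------------------------
# The model equations as pure operations
# ---------------------------------------------------------------------------


def individual_ideal_bmi(hb, norm, w_hb: float):
    """Blend healthy-BMI knowledge and the perceived norm.

    ``w_hb = 0.5`` is the model's default (knowledge activated); ``w_hb = 0``
    leaves the ideal entirely to the social norm, ``w_hb = 1`` entirely to
    knowledge of a healthy BMI.
    """
    if not 0.0 <= w_hb <= 1.0:
        raise InvalidParameterError(f"w_hb must lie in [0, 1], got {w_hb}")
    return w_hb * np.asarray(hb) + (1.0 - w_hb) * np.asarray(norm)


def update_pal(pal0, intent_pab: float, discrepancy, delta_pal_intervention=0.0, floor: float = 1.0):
    """Next physical activity level; anchored at baseline PAL, floored.

    Returns ``(pal_next, n_floored)``.
    """
    raw = np.asarray(pal0) + np.asarray(delta_pal_intervention) + intent_pab * np.asarray(discrepancy)
    floored = np.maximum(raw, floor)
    return floored, int(np.count_nonzero(raw < floor))


def update_tdei(tdei0, intent_eb: float, discrepancy, delta_kcal_intervention=0.0, floor: float = 500.0):
    """Next total daily energy intake; anchored at baseline TDEI, floored.

    Returns ``(tdei_next, n_floored)``.
    """
    raw = np.asarray(tdei0) + np.asarray(delta_kcal_intervention) + intent_eb * np.asarray(discrepancy)
    floored = np.maximum(raw, floor)
    return floored, int(np.count_nonzero(raw < floor))


def update_tdee(bmr_t, pal_next):
    """Next total daily energy expenditure: current BMR times next PAL.

    The index mix (BMR at t, PAL at t+1) is deliberate and matches the
    model's difference-equation form.
    """
    return np.asarray(bmr_t) * np.asarray(pal_next)


def update_weight(w, tdei_next, tdee_next, params: ModelParams):
    """Next weight from the monthly energy balance.

    With default constants the increment is exactly
    ``73 * (TDEI - TDEE) / 18480`` kg.
    """
    w_next = np.asarray(w) + (np.asarray(tdei_next) - np.asarray(tdee_next)) * (
        params.days_per_month / params.kcal_per_kg
    )
    return w_next


def bmi_from_weight(w_next, height0):
    """BMI with height frozen at its baseline value."""
    h = np.asarray(height0, dtype=float)
    if np.any(h <= 0):
        raise InvalidParameterError("height0 must be positive")
    return np.asarray(w_next) / h**2


def bmr_children(gender, age0, w_next):
    """Child basal metabolic rate (kcal/day), linear in weight.

    The gender x age bracket is chosen from the *baseline* age (3-9 vs
    10-18); ages are never advanced during a run.
    """
    gender = np.asarray(gender)
    age0 = np.asarray(age0)
    w = np.asarray(w_next, dtype=float)
    if np.any(age0 < 3) or np.any(age0 > 18):
        bad = np.asarray(age0)[(np.asarray(age0) < 3) | (np.asarray(age0) > 18)]
        raise UnsupportedAgeError(f"age(s) {np.unique(bad)} outside the supported 3-18 range")
    young = age0 <= 9
    boy = gender == "boy"
    slope = np.select(
        [boy & young, boy & ~young, ~boy & young],
        [22.706, 17.686, 20.315],
        default=13.384,
    )
    intercept = np.select(
        [boy & young, boy & ~young, ~boy & young],
        [504.3, 658.2, 485.9],
        default=692.6,
    )
    out = slope * w + intercept
    return out if out.shape else float(out)


def group_median_bmi(bmis) -> float:
    """Group-level median BMI (even n: mean of the middle two)."""
    arr = np.asarray(bmis, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot take the median BMI of an empty group")
    return float(np.median(arr))


def perceived_norm(median_bmi, scib0):
    """Per-child perceived norm: mean of group median BMI and baseline SCIB."""
    return (np.asarray(median_bmi) + np.asarray(scib0)) / 2.0


# ---------------------------------------------------------------------------
# Stepper and simulator
# ---------------------------------------------------------------------------


def init_group(pop: Population, params: ModelParams) -> GroupState:
    """Month-0 state: BMI and BMR from baseline weight, TDEE = BMR x PAL,
    norm from the baseline group median and each child's SCIB."""
    bmi0 = bmi_from_weight(pop.weight0, pop.height0)
    bmr0 = bmr_children(pop.gender, pop.age0, pop.weight0)
    median0 = group_median_bmi(bmi0)
    norm0 = perceived_norm(median0, pop.scib)
    n = len(pop)
    state = StateArrays(
        weight=pop.weight0.astype(float).copy(),
        bmi=np.asarray(bmi0, dtype=float),
        bmr=np.asarray(bmr0, dtype=float),
        pal=pop.pal0.astype(float).copy(),
        tdei=pop.tdei0.astype(float).copy(),
        tdee=np.asarray(bmr0, dtype=float) * pop.pal0,
        norm=np.asarray(norm0, dtype=float),
        iib=np.full(n, np.nan),
        discrepancy=np.full(n, np.nan),
    )
    return GroupState(state=state, median_bmi=median0, month=0)


def step_group(
    group: GroupState,
    pop: Population,
    params: ModelParams,
    intervention: Optional[InterventionAssignment] = None,
) -> tuple[GroupState, int, int]:
    """Advance the whole group one month, synchronously.

    All children update from the common month-``t`` state; the group median
    and every child's perceived norm are recomputed only after all individual
    updates. Returns the new state plus PAL / TDEI floor-event counts.
    """
    s = group.state
    n = len(pop)
    if intervention is not None:
        dpal = intervention.pal_deltas(n)
        dkcal = intervention.kcal_deltas(n)
    else:
        dpal = 0.0
        dkcal = 0.0

    iib = individual_ideal_bmi(pop.healthy_bmi, s.norm, params.w_hb)
    discrepancy = s.bmi - iib
    pal_next, n_pal = update_pal(
        pop.pal0, params.intent_pab, discrepancy, dpal, floor=params.pal_floor
    )
    tdei_next, n_tdei = update_tdei(
        pop.tdei0, params.intent_eb, discrepancy, dkcal, floor=params.tdei_floor
    )
    tdee_next = update_tdee(s.bmr, pal_next)
    w_next = update_weight(s.weight, tdei_next, tdee_next, params)
    if np.any(w_next <= 0):
        i = int(np.argmax(w_next <= 0))
        raise SimulationDivergenceError(
            f"child {pop.ids[i]!r}: weight {w_next[i]:.2f} kg <= 0 at month {group.month + 1}"
        )
    bmi_next = bmi_from_weight(w_next, pop.height0)
    bmr_next = bmr_children(pop.gender, pop.age0, w_next)
    median_next = group_median_bmi(bmi_next)
    norm_next = perceived_norm(median_next, pop.scib)

    new = GroupState(
        state=StateArrays(
            weight=w_next,
            bmi=bmi_next,
            bmr=np.asarray(bmr_next, dtype=float),
            pal=pal_next,
            tdei=tdei_next,
            tdee=tdee_next,
            norm=np.asarray(norm_next, dtype=float),
            iib=np.asarray(iib, dtype=float),
            discrepancy=discrepancy,
        ),
        median_bmi=median_next,
        month=group.month + 1,
    )
    return new, n_pal, n_tdei


def simulate(
    pop: Population,
    params: ModelParams,
    months: int,
    intervention: Optional[InterventionAssignment] = None,
    record_history: bool = False,
) -> Trajectory:
    """Run the group for ``months`` months; return the median-BMI series.

    The returned series has length ``months + 1`` with index 0 the baseline
    median. With ``record_history`` the full per-month :class:`GroupState`
    list is attached.
    """
    if months < 0:
        raise InvalidParameterError("months must be >= 0")
    group = init_group(pop, params)
    medians = np.empty(months + 1)
    medians[0] = group.median_bmi
    history = [group] if record_history else None
    pal_events = tdei_events = 0
    for _ in range(months):
        group, n_pal, n_tdei = step_group(group, pop, params, intervention)
        medians[group.month] = group.median_bmi
        pal_events += n_pal
        tdei_events += n_tdei
        if record_history:
            history.append(group)  # type: ignore[union-attr]
    if pal_events or tdei_events:
        logger.info(
            "behavioural floors hit: %d PAL, %d TDEI events over %d months",
            pal_events,
            tdei_events,
            months,
        )
    return Trajectory(
        median_bmi=medians,
        history=history,
        pal_floor_events=pal_events,
        tdei_floor_events=tdei_events,
    )
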