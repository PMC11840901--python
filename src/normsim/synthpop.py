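"""Synthetic populations with the marginal structure of the study communities.

The six rural communities (and their pool) are known only through printed
baseline descriptives: counts, median/IQR of age, BMI, sociocultural ideal
BMI, energy intake and basal metabolic rate, and categorical fractions for
activity level and the BMI-vs-ideal discrepancy sign. This module turns
those marginals into reproducible child-level populations:

* age: discrete distribution on 8-13 years fitted to the printed
  median/IQR (discretised-normal family, grid-searched);
* BMI: log-normal, median anchored exactly, spread least-squares fitted to
  the IQR endpoints on the log scale;
* height: growth-reference median for age and gender times log-normal noise
  (CV 4%); weight follows from BMI and height;
* activity level: binary 1.46 / 1.7 split at the printed low fraction;
* weight perception: three categories whose counts reproduce the printed
  discrepancy-sign fractions exactly, assigned by a Gaussian-copula latent
  score so that heavier children are more likely to feel "too heavy";
* sociocultural ideal BMI: equal to BMI where perception is "about right",
  otherwise offset by a half-normal deviation in the signed direction;
* healthy BMI: growth-reference median BMI-for-age (or a constant override);
* baseline intake: basal metabolic rate x activity level (baseline energy
  balance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import Population, bmr_children

_PERCEPTIONS = ("too_thin", "about_right", "too_heavy")

#: Approximate growth-reference median height (m) by age and gender.
HEIGHT_REFERENCE: dict[str, dict[int, float]] = {
    "boy": {8: 1.280, 9: 1.335, 10: 1.385, 11: 1.435, 12: 1.490, 13: 1.560},
    "girl": {8: 1.270, 9: 1.325, 10: 1.385, 11: 1.450, 12: 1.515, 13: 1.570},
}

#: Approximate growth-reference median BMI-for-age (kg/m^2) by age and gender,
#: used as each child's "knowledge of a healthy BMI".
HEALTHY_BMI_TABLE: dict[str, dict[int, float]] = {
    "boy": {8: 15.7, 9: 16.0, 10: 16.4, 11: 16.9, 12: 17.5, 13: 18.2},
    "girl": {8: 15.7, 9: 16.1, 10: 16.6, 11: 17.2, 12: 18.0, 13: 18.8},
}


@dataclass(frozen=True)
class CommunityMarginals:
    """Printed baseline descriptives for one community (or the pool)."""

    name: str
    n: int
    age_median_iqr: tuple[float, float, float]  # (median, q25, q75)
    bmi_median_iqr: tuple[float, float, float]
    scib_median_iqr: tuple[float, float, float]
    discrepancy_fractions: tuple[float, float, float]  # (<0, =0, >0)
    pal_fraction_low: float
    tdei_median_iqr: tuple[float, float, float]
    bmr_median_iqr: tuple[float, float, float]
    overweight_pct: float = float("nan")

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("community size must be positive")
        total = sum(self.discrepancy_fractions)
        if abs(total - 1.0) > 0.002:  # printed rounding allowance
            raise ValueError(
                f"{self.name}: discrepancy fractions sum to {total:.4f}, not 1"
            )
        if not 0.0 <= self.pal_fraction_low <= 1.0:
            raise ValueError("pal_fraction_low must lie in [0, 1]")
        for label in ("age", "bmi", "scib", "tdei", "bmr"):
            m, lo, hi = getattr(self, f"{label}_median_iqr")
            if not lo <= m <= hi:
                raise ValueError(f"{self.name}: {label} IQR bounds inverted")


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic-population generator."""

    seed: int = 0
    gender_split: float = 0.5  # proportion of boys
    scib_offset_scale: float = 1.5  # kg/m^2, half-normal deviation scale
    height_cv: float = 0.04
    bmi_perception_corr: float = 0.5  # Gaussian-copula latent correlation
    bmi_range: tuple[float, float] = (12.0, 35.0)  # plausibility truncation, kg/m^2
    pal_levels: tuple[float, float] = (1.46, 1.7)
    height_reference: dict = field(default_factory=lambda: HEIGHT_REFERENCE)
    healthy_bmi_table: dict = field(default_factory=lambda: HEALTHY_BMI_TABLE)
    healthy_bmi_constant: Optional[float] = None

    def __post_init__(self) -> None:
        if self.scib_offset_scale <= 0:
            raise ValueError("scib_offset_scale must be positive")


def table2_marginals() -> dict[str, CommunityMarginals]:
    """The packaged community descriptives: community_1..6 plus 'pooled'."""
    with resources.files("normsim.data").joinpath("community_marginals.csv").open() as fh:
        df = pd.read_csv(fh)
    out: dict[str, CommunityMarginals] = {}
    for row in df.itertuples(index=False):
        out[row.community] = CommunityMarginals(
            name=row.community,
            n=int(row.n),
            age_median_iqr=(row.age_median, row.age_q1, row.age_q3),
            bmi_median_iqr=(row.bmi_median, row.bmi_q1, row.bmi_q3),
            scib_median_iqr=(row.scib_median, row.scib_q1, row.scib_q3),
            discrepancy_fractions=(
                row.disc_lt0_pct / 100.0,
                row.disc_eq0_pct / 100.0,
                row.disc_gt0_pct / 100.0,
            ),
            pal_fraction_low=row.pal_low_pct / 100.0,
            tdei_median_iqr=(row.tdei_median, row.tdei_q1, row.tdei_q3),
            bmr_median_iqr=(row.bmr_median, row.bmr_q1, row.bmr_q3),
            overweight_pct=row.overweight_pct,
        )
    return out


# ---------------------------------------------------------------------------
# Distribution fitting helpers
# ---------------------------------------------------------------------------

_Z75 = stats.norm.ppf(0.75)


def lognormal_from_median_iqr(median: float, q25: float, q75: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal: median anchored, sigma LS-fit to the IQR.

    Printed quantiles are generally not exactly log-normal-consistent, so
    sigma is the least-squares compromise between the two IQR endpoints on
    the log scale while the median is reproduced exactly.
    """
    if not 0 < q25 <= median <= q75:
        raise ValueError("quantiles must satisfy 0 < q25 <= median <= q75")
    mu = np.log(median)
    sigma = (np.log(q75 / median) + np.log(median / q25)) / (2.0 * _Z75)
    return mu, float(max(sigma, 1e-9))


def age_weights_from_median_iqr(
    median: float, q25: float, q75: float, support: tuple[int, ...] = (8, 9, 10, 11, 12, 13)
) -> np.ndarray:
    """Probability weights on the integer age support matching the printed
    median/IQR as closely as possible.

    A discretised-normal family (location x scale grid) is searched; the
    quantile of a candidate is the smallest support point whose CDF reaches
    the probability. Half-integer printed quantiles (e.g. 9.5) are handled
    by the squared-error objective.
    """
    pts = np.asarray(support, dtype=float)
    best, best_err = None, np.inf
    for loc in np.arange(pts[0] - 0.5, pts[-1] + 0.51, 0.05):
        for scale in np.arange(0.6, 3.01, 0.05):
            w = stats.norm.pdf(pts, loc, scale)
            w = w / w.sum()
            cdf = np.cumsum(w)
            q = [pts[np.searchsorted(cdf, p)] for p in (0.25, 0.5, 0.75)]
            err = (q[0] - q25) ** 2 + (q[1] - median) ** 2 + (q[2] - q75) ** 2
            if err < best_err - 1e-12:
                best, best_err = w, err
    return best


# ---------------------------------------------------------------------------
# Attribute assignment rules
# ---------------------------------------------------------------------------


def assign_pal(n: int, fraction_low: float, rng: np.random.Generator,
               levels: tuple[float, float] = (1.46, 1.7)) -> np.ndarray:
    """Binary physical activity level: low with probability ``fraction_low``."""
    if not 0.0 <= fraction_low <= 1.0:
        raise ValueError("fraction_low must lie in [0, 1]")
    low = rng.random(n) < fraction_low
    return np.where(low, levels[0], levels[1])


def assign_perception(
    bmi: np.ndarray,
    fractions: tuple[float, float, float],
    rng: np.random.Generator,
    corr: float = 0.5,
) -> np.ndarray:
    """Three-level weight perception with exact category counts.

    ``fractions`` are the (too_thin, about_right, too_heavy) proportions;
    counts are ``round(f * n)`` (remainder to "about right"). Categories are
    cut on a latent score correlated with the BMI rank (Gaussian copula,
    correlation ``corr``), so heavier children tend to feel "too heavy".
    """
    n = len(bmi)
    f_thin, _, f_heavy = fractions
    k_thin = int(round(f_thin * n))
    k_heavy = int(round(f_heavy * n))
    ranks = stats.rankdata(bmi, method="ordinal")
    z_bmi = stats.norm.ppf(ranks / (n + 1.0))
    latent = corr * z_bmi + np.sqrt(1.0 - corr**2) * rng.standard_normal(n)
    order = np.argsort(latent)
    out = np.full(n, "about_right", dtype=object)
    out[order[:k_thin]] = "too_thin"
    if k_heavy > 0:
        out[order[-k_heavy:]] = "too_heavy"
    return out.astype(str)


def derive_scib(
    bmi: np.ndarray,
    perception: np.ndarray,
    offset_scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sociocultural ideal BMI from own BMI and weight perception.

    "about right" pins the ideal to the child's BMI (discrepancy exactly
    zero); "too heavy"/"too thin" offset it below/above the BMI by a
    half-normal deviation of scale ``offset_scale`` kg/m^2.
    """
    bmi = np.asarray(bmi, dtype=float)
    perception = np.asarray(perception)
    delta = np.abs(rng.normal(0.0, offset_scale, size=len(bmi)))
    scib = bmi.copy()
    scib[perception == "too_heavy"] -= delta[perception == "too_heavy"]
    scib[perception == "too_thin"] += delta[perception == "too_thin"]
    return scib


def assign_healthy_bmi(
    age,
    gender,
    table: dict[str, dict[int, float]] = HEALTHY_BMI_TABLE,
    constant: Optional[float] = None,
) -> np.ndarray:
    """Healthy-BMI knowledge: BMI-for-age reference median (or a constant)."""
    age = np.atleast_1d(np.asarray(age, dtype=int))
    gender = np.atleast_1d(np.asarray(gender))
    if constant is not None:
        return np.full(len(age), float(constant))
    out = np.empty(len(age))
    for i in range(len(age)):
        per_gender = table[str(gender[i])]
        if int(age[i]) not in per_gender:
            raise KeyError(f"age {age[i]} outside the healthy-BMI table range")
        out[i] = per_gender[int(age[i])]
    return out


def baseline_tdei(bmr0, pal0) -> np.ndarray:
    """Baseline intake under baseline energy balance: BMR x PAL."""
    return np.asarray(bmr0, dtype=float) * np.asarray(pal0, dtype=float)


def overweight_fraction(pop: Population, cutoff: float = 19.2) -> float:
    """Fraction of children at or above the overweight BMI cut-off."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    bmi = pop.weight0 / pop.height0**2
    return float(np.mean(bmi >= cutoff))


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------


def generate_community(
    marginals: CommunityMarginals,
    config: GeneratorConfig,
    n: Optional[int] = None,
) -> Population:
    """Generate one community's children from its printed marginals.

    Fully determined by ``config.seed`` (independent sub-streams per
    attribute, so e.g. changing the SCIB scale does not reshuffle BMIs).
    """
    n = marginals.n if n is None else n
    ss = (
        config.seed
        if isinstance(config.seed, np.random.SeedSequence)
        else np.random.SeedSequence(config.seed)
    )
    streams = [np.random.default_rng(s) for s in ss.spawn(6)]
    rng_gender, rng_age, rng_bmi, rng_height, rng_pal, rng_scib = streams

    gender = np.where(rng_gender.random(n) < config.gender_split, "boy", "girl").astype(str)

    ages_support = tuple(sorted(config.healthy_bmi_table["boy"].keys()))
    weights = age_weights_from_median_iqr(*marginals.age_median_iqr, support=ages_support)
    age = rng_age.choice(np.asarray(ages_support), size=n, p=weights)

    mu, sigma = lognormal_from_median_iqr(*marginals.bmi_median_iqr)
    # Stratified inverse-CDF draw: log-normal marginals (truncated to a
    # plausible child BMI range) with sample quantiles that track the fitted
    # distribution even at community sizes in the tens — the generator's job
    # is to reproduce printed marginals, not to add sampling noise on top.
    lo_q, hi_q = stats.norm.cdf(
        (np.log(config.bmi_range) - mu) / sigma
    )
    u = (rng_bmi.permutation(n) + rng_bmi.random(n)) / n
    bmi = np.exp(mu + sigma * stats.norm.ppf(lo_q + (hi_q - lo_q) * u))

    href = np.array(
        [config.height_reference[g][int(a)] for g, a in zip(gender, age)]
    )
    sln = np.sqrt(np.log1p(config.height_cv**2))
    height = href * rng_height.lognormal(0.0, sln, size=n)
    weight = bmi * height**2
    # Re-derive BMI from the stored weight/height so that downstream
    # consumers recomputing W/H^2 see bit-identical values (the "discrepancy
    # exactly zero" construction depends on this).
    bmi = weight / height**2

    pal = assign_pal(n, marginals.pal_fraction_low, rng_pal, levels=config.pal_levels)
    perception = assign_perception(
        bmi, marginals.discrepancy_fractions, rng_scib, corr=config.bmi_perception_corr
    )
    scib = derive_scib(bmi, perception, config.scib_offset_scale, rng_scib)
    scib = np.clip(scib, 10.0, 40.0)  # keep pathological tails in-range
    healthy_bmi = assign_healthy_bmi(
        age, gender, table=config.healthy_bmi_table, constant=config.healthy_bmi_constant
    )
    bmr0 = bmr_children(gender, age, weight)
    tdei0 = baseline_tdei(bmr0, pal)

    ids = np.array([f"{marginals.name}-{i:04d}" for i in range(n)])
    return Population(
        ids=ids,
        community=np.full(n, marginals.name),
        gender=gender,
        age0=age.astype(int),
        height0=height,
        weight0=weight,
        pal0=pal,
        tdei0=tdei0,
        scib=scib,
        healthy_bmi=healthy_bmi,
        perception=perception,
    )


def concat_populations(pops: list[Population], community: Optional[str] = None) -> Population:
    """Concatenate populations; optionally relabel as one norm-sharing group."""
    def cat(name):
        return np.concatenate([getattr(p, name) for p in pops])

    comm = cat("community") if community is None else np.full(
        sum(len(p) for p in pops), community
    )
    perception = (
        cat("perception") if all(p.perception is not None for p in pops) else None
    )
    return Population(
        ids=cat("ids"),
        community=comm,
        gender=cat("gender"),
        age0=cat("age0"),
        height0=cat("height0"),
        weight0=cat("weight0"),
        pal0=cat("pal0"),
        tdei0=cat("tdei0"),
        scib=cat("scib"),
        healthy_bmi=cat("healthy_bmi"),
        perception=perception,
    )


def generate_all_communities(config: GeneratorConfig) -> dict[str, Population]:
    """All six communities, each from its own seeded sub-stream."""
    marg = table2_marginals()
    ss = (
        config.seed
        if isinstance(config.seed, np.random.SeedSequence)
        else np.random.SeedSequence(config.seed)
    )
    seeds = ss.spawn(6)
    out = {}
    for i, name in enumerate(sorted(k for k in marg if k != "pooled")):
        cfg = GeneratorConfig(**{**config.__dict__, "seed": seeds[i]})
        out[name] = generate_community(marg[name], cfg)
    return out


def generate_pooled(config: GeneratorConfig) -> Population:
    """The pooled run: the six communities concatenated into one group."""
    pops = generate_all_communities(config)
    return concat_populations(list(pops.values()), community="pooled")
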