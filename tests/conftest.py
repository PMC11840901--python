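import numpy as np
import pytest

from normsim.core import ModelParams, Population
from normsim.synthpop import GeneratorConfig, generate_pooled


def single_girl_population() -> Population:
    """The single-child reference case: girl, age 10, 1.40 m, 40 kg,
    SCIB 19, healthy BMI 17, PAL 1.46, baseline intake at energy balance."""
    bmr0 = 13.384 * 40.0 + 692.6  # 1227.96
    return Population(
        ids=np.array(["g1"]),
        community=np.array(["test"]),
        gender=np.array(["girl"]),
        age0=np.array([10]),
        height0=np.array([1.40]),
        weight0=np.array([40.0]),
        pal0=np.array([1.46]),
        tdei0=np.array([bmr0 * 1.46]),
        scib=np.array([19.0]),
        healthy_bmi=np.array([17.0]),
    )


def hand_recurrence(months: int, w_hb: float = 0.0) -> list[float]:
    """Independent scalar evaluation of the monthly recurrence for the
    single-girl case. Deliberately plain arithmetic, no package calls."""
    H = 1.40
    W = 40.0
    SCIB, HB = 19.0, 17.0
    PAL0 = 1.46
    BMR = 13.384 * W + 692.6
    TDEI0 = BMR * PAL0
    bmi = W / H**2
    norm = (bmi + SCIB) / 2.0  # single child: median is own BMI
    series = [bmi]
    for _ in range(months):
        iib = w_hb * HB + (1.0 - w_hb) * norm
        disc = bmi - iib
        pal = PAL0 + 0.05 * disc
        tdei = TDEI0 - 50.0 * disc
        tdee = BMR * pal
        W = W + 73.0 * (tdei - tdee) / 18480.0
        bmi = W / H**2
        BMR = 13.384 * W + 692.6
        norm = (bmi + SCIB) / 2.0
        series.append(bmi)
    return series


@pytest.fixture
def oracle_pop() -> Population:
    return single_girl_population()


@pytest.fixture
def homogeneous_pop() -> Population:
    """Five identical girls sitting exactly at the model's fixed point:
    SCIB = healthy BMI = baseline BMI, intake balancing expenditure."""
    n = 5
    h, w = 1.40, 39.2  # BMI exactly 20.0
    bmr0 = 13.384 * w + 692.6
    return Population(
        ids=np.array([f"c{i}" for i in range(n)]),
        community=np.array(["test"] * n),
        gender=np.array(["girl"] * n),
        age0=np.full(n, 10),
        height0=np.full(n, h),
        weight0=np.full(n, w),
        pal0=np.full(n, 1.46),
        tdei0=np.full(n, bmr0 * 1.46),
        scib=np.full(n, 20.0),
        healthy_bmi=np.full(n, 20.0),
    )


@pytest.fixture(scope="session")
def pooled_pop() -> Population:
    return generate_pooled(GeneratorConfig(seed=123))


@pytest.fixture
def params() -> ModelParams:
    return ModelParams()
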