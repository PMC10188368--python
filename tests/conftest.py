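import numpy as np
import pandas as pd
import pytest

from perimort import IntervalCountTable


def make_table(deaths, total, c1=0.0, survey_id="s1"):
    """Interval table with censoring only in interval 1 and at day 10."""
    deaths = np.asarray(deaths, dtype=float)
    censored = np.zeros(10)
    censored[0] = c1
    n10 = total - c1 - deaths[:9].sum()
    censored[9] = n10 - deaths[9]
    return IntervalCountTable(
        deaths=deaths, censored=censored, total_pregnancies=total, survey_id=survey_id
    )


def make_random_table(rng, min_total=500, max_total=20000):
    """Random but realistic interval table: declining risks, some zeros."""
    total = int(rng.integers(min_total, max_total))
    q_sb = rng.uniform(0.005, 0.04)
    q01 = rng.uniform(0.002, 0.03)
    base = rng.uniform(0.0005, 0.004)
    decline = rng.uniform(0.5, 0.9)
    deaths = np.zeros(10)
    c1 = float(rng.binomial(total, 0.03))
    n = total - c1
    deaths[0] = float(rng.binomial(int(n), q_sb))
    n -= deaths[0]
    deaths[1] = float(rng.binomial(int(n), q01))
    n -= deaths[1]
    for j in range(2, 10):
        deaths[j] = float(rng.binomial(int(n), base * decline ** (j - 2)))
        n -= deaths[j]
    return make_table(deaths, total, c1=c1)


@pytest.fixture
def simple_table():
    """1000 pregnancies: 20 stillbirths, 10 deaths on days 0-1, 1 per day 2-6."""
    return make_table([20, 10, 1, 1, 1, 1, 1, 0, 0, 0], total=1000)


@pytest.fixture
def heaped_table():
    """Day-7 heap: deaths on days 5-9 are 4, 4, 12, 2, 3 (index 2.4)."""
    return make_table([100, 96, 30, 20, 12, 4, 4, 12, 2, 3], total=5000)


@pytest.fixture
def records_csv():
    return (
        "survey_id,record_id,gestation_months,conception_offset_months,outcome,"
        "child_alive,age_at_death_days,current_age_months,weight\n"
        "s1,r1,9,20,livebirth,true,,11,1.0\n"
        "s1,r2,9,30,livebirth,false,3,,1.5\n"
        "s1,r3,8,15,stillbirth,,,,2.0\n"
    )
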