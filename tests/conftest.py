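import numpy as np
import pandas as pd
import pytest

import prefiv as pv


def make_table(rows):
    """Build a PatientTable from (hospital, treated, outcome) triples,
    filling the case-mix columns with plausible constants plus jitter so
    designs stay full rank."""
    n = len(rows)
    rng = np.random.default_rng(len(rows))
    df = pd.DataFrame(rows, columns=["hospital_id", "treated", "good_outcome"])
    df["age"] = 70.0 + rng.normal(0, 5, n).round(3)
    df["male"] = rng.integers(0, 2, n)
    df["nihss"] = rng.integers(5, 25, n)
    df["onset_to_ed_min"] = (120.0 + rng.normal(0, 30, n)).clip(0).round(3)
    for c in ["prev_stroke", "atrial_fib", "hypertension", "hypercholesterolemia"]:
        df[c] = rng.integers(0, 2, n)
    return pv.PatientTable(df)


def two_by_two_table(n11, n10, n01, n00, n_hospitals=2, seed=0):
    """Registry reduction of a 2x2 contingency table: n11/n10 good/bad
    among treated, n01/n00 good/bad among untreated, spread over
    hospitals round-robin."""
    rows = []
    for treated, good, count in [(1, 1, n11), (1, 0, n10), (0, 1, n01), (0, 0, n00)]:
        rows += [(None, treated, good)] * count
    rng = np.random.default_rng(seed)
    rng.shuffle(rows)
    rows = [
        (f"H{i % n_hospitals:02d}", t, g) for i, (_, t, g) in enumerate(rows)
    ]
    return make_table(rows)


@pytest.fixture(scope="session")
def ivt_registry():
    table, truth = pv.generate_registry(pv.make_ivt_like_scenario())
    return table, truth


@pytest.fixture(scope="session")
def ga_registry():
    table, truth = pv.generate_registry(pv.make_ga_like_scenario())
    return table, truth
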