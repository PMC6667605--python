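import io

import pandas as pd
import pytest

import saltscreen as ss


def make_table(rows):
    """Long-format table from (genotype, treatment, replicate, trait, value) tuples."""
    return pd.DataFrame(rows, columns=["genotype", "treatment", "replicate", "trait", "value"])


def table_from_means(means):
    """One-replicate table from {(genotype, treatment, trait): value}."""
    rows = [(g, s, 1, t, v) for (g, s, t), v in means.items()]
    return make_table(rows)


@pytest.fixture
def two_trait_means():
    """One genotype, two traits with ratios 0.5/0.8 (moderate) and 0.25/0.4 (high)."""
    cells = {
        ("g1", "control", "PH"): 10.0, ("g1", "moderate", "PH"): 5.0, ("g1", "high", "PH"): 2.5,
        ("g1", "control", "TRL"): 100.0, ("g1", "moderate", "TRL"): 80.0, ("g1", "high", "TRL"): 40.0,
    }
    return ss.aggregate_means(table_from_means(cells))


@pytest.fixture
def no_effect_means():
    """Every trait identical across treatments: all response ratios are 1."""
    cells = {}
    for g in ("g1", "g2", "g3"):
        for t in ss.TRAIT_SET_PRESETS["all-24"]:
            for s in ("control", "moderate", "high"):
                cells[(g, s, t)] = 10.0
    return ss.aggregate_means(table_from_means(cells))


@pytest.fixture
def small_trial():
    """A reproducible 12-genotype synthetic trial with its truth table."""
    cfg = ss.SimConfig(n_genotypes=12, n_reps=4, seed=42)
    return ss.simulate_trial(cfg)


def read_csv_text(text, **kw):
    return ss.read_trait_table(io.StringIO(text), **kw)
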