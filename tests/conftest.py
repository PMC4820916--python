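import numpy as np
import pandas as pd
import pytest

from lipidrisk import Pedigree, SimulationConfig, simulate_pedigree_cohort


@pytest.fixture(scope="session")
def three_gen_pedigree():
    """A programmatic three-generation pedigree covering the standard
    relationship classes: parent-offspring, siblings, grandparent,
    avuncular, half-siblings, double first cousins, first cousins."""
    rows = [
        # founders
        ("gf1", None, None, 1), ("gm1", None, None, 2),
        ("gf2", None, None, 1), ("gm2", None, None, 2),
        ("s1", None, None, 2), ("s2", None, None, 1),
        ("s3", None, None, 2), ("s4", None, None, 2),
        # generation 2: sibships in two families
        ("a1", "gf1", "gm1", 1), ("a2", "gf1", "gm1", 2), ("a3", "gf1", "gm1", 1),
        ("b1", "gf2", "gm2", 1), ("b2", "gf2", "gm2", 2),
        # half-sibling of a1..a3 through gf1
        ("h1", "gf1", "s1", 1),
        # generation 3
        ("c1", "a1", "s3", 1),          # child of a1
        ("c2", "a1", "s3", 2),          # sibling of c1
        ("d1", "a3", "b2", 1),          # cousin-marriage-free child
        # double first cousins: children of a1 x b2's sibling? simpler:
        # two brothers (a1, a3) are already used; use (a2 x b1) and (a3 x b2)
        ("e1", "b1", "a2", 1),
        ("e2", "a3", "b2", 2),
        ("f1", "s2", "c2", 1),          # great-grandchild of gf1
    ]
    return Pedigree(pd.DataFrame(rows, columns=["id", "father", "mother", "sex"]))


@pytest.fixture(scope="session")
def small_family_cohort():
    """Pedigree cohort with planted effects, modest size (fast fits)."""
    cfg = SimulationConfig(n_families=14, seed=42)
    cohort, ped = simulate_pedigree_cohort(cfg)
    return cfg, cohort, ped


@pytest.fixture(scope="session")
def null_family_cohort():
    """Pedigree cohort with no planted lipid effects and no heritability."""
    cfg = SimulationConfig(
        n_families=20, seed=7, planted_species={}, lipid_heritability=0.0,
        lipid_block_correlation=0.0,
        covariate_log_hr={"age": 0.0, "bmi": 0.0, "prediabetes": 0.0},
    )
    cohort, ped = simulate_pedigree_cohort(cfg)
    return cfg, cohort, ped


def exponential_cox_data(n, beta, rate=0.1, censor_scale=None, seed=0, p=None):
    """Simple proportional-hazards data for oracle comparisons."""
    rng = np.random.default_rng(seed)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    p = len(beta) if p is None else p
    X = rng.normal(size=(n, p))
    eta = X @ beta
    T = rng.exponential(1.0 / (rate * np.exp(eta)))
    if censor_scale is None:
        time, event = T, np.ones(n, dtype=int)
    else:
        C = rng.exponential(censor_scale, n)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
    return time, event, X
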