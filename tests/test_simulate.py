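"""Synthetic-cohort generator: determinism, familial structure, planted effects."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from scipy import stats

from lipidrisk import (
    SimulationConfig,
    simulate_ir_measures,
    simulate_pedigree_cohort,
    simulate_unrelated_cohort,
    tertile_groups,
)
from lipidrisk.simulate import planted_linear_predictor
from lipidrisk.insulin import compute_ir_panel


def sibling_pairs(pedigree):
    """All full-sibling index pairs in record order."""
    ids = pedigree.ids
    idx = {i: k for k, i in enumerate(ids)}
    by_parents = {}
    for i in ids:
        fa, mo = pedigree.parents_of(i)
        if fa is not None and mo is not None:
            by_parents.setdefault((fa, mo), []).append(idx[i])
    pairs = []
    for sibs in by_parents.values():
        for a in range(len(sibs)):
            for b in range(a + 1, len(sibs)):
                pairs.append((sibs[a], sibs[b]))
    return pairs


def sib_correlation(cfg_seed, h2, n_families=120):
    cfg = SimulationConfig(
        n_families=n_families, seed=cfg_seed, lipid_heritability=h2,
        lipid_block_correlation=0.0, n_lipid_species=12, n_candidate_species=3,
    )
    cohort, ped = simulate_pedigree_cohort(cfg)
    pairs = sibling_pairs(ped)
    a, b = zip(*pairs)
    rs = []
    for sp in cfg.species_names:
        x = np.log(cohort[sp].to_numpy())
        rs.append(np.corrcoef(x[list(a)], x[list(b)])[0, 1])
    return float(np.mean(rs)), len(pairs)


class TestDeterminism:
    def test_pedigree_cohort_reproducible(self):
        cfg = SimulationConfig(n_families=6, seed=1, n_lipid_species=20)
        c1, p1 = simulate_pedigree_cohort(cfg)
        c2, p2 = simulate_pedigree_cohort(SimulationConfig(n_families=6, seed=1, n_lipid_species=20))
        pd.testing.assert_frame_equal(c1, c2)
        assert p1.ids == p2.ids

    def test_unrelated_cohort_reproducible(self):
        cfg = SimulationConfig(seed=3, n_unrelated=50, n_lipid_species=15)
        pd.testing.assert_frame_equal(
            simulate_unrelated_cohort(cfg), simulate_unrelated_cohort(cfg)
        )

    def test_ir_measures_reproducible(self):
        cfg = SimulationConfig(seed=4, n_unrelated=60, n_lipid_species=15)
        coh = simulate_unrelated_cohort(cfg)
        pd.testing.assert_frame_equal(
            simulate_ir_measures(coh, 0.5, config=cfg),
            simulate_ir_measures(coh, 0.5, config=cfg),
        )


class TestFamilialStructure:
    def test_zero_heritability_gives_uncorrelated_siblings(self):
        r, n_pairs = sib_correlation(11, h2=0.0)
        assert n_pairs > 500
        assert abs(r) < 0.05

    def test_sibling_correlation_increases_with_heritability(self):
        rs = [sib_correlation(12, h2)[0] for h2 in (0.0, 0.4, 0.8)]
        assert rs[0] < rs[1] < rs[2]
        # siblings share relationship 0.5, so expected latent r is ~h2/2
        assert rs[2] > 0.25


class TestOutcomeModel:
    def test_unrelated_event_rate_matches_planted_hazard(self):
        """Poisson count oracle: events / person-years approximates the
        baseline rate when all effects are null."""
        rate = 0.013
        cfg = SimulationConfig(
            seed=21, n_unrelated=2000, n_lipid_species=10, n_candidate_species=3,
            planted_species={}, covariate_log_hr={}, baseline_hazard=rate,
        )
        coh = simulate_unrelated_cohort(cfg)
        events = coh["event"].sum()
        py = coh["person_years"].sum()
        se = np.sqrt(events) / py
        assert abs(events / py - rate) < 3 * se

    def test_oracle_cox_recovers_planted_log_hazards(self):
        """Unpenalized Cox on a large near-unrelated simulation recovers the
        planted per-SD log hazard ratios within 3 SE."""
        cfg = SimulationConfig(
            n_families=130, seed=22, lipid_heritability=0.0,
            lipid_block_correlation=0.0, n_lipid_species=12,
            covariate_log_hr={}, dropout_rate=0.0,
        )
        cohort, _ = simulate_pedigree_cohort(cfg)
        df = pd.DataFrame({"T": cohort["time"], "E": cohort["event"]})
        from lipidrisk import inverse_normalize

        for sp in cfg.planted_species:
            df[sp] = inverse_normalize(cohort[sp].to_numpy()).values
        cph = CoxPHFitter().fit(df, "T", "E")
        for sp, beta in cfg.planted_species.items():
            est = cph.params_[sp]
            se = cph.standard_errors_[sp]
            assert abs(est - beta) < 3 * se, sp

    def test_null_effects_give_equal_tertile_event_fractions(self):
        cfg = SimulationConfig(
            n_families=100, seed=23, planted_species={}, covariate_log_hr={},
            n_lipid_species=10, n_candidate_species=3,
        )
        cohort, _ = simulate_pedigree_cohort(cfg)
        # score by an arbitrary species; under the null it carries no signal
        groups = tertile_groups(cohort[cfg.species_names[0]].to_numpy())
        fractions = [
            cohort.loc[np.asarray(groups == g), "event"].mean()
            for g in ("lower", "middle", "upper")
        ]
        overall = cohort["event"].mean()
        n_per = len(cohort) / 3
        band = 3 * np.sqrt(overall * (1 - overall) / n_per)
        assert max(fractions) - min(fractions) < 2 * band

    def test_interval_conventions(self):
        base = dict(n_families=10, seed=5, n_lipid_species=10, n_candidate_species=3)
        exact, _ = simulate_pedigree_cohort(SimulationConfig(**base))
        mid, _ = simulate_pedigree_cohort(
            SimulationConfig(**base, event_time_convention="interval_midpoint")
        )
        visit, _ = simulate_pedigree_cohort(
            SimulationConfig(**base, event_time_convention="visit")
        )
        ev = exact["event"] == 1
        w = 5.0
        assert np.allclose(mid.loc[ev, "time"] % w, w / 2)
        assert np.allclose(visit.loc[ev, "time"] % w, 0, atol=1e-9)
        assert (visit.loc[ev, "time"] >= exact.loc[ev, "time"] - 1e-9).all()


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lipid_heritability": 1.2},
            {"lipid_block_correlation": 1.0},
            {"event_time_convention": "bogus"},
            {"n_candidate_species": 400},
            {"visit_interval_years": 0.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_zero_families_is_an_error(self):
        with pytest.raises(ValueError, match="zero families"):
            simulate_pedigree_cohort(SimulationConfig(n_families=0))

    def test_zero_unrelated_gives_empty_table(self):
        out = simulate_unrelated_cohort(SimulationConfig(n_unrelated=0))
        assert len(out) == 0

    def test_config_json_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_families=3, seed=9)
        path = tmp_path / "cfg.json"
        cfg.to_json(path)
        assert SimulationConfig.from_json(path) == cfg


class TestIrCoupling:
    def test_invalid_coupling_rejected(self):
        cfg = SimulationConfig(seed=1, n_unrelated=30, n_lipid_species=10, n_candidate_species=3)
        coh = simulate_unrelated_cohort(cfg)
        with pytest.raises(ValueError):
            simulate_ir_measures(coh, 1.5, config=cfg)

    def test_strong_coupling_gives_monotone_homa_medians(self):
        cfg = SimulationConfig(seed=31, n_unrelated=800, n_lipid_species=12)
        coh = simulate_ir_measures(simulate_unrelated_cohort(cfg), 0.8, config=cfg)
        panel = compute_ir_panel(
            coh["fpg"], coh["fpi"], coh["triglycerides"], coh["leptin"], coh["adiponectin"]
        )
        groups = tertile_groups(planted_linear_predictor(cfg, coh))
        med = [
            np.median(panel.loc[np.asarray(groups == g), "homa_ir"])
            for g in ("lower", "middle", "upper")
        ]
        assert med[0] < med[1] < med[2]

    def test_zero_coupling_kruskal_wallis_mostly_non_significant(self):
        n_sig = 0
        n_reps = 50
        for rep in range(n_reps):
            cfg = SimulationConfig(
                seed=100 + rep, n_unrelated=150, n_lipid_species=8, n_candidate_species=3
            )
            coh = simulate_ir_measures(simulate_unrelated_cohort(cfg), 0.0, config=cfg)
            panel = compute_ir_panel(
                coh["fpg"], coh["fpi"], coh["triglycerides"], coh["leptin"], coh["adiponectin"]
            )
            groups = np.asarray(tertile_groups(planted_linear_predictor(cfg, coh)))
            samples = [panel.loc[groups == g, "homa_ir"] for g in ("lower", "middle", "upper")]
            if stats.kruskal(*samples).pvalue < 0.05:
                n_sig += 1
        assert n_sig <= 0.10 * n_reps + 2
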