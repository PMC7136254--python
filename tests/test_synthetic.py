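"""Synthetic cohort generator: planted correlations, loads, dose-response,
GMT fixtures, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mutcorr import (CancerType, CohortSpec, PlantedGene, compute_loads,
                     make_cell_cycle_fixture, read_gmt, simulate_cohort,
                     simulate_dose_response, write_fixture_gmt)


def _spec(**kw):
    defaults = dict(cancer_types=[CancerType("A", 100)], n_genes=50, seed=1)
    defaults.update(kw)
    return CohortSpec(**defaults)


def _realized_rho(expr, mut, gene):
    loads = compute_loads(mut, "A", roster=list(expr.samples))
    x = expr.values.loc[gene, loads.index].to_numpy()
    return stats.spearmanr(x, loads["load_all"].to_numpy()).statistic


class TestCohort:
    def test_target_rho_one_is_exact(self):
        mut, expr, _ = simulate_cohort(
            _spec(planted=[PlantedGene("P", "A", 1.0)]))
        assert _realized_rho(expr["A"], mut["A"], "P") == pytest.approx(1.0)

    @pytest.mark.parametrize("target", [-0.8, -0.4, 0.4, 0.8])
    def test_planted_rho_converges(self, target):
        mut, expr, _ = simulate_cohort(
            _spec(cancer_types=[CancerType("A", 2000)],
                  planted=[PlantedGene("P", "A", target)], seed=7))
        assert abs(_realized_rho(expr["A"], mut["A"], "P") - target) < 0.05

    def test_null_background_rho_near_zero(self):
        mut, expr, _ = simulate_cohort(
            _spec(cancer_types=[CancerType("A", 500)], n_genes=1000, seed=2))
        loads = compute_loads(mut["A"], "A", roster=list(expr["A"].samples))
        ranks = stats.rankdata(expr["A"].values[loads.index].to_numpy(), axis=1)
        ry = stats.rankdata(loads["load_all"])
        rx = ranks - ranks.mean(axis=1, keepdims=True)
        ryc = ry - ry.mean()
        rho = rx @ ryc / (np.linalg.norm(rx, axis=1) * np.linalg.norm(ryc))
        assert np.abs(rho).mean() < 0.1  # null sd ~ 1/sqrt(n-1) ~ 0.045

    def test_degenerate_class_mix_all_missense(self):
        mut, expr, _ = simulate_cohort(
            _spec(class_mix=(1, 0, 0, 0, 0), load_mean=5.0))
        records = mut["A"]
        assert (records["variant_class"] == "missense").all()
        loads = compute_loads(records, "A", roster=list(expr["A"].samples))
        assert (loads["load_missense"] == loads["load_all"]).all()

    def test_class_loads_sum_to_all_load(self):
        mut, _, _ = simulate_cohort(_spec())
        per_class = (mut["A"].groupby(["sample", "variant_class"]).size()
                     .unstack(fill_value=0))
        total = mut["A"].groupby("sample").size()
        assert (per_class.sum(axis=1) == total).all()

    def test_same_seed_byte_identical(self, tmp_path):
        from mutcorr import write_cohort
        for d in ("one", "two"):
            mut, expr, truth = simulate_cohort(
                _spec(planted=[PlantedGene("P", "A", 0.5)], seed=42))
            write_cohort(mut, expr, truth, tmp_path / d)
        for f in (tmp_path / "one").iterdir():
            assert f.read_bytes() == (tmp_path / "two" / f.name).read_bytes()

    def test_seed_changes_output(self):
        mut1, _, _ = simulate_cohort(_spec(seed=1))
        mut2, _, _ = simulate_cohort(_spec(seed=2))
        assert not mut1["A"].equals(mut2["A"])

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="target_rho"):
            PlantedGene("P", "A", 1.5)
        with pytest.raises(ValueError, match="n_samples"):
            CancerType("A", 5)
        with pytest.raises(ValueError, match="sum to 1"):
            _spec(class_mix=(0.5, 0.5, 0.5, 0, 0))
        with pytest.raises(ValueError, match="duplicated"):
            _spec(planted=[PlantedGene("P", "A", 0.1),
                           PlantedGene("P", "A", 0.2)])
        with pytest.raises(ValueError, match="unknown cancer type"):
            _spec(planted=[PlantedGene("P", "B", 0.1)])


class TestDoseResponse:
    def test_bliss_at_half_effects(self):
        # at dose = EC50 each Hill effect is exactly 0.5 -> Bliss 0.75
        d = simulate_dose_response(ec50_a=10, hill_a=1, ec50_b=40, hill_b=1,
                                   ratio=4.0, doses_a=[2.5, 10.0, 40.0],
                                   synergy_alpha=1.0, noise_sd=0.0)
        mid = d.rows.iloc[1]
        assert 1 - mid.survival_a == pytest.approx(0.5)
        assert 1 - mid.survival_b == pytest.approx(0.5)
        assert 1 - mid.survival_ab == pytest.approx(0.75)

    def test_far_below_ec50_no_effect(self):
        d = simulate_dose_response(1e4, 2, 1e4, 2, 1.0, [1e-3, 1e-2, 1e-1],
                                   noise_sd=0.0)
        eff = 1 - d.rows[["survival_a", "survival_b", "survival_ab"]]
        assert (eff < 1e-6).all().all()

    def test_super_bliss_dominates_bliss_on_grid(self):
        doses = list(np.geomspace(1, 256, 9))
        bliss = simulate_dose_response(10, 1.3, 40, 0.8, 4.0, doses,
                                       synergy_alpha=1.0, noise_sd=0.0)
        sup = simulate_dose_response(10, 1.3, 40, 0.8, 4.0, doses,
                                     synergy_alpha=2.0, noise_sd=0.0)
        e_bliss = 1 - bliss.rows["survival_ab"]
        e_sup = 1 - sup.rows["survival_ab"]
        assert (e_sup >= e_bliss - 1e-12).all()
        assert (e_sup > e_bliss).any()

    def test_noise_deterministic_under_seed(self):
        a = simulate_dose_response(10, 1, 10, 1, 1.0, [1, 10, 100],
                                   noise_sd=0.05, seed=3)
        b = simulate_dose_response(10, 1, 10, 1, 1.0, [1, 10, 100],
                                   noise_sd=0.05, seed=3)
        pd.testing.assert_frame_equal(a.rows, b.rows)

    def test_non_monotone_ladder_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            simulate_dose_response(10, 1, 10, 1, 1.0, [1, 3, 2])


class TestGmtFixtures:
    def test_single_set_roundtrip(self, tmp_path):
        mcm = {"MCM": [f"MCM{i}" for i in range(2, 8)]}
        write_fixture_gmt(mcm, tmp_path / "m.gmt")
        lines = (tmp_path / "m.gmt").read_text().splitlines()
        assert len(lines) == 1 and len(lines[0].split("\t")) == 8
        assert read_gmt(tmp_path / "m.gmt") == mcm

    def test_roundtrip_identity(self, tmp_path):
        sets = make_cell_cycle_fixture()
        write_fixture_gmt(sets, tmp_path / "cc.gmt")
        assert read_gmt(tmp_path / "cc.gmt") == sets

    def test_nested_subset_containment(self, tmp_path):
        sets = make_cell_cycle_fixture()
        write_fixture_gmt(sets, tmp_path / "cc.gmt")
        back = read_gmt(tmp_path / "cc.gmt")
        cc = set(back["cell_cycle"])
        assert len(cc) == 124
        assert set(back["MCM"]) < cc and len(back["MCM"]) == 6
        assert set(back["CDK4_6"]) < cc and len(back["CDK4_6"]) == 19
        assert set(back["MCM"]).isdisjoint(back["CDK4_6"])

    def test_duplicate_set_names_rejected(self, tmp_path):
        p = tmp_path / "dup.gmt"
        p.write_text("S\td\ta\tb\nS\td\tc\n")
        with pytest.raises(ValueError, match="duplicate set name"):
            read_gmt(p)

    def test_duplicate_members_rejected_on_write(self, tmp_path):
        with pytest.raises(ValueError, match="duplicate members"):
            write_fixture_gmt({"S": ["a", "a"]}, tmp_path / "x.gmt")
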