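import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nmrclock.core_io import BetaMatrix, CpGManifest, ValidationError
from nmrclock.ewas import (
    bh_fdr,
    cross_species_concordance,
    divergent_cpgs,
    ewas_age,
    island_mean_trajectory,
    membership_counts,
    overlap_test,
    region_class_distribution,
    select_top_cpgs,
    stouffer_meta,
)
from nmrclock.simdata import SimConfig, simulate_dual_species, simulate_methylation_study

from conftest import make_exact_correlation


def _beta_frame(cols: dict, n=None):
    df = pd.DataFrame(cols)
    df.index = [f"s{i}" for i in range(len(df))]
    return df


class TestEwasAge:
    def test_exactly_linear_cpg_capped_at_limits(self):
        ages = np.linspace(1, 20, 10)
        betas = _beta_frame({"cg1": 0.2 + ages / 40})
        tab = ewas_age(betas, ages)
        row = tab.iloc[0]
        assert row["pearson_r"] == pytest.approx(1.0)
        assert np.isfinite(row["fisher_z"]) and row["fisher_z"] > 10
        assert 0 < row["p"] < 1e-20  # at the numerical floor of the t-tail

    def test_closed_form_r06_n28(self):
        # fisher z = atanh(0.6) * sqrt(25) = 3.4657 to 4 d.p.
        x, y = make_exact_correlation(28, 0.6, seed=1)
        betas = _beta_frame({"cg1": 0.5 + 0.05 * y})
        tab = ewas_age(betas, x)
        assert tab.iloc[0]["pearson_r"] == pytest.approx(0.6, abs=1e-12)
        assert tab.iloc[0]["fisher_z"] == pytest.approx(math.atanh(0.6) * 5, abs=5e-5)
        assert tab.iloc[0]["fisher_z"] == pytest.approx(3.4657, abs=1e-4)

    def test_zero_correlation_gives_zero_z_unit_p(self):
        x, y = make_exact_correlation(30, 0.0, seed=2)
        tab = ewas_age(_beta_frame({"cg1": 0.5 + 0.05 * y}), x)
        assert tab.iloc[0]["fisher_z"] == pytest.approx(0.0, abs=1e-12)
        assert tab.iloc[0]["p"] == pytest.approx(1.0, abs=1e-12)

    def test_constant_cpg_flagged_invalid(self):
        ages = np.arange(5.0)
        tab = ewas_age(_beta_frame({"cg1": [0.5] * 5, "cg2": ages / 10}), ages)
        assert not tab.set_index("cpg_id").loc["cg1", "valid"]
        assert tab.set_index("cpg_id").loc["cg2", "valid"]

    def test_pairwise_complete_with_missing_values(self):
        ages = np.linspace(0, 10, 8)
        col = 0.3 + ages / 20
        col_missing = col.copy()
        col_missing[[0, 3]] = np.nan
        tab = ewas_age(_beta_frame({"cg1": col_missing}), ages).iloc[0]
        ok = ~np.isnan(col_missing)
        assert tab["n"] == 6
        assert tab["pearson_r"] == pytest.approx(
            np.corrcoef(col_missing[ok], ages[ok])[0, 1]
        )

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            ewas_age(_beta_frame({"cg1": [0.1, 0.2, 0.3]}), [1, 2, 3])

    def test_matches_brute_force_on_random_inputs(self):
        """fisher z and p agree with independent recomputation to 1e-10."""
        rng = np.random.default_rng(3)
        n = 25
        ages = rng.uniform(0, 26, n)
        betas = pd.DataFrame(
            rng.uniform(0.05, 0.95, (n, 200)), columns=[f"cg{i}" for i in range(200)]
        )
        tab = ewas_age(betas, ages)
        for j in rng.choice(200, 50, replace=False):
            r_ref, p_ref = stats.pearsonr(betas.iloc[:, j], ages)
            row = tab.iloc[j]
            assert row["pearson_r"] == pytest.approx(r_ref, abs=1e-10)
            assert row["fisher_z"] == pytest.approx(math.atanh(r_ref) * math.sqrt(n - 3), abs=1e-10)
            assert row["p"] == pytest.approx(p_ref, abs=1e-10)


class TestStouffer:
    @staticmethod
    def _table(zs, n=30):
        return pd.DataFrame(
            {
                "cpg_id": [f"cg{i}" for i in range(len(zs))],
                "pearson_r": np.tanh(np.asarray(zs, float) / np.sqrt(n - 3)),
                "fisher_z": zs,
                "p": 2 * stats.norm.sf(np.abs(zs)),
                "n": n,
                "stratum": "t",
                "valid": True,
            }
        )

    def test_single_table_is_identity(self):
        t = self._table([1.3, -0.4])
        out = stouffer_meta([t])
        np.testing.assert_allclose(out["fisher_z"], [1.3, -0.4])

    def test_four_equal_z_formula(self):
        tables = [self._table([2.0]) for _ in range(4)]
        out = stouffer_meta(tables)
        assert out["fisher_z"].iloc[0] == pytest.approx(4.0)  # 8 / sqrt(4)

    def test_cancellation(self):
        out = stouffer_meta([self._table([1.5]), self._table([-1.5])])
        assert out["fisher_z"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_k_identical_tables_scale_by_sqrt_k(self):
        z = np.array([0.7, -2.1, 3.3])
        for k in (2, 3, 5):
            out = stouffer_meta([self._table(z)] * k)
            np.testing.assert_allclose(out["fisher_z"], z * np.sqrt(k))

    def test_missing_in_one_stratum_omits_that_stratum(self):
        t1 = self._table([2.0, 2.0])
        t2 = self._table([2.0]).iloc[:1]  # only cg0
        out = stouffer_meta([t1, t2]).set_index("cpg_id")
        assert out.loc["cg0", "fisher_z"] == pytest.approx(4 / np.sqrt(2))
        assert out.loc["cg1", "fisher_z"] == pytest.approx(2.0)

    def test_sqrt_n_weights(self):
        t1 = self._table([2.0], n=12)  # w = sqrt(12)
        t2 = self._table([1.0], n=28)  # w = sqrt(28)
        out = stouffer_meta([t1, t2], weights="sqrt_n")
        expected = (np.sqrt(12) * 2 + np.sqrt(28) * 1) / np.sqrt(12 + 28)
        assert out["fisher_z"].iloc[0] == pytest.approx(expected)


class TestSelectTop:
    @staticmethod
    def _table(ps, zs):
        return pd.DataFrame(
            {
                "cpg_id": [f"cg{i:04d}" for i in range(len(ps))],
                "pearson_r": np.sign(zs) * 0.5,
                "fisher_z": zs,
                "p": ps,
                "n": 50,
                "stratum": "t",
                "valid": True,
            }
        )

    def test_nothing_significant_gives_empty_sets(self):
        t = self._table([0.5] * 10, [1.0] * 10)
        out = select_top_cpgs(t)
        assert out["gain"] == [] and out["loss"] == []

    def test_truncation_keeps_smallest_p(self):
        rng = np.random.default_rng(0)
        ps = rng.uniform(1e-12, 1e-6, 600)
        t = self._table(ps, np.full(600, 5.0))
        out = select_top_cpgs(t, p_threshold=1e-5, max_per_direction=500)
        assert len(out["gain"]) == 500
        kept_p = t.set_index("cpg_id").loc[out["gain"], "p"]
        assert kept_p.max() <= np.sort(ps)[499] + 1e-18

    def test_directions_split_by_z_sign(self):
        t = self._table([1e-8, 1e-8], [3.0, -3.0])
        out = select_top_cpgs(t)
        assert out["gain"] == ["cg0000"] and out["loss"] == ["cg0001"]

    def test_planted_simulation_recall_and_false_positives(self):
        cfg = SimConfig(
            seed=13,
            n_cpgs=2000,
            n_samples_per_tissue=100,
            tissues=("blood",),
            frac_age_related=0.025,  # 50 planted
            effect_scale=5 * 0.15,
            noise_sd=0.15,
            n_sex_cpgs=0,
        )
        matrix, sheet, _, truth = simulate_methylation_study(cfg)
        tab = ewas_age(matrix, sheet.frame["age_years"])
        out = select_top_cpgs(tab, p_threshold=1e-5)
        found = set(out["gain"]) | set(out["loss"])
        true = set(truth.age_cpg_ids)
        assert len(found & true) / len(true) >= 0.9
        assert len(found - true) <= 3


class TestOverlap:
    def test_identical_sets_exact_enumeration_value(self):
        # P(all 5 of B land on A) = 1 / C(20,5)
        A = set(range(5))
        res = overlap_test(A, A, 20)
        assert res["overlap"] == 5
        assert res["p"] == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_disjoint_sets_p_one(self):
        res = overlap_test({1, 2}, {3, 4}, 100)
        assert res["overlap"] == 0 and res["p"] == pytest.approx(1.0)

    def test_b_equals_universe_p_one(self):
        res = overlap_test({1, 2, 3}, set(range(10)), 10)
        assert res["overlap"] == 3 and res["p"] == pytest.approx(1.0)

    def test_set_larger_than_universe_rejected(self):
        with pytest.raises(ValidationError):
            overlap_test(set(range(30)), {1}, 20)

    def test_matches_exact_enumeration_small_case(self):
        # brute force over all C(6,2) placements of B for fixed A
        import itertools

        universe = range(6)
        A = {0, 1, 2}
        k_obs = 1
        count = sum(
            1 for b in itertools.combinations(universe, 2) if len(A & set(b)) >= k_obs
        )
        res = overlap_test(A, {0, 5}, 6)
        assert res["p"] == pytest.approx(count / math.comb(6, 2), rel=1e-12)


class TestMembershipCounts:
    def test_two_overlapping_sets(self):
        counts = membership_counts({"1": {"a", "b"}, "2": {"b", "c"}})
        assert counts == {("1",): 1, ("2",): 1, ("1", "2"): 1}

    def test_identical_sets_only_full_pattern(self):
        counts = membership_counts({"x": {1, 2}, "y": {1, 2}})
        assert counts == {("x", "y"): 2}

    def test_five_random_sets_match_per_element_classification(self):
        rng = np.random.default_rng(4)
        sets = {f"s{i}": set(rng.choice(50, 20, replace=False)) for i in range(5)}
        counts = membership_counts(sets)
        # brute-force oracle: classify each element independently
        oracle = {}
        for el in range(50):
            pat = tuple(sorted(k for k, v in sets.items() if el in v))
            if pat:
                oracle[pat] = oracle.get(pat, 0) + 1
        assert counts == oracle
        assert sum(counts.values()) == len(set().union(*sets.values()))


class TestConcordance:
    @staticmethod
    def _table(zs):
        return pd.DataFrame(
            {
                "cpg_id": [f"cg{i}" for i in range(len(zs))],
                "fisher_z": zs,
                "p": 0.5,
                "valid": True,
            }
        )

    def test_self_concordance_is_one(self):
        t = self._table(np.linspace(-3, 3, 20))
        assert cross_species_concordance(t, t)["r"] == pytest.approx(1.0)

    def test_negated_concordance_is_minus_one(self):
        z = np.linspace(-3, 3, 20)
        assert cross_species_concordance(self._table(z), self._table(-z))["r"] == pytest.approx(-1.0)

    def test_independent_nulls_near_zero(self):
        rng = np.random.default_rng(5)
        r = cross_species_concordance(
            self._table(rng.normal(size=2000)), self._table(rng.normal(size=2000))
        )["r"]
        assert abs(r) < 0.1

    def test_too_few_pairs_rejected(self):
        t = self._table([1.0] * 5)
        with pytest.raises(ValidationError):
            cross_species_concordance(t, t)


class TestDivergent:
    @staticmethod
    def _table(zs, ps, valid=None):
        n = len(zs)
        return pd.DataFrame(
            {
                "cpg_id": [f"cg{i}" for i in range(n)],
                "fisher_z": zs,
                "p": ps,
                "valid": [True] * n if valid is None else valid,
            }
        )

    def test_concordant_in_all_three_excluded(self):
        long1 = self._table([6.0], [1e-9])
        short = self._table([6.0], [1e-9])
        assert divergent_cpgs(long1, long1, short)["cpg_ids"] == []

    def test_opposite_longlived_signs_excluded(self):
        l1 = self._table([6.0], [1e-9])
        l2 = self._table([-6.0], [1e-9])
        flat = self._table([0.1], [0.8])
        assert divergent_cpgs(l1, l2, flat)["cpg_ids"] == []

    def test_flat_short_species_included(self):
        l = self._table([6.0], [1e-9])
        flat = self._table([0.1], [0.8])
        assert divergent_cpgs(l, l, flat)["cpg_ids"] == ["cg0"]

    def test_flat_only_rule_excludes_significant_opposite(self):
        l = self._table([6.0], [1e-9])
        opp = self._table([-6.0], [1e-9])
        assert divergent_cpgs(l, l, opp, rule="flat_or_opposite")["cpg_ids"] == ["cg0"]
        assert divergent_cpgs(l, l, opp, rule="flat_only")["cpg_ids"] == []

    def test_noiseless_three_species_roundtrip_exact(self):
        from conftest import NMR

        cfg = SimConfig(
            seed=11,
            n_cpgs=600,
            n_samples_per_tissue=40,
            tissues=("liver",),
            species_params={
                "naked_mole_rat": NMR["naked_mole_rat"],
                "vervet": type(NMR["naked_mole_rat"])(30.8, 4.0),
                "mouse": type(NMR["naked_mole_rat"])(4.0, 0.15),
            },
            frac_shared_probes=1.0,
            frac_divergent=0.3,
            noise_sd=0.0,
            n_sex_cpgs=0,
        )
        matrix, sheet, _, truth = simulate_dual_species(cfg)
        tabs = {}
        for sp in ("naked_mole_rat", "vervet", "mouse"):
            d = sheet.frame[sheet.frame.species == sp]
            L = cfg.species_params[sp].max_lifespan_years
            tabs[sp] = ewas_age(matrix.values.loc[d.sample_id], d.age_years / L, label=sp)
        res = divergent_cpgs(tabs["naked_mole_rat"], tabs["vervet"], tabs["mouse"])
        assert set(res["cpg_ids"]) == set(truth.divergent_cpg_ids)
        assert len(res["cpg_ids"]) > 0


class TestRegionAndIsland:
    @staticmethod
    def _manifest(classes, islands=None):
        n = len(classes)
        return CpGManifest(
            pd.DataFrame(
                {
                    "cpg_id": [f"cg{i}" for i in range(n)],
                    "chrom": "chr1",
                    "start": range(n),
                    "end": range(2, n + 2),
                    "gene": "G",
                    "signed_tss_distance": 0,
                    "region_class": classes,
                    "island_flag": islands if islands is not None else [False] * n,
                    "species_mappable": "x",
                }
            )
        )

    def test_single_class_proportion_one(self):
        man = self._manifest(["promoter"] * 4)
        out = region_class_distribution(["cg0", "cg1"], man)
        row = out[(out.direction == "all") & (out.region_class == "promoter")]
        assert row["proportion"].iloc[0] == 1.0

    def test_even_two_class_split(self):
        man = self._manifest(["promoter", "promoter", "distal", "distal"])
        out = region_class_distribution(["cg0", "cg2"], man)
        props = out[out.direction == "all"].set_index("region_class")["proportion"]
        assert props["promoter"] == 0.5 and props["distal"] == 0.5

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            region_class_distribution([], self._manifest(["distal"]))

    def test_promoter_bias_enriches_gain_cpgs_over_background(self):
        cfg = SimConfig(
            seed=14,
            n_cpgs=2000,
            n_samples_per_tissue=80,
            tissues=("blood",),
            frac_age_related=0.1,
            promoter_hyper_bias=0.9,
            noise_sd=0.1,
        )
        matrix, sheet, manifest, truth = simulate_methylation_study(cfg)
        tab = ewas_age(matrix, sheet.frame["age_years"])
        tops = select_top_cpgs(tab, p_threshold=1e-5)
        directions = {c: "gain" for c in tops["gain"]}
        directions.update({c: "loss" for c in tops["loss"]})
        out = region_class_distribution(list(directions), manifest, directions)

        def prop(direction):
            rows = out[(out.direction == direction) & (out.region_class == "promoter")]
            return rows["proportion"].iloc[0] if len(rows) else 0.0

        assert prop("gain") > prop("background")

    def test_island_gain_trajectory_positive_slope(self):
        cfg = SimConfig(
            seed=15,
            n_cpgs=800,
            n_samples_per_tissue=100,
            tissues=("blood",),
            frac_age_related=0.15,
            promoter_hyper_bias=1.0,  # every promoter/island age CpG gains
            noise_sd=0.1,
        )
        matrix, sheet, manifest, _ = simulate_methylation_study(cfg)
        res = island_mean_trajectory(matrix, manifest, sheet.frame["age_years"])
        assert res["island"]["slope_per_year"] > 0
        assert res["island"]["p"] < 0.01

    def test_null_study_slopes_within_three_se(self):
        cfg = SimConfig(
            seed=16,
            n_cpgs=500,
            n_samples_per_tissue=60,
            tissues=("blood",),
            frac_age_related=0.0,
            noise_sd=0.15,
            n_sex_cpgs=0,
        )
        matrix, sheet, manifest, _ = simulate_methylation_study(cfg)
        res = island_mean_trajectory(matrix, manifest, sheet.frame["age_years"])
        for stratum in ("island", "open_sea"):
            assert abs(res[stratum]["slope_per_year"]) < 3 * res[stratum]["slope_se"]

    def test_constant_matrix_slopes_exactly_zero(self):
        man = self._manifest(["promoter", "distal"], islands=[True, False])
        betas = pd.DataFrame(0.5, index=["s1", "s2", "s3", "s4"], columns=["cg0", "cg1"])
        res = island_mean_trajectory(betas, man, [1.0, 2.0, 3.0, 4.0])
        assert res["island"]["slope_per_year"] == 0.0
        assert res["open_sea"]["slope_per_year"] == 0.0


def test_bh_fdr_matches_brute_force():
    rng = np.random.default_rng(6)
    p = rng.uniform(size=500)

    def brute(pvals):
        n = len(pvals)
        order = np.argsort(pvals)
        adj = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, pvals[i] * n / rank)
            adj[i] = running
        return adj

    np.testing.assert_allclose(bh_fdr(p), brute(p), atol=1e-12)
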