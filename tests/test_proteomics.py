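import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rhythmlab as rl
from rhythmlab.proteomics import (GroupDesign, ProteinTable, bh_adjust,
                                  fisher_enrichment, impute_downshifted_normal,
                                  preprocess_protein_table, sample_correlation_qc,
                                  two_sample_s0_test)
from rhythmlab.simulate import ProteomeSimConfig, simulate_protein_table


def wt_ko_design(table, excluded=()):
    return GroupDesign({s: ("WT" if s.startswith("WT") else "KO")
                        for s in table.samples}, excluded=list(excluded),
                       group_order=("WT", "KO"))


@pytest.fixture(scope="module")
def small_table():
    cfg = ProteomeSimConfig(n_proteins=300, n_decoy=10, n_contaminant=5,
                            n_site_only=3, seed=11)
    table, truth = simulate_protein_table(cfg)
    return table, truth


class TestPreprocess:
    def test_flag_stage_drops_exactly_flagged_rows(self, small_table):
        table, _ = small_table
        filt, counts = preprocess_protein_table(table, wt_ko_design(table))
        assert counts["raw"] == 318
        assert counts["flag_filtered"] == 300
        assert not filt.flags.any().any()

    def test_all_present_table_loses_nothing_at_min_valid(self):
        cfg = ProteomeSimConfig(n_proteins=100, missing_midpoint=0.0,
                                n_decoy=0, n_contaminant=0, n_site_only=0, seed=1)
        table, _ = simulate_protein_table(cfg)
        _, counts = preprocess_protein_table(table, wt_ko_design(table))
        assert counts["min_valid_filtered"] == 100

    def test_min_valid_counts_only_retained_samples(self, small_table):
        table, _ = small_table
        _, c_all = preprocess_protein_table(table, wt_ko_design(table))
        _, c_excl = preprocess_protein_table(table,
                                             wt_ko_design(table, ["KO1"]))
        assert c_excl["min_valid_filtered"] <= c_all["min_valid_filtered"]

    def test_double_log2_guard(self, small_table):
        table, _ = small_table
        filt, _ = preprocess_protein_table(table, wt_ko_design(table))
        with pytest.raises(ValueError):
            preprocess_protein_table(filt, wt_ko_design(filt))

    def test_design_needs_two_samples_per_group(self):
        with pytest.raises(ValueError):
            GroupDesign({"a": "WT", "b": "WT", "c": "KO"}, excluded=["c"])


class TestImputation:
    def test_imputed_cells_match_downshifted_normal(self):
        """Marginal of imputed cells ~ Normal(mu - 1.8 sigma, (0.3 sigma)^2)."""
        rng = np.random.default_rng(0)
        n = 30000
        col = rng.normal(25.0, 2.0, size=n)
        miss = np.zeros(n, bool)
        miss[:10000] = True
        vals = col.copy()
        vals[miss] = np.nan
        tb = ProteinTable(pd.DataFrame({"a": vals, "b": rng.normal(25, 2, n)}),
                          log2_scale=True)
        imp = impute_downshifted_normal(tb, seed=3)
        got = imp.intensities["a"].to_numpy()[miss]
        obs = col[~miss]
        mu, sd = obs.mean(), obs.std(ddof=1)
        ks = stats.kstest(got, stats.norm(mu - 1.8 * sd, 0.3 * sd).cdf)
        assert ks.pvalue > 0.01
        assert got.mean() == pytest.approx(mu - 1.8 * sd, abs=0.05)
        assert got.std() == pytest.approx(0.3 * sd, abs=0.05)

    def test_identity_parameters_reproduce_observed_fit(self):
        rng = np.random.default_rng(1)
        n = 20000
        vals = rng.normal(24.0, 1.5, size=n)
        vals[:5000] = np.nan
        tb = ProteinTable(pd.DataFrame({"a": vals, "b": rng.normal(24, 1.5, n)}),
                          log2_scale=True)
        imp = impute_downshifted_normal(tb, downshift=0.0, width=1.0, seed=4)
        got = imp.intensities["a"].to_numpy()[:5000]
        obs = vals[5000:]
        assert got.mean() == pytest.approx(obs.mean(), abs=0.1)
        assert got.std() == pytest.approx(obs.std(), abs=0.1)

    def test_deterministic_given_seed(self, small_table):
        table, _ = small_table
        filt, _ = preprocess_protein_table(table, wt_ko_design(table))
        a = impute_downshifted_normal(filt, seed=9)
        b = impute_downshifted_normal(filt, seed=9)
        assert a.intensities.equals(b.intensities)
        assert not a.intensities.isna().any().any()

    def test_column_with_too_few_observations_rejected(self):
        tb = ProteinTable(pd.DataFrame({"a": [1.0, np.nan, np.nan],
                                        "b": [1.0, 2.0, 3.0]}), log2_scale=True)
        with pytest.raises(ValueError):
            impute_downshifted_normal(tb)

    def test_raw_scale_table_rejected(self, small_table):
        table, _ = small_table
        with pytest.raises(ValueError):
            impute_downshifted_normal(table)


class TestCorrelationQC:
    def test_duplicated_column_has_unit_correlation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(25, 2, 500)
        tb = ProteinTable(pd.DataFrame({"a": x, "b": x, "c": x + rng.normal(
            0, 0.1, 500)}), log2_scale=True)
        corr, flagged = sample_correlation_qc(tb)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert not flagged

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(3)
        tb = ProteinTable(pd.DataFrame(rng.normal(25, 2, size=(4000, 3)),
                                       columns=list("abc")), log2_scale=True)
        corr, flagged = sample_correlation_qc(tb)
        off = corr.to_numpy()[np.triu_indices(3, 1)]
        assert np.all(np.abs(off) < 0.05)
        assert len(flagged) == 3  # r <= 0.9 everywhere

    def test_replicates_exceed_threshold_by_variance_ratio(self):
        """r ~ sigma_b^2 / (sigma_b^2 + sigma_e^2) = 2.25/(2.25+0.09) > 0.9."""
        rng = np.random.default_rng(4)
        base = rng.normal(25, 1.5, 4000)
        cols = {f"s{i}": base + rng.normal(0, 0.3, 4000) for i in range(3)}
        tb = ProteinTable(pd.DataFrame(cols), log2_scale=True)
        corr, flagged = sample_correlation_qc(tb)
        assert not flagged
        assert corr.min().min() > 0.9


class TestS0Test:
    def test_s0_zero_reduces_to_student_t(self, small_table):
        table, _ = small_table
        design = wt_ko_design(table)
        filt, _ = preprocess_protein_table(table, design)
        imp = impute_downshifted_normal(filt, seed=5)
        dep = two_sample_s0_test(imp, design, s0=0.0)
        ref = stats.ttest_ind(imp.intensities[design.samples_of("KO")],
                              imp.intensities[design.samples_of("WT")], axis=1)
        assert np.allclose(dep["t_stat"], ref.statistic)
        assert np.allclose(dep["p_value"], ref.pvalue)

    def test_identical_groups_give_null_result(self):
        rng = np.random.default_rng(6)
        x = rng.normal(25, 1, size=(50, 3))
        df = pd.DataFrame(np.hstack([x, x]),
                          columns=["WT1", "WT2", "WT3", "KO1", "KO2", "KO3"])
        tb = ProteinTable(df, log2_scale=True)
        dep = two_sample_s0_test(tb, wt_ko_design(tb), s0=0.1)
        assert np.allclose(dep["t_stat"], 0.0)
        assert np.allclose(dep["p_value"], 1.0)
        assert not dep["significant"].any()

    def test_null_pvalues_uniform(self):
        """dep_fraction 0, 4 vs 3, complete data, s0 = 0: p ~ Uniform(0,1)."""
        cfg = ProteomeSimConfig(n_proteins=4000, n_per_group=(4, 3),
                                dep_fraction=0.0, missing_midpoint=5.0,
                                n_decoy=0, n_contaminant=0, n_site_only=0,
                                seed=7)
        table, _ = simulate_protein_table(cfg)
        design = wt_ko_design(table)
        filt, _ = preprocess_protein_table(table, design)
        dep = two_sample_s0_test(filt, design, s0=0.0)
        assert stats.kstest(dep["p_value"], "uniform").pvalue > 0.01

    def test_s0_damps_small_fold_changes_most(self, small_table):
        table, _ = small_table
        design = wt_ko_design(table)
        filt, _ = preprocess_protein_table(table, design)
        imp = impute_downshifted_normal(filt, seed=8)
        d0 = two_sample_s0_test(imp, design, s0=0.0)["t_stat"].abs()
        d1 = two_sample_s0_test(imp, design, s0=0.1)["t_stat"].abs()
        assert np.all(d1 <= d0 + 1e-12)

    def test_direction_counts_partition_significant_set(self):
        cfg = ProteomeSimConfig(effect_mean=2.0, seed=9)
        table, _ = simulate_protein_table(cfg)
        design = wt_ko_design(table)
        filt, _ = preprocess_protein_table(table, design)
        imp = impute_downshifted_normal(filt, seed=9)
        dep = two_sample_s0_test(imp, design, s0=0.0)
        n_sig = int(dep["significant"].sum())
        assert n_sig > 0
        assert n_sig == int((dep["direction"] == "up").sum()
                            + (dep["direction"] == "down").sum())


class TestBHAdjust:
    def test_step_up_hand_example(self):
        q = bh_adjust([0.01, 0.02, 0.04, 0.5])
        assert np.allclose(q, [0.04, 0.04, 0.04 * 4 / 3, 0.5])

    def test_all_ones_and_singleton(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_oracle_over_permutations(self):
        def oracle(p):
            m = len(p)
            order = np.argsort(p)
            q = np.empty(m)
            running = np.inf
            for rank in range(m - 1, -1, -1):
                i = order[rank]
                running = min(running, m * p[i] / (rank + 1))
                q[i] = running
            return q

        grid = [0.001, 0.01, 0.2, 0.04, 0.9]
        for perm in itertools.permutations(grid):
            assert np.allclose(bh_adjust(list(perm)), oracle(np.array(perm)))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])


class TestFisherEnrichment:
    def test_whole_background_term_is_null(self):
        bg = [f"p{i}" for i in range(50)]
        fg = bg[:10]
        res = fisher_enrichment(fg, bg, {"GO:ALL": set(bg)})
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_perfect_overlap_closed_form(self):
        """All 10 foreground proteins in a 10-member term: p = 1/C(100,10)."""
        bg = [f"p{i}" for i in range(100)]
        fg = bg[:10]
        res = fisher_enrichment(fg, bg, {"T": set(fg)})
        from math import comb
        assert res.loc[0, "p_value"] == pytest.approx(1.0 / comb(100, 10),
                                                      rel=1e-9)
        assert res.loc[0, "significant"]

    def test_small_terms_excluded(self):
        bg = [f"p{i}" for i in range(30)]
        fg = bg[:6]
        res = fisher_enrichment(fg, bg, {"small": {"p0", "p1"},
                                         "big": set(bg[:5])})
        assert list(res["term"]) == ["big"]

    def test_foreground_must_be_subset(self):
        with pytest.raises(ValueError):
            fisher_enrichment(["x"], ["a", "b"], {})


class TestFullPipeline:
    def test_planted_effects_are_recovered_end_to_end(self):
        cfg = ProteomeSimConfig(effect_mean=2.0, seed=12)
        table, truth = simulate_protein_table(cfg)
        design = wt_ko_design(table, excluded=["KO1"])
        filt, counts = preprocess_protein_table(table, design)
        imp = impute_downshifted_normal(filt, seed=12)
        dep = two_sample_s0_test(imp, design, s0=0.0)
        sig = dep.index[dep["significant"]]
        assert len(sig) > 50
        # enrichment of a term built from true positives is detected
        bg = list(dep.index)
        true_ids = set(truth.index[truth["is_dep"]]) & set(bg)
        ann = {"planted": set(list(true_ids)[:100]),
               "random": set(bg[:100])}
        res = fisher_enrichment(list(sig), bg, ann)
        planted = res.set_index("term")
        assert planted.loc["planted", "p_value"] < 1e-6

    def test_power_nondecreasing_in_effect_size(self):
        tps = []
        for em in (0.5, 1.0, 2.0):
            cfg = ProteomeSimConfig(n_proteins=2000, effect_mean=em, seed=13)
            table, truth = simulate_protein_table(cfg)
            design = wt_ko_design(table)
            filt, _ = preprocess_protein_table(table, design)
            imp = impute_downshifted_normal(filt, seed=13)
            dep = two_sample_s0_test(imp, design, s0=0.0)
            sig = [i for i in dep.index[dep["significant"]] if i in truth.index]
            tps.append(int(truth.loc[sig, "is_dep"].sum()))
        assert tps[0] <= tps[1] <= tps[2]
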