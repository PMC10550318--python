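"""NB differential expression: calibration, recovery, and oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from regulonkit import diffexpr
from regulonkit.diffexpr import (bh_adjust, estimate_dispersions, lrt_timeseries,
                                 wald_pairwise, ALPHA_MIN)
from regulonkit.quantio import CountMatrix, SampleSheet, size_factors
from regulonkit.synthetic import SimConfig, generate_depletion_experiment


@pytest.fixture(scope="module")
def null_experiment():
    """2000-gene simulation with no planted effects."""
    cfg = SimConfig(seed=7, n_direct_targets=0, n_confounded=0, n_slow=0)
    counts, sheet, _, _ = generate_depletion_experiment(cfg)
    sf = size_factors(counts)
    disp = estimate_dispersions(counts, sheet, sf)
    return counts, sheet, sf, disp


@pytest.fixture(scope="module")
def planted_experiment(depletion_experiment):
    counts, sheet, _, truth = depletion_experiment
    sf = size_factors(counts)
    disp = estimate_dispersions(counts, sheet, sf)
    return counts, sheet, sf, disp, truth


class TestBhAdjust:
    def test_worked_example(self):
        padj = bh_adjust([0.002, 0.01, 0.03, 0.04])
        assert padj.tolist() == pytest.approx([0.008, 0.02, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]).tolist() == [0.37]

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_exhaustive_step_up_oracle(self, ps):
        got = bh_adjust(ps)
        m = len(ps)
        order = sorted(range(m), key=lambda i: ps[i])
        # brute-force step-up: padj_(i) = min over j >= i of p_(j)*m/(j+1)
        expected = [None] * m
        for rank, i in enumerate(order):
            expected[i] = min(
                min(ps[order[j]] * m / (j + 1) for j in range(rank, m)), 1.0)
        assert got.tolist() == pytest.approx(expected)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(1)
        p = rng.uniform(size=500)
        assert bh_adjust(p) == pytest.approx(
            multipletests(p, method="fdr_bh")[1])

    def test_invalid_p_rejected_and_nan_passthrough(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        out = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(out[1]) and not np.isnan(out[0])

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=100)
        padj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(padj[order]) >= -1e-12).all()
        assert (padj >= p).all()


class TestDispersions:
    def test_poisson_data_floors_near_zero(self):
        cfg = SimConfig(seed=9, n_direct_targets=0, n_confounded=0, n_slow=0,
                        dispersion=0.0)
        counts, sheet, _, _ = generate_depletion_experiment(cfg)
        sf = size_factors(counts)
        disp = estimate_dispersions(counts, sheet, sf)
        assert np.median(disp) <= 0.01

    def test_simulated_alpha_recovered(self, null_experiment):
        _, _, _, disp = null_experiment
        assert 0.03 <= np.median(disp) <= 0.08

    def test_constant_gene_floored(self):
        values = pd.DataFrame({f"s{i}": [5, 10] for i in range(4)},
                              index=["flat", "alsoflat"])
        sheet = SampleSheet(pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(4)],
            "condition": ["control", "control", "depletion", "depletion"],
            "timepoint": [0, 0, 0, 0],
            "replicate": [1, 2, 1, 2]}))
        cm = CountMatrix(values)
        disp = estimate_dispersions(cm, sheet, pd.Series(1.0, index=cm.samples))
        # zero empirical variance floors the raw estimate; shrinkage to the
        # (floored) median keeps it at the floor
        assert disp.to_numpy() == pytest.approx(ALPHA_MIN)


class TestLrtTimeseries:
    def test_null_pvalues_uniform(self, null_experiment):
        counts, sheet, sf, disp = null_experiment
        res = lrt_timeseries(counts, sheet, sf, disp, timepoints=[0, 15, 30, 60, 120])
        p = res["pvalue"].dropna().to_numpy()
        assert stats.kstest(p, "uniform").statistic < 0.05

    def test_planted_interaction_detected(self, planted_experiment):
        counts, sheet, sf, disp, truth = planted_experiment
        res = lrt_timeseries(counts, sheet, sf, disp,
                             timepoints=[0, 15, 30, 60, 120]).set_index("gene_id")
        direct = truth.index[truth["class"] == "direct"]
        assert (res.loc[direct, "padj"] < 0.05).mean() >= 0.95

    def test_constant_condition_gives_zero_statistic(self, small_counts):
        counts, sheet = small_counts
        # relabel both conditions identically: full design collapses onto reduced
        table = sheet.table.copy()
        table["condition"] = "control"
        table.loc[2:, "replicate"] = [3, 4]
        merged = SampleSheet(table)
        sf = pd.Series(1.0, index=counts.samples)
        disp = pd.Series(0.1, index=counts.genes)
        with pytest.raises(diffexpr.ContrastError):
            lrt_timeseries(counts, merged, sf, disp)

    def test_statistic_invariant_to_replicate_relabeling(self, planted_experiment):
        counts, sheet, sf, disp, _ = planted_experiment
        res1 = lrt_timeseries(counts, sheet, sf, disp)
        table = sheet.table.copy()
        swap = table["replicate"].map({1: 2, 2: 1, 3: 3})
        table["replicate"] = swap
        res2 = lrt_timeseries(counts, SampleSheet(table), sf, disp)
        assert res1["stat"].to_numpy() == pytest.approx(res2["stat"].to_numpy())

    def test_agrees_with_statsmodels_nb_glm(self):
        """Full-vs-reduced LRT matches a statsmodels NB GLM fit at fixed alpha."""
        import statsmodels.api as sm
        rng = np.random.default_rng(0)
        alpha = 0.1
        n_per = 4
        tps = [0, 15]
        rows = []
        for cond in ("control", "depletion"):
            for t in tps:
                for r in range(1, n_per + 1):
                    rows.append({"sample_id": f"{cond}_{t}_{r}", "condition": cond,
                                 "timepoint": t, "replicate": r})
        sheet = SampleSheet(pd.DataFrame(rows))
        mu = {("control", 0): 20, ("control", 15): 25,
              ("depletion", 0): 22, ("depletion", 15): 60}
        data = {row["sample_id"]: [rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu[(row["condition"], row["timepoint"])]))
                                   for _ in range(1)]
                for row in rows}
        counts = CountMatrix(pd.DataFrame(data, index=["g1"]))
        sf = pd.Series(1.0, index=counts.samples)
        disp = pd.Series(alpha, index=counts.genes)
        res = lrt_timeseries(counts, sheet, sf, disp)

        y = counts.values.iloc[0].to_numpy()
        cond = np.array([s.startswith("depletion") for s in counts.samples], dtype=float)
        tp = np.array([float(s.split("_")[1]) == 15 for s in counts.samples], dtype=float)
        X_full = np.column_stack([np.ones_like(y), cond, tp, cond * tp])
        X_red = np.column_stack([np.ones_like(y), tp])
        fam = sm.families.NegativeBinomial(alpha=alpha)
        llf = sm.GLM(y, X_full, family=fam).fit().llf
        llr = sm.GLM(y, X_red, family=fam).fit().llf
        assert res["stat"].iloc[0] == pytest.approx(2 * (llf - llr), abs=1e-4)


class TestWaldPairwise:
    def test_identical_groups_give_zero_lfc(self, small_counts):
        counts, sheet = small_counts
        values = counts.values.copy()
        values[["depletion_0_1", "depletion_0_2"]] = values[
            ["control_0_1", "control_0_2"]].to_numpy()
        cm = CountMatrix(values)
        sf = pd.Series(1.0, index=cm.samples)
        disp = pd.Series(0.05, index=cm.genes)
        res = wald_pairwise(cm, sheet, sf, disp, 0)
        assert res["log2FC"].to_numpy() == pytest.approx(0.0)
        assert (res["pvalue"] > 0.99).all()

    def test_planted_fourfold_recovered(self):
        cfg = SimConfig(seed=13, effect_log2fc_range=(2.0, 2.0),
                        baseline_target_mean=50.0)
        counts, sheet, _, truth = generate_depletion_experiment(cfg)
        sf = size_factors(counts)
        disp = estimate_dispersions(counts, sheet, sf)
        res = wald_pairwise(counts, sheet, sf, disp, 15).set_index("gene_id")
        direct = truth.index[truth["class"] == "direct"]
        assert res.loc[direct, "log2FC"].mean() == pytest.approx(2.0, abs=0.3)

    def test_all_zero_group_pseudocount_lfc(self):
        values = pd.DataFrame({"control_0_1": [10], "control_0_2": [10],
                               "depletion_0_1": [0], "depletion_0_2": [0]},
                              index=["g1"])
        sheet = SampleSheet(pd.DataFrame({
            "sample_id": list(values.columns),
            "condition": ["control", "control", "depletion", "depletion"],
            "timepoint": [0] * 4, "replicate": [1, 2, 1, 2]}))
        cm = CountMatrix(values)
        res = wald_pairwise(cm, sheet, pd.Series(1.0, index=cm.samples),
                            pd.Series(0.05, index=cm.genes), 0)
        assert res["log2FC"].iloc[0] == pytest.approx(np.log2(0.5 / 10.5), abs=1e-9)

    def test_missing_timepoint_is_contrast_error(self, small_counts):
        counts, sheet = small_counts
        with pytest.raises(diffexpr.ContrastError):
            wald_pairwise(counts, sheet, pd.Series(1.0, index=counts.samples),
                          pd.Series(0.05, index=counts.genes), 99)

    def test_direction_agrees_with_lrt_on_planted_genes(self, planted_experiment):
        counts, sheet, sf, disp, truth = planted_experiment
        res = wald_pairwise(counts, sheet, sf, disp, 15).set_index("gene_id")
        strong = truth.index[(truth["class"] == "direct")
                             & (truth["lfc_t15"].abs() >= 1)]
        sign_match = np.sign(res.loc[strong, "log2FC"]) == np.sign(
            truth.loc[strong, "lfc_t15"])
        assert sign_match.mean() >= 0.99


class TestFdrControl:
    def test_null_discovery_fraction_bounded(self, null_experiment):
        counts, sheet, sf, disp = null_experiment
        res = lrt_timeseries(counts, sheet, sf, disp, timepoints=[0, 15, 30, 60, 120])
        assert (res["padj"] < 0.05).mean() <= 0.07
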