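"""NB-GLM LRT machinery: normalization factors, dispersion, LRT, BH."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import kstest

from peakforge.differential import (
    bh_adjust,
    design_matrix,
    diff_genes_day90,
    diff_peaks,
    estimate_dispersion,
    nb_lrt,
    size_factors,
)
from peakforge.intervals import CountMatrix
from peakforge.simulate import (
    SimulationConfig,
    make_annotation,
    make_count_matrix,
    make_design_table,
    make_expression_matrix,
)


def cm_from(arr, samples=None):
    arr = np.asarray(arr)
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    df = pd.DataFrame(arr, columns=samples)
    return CountMatrix(counts=df, library_sizes=df.sum(axis=0))


class TestSizeFactors:
    def test_identical_columns_give_ones(self, rng):
        col = rng.integers(1, 200, size=40)
        cm = cm_from(np.column_stack([col] * 4))
        assert np.allclose(size_factors(cm), 1.0)

    def test_doubled_column_doubles_factor(self, rng):
        col = rng.integers(1, 200, size=40)
        cm = cm_from(np.column_stack([col, 2 * col]))
        sf = size_factors(cm)
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0)

    def test_requires_an_all_positive_feature(self):
        cm = cm_from([[0, 5], [3, 0]])
        with pytest.raises(ValueError):
            size_factors(cm)


class TestDispersion:
    def test_poisson_data_near_zero(self, design, rng):
        mu = rng.uniform(50, 500, size=300)
        counts = rng.poisson(mu[:, None], size=(300, len(design)))
        alpha = estimate_dispersion(cm_from(counts, list(design.index)), design)
        assert alpha.median() < 0.05

    def test_planted_dispersion_recovered(self, design, rng):
        alpha_true = 0.2
        mu = rng.uniform(100, 400, size=400)
        r = 1 / alpha_true
        counts = rng.negative_binomial(
            r, r / (r + mu[:, None]), size=(400, len(design))
        )
        alpha = estimate_dispersion(cm_from(counts, list(design.index)), design)
        assert 0.5 * alpha_true < alpha.median() < 1.5 * alpha_true

    def test_constant_counts_floor(self, design):
        counts = np.full((20, len(design)), 37)
        alpha = estimate_dispersion(cm_from(counts, list(design.index)), design)
        assert (alpha <= 1e-6).all()


class TestNbLrt:
    def test_null_features_have_flat_statistics(self, design, rng):
        counts = rng.poisson(100, size=(200, len(design)))
        cm = cm_from(counts, list(design.index))
        fit = nb_lrt(cm, design, full=("size", "timepoint"), reduced=("size",))
        assert (fit.table["lrt_stat"] >= -1e-6).all()
        assert fit.table["pvalue"].mean() > 0.3

    def test_matches_poisson_glm_oracle_at_small_alpha(self, design, rng):
        counts = rng.poisson(rng.uniform(30, 300, size=(60, 1)),
                             size=(60, len(design)))
        cm = cm_from(counts, list(design.index))
        tiny = pd.Series(1e-10, index=cm.feature_ids)
        ones = pd.Series(1.0, index=cm.sample_ids)
        fit = nb_lrt(cm, design, full=("size", "timepoint"), reduced=("size",),
                     alpha=tiny, factors=ones)
        x_full, _ = design_matrix(design, ("size", "timepoint"))
        x_red, _ = design_matrix(design, ("size",))
        for i in range(60):
            y = counts[i]
            llf = sm.GLM(y, x_full, family=sm.families.Poisson()).fit().llf
            llr = sm.GLM(y, x_red, family=sm.families.Poisson()).fit().llf
            assert fit.table["lrt_stat"].iloc[i] == pytest.approx(
                2 * (llf - llr), abs=1e-3
            )

    def test_null_pvalues_uniform(self, design, rng):
        # null NB counts at the generator's median base mean (100); the
        # LRT is fed the generating dispersion, isolating its own
        # chi-square calibration from dispersion-estimation noise
        alpha_true = 0.1
        r = 1 / alpha_true
        counts = rng.negative_binomial(r, r / (r + 100.0),
                                       size=(2000, len(design)))
        cm = cm_from(counts, list(design.index))
        fit = nb_lrt(cm, design, full=("size", "timepoint"), reduced=("size",),
                     alpha=pd.Series(alpha_true, index=cm.feature_ids))
        p = fit.table["pvalue"].dropna()
        assert kstest(p, "uniform").pvalue > 0.01
        assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.01)

    def test_reduced_must_nest_in_full(self, design, rng):
        cm = cm_from(rng.poisson(50, size=(5, len(design))), list(design.index))
        with pytest.raises(ValueError):
            nb_lrt(cm, design, full=("size",), reduced=("timepoint",))

    def test_log2fc_recovery_bias(self, design):
        biases = []
        for seed in range(30, 35):
            cfg = SimulationConfig(seed=seed, nb_dispersion=0.1, effect_log2fc=2.5)
            cm, truth = make_count_matrix(400, design, cfg)
            fit = nb_lrt(cm, design, full=("size", "timepoint"), reduced=("size",))
            lfc_cols = [c for c in fit.table.columns if c.startswith("log2fc_")]
            # for each affected peak compare the contrast at its active
            # timepoint with the planted effect (reference level excluded)
            for name, row in truth[truth["affected"]].iterrows():
                col = f"log2fc_{row['active_timepoint']}"
                if col in lfc_cols:
                    biases.append(fit.table.loc[name, col] - row["log2fc"])
        assert abs(np.mean(biases)) < 0.1


class TestBH:
    def test_single_pvalue_identity(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_hand_step_up(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_order_invariance(self, rng):
        p = rng.random(50)
        perm = rng.permutation(50)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_matches_definitional_oracle(self, rng):
        p = rng.random(40)
        adj = bh_adjust(p)
        m = len(p)
        order = np.argsort(p)
        for rank_i, i in enumerate(order, start=1):
            candidates = [
                min(1.0, m * p[j] / rank_j)
                for rank_j, j in enumerate(order, start=1)
                if rank_j >= rank_i
            ]
            assert adj[i] == pytest.approx(min(candidates))

    def test_nan_excluded_from_m(self):
        adj = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(adj[1])
        assert adj[0] == pytest.approx(min(1.0, 2 * 0.01 / 1))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([1.5])


class TestDiffPeaks:
    def test_planted_effects_recovered_with_fdr_control(self, design):
        fdps, powers = [], []
        for seed in (1, 2, 3):
            cfg = SimulationConfig(seed=seed)
            cm, truth = make_count_matrix(2000, design, cfg)
            table = diff_peaks(cm, design)
            sig = table["significant"]
            fdps.append((sig & ~truth["affected"]).sum() / max(1, sig.sum()))
            powers.append((sig & truth["affected"]).sum()
                          / truth["affected"].sum())
        assert np.mean(fdps) <= 0.10
        assert np.mean(powers) > 0.5

    def test_infinite_lfc_threshold_blocks_everything(self, design):
        cfg = SimulationConfig(seed=4)
        cm, _ = make_count_matrix(300, design, cfg)
        table = diff_peaks(cm, design, lfc_min=np.inf)
        assert not table["significant"].any()

    def test_sub_threshold_effect_excluded_by_filter(self, design):
        cfg = SimulationConfig(seed=5, effect_log2fc=1.0)
        cm, truth = make_count_matrix(600, design, cfg)
        table = diff_peaks(cm, design, lfc_min=2.0)
        detected = table["padj"] < 0.10
        assert detected.any()  # the LRT sees the sub-threshold effect
        assert not table["significant"].any()  # the fold-change filter removes it


class TestDiffGenesDay90:
    def test_planted_size_effect_recovered(self, genome, design):
        cfg = SimulationConfig(seed=6)
        em, truth = make_expression_matrix(genome, design, cfg)
        table = diff_genes_day90(em, design)
        up = truth[(truth["sign"] > 0)].index
        recovered = table.loc[up, "significant"]
        assert recovered.mean() > 0.5
        assert (table.loc[up, "log2fc_large"] > 0).all()
        fdp = (table["significant"] & ~truth["affected"]).sum() / max(
            1, table["significant"].sum()
        )
        assert fdp <= 0.2

    def test_contrast_identity(self, genome, design):
        cfg = SimulationConfig(seed=7)
        em, _ = make_expression_matrix(genome, design, cfg)
        table = diff_genes_day90(em, design)
        assert np.allclose(
            table["log2fc_average_vs_large"],
            table["log2fc_average"] - table["log2fc_large"],
        )

    def test_reference_relabel_flips_signs(self, genome, design):
        cfg = SimulationConfig(seed=8)
        em, _ = make_expression_matrix(genome, design, cfg)
        table = diff_genes_day90(em, design)
        relev = design.copy()
        relev["size"] = pd.Categorical(
            relev["size"].astype(str), categories=["large", "average", "small"]
        )
        flipped = diff_genes_day90(em, relev)
        assert np.allclose(
            flipped["log2fc_small"], -table["log2fc_large"], atol=1e-4
        )

    def test_requires_enough_samples(self, genome, design):
        cfg = SimulationConfig(seed=9)
        em, _ = make_expression_matrix(genome, design, cfg)
        with pytest.raises(ValueError):
            diff_genes_day90(em, design, timepoint="NOPE")
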