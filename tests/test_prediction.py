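"""Binned-annotation logistic models: binning, labels, pruning, fitting,
calibration, ROC, and reporting arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from eqtlprio import SimConfig
from eqtlprio.prediction import (
    FDR_LEVELS,
    MODEL_FACTORS,
    STATE_LEVELS,
    PredictionModel,
    SeparationError,
    assign_gwas_labels,
    bin_cadd,
    bin_distance,
    bin_fdr,
    bin_maf,
    calibration_table,
    coefficient_z_distance,
    fit_model,
    ld_prune,
    predict_probs,
    report_reduction,
    roc_auc,
    top_bin_crosstab,
)
from eqtlprio.synthetic import (
    simulate_feature_table,
    simulate_genotypes,
    simulate_gwas_catalog,
)
from eqtlprio.types import GenotypeMatrix


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

class TestBinning:
    @pytest.mark.parametrize("d,label", [
        (0, "0 kb (within gene)"),
        (1, "(0-10 kb]"),
        (10_000, "(0-10 kb]"),
        (10_001, "(10-50 kb]"),
        (50_000, "(10-50 kb]"),
        (50_001, "(50-100 kb]"),
        (100_000, "(50-100 kb]"),
    ])
    def test_distance_edges(self, d, label):
        assert bin_distance(np.array([d]))[0] == label

    @pytest.mark.parametrize("m,label", [
        (0.01, "[1-5%]"),
        (0.05, "[1-5%]"),
        (0.0501, "(5-10%]"),
        (0.10, "(5-10%]"),
        (0.101, ">10%"),
        (0.5, ">10%"),
    ])
    def test_maf_edges(self, m, label):
        assert bin_maf(np.array([m]))[0] == label

    @pytest.mark.parametrize("f,label", [
        (0.0, "[0-1%)"),
        (0.0099, "[0-1%)"),
        (0.01, "[1-5%)"),
        (0.03, "[1-5%)"),
        (0.05, "[5-10%)"),
        (0.10, "[10-50%)"),
        (0.499, "[10-50%)"),
        (0.50, ">50%"),
        (1.0, ">50%"),
    ])
    def test_fdr_edges_right_open(self, f, label):
        assert bin_fdr(np.array([f]))[0] == label

    @pytest.mark.parametrize("c,label", [
        (0.0, "[0, 5]"),
        (5.0, "[0, 5]"),       # first bin closed on both sides
        (5.0001, "(5, 10]"),
        (10.0, "(5, 10]"),
        (20.0, "(10, 20]"),
        (30.0, "(20, 30]"),
        (60.0, "(30, 60]"),
    ])
    def test_cadd_edges(self, c, label):
        assert bin_cadd(np.array([c]))[0] == label

    def test_cadd_above_range_clamped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = bin_cadd(np.array([75.0]))
        assert out[0] == "(30, 60]"
        assert "clamped" in caplog.text


# ---------------------------------------------------------------------------
# GWAS label assignment
# ---------------------------------------------------------------------------

def _panel(dosages, positions):
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    return GenotypeMatrix(
        sample_ids=np.array([f"s{i}" for i in range(n)]),
        snp_ids=np.array([f"r{j}" for j in range(p)]),
        positions=np.asarray(positions),
        dosages=dosages,
    )


class TestAssignGwasLabels:
    def _snps(self, positions):
        return pd.DataFrame({
            "snp_id": [f"r{j}" for j in range(len(positions))],
            "position": positions,
        })

    def test_catalog_member_labelled(self):
        rng = np.random.default_rng(0)
        gm = _panel(rng.binomial(2, 0.3, (50, 3)), [100, 200, 300])
        lab = assign_gwas_labels(self._snps([100, 200, 300]), ["r1"], gm)
        assert lab.tolist() == [0, 1, 0]

    def test_perfect_ld_proxy_labelled(self):
        rng = np.random.default_rng(1)
        a = rng.binomial(2, 0.4, 80)
        b = rng.binomial(2, 0.4, 80)
        gm = _panel(np.column_stack([a, a, b]), [100, 500, 900])
        lab = assign_gwas_labels(self._snps([100, 500, 900]), ["r0"], gm)
        # r1 duplicates r0 (r^2 = 1 > 0.8); r2 is independent
        assert lab.tolist() == [1, 1, 0]

    def test_proxy_outside_window_not_labelled(self):
        rng = np.random.default_rng(2)
        a = rng.binomial(2, 0.4, 80)
        gm = _panel(np.column_stack([a, a]), [0, 1_000_000])
        lab = assign_gwas_labels(self._snps([0, 1_000_000]), ["r0"], gm,
                                 window=250_000)
        assert lab.tolist() == [1, 0]

    def test_catalog_snp_absent_from_reference_warns(self, caplog):
        rng = np.random.default_rng(3)
        gm = _panel(rng.binomial(2, 0.3, (40, 2)), [10, 20])
        snps = pd.DataFrame({"snp_id": ["r0", "r1", "rsX"],
                             "position": [10, 20, 30]})
        with caplog.at_level("WARNING"):
            lab = assign_gwas_labels(snps, ["rsX"], gm)
        assert lab.tolist() == [0, 0, 1]  # labels itself, proxies impossible
        assert "absent from reference" in caplog.text


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

class TestLdPrune:
    def test_independent_snps_mostly_retained(self):
        cfg = SimConfig(n_cohorts=1, n_samples=(500,), n_genes=20,
                        n_snps_per_gene=10, seed=41)
        gm = simulate_genotypes(cfg, 0)
        kept = ld_prune(gm)
        assert len(kept) >= 0.95 * gm.n_snps

    def test_duplicate_column_pruned(self):
        rng = np.random.default_rng(42)
        base = rng.binomial(2, 0.4, (300, 10)).astype(float)
        dup = np.column_stack([base, base[:, 0]])  # snp r10 duplicates r0
        gm = _panel(dup, np.arange(11) * 1000)
        kept = ld_prune(gm, window=11, step=5)
        assert len({"r0", "r10"} & kept) == 1
        assert len(kept) == 10

    def test_strong_ld_blocks_thinned(self):
        cfg = SimConfig(n_cohorts=1, n_samples=(400,), n_genes=20,
                        n_snps_per_gene=10, ld_rho=0.97, seed=43)
        gm = simulate_genotypes(cfg, 0)
        kept = ld_prune(gm)
        assert len(kept) < 0.8 * gm.n_snps

    def test_monomorphic_dropped(self):
        rng = np.random.default_rng(44)
        d = rng.binomial(2, 0.3, (100, 6)).astype(float)
        d[:, 2] = 1.0
        gm = _panel(d, np.arange(6) * 100)
        assert "r2" not in ld_prune(gm, window=6, step=2)

    @pytest.mark.parametrize("kwargs", [
        {"window": 5, "step": 5},
        {"window": 5, "step": 0},
        {"vif_threshold": 1.0},
    ])
    def test_bad_parameters(self, kwargs):
        gm = _panel(np.random.default_rng(0).binomial(2, 0.3, (50, 8)),
                    np.arange(8) * 100)
        with pytest.raises(ValueError):
            ld_prune(gm, **kwargs)


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def _base_features(n):
    return pd.DataFrame({
        "snp_id": [f"r{i}" for i in range(n)],
        "probe_id": "p",
        "gene_id": "g",
        "distance_bin": pd.Categorical(["0 kb (within gene)"] * n),
        "maf_bin": pd.Categorical([">10%"] * n),
        "chrom_state": pd.Categorical(["(13) Heterochromatin"] * n),
        "structural_class": pd.Categorical(["none"] * n),
        "fdr_bin": pd.Categorical([">50%"] * n),
    })


class TestFitModel:
    def test_intercept_only_recovers_logit_of_rate(self):
        n = 2_000
        feats = _base_features(n)
        y = np.zeros(n)
        y[:400] = 1  # 20% rate
        m = fit_model(feats, y, "M3")
        # all factors sit at base level, so the fit is intercept-only and
        # the ML intercept is exactly the logit of the sample rate
        assert m.params["const"] == pytest.approx(logit(0.2), abs=1e-6)
        assert len(m.params) == 1

    def test_null_coefficients_near_zero(self):
        cfg = SimConfig(seed=45)
        feats = simulate_feature_table(30_000, cfg)
        rng = np.random.default_rng(46)
        y = rng.random(30_000) < 0.10
        m = fit_model(feats, y.astype(int), "M3")
        z = (m.params.drop("const") / m.bse.drop("const")).abs()
        assert (z < 4).all()

    def test_recovers_generating_coefficients(self):
        cfg = SimConfig(seed=47, gwas_coefs={
            "fdr_bin:[0-1%)": 0.7, "fdr_bin:[1-5%)": 0.45,
            "fdr_bin:[5-10%)": 0.3, "fdr_bin:[10-50%)": 0.2,
            "chrom_state:(1) Active Promoter": 0.6,
            "chrom_state:(4) Strong Enhancer": 0.65,
            "chrom_state:(5) Strong Enhancer": 0.5,
            "maf_bin:[1-5%]": -1.6, "maf_bin:(5-10%]": -0.9,
            "distance_bin:(0-10 kb]": -0.1,
            "distance_bin:(10-50 kb]": -0.15,
            "distance_bin:(50-100 kb]": -0.2,
        })
        feats = simulate_feature_table(120_000, cfg)
        catalog, truth = simulate_gwas_catalog(feats, cfg)
        m = fit_model(catalog, catalog["gwas_hit"], "M3")
        zd = coefficient_z_distance(m, truth)
        assert (zd["z"] < 4).mean() >= 0.95
        assert zd["z"].median() < 2

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            fit_model(_base_features(10), np.zeros(10), "M9")

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_model(_base_features(10), np.zeros(10), "M3")

    def test_missing_feature_column_rejected(self):
        feats = _base_features(20).drop(columns="fdr_bin")
        y = np.array([0, 1] * 10)
        with pytest.raises(ValueError, match="fdr_bin"):
            fit_model(feats, y, "M3")

    def test_missing_base_level_rejected(self):
        feats = _base_features(20)
        feats["maf_bin"] = pd.Categorical(["[1-5%]"] * 20)
        y = np.array([0, 1] * 10)
        with pytest.raises(ValueError, match="base level"):
            fit_model(feats, y, "M3")

    def test_separation_detected_and_named(self):
        n = 200
        feats = _base_features(n)
        states = ["(13) Heterochromatin"] * n
        y = np.zeros(n)
        # every pair in Active Promoter is a hit and nothing else is:
        # that dummy column perfectly predicts the label
        states[:20] = ["(1) Active Promoter"] * 20
        y[:20] = 1
        feats["chrom_state"] = pd.Categorical(states, categories=STATE_LEVELS)
        with pytest.raises(SeparationError, match="Active Promoter"):
            fit_model(feats, y, "M3")

    def test_ridge_fallback_fits_separated_data(self, caplog):
        n = 200
        feats = _base_features(n)
        states = ["(13) Heterochromatin"] * n
        states[:20] = ["(1) Active Promoter"] * 20
        y = np.zeros(n)
        y[:20] = 1
        feats["chrom_state"] = pd.Categorical(states, categories=STATE_LEVELS)
        with caplog.at_level("WARNING"):
            m = fit_model(feats, y, "M3", ridge=1.0)
        assert np.isfinite(m.params).all()
        assert "ridge" in caplog.text

    def test_model_menu_factor_sets(self):
        assert set(MODEL_FACTORS) == {"M1", "M2", "M3", "M3B", "M3+CADD"}
        assert "distance_bin" not in MODEL_FACTORS["M3B"]
        assert "cadd_bin" in MODEL_FACTORS["M3+CADD"]


# ---------------------------------------------------------------------------
# prediction and evaluation
# ---------------------------------------------------------------------------

def _toy_model():
    params = pd.Series({
        "const": -3.0,
        "fdr_bin[[0-1%)]": 1.0,
        "fdr_bin[[1-5%)]": 0.5,
    })
    return PredictionModel(
        model_name="toy", params=params,
        bse=pd.Series(0.1, index=params.index),
        wald_p=pd.Series(0.5, index=params.index),
        factors={"fdr_bin": (["[0-1%)", "[1-5%)"], ">50%")},
    )


class TestPredict:
    def test_all_base_row_is_expit_intercept(self):
        m = _toy_model()
        feats = pd.DataFrame({"fdr_bin": [">50%"]})
        assert predict_probs(m, feats)[0] == pytest.approx(expit(-3.0))

    def test_coefficient_ordering_propagates(self):
        m = _toy_model()
        feats = pd.DataFrame({"fdr_bin": ["[0-1%)", "[1-5%)", ">50%"]})
        p = predict_probs(m, feats)
        assert p[0] > p[1] > p[2]
        np.testing.assert_allclose(p, expit([-2.0, -2.5, -3.0]))

    def test_unseen_level_maps_to_base(self, caplog):
        m = _toy_model()
        with caplog.at_level("WARNING"):
            p = predict_probs(m, pd.DataFrame({"fdr_bin": ["[5-10%)"]}))
        assert p[0] == pytest.approx(expit(-3.0))
        assert "unseen" in caplog.text

    def test_training_mean_identity(self):
        """With an intercept, ML fitted probabilities average to the
        observed label rate on the training data."""
        cfg = SimConfig(seed=48)
        feats = simulate_feature_table(20_000, cfg)
        rng = np.random.default_rng(49)
        y = (rng.random(20_000) < 0.08).astype(int)
        m = fit_model(feats, y, "M2")
        assert predict_probs(m, feats).mean() == pytest.approx(y.mean(), abs=1e-6)


class TestCalibration:
    def test_bin_counts_partition_reference_model(self):
        rng = np.random.default_rng(50)
        probs = {"M3": rng.random(5_000) * 0.2, "M2": rng.random(5_000) * 0.1}
        y = rng.integers(0, 2, 5_000)
        tab = calibration_table(probs, y, n_bins=10)
        assert tab["n_M3"].sum() == 5_000
        assert len(tab.attrs["edges"]) == 11

    def test_constant_predictor_lands_in_last_bin(self):
        probs = {"M3": np.full(100, 0.05)}
        tab = calibration_table(probs, np.zeros(100), n_bins=5)
        assert tab["n_M3"].tolist() == [0, 0, 0, 0, 100]

    def test_missing_reference_model_rejected(self):
        with pytest.raises(ValueError, match="reference model"):
            calibration_table({"M1": np.array([0.1])}, [0], ref_model="M3")

    def test_well_calibrated_model_tracks_diagonal(self):
        rng = np.random.default_rng(51)
        p = rng.uniform(0.05, 0.95, 40_000)
        y = (rng.random(40_000) < p).astype(int)
        tab = calibration_table({"M3": p}, y, n_bins=10)
        mid = (tab["bin_lo"] + tab["bin_hi"]) / 2
        np.testing.assert_allclose(tab["obs_prop_M3"], mid, atol=0.05)


class TestRoc:
    def test_constant_scores_auc_half(self):
        y = np.array([0, 1, 0, 1, 1])
        assert roc_auc(np.full(5, 0.3), y).auc == pytest.approx(0.5)

    def test_perfect_separation_auc_one(self):
        y = np.array([0, 0, 0, 1, 1])
        p = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        assert roc_auc(p, y).auc == pytest.approx(1.0)

    def test_matches_pair_counting_oracle_with_ties(self):
        y = np.array([0, 0, 1, 1, 0, 1])
        p = np.array([0.1, 0.4, 0.35, 0.8, 0.4, 0.9])
        wins = ties = 0
        for pi in p[y == 1]:
            for pj in p[y == 0]:
                wins += pi > pj
                ties += pi == pj
        oracle = (wins + 0.5 * ties) / (y.sum() * (len(y) - y.sum()))
        assert roc_auc(p, y).auc == pytest.approx(oracle)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestTopBinCrosstab:
    def test_layout_and_conservation(self):
        cfg = SimConfig(seed=52)
        feats = simulate_feature_table(4_000, cfg)
        rng = np.random.default_rng(53)
        probs = rng.random(4_000) * 0.2
        edges = np.linspace(0.0, 0.2, 11)
        out = top_bin_crosstab(feats, probs, edges, n_top=2)
        assert out["table"].shape == (16, 5)
        assert list(out["table"].index) == STATE_LEVELS
        assert list(out["table"].columns) == FDR_LEVELS
        assert out["table"].to_numpy().sum() == out["n_pairs"]
        assert out["threshold"] == pytest.approx(edges[-3])
        assert out["n_pairs"] == int((probs >= edges[-3]).sum())
        assert out["n_snps"] <= out["n_pairs"]

    def test_empty_top_bins(self):
        cfg = SimConfig(seed=54)
        feats = simulate_feature_table(100, cfg)
        out = top_bin_crosstab(feats, np.full(100, 0.01),
                               np.linspace(0, 1, 11), n_top=2)
        assert out["n_pairs"] == 0
        assert out["table"].to_numpy().sum() == 0


class TestReportReduction:
    def test_search_space_reduction_arithmetic(self):
        out = report_reduction(78_228, 2_067_404, 7_101)
        assert out["reduction_pct"] == pytest.approx(96.2, abs=0.05)
        assert out["catalog_overlap_pct"] == pytest.approx(9.1, abs=0.05)

    def test_no_reduction_when_everything_retained(self):
        assert report_reduction(100, 100, 10)["reduction_pct"] == 0.0

    def test_degenerate_denominators_are_nan(self):
        out = report_reduction(0, 0, 0)
        assert np.isnan(out["reduction_pct"])
        assert np.isnan(out["catalog_overlap_pct"])
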