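import numpy as np
import pandas as pd
import pytest

from gscore import MRModel, consensus, egger, harmonize, ivw, mv_ivw
from gscore.errors import (
    CollinearityError,
    EmptyInstrumentError,
    ValidationError,
)
from gscore.mr import (
    HarmonizedSet,
    MREstimate,
    MRResult,
    sensitivity_filter,
    weighted_median,
)

from conftest import make_sumstats


def make_h(bx, by, sy, sx=None, bx2=None, sx2=None, excluded=None):
    bx = np.asarray(bx, float)
    data = {
        "snp": [f"rs{i}" for i in range(len(bx))],
        "bx": bx,
        "sx": np.asarray(sx, float) if sx is not None else np.full(len(bx), 0.01),
        "by": np.asarray(by, float),
        "sy": np.asarray(sy, float),
        "flipped": False,
        "excluded": np.asarray(excluded, bool) if excluded is not None
        else np.zeros(len(bx), bool),
        "reason": "",
    }
    if bx2 is not None:
        data["bx2"] = np.asarray(bx2, float)
        data["sx2"] = np.asarray(sx2, float) if sx2 is not None else data["sx"]
    return HarmonizedSet(df=pd.DataFrame(data), exposure="int",
                         outcome="cad", exposure2="edu" if bx2 is not None else None)


class TestHarmonize:
    @staticmethod
    def _tables(out_a1, out_a2, by=0.02):
        exp = make_sumstats(trait="int", snp=["rs1", "rs2"], a1=["A", "C"],
                            a2=["G", "T"], eaf=[0.3, 0.4],
                            beta=[0.02, 0.03], se=[0.005, 0.005],
                            p=[1e-4, 1e-5], n=[1e5, 1e5])
        out = make_sumstats(trait="cad", snp=["rs1", "rs2"],
                            a1=[out_a1, "C"], a2=[out_a2, "T"],
                            eaf=[0.3, 0.4], beta=[by, 0.01],
                            se=[0.006, 0.006], p=[0.01, 0.1], n=[2e5, 2e5])
        return exp, out

    def test_swapped_alleles_flip_outcome_sign(self):
        exp, out = self._tables("G", "A", by=0.02)
        h = harmonize(exp, out)
        row = h.df.set_index("snp").loc["rs1"]
        assert row["by"] == pytest.approx(-0.02)
        assert bool(row["flipped"])

    def test_identical_coding_unchanged(self):
        exp, out = self._tables("A", "G", by=0.02)
        h = harmonize(exp, out)
        row = h.df.set_index("snp").loc["rs1"]
        assert row["by"] == pytest.approx(0.02)
        assert not bool(row["flipped"])

    def test_palindromic_excluded_with_reason(self):
        exp = make_sumstats(trait="int", snp=["rs1"], a1=["A"], a2=["T"],
                            eaf=[0.3], beta=[0.02], se=[0.005],
                            p=[1e-4], n=[1e5])
        out = make_sumstats(trait="cad", snp=["rs1"], a1=["A"], a2=["T"],
                            eaf=[0.3], beta=[0.01], se=[0.006],
                            p=[0.01], n=[2e5])
        h = harmonize(exp, out)
        assert bool(h.df["excluded"].iloc[0])
        assert h.df["reason"].iloc[0] == "palindromic"

    def test_missing_in_outcome_dropped_with_reason(self):
        exp = make_sumstats(trait="int", snp=["rs1", "rs2"], a1=["A", "C"],
                            a2=["G", "T"], eaf=[0.3, 0.4],
                            beta=[0.02, 0.03], se=[0.005, 0.005],
                            p=[1e-4, 1e-5], n=[1e5, 1e5])
        out = make_sumstats(trait="cad", snp=["rs1"], a1=["A"], a2=["G"],
                            eaf=[0.3], beta=[0.01], se=[0.006],
                            p=[0.01], n=[2e5])
        h = harmonize(exp, out)
        assert h.df.set_index("snp").loc["rs2", "reason"] == "missing_in_outcome"
        assert h.n_retained == 1

    def test_zero_overlap_raises(self):
        exp = make_sumstats(trait="int", snp=["rs1"], a1=["A"], a2=["G"],
                            eaf=[0.3], beta=[0.02], se=[0.005], p=[1e-4],
                            n=[1e5])
        out = make_sumstats(trait="cad", snp=["rsX"], a1=["A"], a2=["G"],
                            eaf=[0.3], beta=[0.01], se=[0.006], p=[0.01],
                            n=[2e5])
        with pytest.raises(EmptyInstrumentError):
            harmonize(exp, out)

    def test_shared_cohort_tag_warns(self, caplog):
        exp, out = self._tables("A", "G")
        exp.cohort = out.cohort = "ukb"
        with caplog.at_level("WARNING"):
            harmonize(exp, out)
        assert "two-sample" in caplog.text


class TestIVW:
    def test_wald_ratio_limit(self):
        h = make_h(bx=[0.02, 0.02], by=[0.01, 0.01], sy=[0.005, 0.005])
        assert ivw(h).beta == pytest.approx(0.5, rel=1e-12)

    def test_null_outcome_gives_zero(self):
        h = make_h(bx=[0.02, 0.03, 0.04], by=[0.0, 0.0, 0.0],
                   sy=[0.005] * 3)
        assert ivw(h).beta == 0.0

    def test_equals_wls_through_origin_oracle(self, rng):
        """Independent oracle: statsmodels WLS without intercept."""
        import statsmodels.api as sm

        for _ in range(20):
            m = 242
            bx = rng.normal(0.02, 0.01, m)
            by = -0.3 * bx + rng.normal(0, 0.005, m)
            sy = rng.uniform(0.003, 0.01, m)
            h = make_h(bx=bx, by=by, sy=sy)
            est = ivw(h)
            wls = sm.WLS(by, bx, weights=1.0 / sy**2).fit()
            assert est.beta == pytest.approx(float(wls.params[0]), abs=1e-10)

    def test_excluded_rows_ignored(self):
        h = make_h(bx=[0.02, 0.02, 1.0], by=[0.01, 0.01, 9.0],
                   sy=[0.005] * 3, excluded=[False, False, True])
        assert ivw(h).beta == pytest.approx(0.5, rel=1e-12)
        assert ivw(h).n_snps == 2

    def test_fewer_than_two_snps_raises(self):
        h = make_h(bx=[0.02], by=[0.01], sy=[0.005])
        with pytest.raises(EmptyInstrumentError):
            ivw(h)


class TestEgger:
    def test_exact_linear_case(self):
        bx = np.array([0.01, 0.02, 0.03, 0.04])
        h = make_h(bx=bx, by=0.5 * bx, sy=[0.005] * 4)
        est = egger(h)
        assert est.beta == pytest.approx(0.5, abs=1e-10)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine_case_recovers_intercept(self):
        bx = np.array([0.01, 0.02, 0.03, 0.04])
        h = make_h(bx=bx, by=0.002 + 0.5 * bx, sy=[0.005] * 4)
        est = egger(h)
        assert est.beta == pytest.approx(0.5, abs=1e-10)
        assert est.intercept == pytest.approx(0.002, abs=1e-12)

    def test_slope_equals_ivw_when_intercept_constrained(self, rng):
        from gscore.mr import _weighted_regression

        bx = np.abs(rng.normal(0.02, 0.01, 50))
        by = -0.3 * bx + rng.normal(0, 0.004, 50)
        sy = rng.uniform(0.003, 0.01, 50)
        h = make_h(bx=bx, by=by, sy=sy)
        coef, _, _ = _weighted_regression(bx[:, None], by, 1.0 / sy**2)
        assert ivw(h).beta == pytest.approx(float(coef[0]), abs=1e-12)

    def test_reorientation_makes_result_sign_independent(self, rng):
        bx = rng.normal(0.02, 0.01, 30)
        by = 0.4 * bx + rng.normal(0, 0.003, 30)
        sy = rng.uniform(0.003, 0.01, 30)
        flip = rng.random(30) < 0.5
        h1 = make_h(bx=bx, by=by, sy=sy)
        h2 = make_h(bx=np.where(flip, -bx, bx),
                    by=np.where(flip, -by, by), sy=sy)
        assert egger(h1).beta == pytest.approx(egger(h2).beta, rel=1e-12)

    def test_constant_bx_collinear(self):
        h = make_h(bx=[0.02] * 5, by=[0.01] * 5, sy=[0.005] * 5)
        with pytest.raises(CollinearityError):
            egger(h)


class TestWeightedMedian:
    def test_equal_weights_simple_median(self):
        h = make_h(bx=[1.0, 1.0, 1.0], by=[0.1, 0.5, 0.9], sy=[1.0] * 3)
        est = weighted_median(h, n_boot=0)
        assert est.beta == pytest.approx(0.5, abs=1e-12)

    def test_equal_weights_equals_numpy_median_odd_counts(self, rng):
        for m in (3, 5, 7, 9):
            by = rng.normal(0, 1, m)
            h = make_h(bx=np.ones(m), by=by, sy=np.ones(m))
            est = weighted_median(h, n_boot=0)
            assert est.beta == pytest.approx(float(np.median(by)), abs=1e-12)

    def test_dominant_weight_pins_estimate(self):
        # one SNP carries 60% of total weight (weights ~ bx^2/sy^2)
        bx = np.array([np.sqrt(6.0), 1.0, 1.0, 1.0, 1.0])
        ratios = np.array([0.7, 0.1, 0.2, 1.2, 1.5])
        h = make_h(bx=bx, by=ratios * bx, sy=np.ones(5))
        est = weighted_median(h, n_boot=0)
        # cumulative weight crosses 0.5 inside the bracket around 0.7
        assert 0.2 <= est.beta <= 1.2
        assert est.beta == pytest.approx(0.7, abs=0.15)

    def test_breakdown_resistance_with_minority_invalid(self, rng):
        """With <50% of the weight on wildly invalid instruments and tight
        per-ratio noise, the weighted median stays at the truth while the
        IVW mean is dragged away."""
        wm_errs, ivw_errs = [], []
        for _ in range(100):
            m = 60
            bx = np.abs(rng.normal(0.02, 0.005, m))
            by = 0.2 * bx
            by[:20] += rng.uniform(0.002, 0.01, 20)  # 1/3 wildly invalid
            sy = np.full(m, 0.002)
            h = make_h(bx=bx, by=by + rng.normal(0, 0.0002, m), sy=sy)
            wm_errs.append(weighted_median(h, n_boot=0).beta - 0.2)
            ivw_errs.append(ivw(h).beta - 0.2)
        assert abs(np.mean(wm_errs)) < 0.02
        assert abs(np.mean(wm_errs)) < 0.25 * abs(np.mean(ivw_errs))

    def test_zero_bx_dropped(self, caplog):
        h = make_h(bx=[0.0, 1.0, 1.0, 1.0], by=[9.0, 0.1, 0.5, 0.9],
                   sy=[1.0] * 4)
        with caplog.at_level("WARNING"):
            est = weighted_median(h, n_boot=0)
        assert est.beta == pytest.approx(0.5, abs=1e-12)
        assert est.n_snps == 3

    def test_bootstrap_reproducible_with_seed(self):
        h = make_h(bx=[1.0, 1.2, 0.8, 1.1], by=[0.1, 0.5, 0.9, 0.4],
                   sy=[0.2] * 4, sx=[0.1] * 4)
        a = weighted_median(h, n_boot=200, seed=5)
        b = weighted_median(h, n_boot=200, seed=5)
        assert a.se == b.se
        assert a.se > 0

    def test_bootstrap_without_seed_rejected(self):
        h = make_h(bx=[1.0, 1.2, 0.8], by=[0.1, 0.5, 0.9], sy=[0.2] * 3)
        with pytest.raises(ValidationError, match="seed"):
            weighted_median(h, n_boot=100, seed=None)


class TestMultivariable:
    def test_exact_two_exposure_solution(self):
        rng = np.random.default_rng(3)
        bx1 = np.abs(rng.normal(0.02, 0.01, 30))
        bx2 = np.abs(rng.normal(0.03, 0.01, 30))
        by = -0.3 * bx1 + 0.1 * bx2
        h = make_h(bx=bx1, by=by, sy=np.full(30, 0.005), bx2=bx2)
        est1, est2 = mv_ivw(h)
        assert est1.beta == pytest.approx(-0.3, abs=1e-10)
        assert est2.beta == pytest.approx(0.1, abs=1e-10)
        assert est1.exposure == "int" and est2.exposure == "edu"

    def test_zero_second_column_reduces_to_ivw(self, rng):
        bx = np.abs(rng.normal(0.02, 0.01, 20))
        by = -0.3 * bx + rng.normal(0, 0.003, 20)
        sy = rng.uniform(0.004, 0.01, 20)
        h2 = make_h(bx=bx, by=by, sy=sy, bx2=np.zeros(20))
        h1 = make_h(bx=bx, by=by, sy=sy)
        (est,) = mv_ivw(h2)
        assert est.beta == pytest.approx(ivw(h1).beta, rel=1e-12)

    def test_rank_deficiency_raises_with_condition_number(self, rng):
        bx = np.abs(rng.normal(0.02, 0.01, 20))
        h = make_h(bx=bx, by=0.1 * bx, sy=np.full(20, 0.005), bx2=2.0 * bx)
        with pytest.raises(CollinearityError, match="condition"):
            mv_ivw(h)


class TestSignEquivariance:
    def test_negating_outcome_negates_all_estimates(self, rng):
        m = 50
        bx = np.abs(rng.normal(0.02, 0.01, m))
        by = -0.25 * bx + rng.normal(0, 0.004, m)
        sy = rng.uniform(0.003, 0.01, m)
        h_pos = make_h(bx=bx, by=by, sy=sy)
        h_neg = make_h(bx=bx, by=-by, sy=sy)
        assert ivw(h_neg).beta == pytest.approx(-ivw(h_pos).beta, rel=1e-12)
        assert egger(h_neg).beta == pytest.approx(-egger(h_pos).beta, rel=1e-12)
        wm_pos = weighted_median(h_pos, n_boot=0).beta
        wm_neg = weighted_median(h_neg, n_boot=0).beta
        assert wm_neg == pytest.approx(-wm_pos, rel=1e-10)


def _result(p_ivw, p_egger, p_wm):
    ests = {
        "IVW": MREstimate("IVW", -0.3, 0.05, p_ivw, 200),
        "Egger": MREstimate("Egger", -0.25, 0.1, p_egger, 200),
        "WeightedMedian": MREstimate("WeightedMedian", -0.28, 0.07, p_wm, 200),
    }
    return MRResult(exposure="int", outcome="cad", estimates=ests,
                    n_snps_used=200)


class TestConsensus:
    @pytest.mark.parametrize("pvals,expected", [
        ((0.01, 0.20, 0.03), True),
        ((0.20, 0.30, 0.01), False),
        ((0.049, 0.051, 0.049), True),   # strict < 0.05 at the boundary
        ((0.05, 0.05, 0.05), False),
        ((0.001, 0.001, 0.9), True),
    ])
    def test_two_of_three_rule(self, pvals, expected):
        res = consensus(_result(*pvals))
        assert res.reliable is expected
        assert res.reported.method == "IVW"

    def test_missing_method_rejected(self):
        res = _result(0.01, 0.01, 0.01)
        del res.estimates["Egger"]
        with pytest.raises(ValidationError, match="Egger"):
            consensus(res)


class TestSensitivityFilter:
    @staticmethod
    def _risk(trait, snp, p):
        return make_sumstats(trait=trait, snp=snp, a1=["A"] * len(snp),
                             a2=["G"] * len(snp), eaf=[0.3] * len(snp),
                             beta=[0.01] * len(snp), se=[0.005] * len(snp),
                             p=p, n=[1e5] * len(snp))

    def test_threshold_is_strict(self):
        h = make_h(bx=[0.02, 0.02, 0.02], by=[0.01] * 3, sy=[0.005] * 3)
        risk = self._risk("bmi", ["rs0", "rs1", "rs2"], [5e-4, 0.002, 1e-3])
        out = sensitivity_filter(h, [risk], p_threshold=1e-3)
        assert out.df["excluded"].tolist() == [True, False, False]
        assert out.df["reason"].iloc[0] == "risk_factor:bmi"
        assert out.filter_counts == {"bmi": 1}

    def test_missing_snp_not_excluded(self):
        h = make_h(bx=[0.02, 0.02], by=[0.01] * 2, sy=[0.005] * 2)
        risk = self._risk("hdl", ["rs0"], [1e-6])
        out = sensitivity_filter(h, [risk])
        assert out.df["excluded"].tolist() == [True, False]

    def test_any_factor_excludes(self):
        h = make_h(bx=[0.02, 0.02, 0.02], by=[0.01] * 3, sy=[0.005] * 3)
        bmi = self._risk("bmi", ["rs0", "rs1", "rs2"], [0.5, 1e-5, 0.5])
        hdl = self._risk("hdl", ["rs0", "rs1", "rs2"], [0.5, 0.5, 1e-5])
        out = sensitivity_filter(h, [bmi, hdl])
        assert out.n_retained == 1
        assert out.filter_counts == {"bmi": 1, "hdl": 1}


class TestMRModel:
    def test_recovers_configured_truth_on_clean_instruments(self):
        """Analytic two-sample tables without pleiotropy (single exposure
        in the outcome model): all methods near the configured effect."""
        from gscore import simulate

        out = simulate.simulate_summary_stats(simulate.SimConfig(seed=77))
        t = out.summary_stats
        model = MRModel.from_summary_stats(t["intelligence"], t["cad"])
        res = model.fit(n_boot=200, seed=9)
        truth = out.truth["beta_intelligence"]
        for method in ("IVW", "Egger", "WeightedMedian"):
            est = res.estimates[method]
            assert est.beta == pytest.approx(truth, abs=4 * est.se)
        assert res.reliable is True
        assert res.n_snps_used == 242

    def test_summary_text_mentions_all_methods(self, mr_tables):
        t = mr_tables.summary_stats
        res = MRModel.from_summary_stats(
            t["intelligence"], t["cad"], t["education"]).fit(
            n_boot=50, seed=2)
        text = res.summary()
        for token in ("IVW", "Egger", "WeightedMedian", "MV-IVW", "consensus"):
            assert token in text
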