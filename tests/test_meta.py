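"""Unit and property tests for the correlation-pooling meta-analysis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualsafe import (
    CorrelationMetaAnalysis,
    EffectSizeRecord,
    apply_reliability_correction,
    convert_to_r,
    generate_synthetic_effect_table,
    normalize_coefficients,
    pool_correlations,
    variance_of_r,
)

def rec(r, n, path="A->B", sid="s", kind="r", df=None):
    return EffectSizeRecord(path_id=path, study_id=sid, n=n, effect_kind=kind,
                            effect_value=r, df=df)


class TestVarianceOfR:
    @pytest.mark.parametrize(
        "r,n,expected",
        [(0.0, 101, 0.01), (0.5, 101, 0.005625), (0.74, 267, (1 - 0.74**2) ** 2 / 266)],
    )
    def test_values(self, r, n, expected):
        assert variance_of_r(r, n) == pytest.approx(expected, rel=1e-12)

    def test_vanishes_as_r_approaches_one(self):
        assert variance_of_r(1 - 1e-9, 50) < 1e-16

    @pytest.mark.parametrize("r,n", [(1.0, 10), (-1.0, 10), (0.3, 1)])
    def test_invalid_inputs(self, r, n):
        with pytest.raises(ValueError):
            variance_of_r(r, n)

    @given(st.floats(-0.99, 0.99), st.integers(5, 10_000))
    def test_positive_and_decreasing_in_n(self, r, n):
        v = variance_of_r(r, n)
        assert v > 0
        assert variance_of_r(r, n + 100) < v


class TestConvertToR:
    def test_r_passthrough(self):
        assert convert_to_r(rec(0.44, 100)) == 0.44

    def test_null_t(self):
        assert convert_to_r(rec(0.0, 52, kind="t", df=50)) == 0.0

    def test_t_statistic(self):
        # r = t / sqrt(t^2 + df); oracle evaluated by hand
        assert convert_to_r(rec(2.0, 102, kind="t", df=100)) == pytest.approx(
            0.19611613513818404, abs=1e-12
        )

    def test_t_sign_preserved(self):
        assert convert_to_r(rec(-2.0, 102, kind="t", df=100)) == pytest.approx(
            -0.19611613513818404, abs=1e-12
        )

    def test_f_statistic_matches_squared_t(self):
        # F with df1=1 is t^2, so the magnitudes must agree
        r_t = convert_to_r(rec(2.0, 102, kind="t", df=100))
        r_f = convert_to_r(rec(4.0, 102, kind="F", df=100))
        assert r_f == pytest.approx(abs(r_t), abs=1e-12)

    def test_negative_f_rejected(self):
        with pytest.raises(ValueError):
            rec(-1.0, 100, kind="F", df=50)

    def test_t_without_df_rejected(self):
        with pytest.raises(ValueError):
            rec(2.0, 100, kind="t")

    def test_beta_passthrough_warns(self):
        with pytest.warns(UserWarning, match="beta"):
            assert convert_to_r(rec(0.3, 100, kind="beta")) == 0.3


class TestPoolCorrelations:
    def test_symmetric_two_study(self):
        est = pool_correlations([rec(0.4, 100, sid="a"), rec(0.4, 100, sid="b")])
        assert est.rho_hat == pytest.approx(0.4, abs=1e-12)
        assert not est.single_study

    def test_single_study_flagged(self):
        # one study of n=267 with r=0.74: the estimate is the study's own r
        est = pool_correlations([rec(0.74, 267, path="ST->SCA")])
        assert est.rho_hat == 0.74
        assert est.single_study
        assert est.var_rho_hat == pytest.approx(variance_of_r(0.74, 267), rel=1e-12)

    def test_two_study_inverse_variance_oracle(self):
        # hand evaluation of the inverse-variance pooled estimate with
        # nu_i = (1 - r_i^2)^2 / (n_i - 1):
        #   w1 = 1/nu(0.443, 256) = 394.7275..., w2 = 1/nu(0.37, 257) = 343.6514...
        #   rho_hat = (w1*0.443 + w2*0.37)/(w1 + w2) = 0.4090248...
        est = pool_correlations([rec(0.443, 256, sid="a"), rec(0.37, 257, sid="b")])
        assert est.rho_hat == pytest.approx(0.4090248306027437, abs=1e-12)
        assert est.var_rho_hat == pytest.approx(0.0013543192096968565, rel=1e-10)
        assert est.z_stat == pytest.approx(11.114480140385837, rel=1e-10)
        assert est.ci_low == pytest.approx(0.33689604663568057, abs=1e-9)
        assert est.ci_high == pytest.approx(0.4811536145698068, abs=1e-9)

    def test_matches_statsmodels_fixed_effect(self):
        # independent cross-check: statsmodels' inverse-variance fixed-effect
        # combiner on the same effects and variances
        from statsmodels.stats.meta_analysis import combine_effects

        rs = np.array([0.636, 0.301, 0.56, 0.301, 0.12])
        ns = np.array([304, 304, 305, 305, 305])
        est = pool_correlations(
            [rec(r, int(n), sid=f"s{i}") for i, (r, n) in enumerate(zip(rs, ns))]
        )
        sm = combine_effects(rs, (1 - rs**2) ** 2 / (ns - 1))
        assert est.rho_hat == pytest.approx(sm.mean_effect_fe, rel=1e-10)
        assert math.sqrt(est.var_rho_hat) == pytest.approx(sm.sd_eff_w_fe, rel=1e-10)

    def test_empty_and_mixed_paths_rejected(self):
        with pytest.raises(ValueError):
            pool_correlations([])
        with pytest.raises(ValueError):
            pool_correlations([rec(0.3, 100, path="A->B"), rec(0.3, 100, path="C->D")])

    @given(
        st.lists(
            st.tuples(st.floats(-0.9, 0.9), st.integers(10, 500)),
            min_size=1,
            max_size=8,
        )
    )
    @settings(deadline=None, max_examples=60)
    def test_estimate_within_input_range_and_variance_bound(self, studies):
        records = [rec(r, n, sid=f"s{i}") for i, (r, n) in enumerate(studies)]
        est = pool_correlations(records)
        rs = [r for r, _ in studies]
        assert min(rs) - 1e-12 <= est.rho_hat <= max(rs) + 1e-12
        # pooling never increases variance beyond the best single study
        assert est.var_rho_hat <= min(variance_of_r(r, n) for r, n in studies) + 1e-15
        assert est.ci_low <= est.rho_hat <= est.ci_high

    def test_order_and_batch_invariance(self):
        records = [rec(r, n, sid=f"s{i}") for i, (r, n) in enumerate(
            [(0.1, 50), (0.5, 200), (-0.2, 120), (0.33, 80)]
        )]
        fwd = pool_correlations(records)
        rev = pool_correlations(records[::-1])
        assert fwd.rho_hat == pytest.approx(rev.rho_hat, abs=1e-14)
        assert fwd.var_rho_hat == pytest.approx(rev.var_rho_hat, abs=1e-18)
        # pooling the pooled halves with their own variances reproduces the whole
        a, b = pool_correlations(records[:2]), pool_correlations(records[2:])
        w = np.array([1 / a.var_rho_hat, 1 / b.var_rho_hat])
        merged = float(np.dot(w, [a.rho_hat, b.rho_hat]) / w.sum())
        assert merged == pytest.approx(fwd.rho_hat, abs=1e-12)


class TestReliabilityCorrection:
    def test_identity_and_simple_correction(self):
        assert apply_reliability_correction(0.3, 1.0, 1.0) == 0.3
        assert apply_reliability_correction(0.3, 0.81, 1.0) == pytest.approx(1 / 3, rel=1e-12)

    def test_clipping_warns(self):
        with pytest.warns(UserWarning, match="clipped"):
            rc = apply_reliability_correction(0.9, 0.5, 0.5)
        assert 0 < rc < 1

    @pytest.mark.parametrize("rxx,ryy", [(0.0, 1.0), (-0.5, 1.0), (1.0, 1.5)])
    def test_invalid_reliabilities(self, rxx, ryy):
        with pytest.raises(ValueError):
            apply_reliability_correction(0.3, rxx, ryy)


class TestNormalizeCoefficients:
    def test_published_two_parent_rows(self):
        # the published corrected correlations for the USPH and WE parents
        # normalize to the published coefficient rows
        out = normalize_coefficients(
            {"PH->USPH": 0.650, "PF->USPH": 0.744},
            {"USPH": ("PH->USPH", "PF->USPH")},
        )
        assert out["PH->USPH"] == pytest.approx(0.466, abs=5e-4)
        assert out["PF->USPH"] == pytest.approx(0.534, abs=5e-4)
        out = normalize_coefficients(
            {"PW->WE": 0.635, "WI->WE": 0.569}, {"WE": ("PW->WE", "WI->WE")}
        )
        assert out["PW->WE"] == pytest.approx(0.527, abs=5e-4)
        assert out["WI->WE"] == pytest.approx(0.473, abs=5e-4)

    def test_single_parent_passthrough(self):
        out = normalize_coefficients({"ST->SCA": 0.74}, {"SCA": ("ST->SCA",)})
        assert out["ST->SCA"] == 0.74

    def test_equal_parents_symmetry(self):
        out = normalize_coefficients({"a": 0.5, "b": 0.5}, {"X": ("a", "b")})
        assert out == {"a": 0.5, "b": 0.5}

    def test_signs_reattached_and_abs_sum_one(self):
        out = normalize_coefficients(
            {"u": -0.3, "v": 0.6, "w": -0.1}, {"X": ("u", "v", "w")}
        )
        assert out["u"] < 0 and out["w"] < 0 and out["v"] > 0
        assert sum(abs(c) for c in out.values()) == pytest.approx(1.0, abs=1e-12)

    def test_missing_parent_names_path(self):
        with pytest.raises(ValueError, match="PF->USPH"):
            normalize_coefficients({"PH->USPH": 0.65}, {"USPH": ("PH->USPH", "PF->USPH")})


class TestSyntheticTables:
    def test_deterministic_given_seed(self):
        a = generate_synthetic_effect_table({"A->B": 0.4}, 5, 100, seed=7)
        b = generate_synthetic_effect_table({"A->B": 0.4}, 5, 100, seed=7)
        assert [r.effect_value for r in a] == [r.effect_value for r in b]

    def test_draws_within_open_interval(self):
        tab = generate_synthetic_effect_table({"A->B": 0.6}, 2, 500, seed=3)
        assert all(-1 < r.effect_value < 1 for r in tab)

    def test_recovery_of_null_correlation(self):
        # pooled standard error at (rho=0, k=50, n=1000) is ~0.0045, so the
        # estimate lands within +-0.02 of the truth
        tab = generate_synthetic_effect_table({"A->B": 0.0}, 50, 1000, seed=11)
        est = pool_correlations(tab)
        assert abs(est.rho_hat) < 0.02

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            generate_synthetic_effect_table({"A->B": 1.0}, 5, 100, seed=1)
        with pytest.raises(ValueError):
            generate_synthetic_effect_table({"A->B": 0.3}, 1, 100, seed=1)


class TestModelSurface:
    def test_fit_pools_packaged_table(self, effect_records):
        res = CorrelationMetaAnalysis(effect_records).fit()
        assert len(res.estimates) == 16
        st_sca = res.estimates["ST->SCA"]
        assert st_sca.single_study and st_sca.rho_hat == 0.74
        sm_sb = res.estimates["SM->SB"]
        assert sm_sb.k == 8 and sm_sb.n_total == 2414
        assert "*" in res.summary()

    def test_normalized_coefficients_validate(self, effect_records):
        cs = CorrelationMetaAnalysis(effect_records).fit().coefficient_set()
        for dep, parents in [("SCO", ("SCL->SCO", "SCU->SCO")), ("USPH", ("PH->USPH", "PF->USPH"))]:
            assert sum(abs(cs[p]) for p in parents) == pytest.approx(1.0, abs=1e-12)
        assert cs["USPH->SB"] < 0 and cs["USPS->SB"] < 0 and cs["WE->SB"] < 0

    def test_from_dataframe_round_trip(self, effect_records):
        import pandas as pd

        df = pd.DataFrame(
            {
                "path_id": [r.path_id for r in effect_records],
                "study_id": [r.study_id for r in effect_records],
                "n": [r.n for r in effect_records],
                "effect_kind": [r.effect_kind for r in effect_records],
                "effect_value": [r.effect_value for r in effect_records],
                "df": [r.df for r in effect_records],
            }
        )
        res = CorrelationMetaAnalysis.from_dataframe(df).fit()
        direct = CorrelationMetaAnalysis(effect_records).fit()
        for path in res.estimates:
            assert res.estimates[path].rho_hat == pytest.approx(
                direct.estimates[path].rho_hat, abs=1e-15
            )
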