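import dataclasses

import numpy as np
import pandas as pd
import pytest

import cardiomet as cm
from cardiomet.synthetic import REQUIRED_VARIABLES, _truncation_adjusted_mean


class TestCiToSd:
    def test_zero_width_interval(self):
        assert cm.ci_to_sd(97.4, 97.4, 97.4, 32) == 0.0

    def test_against_t_quantile(self):
        # half-width 5.9, sqrt(32)=5.657, t_{0.975,31}=2.0395
        assert cm.ci_to_sd(97.4, 91.5, 103.3, 32) == pytest.approx(16.365, abs=5e-3)

    def test_round_trip_recovers_half_width(self):
        from scipy import stats

        sd = cm.ci_to_sd(97.4, 91.5, 103.3, 32)
        half = stats.t.ppf(0.975, 31) * sd / np.sqrt(32)
        assert half == pytest.approx(5.9, abs=1e-12)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(cm.ValidationError):
            cm.ci_to_sd(97.4, 103.3, 91.5, 32)


class TestDefaultSpecs:
    def test_sample_sizes_and_sex_split(self, default_specs):
        for spec in default_specs:
            assert spec.n == 32
            assert spec.n_female == 23

    def test_printed_means(self, default_specs):
        pws, eob = default_specs
        assert eob.variables["bmr"].mean == 2096
        assert pws.variables["glucose"].mean == 93.1
        assert eob.variables["weight"].sd == pytest.approx(12.06, abs=0.01)

    def test_correlation_is_psd_with_unit_diagonal(self, default_specs):
        corr = default_specs[0].correlation
        assert np.allclose(np.diag(corr), 1.0)
        assert np.linalg.eigvalsh(corr).min() > -1e-10

    def test_non_psd_correlation_rejected(self, default_specs):
        bad = np.array(default_specs[0].correlation, copy=True)
        i, j = 0, 1
        bad[i, j] = bad[j, i] = 2.0  # breaks PSD
        with pytest.raises(cm.ValidationError):
            dataclasses.replace(default_specs[0], correlation=bad)


class TestVariableSpec:
    def test_negative_sd_rejected(self):
        with pytest.raises(cm.ValidationError):
            cm.VariableSpec(name="x", mean=1.0, sd=-1.0)

    def test_mean_must_exceed_lower_bound(self):
        with pytest.raises(cm.ValidationError):
            cm.VariableSpec(name="x", mean=1.0, sd=1.0, lower_bound=2.0)


class TestTruncationAdjustment:
    def test_no_bound_is_identity(self):
        assert _truncation_adjusted_mean(5.0, 1.0, None) == 5.0

    def test_far_bound_is_identity(self):
        assert _truncation_adjusted_mean(100.0, 1.0, 0.0) == 100.0

    def test_truncated_mean_hits_target(self):
        from scipy import stats

        mu = _truncation_adjusted_mean(0.81, 0.61, 0.0)
        assert mu < 0.81  # shifted down to offset the upward truncation bias
        a = (0.0 - mu) / 0.61
        assert stats.truncnorm.mean(a, np.inf, loc=mu, scale=0.61) == pytest.approx(0.81, abs=1e-8)


class TestGenerateCohort:
    def test_counts_and_sexes(self, pws_cohort):
        assert len(pws_cohort) == 32
        assert sum(1 for s in pws_cohort if s.sex == "F") == 23
        assert sum(1 for s in pws_cohort if s.sex == "M") == 9

    def test_deterministic_for_fixed_seed(self, default_specs):
        a = cm.generate_cohort(default_specs[0]).to_dataframe()
        b = cm.generate_cohort(default_specs[0]).to_dataframe()
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self, default_specs):
        other = dataclasses.replace(default_specs[0], seed=default_specs[0].seed + 99)
        a = cm.generate_cohort(default_specs[0]).to_dataframe()
        b = cm.generate_cohort(other).to_dataframe()
        assert not a["weight"].equals(b["weight"])

    def test_degenerate_all_sd_zero(self, default_specs):
        variables = {
            name: dataclasses.replace(v, sd=0.0, sex_offset=0.0)
            for name, v in default_specs[0].variables.items()
        }
        spec = dataclasses.replace(default_specs[0], variables=variables, correlation=None)
        cohort = cm.generate_cohort(spec)
        df = cohort.to_dataframe()
        for varname in ("weight", "glucose", "dbp"):
            assert df[varname].nunique() == 1
            assert df[varname].iloc[0] == pytest.approx(spec.variables[varname].mean)

    def test_large_sample_mean_converges(self, default_specs):
        from cardiomet.synthetic import scaled_spec

        spec = scaled_spec(default_specs[0], n=5000)
        cohort = cm.generate_cohort(spec)
        assert cohort.targets["weight"].mean() == pytest.approx(spec.variables["weight"].mean, abs=0.5)

    def test_subject_invariants_hold(self, pws_cohort, eob_cohort):
        for cohort in (pws_cohort, eob_cohort):
            for s in cohort:
                assert s.weight > 0 and s.height > 0 and s.resistance > 0
                assert s.sbp > s.dbp
                assert min(s.glucose, s.insulin, s.total_c, s.hdl_c, s.tg, s.crp) >= 0

    def test_weir_roundtrip_recovers_assigned_bmr(self, pws_cohort):
        recovered = np.array([cm.weir_bmr(s.vo2, s.vco2) for s in pws_cohort])
        assert np.abs(recovered - pws_cohort.targets["bmr"].to_numpy()).max() < 0.5

    def test_bia_roundtrip_recovers_assigned_ffm(self, pws_cohort):
        recovered = np.array([cm.predict_ffm(s) for s in pws_cohort])
        assert recovered == pytest.approx(pws_cohort.targets["ffm"].to_numpy(), abs=1e-8)

    def test_t2dm_flag_counts(self, pws_cohort, eob_cohort):
        assert sum(s.diagnosed_t2dm for s in pws_cohort) == 6
        assert sum(s.diagnosed_t2dm for s in eob_cohort) == 4

    def test_sex_offset_mean_preserving_height_gap(self, default_specs):
        from cardiomet.synthetic import scaled_spec

        cohort = cm.generate_cohort(scaled_spec(default_specs[0], n=4000))
        t = cohort.targets
        gap = t[t["sex"] == "M"]["height"].mean() - t[t["sex"] == "F"]["height"].mean()
        assert gap == pytest.approx(0.10, abs=0.02)
        assert t["height"].mean() == pytest.approx(default_specs[0].variables["height"].mean, abs=0.01)

    def test_missing_variable_rejected(self, default_specs):
        variables = dict(default_specs[0].variables)
        removed = variables.pop("crp")
        spec = dataclasses.replace(default_specs[0], variables=variables, correlation=None)
        with pytest.raises(cm.ValidationError, match="crp"):
            cm.generate_cohort(spec)

    def test_redraw_cap_exceeded_names_constraint(self, default_specs):
        # FFM target above body weight with zero variance: every draw violates
        variables = {
            name: dataclasses.replace(v, sd=0.0, sex_offset=0.0)
            for name, v in default_specs[0].variables.items()
        }
        variables["ffm"] = dataclasses.replace(variables["ffm"], mean=200.0)
        spec = dataclasses.replace(default_specs[0], variables=variables, correlation=None)
        with pytest.raises(cm.GenerationError, match="ffm"):
            cm.generate_cohort(spec, max_redraw_rounds=5)
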