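import numpy as np
import pytest

from voe import (
    MERanges,
    MeasurementVibration,
    ModelVibration,
    SamplingVibration,
    VoeError,
    generate_cohort,
    vibration_over_sample_sizes,
)
from voe.model_space import favourite_model

from conftest import small_generator_spec

NO_ERROR = MERanges(1, 1, 1, 1, 1, 1)


class TestModelVibration:
    def test_k3_deterministic_and_complete(self, small_cohort):
        r1 = ModelVibration(small_cohort).fit()
        r2 = ModelVibration(small_cohort).fit()
        assert len(r1.estimates) == 2 ** len(small_cohort.optional_vars)
        assert [e.log_hr for e in r1.estimates] == [e.log_hr for e in r2.estimates]

    def test_k0_reduces_to_baseline_fit(self, small_cohort):
        res = ModelVibration(small_cohort, optional_vars=[]).fit()
        assert len(res.estimates) == 1
        assert res.estimates[0].converged

    def test_provenance_unique(self, small_cohort):
        res = ModelVibration(small_cohort).fit()
        ids = [e.provenance for e in res.estimates]
        assert len(set(ids)) == len(ids)


class TestSamplingVibration:
    def test_subset_size_and_count(self, small_cohort):
        B = 10
        res = SamplingVibration(small_cohort, B=B, fraction=0.5).fit(seed=3)
        assert len(res.estimates) == B
        assert res.settings["subset_size"] == small_cohort.n // 2
        assert res.reference is not None and res.reference.converged

    def test_seeded_determinism(self, small_cohort):
        r1 = SamplingVibration(small_cohort, B=5).fit(seed=42)
        r2 = SamplingVibration(small_cohort, B=5).fit(seed=42)
        assert [e.log_hr for e in r1.estimates] == [e.log_hr for e in r2.estimates]

    def test_spread_shrinks_as_fraction_grows(self, small_cohort):
        lo = SamplingVibration(small_cohort, B=30, fraction=0.5).fit(seed=1)
        hi = SamplingVibration(small_cohort, B=30, fraction=0.95).fit(seed=1)
        spread = lambda r: np.std([e.log_hr for e in r.converged_estimates])
        assert spread(hi) < spread(lo)

    def test_parameter_validation(self, small_cohort):
        with pytest.raises(VoeError):
            SamplingVibration(small_cohort, B=0)
        with pytest.raises(VoeError):
            SamplingVibration(small_cohort, fraction=1.0)


class TestMeasurementVibration:
    def test_no_error_limit_reproduces_reference_exactly(self, small_cohort):
        res = MeasurementVibration(small_cohort, ranges=NO_ERROR, B=5).fit(seed=9)
        ref = res.reference
        for e in res.estimates:
            assert e.log_hr == ref.log_hr and e.p_value == ref.p_value

    def test_seeded_determinism(self, small_cohort):
        kw = dict(scenario="both", B=5)
        r1 = MeasurementVibration(small_cohort, **kw).fit(seed=17)
        r2 = MeasurementVibration(small_cohort, **kw).fit(seed=17)
        assert [e.log_hr for e in r1.estimates] == [e.log_hr for e in r2.estimates]

    def test_exposure_error_attenuates_positive_effect(self):
        # classical error in the exposure pulls the hazard ratio toward 1
        cohort = generate_cohort(small_generator_spec(4000), seed=31)
        res = MeasurementVibration(cohort, scenario="exposure_only", B=30).fit(seed=5)
        ref_hr = res.reference.hr
        median_hr = np.median([e.hr for e in res.converged_estimates])
        assert ref_hr > 1
        assert abs(np.log(median_hr)) < abs(np.log(ref_hr))

    def test_wider_ranges_widen_the_spread(self, small_cohort):
        tight = MERanges(0.98, 0.999, 0.98, 0.999, 0.98, 0.999)
        wide = MERanges(0.6, 0.999, 0.6, 0.999, 0.6, 0.999)
        iqr = lambda res: np.subtract(
            *np.percentile([e.log_hr for e in res.converged_estimates], [75, 25])
        )
        r_tight = MeasurementVibration(small_cohort, ranges=tight, B=30).fit(seed=2)
        r_wide = MeasurementVibration(small_cohort, ranges=wide, B=30).fit(seed=2)
        assert iqr(r_wide) > iqr(r_tight)

    def test_scenario_recorded(self, small_cohort):
        res = MeasurementVibration(small_cohort, scenario="adjustment_only", B=3).fit(
            seed=1
        )
        assert res.scenario == "adjustment_only"
        assert res.summary_dict()["scenario"] == "adjustment_only"


class TestSweep:
    def test_single_size_single_engine(self):
        spec = small_generator_spec(1)
        table = vibration_over_sample_sizes(spec, [400], engines=("model",), seed=6)
        assert len(table) == 1
        assert table.loc[0, "vibration_type"] == "model"

    def test_sampling_rhr_decreases_with_n(self):
        spec = small_generator_spec(1)
        table = vibration_over_sample_sizes(
            spec, [400, 3000], engines=("sampling",), B=60, seed=8
        )
        rhr = table.set_index("n")["rhr"]
        assert rhr[400] > rhr[3000]

    def test_seeded_reproducibility(self):
        spec = small_generator_spec(1)
        kw = dict(sizes=[300], engines=("sampling",), B=10, seed=13)
        t1 = vibration_over_sample_sizes(spec, **kw)
        t2 = vibration_over_sample_sizes(spec, **kw)
        assert t1.equals(t2)

    def test_sizes_must_increase(self):
        with pytest.raises(VoeError):
            vibration_over_sample_sizes(small_generator_spec(1), [500, 500])


def test_summary_text_mentions_key_quantities(small_cohort):
    res = SamplingVibration(small_cohort, B=5).fit(seed=4)
    text = res.summary()
    for token in ("RHR", "RP", "Janus", "sampling vibration"):
        assert token in text


def test_favourite_default_uses_all_adjustments(small_cohort):
    sv = SamplingVibration(small_cohort, B=1)
    fav = favourite_model(
        small_cohort.optional_vars, small_cohort.baseline_vars, small_cohort.exposure
    )
    assert sv.favourite == fav
    assert set(sv.favourite.included_adjustments) == set(small_cohort.adjustment_vars)
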