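"""Design templates: boxcars, the canonical HRF and signal scaling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmrisnr import (
    DesignSpec,
    HRFParams,
    activation_signal,
    boxcar,
    canonical_hrf,
    contrast_signal,
)


class TestBoxcar:
    def test_block_alternates_task_first(self, block_spec):
        vec = boxcar(block_spec)
        assert vec.size == 100
        assert vec.sum() == 50  # 50% duty cycle
        assert np.all(vec[:10] == 1) and np.all(vec[10:20] == 0)

    @pytest.mark.parametrize("duration", [80.0, 160.0, 240.0])
    def test_block_duty_cycle_is_half_for_whole_periods(self, duration):
        spec = DesignSpec("block", total_duration=duration)
        vec = boxcar(spec)
        assert vec.mean() == 0.5

    def test_contrast_follows_condition1_condition2_rest_pattern(self, contrast_spec):
        b1, b2 = boxcar(contrast_spec)
        # hand enumeration of the repeating A-B-rest pattern (10-sample epochs)
        expected_a = sorted(
            set(range(0, 10)) | set(range(30, 40)) | set(range(60, 70)) | set(range(90, 100))
        )
        expected_b = sorted(set(range(10, 20)) | set(range(40, 50)) | set(range(70, 80)))
        assert list(np.flatnonzero(b1)) == expected_a
        assert list(np.flatnonzero(b2)) == expected_b
        assert not np.any(b1 * b2)

    def test_event_related_seeded_reproducibility(self):
        a = boxcar(DesignSpec("event_related", rng_seed=3))
        b = boxcar(DesignSpec("event_related", rng_seed=3))
        c = boxcar(DesignSpec("event_related", rng_seed=4))
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)
        assert a.sum() == 25

    def test_event_density_error_names_the_problem(self):
        spec = DesignSpec("event_related", total_duration=20.0, n_events=25)
        with pytest.raises(ValueError, match="25"):
            boxcar(spec)

    def test_events_with_duration_do_not_overlap(self):
        spec = DesignSpec("event_related", n_events=10, event_duration=6.0, rng_seed=0)
        vec = boxcar(spec)
        assert vec.sum() == 30  # 10 events x 3 samples, none merged short

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            DesignSpec("blocky")
        with pytest.raises(ValueError):
            DesignSpec("block", total_duration=-5)
        with pytest.raises(ValueError):
            DesignSpec("block", total_duration=201.0)  # not a multiple of TR
        with pytest.raises(ValueError):
            DesignSpec("event_related", n_events=0)


class TestCanonicalHrf:
    def test_zero_at_origin_and_peak_location(self, hrf):
        t = np.arange(0, 30, 0.01)
        k = canonical_hrf(t, hrf)
        assert k[0] == 0.0
        assert abs(t[np.argmax(k)] - hrf.peak_delay) < 1.0

    def test_no_undershoot_gives_nonnegative_kernel(self):
        t = np.arange(0, 32, 0.1)
        k = canonical_hrf(t, HRFParams(undershoot_ratio=0.0))
        assert np.all(k >= 0)

    def test_undershoot_present_by_default(self, hrf):
        k = canonical_hrf(np.arange(0, 32, 0.1), hrf)
        assert k.min() < 0

    def test_non_uniform_grid_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            canonical_hrf(np.array([0.0, 1.0, 3.0, 4.0]))
        with pytest.raises(ValueError, match="start at 0"):
            canonical_hrf(np.array([1.0, 2.0, 3.0]))

    def test_round_trip_config(self, hrf):
        assert HRFParams.from_config(hrf.to_config()) == hrf


class TestActivationSignal:
    def test_peak_anchored_scaling(self, block_spec):
        sig = activation_signal(block_spec, baseline=100.0, psc=1.0)
        assert sig.amplitude == pytest.approx(1.0)
        assert sig.samples.max() - sig.baseline == pytest.approx(
            100.0 * 1.0 / 100.0, rel=1e-9
        )

    def test_zero_psc_gives_flat_baseline(self, block_spec):
        sig = activation_signal(block_spec, psc=0.0)
        assert np.all(sig.samples == 100.0)
        assert sig.amplitude == 0.0
        assert sig.fluctuation_sd == 0.0

    @pytest.mark.parametrize("design", ["block", "event_related"])
    def test_sigma_s_scales_linearly_with_psc(self, design):
        spec = DesignSpec(design, rng_seed=5)
        s1 = activation_signal(spec, psc=1.0)
        s2 = activation_signal(spec, psc=2.0)
        assert s2.fluctuation_sd == pytest.approx(2 * s1.fluctuation_sd, rel=1e-12)

    def test_sigma_s_invariant_to_baseline(self, block_spec):
        lo = activation_signal(block_spec, baseline=100.0, psc=2.0)
        hi = activation_signal(block_spec, baseline=500.0, psc=2.0 * 100.0 / 500.0)
        # same absolute amplitude a = 2 in both cases
        assert lo.amplitude == pytest.approx(hi.amplitude)
        assert lo.fluctuation_sd == pytest.approx(hi.fluctuation_sd, rel=1e-12)

    def test_er_amplitude_fixed_but_sigma_varies_across_seeds(self):
        sds = []
        for seed in range(6):
            sig = activation_signal(DesignSpec("event_related", rng_seed=seed))
            assert sig.amplitude == pytest.approx(1.0)
            sds.append(sig.fluctuation_sd)
        assert np.std(sds) > 0

    def test_contrast_condition_effect_ratio(self, contrast_spec):
        s1, s2 = activation_signal(contrast_spec, psc=1.0)
        assert s1.amplitude == pytest.approx(2 * s2.amplitude)
        assert s1.amplitude == pytest.approx(1.0)


class TestContrastSignal:
    def test_identical_conditions_cancel(self, contrast_spec):
        s1, _ = activation_signal(contrast_spec)
        d = contrast_signal(s1, s1)
        assert d.amplitude == 0.0
        assert np.all(d.samples == 0.0)

    def test_swap_negates_samples_keeps_amplitude(self, contrast_spec):
        s1, s2 = activation_signal(contrast_spec)
        d12 = contrast_signal(s1, s2)
        d21 = contrast_signal(s2, s1)
        assert d12.amplitude == pytest.approx(d21.amplitude)
        assert np.allclose(d12.samples, -d21.samples)

    def test_amplitude_is_max_minus_min(self, contrast_spec):
        s1, s2 = activation_signal(contrast_spec)
        d = contrast_signal(s1, s2)
        diff = s1.samples - s2.samples
        assert d.amplitude == pytest.approx(diff.max() - diff.min())
        assert d.baseline == 0.0

    def test_length_mismatch_rejected(self, contrast_spec):
        s1, s2 = activation_signal(contrast_spec)
        short = activation_signal(DesignSpec("block", total_duration=100.0))
        with pytest.raises(ValueError, match="mismatch"):
            contrast_signal(s1, short)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    psc=st.floats(0.1, 20.0),
    baseline=st.floats(10.0, 1000.0),
)
def test_peak_anchor_property(psc, baseline):
    sig = activation_signal(DesignSpec("block"), baseline=baseline, psc=psc)
    assert sig.samples.max() - baseline == pytest.approx(
        baseline * psc / 100.0, rel=1e-9
    )


def test_design_spec_config_round_trip(er_spec):
    assert DesignSpec.from_config(er_spec.to_config()) == er_spec
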