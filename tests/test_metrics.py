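import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmibench import (
    ALL_VARIANTS,
    CONTRAST_VARIANTS,
    NON_DETECT,
    SNR_VARIANTS,
    IntensityImage,
    RegionStats,
    SimilarityTransform,
    WellSet,
    build_masks,
    compute_metric_table,
    michelson,
    snr1,
    snr2,
    snr3,
    snr4,
    to_db,
    weber,
)
from fmibench.errors import DomainError, UndefinedNoiseError
from conftest import make_stats


class TestToDb:
    def test_twofold_reference(self):
        assert to_db(2.0) == pytest.approx(6.0206, abs=1e-3)

    def test_unity(self):
        assert to_db(1.0) == 0.0

    def test_ten(self):
        assert to_db(10.0) == pytest.approx(20.0)

    def test_zero_is_sentinel(self):
        assert to_db(0.0) == NON_DETECT

    def test_negative_raises(self):
        with pytest.raises(DomainError):
            to_db(-0.5)


class TestSnr1:
    def test_hundred_counts(self):
        assert snr1(make_stats(mean=100)) == pytest.approx(20.0)

    def test_one_count(self):
        assert snr1(make_stats(mean=1)) == 0.0

    def test_zero_counts_sentinel(self):
        assert snr1(make_stats(mean=0)) == NON_DETECT

    def test_negative_mean_raises(self):
        with pytest.raises(DomainError):
            snr1(RegionStats(mean=-5, std=1, min=-10, max=0, count=4))


class TestSnr2:
    def test_default_shot_form(self):
        # S=100, N=44: 100/sqrt(144) = 100/12
        v = snr2(make_stats(mean=100), make_stats(mean=44))
        assert v == pytest.approx(20 * math.log10(100 / 12), abs=1e-6)
        assert v == pytest.approx(18.42, abs=0.01)

    def test_ratio_form(self):
        v = snr2(make_stats(mean=100), make_stats(mean=44), mode="ratio")
        assert v == pytest.approx(20 * math.log10(100 / 144), abs=1e-6)
        assert v == pytest.approx(-3.17, abs=0.01)

    def test_zero_signal_sentinel(self):
        assert snr2(make_stats(mean=0), make_stats(mean=10)) == NON_DETECT

    def test_both_zero_sentinel(self):
        assert snr2(make_stats(mean=0), make_stats(mean=0)) == NON_DETECT


class TestSnr3:
    def test_closed_form(self):
        v = snr3(make_stats(mean=300, std=50), make_stats(mean=100))
        assert v == pytest.approx(20 * math.log10(4), abs=1e-9)
        assert v == pytest.approx(12.04, abs=0.01)

    def test_equal_means_sentinel(self):
        assert snr3(make_stats(mean=100, std=5), make_stats(mean=100)) == NON_DETECT

    def test_zero_signal_std_raises(self):
        with pytest.raises(UndefinedNoiseError):
            snr3(make_stats(mean=100, std=0), make_stats(mean=50))


class TestSnr4:
    def test_closed_form(self):
        v = snr4(make_stats(mean=300), make_stats(mean=100, std=50))
        assert v == pytest.approx(12.04, abs=0.01)

    def test_twofold_noise_is_six_db(self):
        # S - N = 2 sigma_N: the detection-limit reference, ~6 dB
        v = snr4(make_stats(mean=120), make_stats(mean=100, std=10))
        assert v == pytest.approx(20 * math.log10(2), abs=1e-9)
        assert round(v) == 6

    def test_equal_means_sentinel(self):
        assert snr4(make_stats(mean=100), make_stats(mean=100, std=5)) == NON_DETECT

    def test_zero_background_std_raises(self):
        with pytest.raises(UndefinedNoiseError):
            snr4(make_stats(mean=100), make_stats(mean=50, std=0))


class TestContrast:
    def test_michelson_twofold_reference(self):
        for u in (1.0, 13.0, 4096.0):
            c = michelson(make_stats(mean=2 * u, max_=2 * u), make_stats(mean=u, min_=u))
            assert c == pytest.approx(1 / 3)

    def test_michelson_equal_is_zero(self):
        assert michelson(make_stats(mean=7, max_=7), make_stats(mean=7, min_=7)) == 0

    def test_michelson_zero_background(self):
        assert michelson(make_stats(mean=5, max_=5), make_stats(mean=0, min_=0)) == 1

    def test_michelson_both_zero_sentinel(self):
        assert michelson(make_stats(mean=0), make_stats(mean=0)) == NON_DETECT

    def test_weber_twofold_reference(self):
        for u in (1.0, 13.0, 4096.0):
            c = weber(make_stats(mean=2 * u, max_=2 * u), make_stats(mean=u, min_=u))
            assert c == pytest.approx(1.0)

    def test_weber_equal_is_zero(self):
        assert weber(make_stats(mean=9, max_=9), make_stats(mean=9, min_=9)) == 0

    def test_weber_zero_background_raises(self):
        with pytest.raises(DomainError):
            weber(make_stats(mean=5, max_=5), make_stats(mean=0, min_=0))

    @settings(max_examples=100, deadline=None)
    @given(imax=st.floats(0.01, 1e6), imin=st.floats(0.01, 1e6))
    def test_weber_michelson_identity(self, imax, imin):
        """CW = 2 CM / (1 - CM) when Is = Imax and Ib = Imin."""
        sig = make_stats(mean=imax, max_=imax)
        bg = make_stats(mean=imin, min_=imin)
        cm = michelson(sig, bg)
        if abs(1 - cm) < 1e-9:
            return
        cw = weber(sig, bg)
        assert cw == pytest.approx(2 * cm / (1 - cm), rel=1e-6, abs=1e-9)

    @settings(max_examples=100, deadline=None)
    @given(imax=st.floats(0, 1e6), imin=st.floats(0, 1e6))
    def test_michelson_bounds(self, imax, imin):
        if imax + imin == 0:
            return
        hi, lo = max(imax, imin), min(imax, imin)
        cm = michelson(make_stats(mean=hi, max_=hi), make_stats(mean=lo, min_=lo))
        assert 0 <= cm <= 1
        assert (cm == 0) == (hi == lo)


class TestScalingProperties:
    @settings(max_examples=50, deadline=None)
    @given(k=st.floats(0.01, 1000))
    def test_scale_invariant_variants(self, k):
        sig = make_stats(mean=300, std=40, min_=200, max_=400)
        bg = make_stats(mean=100, std=10, min_=80, max_=120)
        sig_k = make_stats(mean=300 * k, std=40 * k, min_=200 * k, max_=400 * k)
        bg_k = make_stats(mean=100 * k, std=10 * k, min_=80 * k, max_=120 * k)
        assert snr3(sig_k, bg_k) == pytest.approx(snr3(sig, bg), rel=1e-9)
        assert snr4(sig_k, bg_k) == pytest.approx(snr4(sig, bg), rel=1e-9)
        assert michelson(sig_k, bg_k) == pytest.approx(michelson(sig, bg), rel=1e-9)
        assert weber(sig_k, bg_k) == pytest.approx(weber(sig, bg), rel=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(k=st.floats(0.01, 1000))
    def test_sqrt_scaling_variants(self, k):
        """snr1 and snr2 scale as sqrt(k) in linear form: +10 log10 k dB."""
        sig = make_stats(mean=300)
        bg = make_stats(mean=100)
        shift = 10 * math.log10(k)
        sig_k = make_stats(mean=300 * k)
        bg_k = make_stats(mean=100 * k)
        assert snr1(sig_k) == pytest.approx(snr1(sig) + shift, rel=1e-9, abs=1e-9)
        assert snr2(sig_k, bg_k) == pytest.approx(
            snr2(sig, bg) + shift, rel=1e-9, abs=1e-9
        )


def _sparse_wellset():
    centers = [(40 + 70 * r, 40 + 70 * c) for r in range(3) for c in range(3)]
    return WellSet(
        centers=np.asarray(centers, float),
        radius=10.0,
        depths_mm=np.array([0.2, 0.4, 0.6, 0.8, 1.0, 1.33, 1.66, 2.0, 3.0]),
        b2_center=np.array([40.0, 250.0]),
        b2_radius=10.0,
        transform=SimilarityTransform(),
    )


class TestComputeMetricTable:
    def test_eleven_variants_per_well(self, noiseless_image):
        from fmibench import default_template, segment_wells

        ws = segment_wells(noiseless_image, default_template())
        masks = build_masks(ws, noiseless_image.shape)
        table = compute_metric_table(noiseless_image, masks, "sys")
        assert len(table.df) == 9 * 11
        piv = table.pivot()
        assert piv.shape == (9, 11)
        assert set(piv.columns) == set(ALL_VARIANTS)
        assert len(SNR_VARIANTS) == 7 and len(CONTRAST_VARIANTS) == 4

    def test_constant_image_degenerate(self):
        ws = _sparse_wellset()
        img = IntensityImage(values=np.full((260, 300), 50.0), bit_depth=16)
        masks = build_masks(ws, img.shape)
        table = compute_metric_table(img, masks, "flat")
        piv = table.pivot()
        # all contrasts 0
        for v in CONTRAST_VARIANTS:
            assert np.all(piv[v] == 0)
        # zero-noise SNRs flagged NaN, never silently dropped
        for v in ("SNR3b1", "SNR3b2", "SNR4b1", "SNR4b2"):
            assert np.all(np.isnan(piv[v]))
        notes = table.df[table.df["variant"] == "SNR4b1"]["note"]
        assert (notes != "").all()

    def test_snr4b2_decreasing_with_depth(self, noiseless_image):
        """Noiseless attenuated wells over fixed analytic background noise:
        SNR4b2 must fall strictly with depth."""
        from fmibench import default_template, region_stats, segment_wells

        ws = segment_wells(noiseless_image, default_template())
        masks = build_masks(ws, noiseless_image.shape)
        bg = make_stats(mean=100, std=5.0, min_=90, max_=110)
        vals = [
            snr4(region_stats(noiseless_image, m), bg) for m in masks.well_masks
        ]
        assert np.all(np.diff(vals) < 0)

    def test_provenance_stamped(self, noiseless_image):
        from fmibench import default_template, segment_wells

        ws = segment_wells(noiseless_image, default_template())
        masks = build_masks(ws, noiseless_image.shape)
        table = compute_metric_table(
            noiseless_image, masks, "sys", snr2_mode="ratio", std_ddof=1
        )
        assert table.provenance["snr2_mode"] == "ratio"
        assert table.provenance["std_convention"] == "sample"
        assert table.provenance["db_convention"] == "20*log10"
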