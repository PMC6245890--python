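"""AIF extraction/QC, Fermi deconvolution, pixel maps and segment calls."""

import numpy as np
import pytest

from fermiperf.contours import build_segment_map, delineate_series
from fermiperf.data import SampledCurve
from fermiperf.exceptions import InputError
from fermiperf.kinetics import AifParams, FermiParams, make_aif, \
    make_tissue_curve
from fermiperf.phantom import PhantomConfig, make_phantom
from fermiperf.quant import (Aif, MbfMap, extract_aif, fermi_deconvolve,
                             pixelwise_mbf, qc_aif, segment_summary)


def synthetic_aif(times, amplitude=4.0):
    curve = make_aif(AifParams(amplitude=amplitude, onset=8.0, alpha=3.0,
                               beta=2.0), times)
    return Aif(curve, dilution=10.0, arrival_time=8.5, arrival_frame=17,
               quality=np.inf)


class TestExtractAif:
    def test_noiseless_round_trip(self, clean_phantom):
        _, _, prebolus, truth = clean_phantom
        aif = extract_aif(prebolus, truth.blood_pool_mask)
        assert np.max(np.abs(aif.curve.values - truth.aif_bolus.values)) < 1e-9
        assert aif.quality == np.inf
        assert qc_aif(aif)

    def test_default_dilution_matches_protocol_dose_ratio(self):
        assert 0.075 / 0.0075 == pytest.approx(Aif(SampledCurve(
            np.arange(5.0), np.zeros(5))).dilution)

    def test_flat_series_flagged(self):
        from fermiperf.data import DynamicSeries
        data = np.full((1, 30, 10, 10), 2.0)
        series = DynamicSeries(data, np.arange(30.0))
        mask = np.ones((1, 10, 10), dtype=bool)
        aif = extract_aif(series, mask)
        assert aif.quality == 0.0
        assert not aif.arrival_defined
        assert not qc_aif(aif)

    def test_empty_mask_rejected(self, clean_phantom):
        prebolus = clean_phantom[2]
        mask = np.zeros((3,) + prebolus.spatial_shape, dtype=bool)
        with pytest.raises(InputError):
            extract_aif(prebolus, mask)


class TestQc:
    def test_degraded_prebolus_fails(self):
        cfg = PhantomConfig(noise_sd=0.0, motion_amplitude=0.0, n_frames=60,
                            prebolus_noise_sd=0.25, seed=2)
        *_, prebolus, truth = make_phantom(cfg)
        aif = extract_aif(prebolus, truth.blood_pool_mask)
        assert aif.quality < 5.0
        assert not qc_aif(aif)

    def test_zero_threshold_always_passes(self):
        aif = Aif(SampledCurve(np.arange(5.0), np.zeros(5)), quality=0.01)
        assert qc_aif(aif, min_quality=0)


class TestFermiDeconvolve:
    def test_zero_tissue_gives_zero_flow(self, times):
        aif = synthetic_aif(times)
        fit = fermi_deconvolve(aif, np.zeros_like(times), times=times)
        assert fit.mbf == 0.0 and fit.converged

    def test_noiseless_round_trip(self, times):
        aif = synthetic_aif(times)
        true = FermiParams(F=1.0, k=0.3, tau0=6.0, td=2.0)
        tissue = make_tissue_curve(aif.curve, true)
        fit = fermi_deconvolve(aif, tissue, times=times)
        assert fit.mbf == pytest.approx(true.mbf, rel=0.01)
        assert fit.converged

    def test_constant_impulse_limit_recovers_half_F(self, times):
        # k = 0, tau0 = 0: tissue = (F/2) * cumulative integral of AIF
        aif = synthetic_aif(times)
        F = 2.0
        dt = times[1] - times[0]
        tissue = (F / 2.0) * np.cumsum(aif.curve.values) * dt
        fit = fermi_deconvolve(aif, tissue, times=times)
        assert fit.mbf == pytest.approx(F / 2.0, rel=0.01)

    def test_nonfinite_input_rejected(self, times):
        aif = synthetic_aif(times)
        bad = np.zeros_like(times)
        bad[5] = np.nan
        with pytest.raises(InputError):
            fermi_deconvolve(aif, bad, times=times)

    def test_summary_reports_estimates(self, times):
        aif = synthetic_aif(times)
        tissue = make_tissue_curve(aif.curve, FermiParams(F=1.0, k=0.3,
                                                          tau0=6.0))
        fit = fermi_deconvolve(aif, tissue, times=times)
        text = fit.summary()
        assert "MBF" in text and "tau0" in text

    def test_scale_invariance_of_flow(self, times):
        # scaling AIF and tissue by the same factor leaves MBF unchanged
        aif = synthetic_aif(times)
        tissue = make_tissue_curve(aif.curve, FermiParams(F=1.0, k=0.3,
                                                          tau0=6.0, td=1.0))
        fit1 = fermi_deconvolve(aif, tissue, times=times)
        scaled = Aif(SampledCurve(times, aif.curve.values * 37.0),
                     arrival_frame=aif.arrival_frame, quality=np.inf)
        fit2 = fermi_deconvolve(scaled, tissue.values * 37.0, times=times)
        assert fit2.mbf == pytest.approx(fit1.mbf, rel=1e-6)


class TestPixelwise:
    def test_empty_mask_gives_empty_map(self, clean_phantom):
        stress, *_, truth = clean_phantom
        aif = extract_aif(clean_phantom[2], truth.blood_pool_mask)
        mask = np.zeros_like(truth.myocardium_mask)
        mp = pixelwise_mbf(stress, aif, mask)
        assert np.all(np.isnan(mp.mbf)) and mp.n_pixels == 0

    def test_noiseless_pixels_match_truth(self, clean_phantom):
        stress, *_, truth = clean_phantom
        aif = extract_aif(clean_phantom[2], truth.blood_pool_mask)
        # a thin sample of pure pixels is enough to check exact recovery
        mask = np.zeros_like(truth.pure_myocardium_mask)
        idx = np.argwhere(truth.pure_myocardium_mask)
        for sl, r, c in idx[:: max(1, len(idx) // 60)]:
            mask[sl, r, c] = True
        mp = pixelwise_mbf(stress, aif, mask)
        errs = []
        for sl, r, c in np.argwhere(mask):
            seg = int(truth.label_maps[sl, r, c])
            errs.append(abs(mp.mbf[sl, r, c] - truth.mbf_stress[seg])
                        / truth.mbf_stress[seg])
        assert np.quantile(errs, 0.99) < 0.01


@pytest.fixture(scope="module")
def segmap(clean_phantom):
    stress = clean_phantom[0]
    cs = delineate_series(stress)
    return build_segment_map(cs, shape=stress.spatial_shape)


class TestSegmentSummary:
    def _const_maps(self, segmap, stress_val, rest_val, override=None):
        shape = segmap.labels.shape
        mask = segmap.labels > 0
        stress = np.where(mask, stress_val, np.nan)
        rest = np.where(mask, rest_val, np.nan)
        if override:
            for seg, val in override.items():
                stress[segmap.labels == seg] = val
        conv = mask.copy()
        return (MbfMap(stress, np.zeros(shape), conv, mask),
                MbfMap(rest, np.zeros(shape), conv, mask))

    def test_uniform_reserve_no_ischemia(self, segmap):
        s, r = self._const_maps(segmap, 3.0, 1.0)
        table = segment_summary(s, r, segmap)
        assert np.allclose(table.table.mpr, 3.0)
        assert not table.table.ischemic.any()
        assert not table.patient_call

    def test_single_ischemic_segment_propagates(self, segmap):
        s, r = self._const_maps(segmap, 3.0, 1.0, override={7: 1.4})
        table = segment_summary(s, r, segmap)
        assert bool(table.table.loc[7, "ischemic"])
        assert table.territory_calls == {"LAD": True, "RCA": False,
                                         "LCX": False}
        assert table.patient_call

    def test_threshold_is_strict(self, segmap):
        s, r = self._const_maps(segmap, 3.0, 1.0, override={5: 1.5})
        table = segment_summary(s, r, segmap)
        assert table.table.loc[5, "mpr"] == pytest.approx(1.5)
        assert not bool(table.table.loc[5, "ischemic"])
        assert not table.patient_call

    def test_zero_rest_marked_indeterminate(self, segmap):
        s, r = self._const_maps(segmap, 3.0, 0.0)
        with pytest.warns(UserWarning):
            table = segment_summary(s, r, segmap)
        assert table.table.indeterminate.all()
        assert not table.patient_call
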