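"""Reference-frequency attenuation estimation: spectra, recovery, invariances."""

import numpy as np
import pytest
from dataclasses import replace

from usradiomics.attenuation import (
    AttenuationSpec,
    attenuation_map,
    estimate_attenuation,
    local_spectra,
)
from usradiomics.rf_core import RFFrame
from usradiomics.synth import PhantomSpec, simulate_rf

from conftest import narrowband_frame


def test_spec_validation():
    with pytest.raises(ValueError):
        AttenuationSpec(bounds_db=(0.0, -2.0))
    with pytest.raises(ValueError):
        AttenuationSpec(lateral_kernel_mm=0.1, lateral_step_mm=0.2)


def test_axial_step_arithmetic():
    spec = AttenuationSpec()
    # 3 mm window with 95% overlap -> 0.15 mm step
    assert np.isclose(spec.axial_window_mm * (1 - spec.axial_overlap), 0.15)


def test_white_noise_spectra_flat(rng):
    x = rng.standard_normal((2000, 60))
    frame = RFFrame(samples=x, sampling_rate=56e6, line_pitch=2e-4, focus_depth=0.03)
    profs = local_spectra(frame, AttenuationSpec())
    prof = profs[0]
    band = (prof.freqs_mhz > 4) & (prof.freqs_mhz < 7)
    mean_spec = prof.power.mean(axis=0)
    ratio = mean_spec[band].max() / mean_spec[band].min()
    assert ratio < 2.5  # flat within estimator variance


def test_narrowband_peak_location():
    frame = narrowband_frame(fc_mhz=5.0, n_ax=2000, n_lines=60)
    profs = local_spectra(frame, AttenuationSpec(), None)
    prof = profs[0]
    peak = prof.freqs_mhz[np.argmax(prof.power.mean(axis=0))]
    df = prof.freqs_mhz[1] - prof.freqs_mhz[0]
    assert abs(peak - 5.0) <= df + 1e-9


def test_region_too_small_rejected(small_frame):
    spec = AttenuationSpec(axial_window_mm=30.0)
    with pytest.raises(ValueError):
        local_spectra(small_frame, spec)


class TestRecovery:
    def test_zero_slope_recovered(self):
        spec = PhantomSpec(
            depth_extent_cm=4.5, lateral_extent_cm=3.0, attenuation_slope=0.0,
            focus_depth_cm=3.5, seed=21,
        )
        fr = simulate_rf(spec)
        res = estimate_attenuation(
            local_spectra(fr, AttenuationSpec()), AttenuationSpec()
        )
        assert abs(np.nanmean(res["values"])) <= 0.05

    def test_half_db_slope_within_seven_percent(self):
        spec = PhantomSpec(
            depth_extent_cm=4.5, lateral_extent_cm=3.0, attenuation_slope=0.5,
            focus_depth_cm=3.5, seed=22,
        )
        fr = simulate_rf(spec)
        res = estimate_attenuation(
            local_spectra(fr, AttenuationSpec()), AttenuationSpec()
        )
        mean = np.nanmean(res["values"])
        assert abs(abs(mean) - 0.5) / 0.5 <= 0.07
        vals = res["values"][np.isfinite(res["values"])]
        assert np.all((vals >= -2.0) & (vals <= 0.0))

    def test_tgc_cancels(self):
        """A depth-dependent frequency-independent gain changes no estimate."""
        spec = PhantomSpec(
            depth_extent_cm=2.0, lateral_extent_cm=1.2, attenuation_slope=0.5,
            focus_depth_cm=1.6, seed=23,
        )
        fr = simulate_rf(spec)
        base = estimate_attenuation(local_spectra(fr, AttenuationSpec()),
                                    AttenuationSpec())
        gain = np.exp(np.linspace(0, 1.5, fr.n_axial))
        fr_tgc = RFFrame(
            samples=fr.samples * gain[:, None],
            sampling_rate=fr.sampling_rate,
            line_pitch=fr.line_pitch,
            focus_depth=fr.focus_depth,
        )
        with_gain = estimate_attenuation(local_spectra(fr_tgc, AttenuationSpec()),
                                         AttenuationSpec())
        # the cancellation is exact for within-window-constant gain; the smooth
        # exponential leaves only a small residual per estimate
        assert np.allclose(base["values"], with_gain["values"],
                           atol=0.1, equal_nan=True)
        assert abs(np.nanmean(base["values"]) - np.nanmean(with_gain["values"])) < 0.02

    def test_global_scale_invariance(self):
        spec = PhantomSpec(
            depth_extent_cm=2.0, lateral_extent_cm=1.2, attenuation_slope=0.5,
            focus_depth_cm=1.6, seed=24,
        )
        fr = simulate_rf(spec)
        r1 = estimate_attenuation(local_spectra(fr, AttenuationSpec()),
                                  AttenuationSpec())
        fr2 = RFFrame(samples=fr.samples * 1e3, sampling_rate=fr.sampling_rate,
                      line_pitch=fr.line_pitch, focus_depth=fr.focus_depth)
        r2 = estimate_attenuation(local_spectra(fr2, AttenuationSpec()),
                                  AttenuationSpec())
        assert np.allclose(r1["values"], r2["values"], atol=1e-9, equal_nan=True)

    def test_bounds_always_respected(self):
        """Even absurd input yields only values inside [-2, 0] dB/cm/MHz."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal((1500, 60)) * np.exp(
            np.linspace(0, 8, 1500)
        )[:, None]
        frame = RFFrame(samples=x, sampling_rate=56e6, line_pitch=2e-4,
                        focus_depth=0.02)
        res = estimate_attenuation(local_spectra(frame, AttenuationSpec()),
                                   AttenuationSpec())
        vals = res["values"][np.isfinite(res["values"])]
        assert np.all((vals >= -2.0) & (vals <= 0.0))


def test_attenuation_map_respects_region(small_frame):
    from usradiomics.rf_core import RegionMasks

    shape = small_frame.samples.shape
    tumor = np.zeros(shape, bool)
    tumor[200:500, 10:40] = True
    ring = np.zeros(shape, bool)
    ring[150:550, 5:45] = True
    ring &= ~tumor
    masks = RegionMasks(tumor=tumor, peri_tumor=ring)
    amap = attenuation_map(small_frame, AttenuationSpec(), masks)
    assert np.isnan(amap[~masks.union]).all()
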