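"""Phantom and cohort generator: determinism, speckle regime, attenuation truth."""

import numpy as np
import pytest
from scipy import stats

from usradiomics.rf_core import compute_envelope
from usradiomics.synth import (
    CohortSpec,
    PhantomSpec,
    RegionParams,
    simulate_cohort,
    simulate_feature_cohort,
    simulate_rf,
)


def test_same_seed_bit_identical():
    spec = PhantomSpec(depth_extent_cm=1.0, lateral_extent_cm=0.5, seed=7)
    f1 = simulate_rf(spec)
    f2 = simulate_rf(spec)
    assert np.array_equal(f1.samples, f2.samples)


def test_different_seed_differs():
    s1 = PhantomSpec(depth_extent_cm=1.0, lateral_extent_cm=0.5, seed=7)
    s2 = PhantomSpec(depth_extent_cm=1.0, lateral_extent_cm=0.5, seed=8)
    assert not np.array_equal(simulate_rf(s1).samples, simulate_rf(s2).samples)


def test_spec_validation():
    with pytest.raises(ValueError):
        PhantomSpec(attenuation_slope=3.0)
    with pytest.raises(ValueError):
        PhantomSpec(scatterer_density=0.0)
    with pytest.raises(ValueError):
        PhantomSpec(sampling_rate_hz=5e6)  # Nyquist violation
    with pytest.raises(ValueError):
        CohortSpec(n_per_group=0)


def test_fully_developed_speckle_is_rayleigh(small_frame):
    """Zero-attenuation dense Rayleigh phantom: decorrelated envelope samples
    pass a Kolmogorov-Smirnov Rayleigh goodness-of-fit at alpha = 0.01."""
    env = compute_envelope(small_frame).amplitude
    # subsample beyond the speckle correlation length (~pulse x beam)
    sub = env[100:-100:40, ::4].ravel()
    scale = np.sqrt((sub**2).mean() / 2.0)
    _, p = stats.kstest(sub, "rayleigh", args=(0, scale))
    assert p > 0.01


def test_spectral_centroid_decreases_with_depth():
    """Known transmitted spectrum oracle: with positive attenuation slope the
    depth-resolved centroid must decrease monotonically (block averages)."""
    spec = PhantomSpec(
        depth_extent_cm=3.0, lateral_extent_cm=1.0, attenuation_slope=0.5,
        focus_depth_cm=1.5, seed=3,
    )
    fr = simulate_rf(spec)
    x = fr.samples
    n_blocks = 6
    step = x.shape[0] // n_blocks
    cents = []
    for b in range(n_blocks):
        seg = x[b * step : (b + 1) * step]
        spec_p = (np.abs(np.fft.rfft(seg, axis=0)) ** 2).mean(axis=1)
        f = np.fft.rfftfreq(seg.shape[0], d=1 / fr.sampling_rate)
        cents.append((f * spec_p).sum() / spec_p.sum())
    assert np.all(np.diff(cents) < 0)


def test_density_change_keeps_rayleigh_family():
    """Doubling scatterer density must not leave the fully developed regime."""
    ms = []
    for dens in (30.0, 60.0):
        spec = PhantomSpec(
            depth_extent_cm=1.5, lateral_extent_cm=2.0, attenuation_slope=0.0,
            scatterer_density=dens, seed=5,
        )
        env = compute_envelope(simulate_rf(spec)).amplitude
        # normalize out the depth-dependent focal gain before pooling depths
        env = env / np.sqrt((env**2).mean(axis=1, keepdims=True))
        sub = env[50:-50:30, ::3].ravel()
        a2 = sub**2
        ms.append(a2.mean() ** 2 / a2.var())
    assert all(abs(m - 1.0) < 0.15 for m in ms)


class TestCohort:
    def test_structure_and_determinism(self):
        spec = CohortSpec(
            n_per_group=2,
            timepoints=("pre",),
            phantom=PhantomSpec(depth_extent_cm=1.0, lateral_extent_cm=0.8),
            seed=1,
        )
        rows1 = list(simulate_cohort(spec))
        rows2 = list(simulate_cohort(spec))
        assert len(rows1) == 4
        labels = [r[2] for r in rows1]
        assert labels.count(0) == labels.count(1) == 2
        for r1, r2 in zip(rows1, rows2):
            assert np.array_equal(r1[3].samples, r2[3].samples)

    def test_tumor_mask_area_matches_geometry(self):
        ph = PhantomSpec(depth_extent_cm=1.8, lateral_extent_cm=1.8, focus_depth_cm=1.2)
        spec = CohortSpec(
            n_per_group=1, timepoints=("pre",), phantom=ph,
            tumor_radius_mm=(6.0, 6.0), seed=2,
        )
        _, _, _, frame, masks, truth = next(iter(simulate_cohort(spec)))
        area_mm2 = masks.tumor.sum() * (frame.axial_pitch * 1e3) * (
            frame.line_pitch * 1e3
        )
        assert abs(area_mm2 - np.pi * 36.0) / (np.pi * 36.0) < 0.05
        assert not (masks.tumor & masks.peri_tumor).any()

    def test_truth_emitted(self):
        spec = CohortSpec(
            n_per_group=1, timepoints=("pre",),
            phantom=PhantomSpec(depth_extent_cm=1.0, lateral_extent_cm=0.8),
            seed=3,
        )
        _, _, label, _, _, truth = next(iter(simulate_cohort(spec)))
        for key in ("label", "attenuation", "tumor_density", "tumor_radius_scale"):
            assert key in truth


class TestFeatureCohort:
    def test_shape_and_balance(self):
        table, reps = simulate_feature_cohort(n_per_group=5, seed=0)
        assert table.shape == (30, 175)  # 174 features + label
        assert (table["label"] == 1).sum() == 15
        assert reps.index.get_level_values("replicate").nunique() == 3

    def test_null_effect_groups_exchangeable(self):
        """With zero effect the group mean difference is at chance level."""
        table, _ = simulate_feature_cohort(n_per_group=15, effect_sd=0.0, seed=4)
        pre = table.xs("pre", level="timepoint")
        X = pre.drop(columns="label")
        y = pre["label"].to_numpy()
        d = X[y == 1].mean() - X[y == 0].mean()
        pooled = X.std()
        # standardized effect sizes should look like N(0, 2/n) noise
        z = (d / (pooled * np.sqrt(2.0 / 15.0))).abs()
        assert z.median() < 1.5

    def test_determinism(self):
        t1, r1 = simulate_feature_cohort(n_per_group=4, effect_sd=1.0, seed=9)
        t2, r2 = simulate_feature_cohort(n_per_group=4, effect_sd=1.0, seed=9)
        assert t1.equals(t2) and r1.equals(r2)
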