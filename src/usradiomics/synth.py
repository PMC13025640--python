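"""Synthetic RF phantom and longitudinal two-group cohort generator.

No clinical RF data ships with this package, so every estimator downstream is
validated against phantoms whose ground truth is known by construction:

* ``simulate_rf`` builds a linear-array RF frame by convolving a random
  sub-resolution scatterer field with a Gaussian-modulated pulse whose
  spectrum is progressively attenuated with depth at a known slope
  (dB/cm/MHz). Scatterer "size" is a per-scatterer Gaussian footprint whose
  width low-passes the backscattered spectrum — the physical premise of
  H-scan frequency imaging (smaller scatterers return higher-frequency
  content).
* ``simulate_cohort`` embeds a tumor disc with group- and timepoint-dependent
  generative parameters into such frames, emulating a two-arm longitudinal
  response-monitoring study (responder-like vs non-responder-like).
* ``simulate_feature_cohort`` draws the assembled per-patient feature table
  directly from group-shifted distributions; it is the desk-scale condition
  used to calibrate the classifier (null and strong-effect cohorts) where
  re-running the full RF-to-feature pipeline per patient would be wasteful.

Determinism: every public entry point is a pure function of its spec,
including the seed; per-patient substreams are derived with
``np.random.SeedSequence(entropy=seed, spawn_key=...)`` so cohorts are
reproducible under any generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import fftconvolve

from .rf_core import RFFrame, RegionMasks

DB_PER_NEPER = 8.685889638065035  # 20 / ln(10)


@dataclass
class PhantomSpec:
    """Generative description of a speckle phantom with known attenuation.

    ``attenuation_slope`` is the magnitude of the frequency-dependent loss in
    dB/cm/MHz (two-way path accounted for during synthesis). ``scatterer_density``
    counts scatterers per resolution cell; densities well above ~5 give fully
    developed (Rayleigh) speckle. ``scatterer_radius_scale`` multiplies the
    Gaussian scatterer footprint (scale 1 ~ 40 um); larger scatterers low-pass
    the backscatter spectrum.
    """

    depth_extent_cm: float = 3.0
    lateral_extent_cm: float = 2.0
    scatterer_density: float = 30.0
    scatterer_radius_scale: float = 1.0
    attenuation_slope: float = 0.5  # dB/cm/MHz, magnitude
    pulse_center_mhz: float = 5.5
    pulse_bandwidth: float = 0.6  # fractional (FWHM of power spectrum / fc)
    focus_depth_cm: float = 1.5
    amplitude_model: str = "rayleigh"  # rayleigh | nakagami | burr
    amplitude_params: tuple = ()
    sampling_rate_hz: float = 56e6
    line_pitch_m: float = 2e-4
    noise_db: float = -40.0  # additive white noise re speckle RMS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.attenuation_slope <= 2.0:
            raise ValueError("attenuation_slope must lie in [0, 2] dB/cm/MHz")
        if self.scatterer_density <= 0:
            raise ValueError("scatterer_density must be positive")
        f_max = self.pulse_center_mhz * (1.0 + self.pulse_bandwidth)
        if self.sampling_rate_hz <= 2.0 * f_max * 1e6:
            raise ValueError("sampling rate violates Nyquist for the pulse band")

    @property
    def axial_pitch_m(self) -> float:
        return 1540.0 / (2.0 * self.sampling_rate_hz)

    @property
    def n_axial(self) -> int:
        return int(round(self.depth_extent_cm * 1e-2 / self.axial_pitch_m))

    @property
    def n_lines(self) -> int:
        return int(round(self.lateral_extent_cm * 1e-2 / self.line_pitch_m))


@dataclass
class RegionParams:
    """Scatterer-field parameters for one tissue region."""

    density: float = 30.0
    radius_scale: float = 1.0
    amplitude_model: str = "rayleigh"
    amplitude_params: tuple = ()
    echogenicity: float = 1.0  # relative scatterer strength
    hetero: float = 0.0  # SD of a low-frequency multiplicative modulation


def _scatterer_amplitudes(model: str, params: tuple, n: int, rng) -> np.ndarray:
    """Draw signed scatterer strengths under the requested amplitude law."""
    if model == "rayleigh":
        return rng.standard_normal(n)
    if model == "nakagami":
        m, omega = params if params else (1.0, 1.0)
        mag = np.sqrt(rng.gamma(m, omega / m, n))
        return mag * rng.choice([-1.0, 1.0], n)
    if model == "burr":
        b, lam = params if params else (3.0, 1.0)
        u = rng.uniform(size=n)
        mag = lam * np.sqrt(u ** (-1.0 / (b - 1.0)) - 1.0)
        return mag * rng.choice([-1.0, 1.0], n)
    raise ValueError(f"unknown amplitude model {model!r}")


def _scatterer_field(
    shape: tuple[int, int],
    params: RegionParams,
    spec: PhantomSpec,
    rng,
) -> np.ndarray:
    """Random sub-resolution scatterer field for one region's parameters."""
    n_ax, n_lat = shape
    # resolution cell ~ pulse length x beam width, in grid samples
    sigma_t = _pulse_sigma_t(spec)
    pulse_len = 2.355 * sigma_t * spec.sampling_rate_hz  # FWHM in samples
    beam_lines = max(3.0, 4e-4 / spec.line_pitch_m)  # ~0.4 mm beam
    cell_px = max(pulse_len * beam_lines, 1.0)
    p = min(1.0, params.density / cell_px)
    mask = rng.uniform(size=shape) < p
    amp = np.zeros(shape)
    idx = np.flatnonzero(mask)
    amp.flat[idx] = _scatterer_amplitudes(
        params.amplitude_model, params.amplitude_params, idx.size, rng
    )
    amp *= params.echogenicity
    if params.hetero > 0:
        # smooth multiplicative modulation: spatial texture heterogeneity
        mod = rng.standard_normal(shape)
        mod = gaussian_filter1d(gaussian_filter1d(mod, 40, axis=0), 4, axis=1)
        mod /= max(mod.std(), 1e-12)
        amp *= np.exp(params.hetero * mod)
    # scatterer footprint: Gaussian blur whose width encodes scatterer size
    sigma_ax = params.radius_scale * 40e-6 / spec.axial_pitch_m
    amp = gaussian_filter1d(amp, sigma_ax, axis=0)
    return amp


def _pulse_sigma_t(spec: PhantomSpec) -> float:
    """Temporal sigma (s) of the Gaussian pulse envelope from fractional bandwidth."""
    sigma_f = spec.pulse_bandwidth * spec.pulse_center_mhz * 1e6 / 2.355
    return 1.0 / (2.0 * np.pi * sigma_f)


def _propagate(field: np.ndarray, spec: PhantomSpec, rng) -> np.ndarray:
    """Convolve a scatterer field with the depth-attenuated pulse (overlap-add).

    The frequency-dependent loss exp(-2 alpha_Np f z) is applied blockwise in
    depth (0.5 mm blocks), which is piecewise-constant but fine relative to the
    3 mm spectral-analysis windows used downstream. A depth-dependent lateral
    Gaussian emulates the focal waist; being frequency independent it cancels
    in the attenuation estimator exactly like TGC.
    """
    n_ax, n_lat = field.shape
    fs = spec.sampling_rate_hz
    sigma_t = _pulse_sigma_t(spec)
    klen = int(np.ceil(8 * sigma_t * fs)) | 1
    t = (np.arange(klen) - klen // 2) / fs
    env = np.exp(-0.5 * (t / sigma_t) ** 2)
    base_pulse = env * np.cos(2 * np.pi * spec.pulse_center_mhz * 1e6 * t)

    nfft = int(2 ** np.ceil(np.log2(klen * 2)))
    freqs_mhz = np.fft.rfftfreq(nfft, d=1.0 / fs) / 1e6
    P = np.fft.rfft(base_pulse, nfft)

    block = max(8, int(round(0.5e-3 / spec.axial_pitch_m)))  # 0.5 mm blocks
    alpha_np = spec.attenuation_slope / DB_PER_NEPER  # Np/cm/MHz
    out = np.zeros((n_ax + klen - 1, n_lat))
    zf_cm = spec.focus_depth_cm
    for start in range(0, n_ax, block):
        stop = min(start + block, n_ax)
        z_cm = (start + stop) / 2 * spec.axial_pitch_m * 1e2
        # two-way amplitude loss exp(-2 alpha f z)
        gain = np.exp(-2.0 * alpha_np * freqs_mhz * z_cm)
        kernel = np.fft.irfft(P * gain, nfft)[:klen]
        sub = field[start:stop]
        # focal waist: lateral blur grows away from the focus. The blur is
        # variance-preserving: the depth profile of focal gain is frequency
        # independent (it cancels in spectral estimators exactly like TGC),
        # but a depth-varying field variance would warp the effective centers
        # of finite spectral windows and bias slope differences, so only the
        # lateral correlation length is depth dependent here.
        sigma_lat = 0.8 * np.sqrt(1.0 + ((z_cm - zf_cm) / max(zf_cm, 0.5)) ** 2)
        blurred = gaussian_filter1d(sub, sigma_lat, axis=1)
        bstd = blurred.std()
        if bstd > 0:
            blurred *= sub.std() / bstd
        sub = blurred
        out[start : stop + klen - 1] += fftconvolve(sub, kernel[:, None], mode="full")
    rf = out[klen // 2 : klen // 2 + n_ax]
    if spec.noise_db > -np.inf:
        rms = rf.std()
        rf = rf + rng.standard_normal(rf.shape) * rms * 10 ** (spec.noise_db / 20.0)
    return rf


def simulate_rf(
    spec: PhantomSpec,
    region_mask: np.ndarray | None = None,
    region_params: RegionParams | None = None,
) -> RFFrame:
    """Simulate one RF frame; optionally override a region's scatterer field.

    ``region_mask`` (frame-grid boolean) with ``region_params`` substitutes a
    second scatterer population inside the mask — used for tumor inclusions and
    two-region scatterer-size phantoms. Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    bg = RegionParams(
        density=spec.scatterer_density,
        radius_scale=spec.scatterer_radius_scale,
        amplitude_model=spec.amplitude_model,
        amplitude_params=spec.amplitude_params,
    )
    shape = (spec.n_axial, spec.n_lines)
    field = _scatterer_field(shape, bg, spec, rng)
    if region_mask is not None:
        if region_params is None:
            raise ValueError("region_params required with region_mask")
        field2 = _scatterer_field(shape, region_params, spec, rng)
        field = np.where(region_mask, field2, field)
    rf = _propagate(field, spec, rng)
    band_lo = max(1.0, spec.pulse_center_mhz * (1 - spec.pulse_bandwidth))
    return RFFrame(
        samples=rf,
        sampling_rate=spec.sampling_rate_hz,
        line_pitch=spec.line_pitch_m,
        transducer_band=(3.0, 8.0),
        focus_depth=spec.focus_depth_cm * 1e-2,
    )


# ---------------------------------------------------------------------------
# Longitudinal two-group RF cohort
# ---------------------------------------------------------------------------

TIMEPOINTS = ("pre", "t10", "t30")


@dataclass
class CohortSpec:
    """Two-group longitudinal cohort at three assessment timepoints.

    ``group_effects`` maps a generative parameter to the additive shift the
    responder-like (label 1) group receives at each follow-up timepoint,
    relative to the non-responder-like group. Supported keys: ``radius_scale``
    (H-scan frequency truth), ``density`` (speckle shape truth),
    ``attenuation`` (dB/cm/MHz), ``hetero`` (texture heterogeneity). Zero
    effects make the two groups exchangeable draws from one distribution.
    """

    n_per_group: int = 15
    timepoints: tuple = TIMEPOINTS
    group_effects: dict = field(default_factory=dict)
    tumor_radius_mm: tuple[float, float] = (5.0, 9.0)
    noise_sd: float = 0.1
    phantom: PhantomSpec = field(default_factory=lambda: PhantomSpec())
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("cohort needs at least one patient per group")


def _patient_rng(seed: int, *key: int):
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def simulate_cohort(spec: CohortSpec):
    """Yield (patient_id, timepoint, label, RFFrame, RegionMasks, truth) tuples.

    The tumor is a disc (radius drawn per patient from ``tumor_radius_mm``)
    centered pre-focally; its scatterer parameters differ from background and,
    between groups, by ``group_effects`` at follow-up timepoints. Masks are on
    the frame grid. ``truth`` records the generative parameters.
    """
    base = spec.phantom
    for gi, label in enumerate((0, 1)):
        for pi in range(spec.n_per_group):
            prng = _patient_rng(spec.seed, gi, pi)
            radius_mm = prng.uniform(*spec.tumor_radius_mm)
            pid = f"g{label}p{pi:02d}"
            for ti, tp in enumerate(spec.timepoints):
                trng = _patient_rng(spec.seed, gi, pi, ti)
                eff = {
                    k: (v[ti] if np.ndim(v) else v) * label
                    for k, v in spec.group_effects.items()
                }
                tum = RegionParams(
                    density=max(1.0, base.scatterer_density * 0.6
                                + eff.get("density", 0.0)
                                + trng.normal(0, spec.noise_sd)),
                    radius_scale=max(
                        0.2,
                        base.scatterer_radius_scale * 1.3
                        + eff.get("radius_scale", 0.0)
                        + trng.normal(0, spec.noise_sd * 0.2),
                    ),
                    echogenicity=0.7,
                    hetero=max(0.0, 0.3 + eff.get("hetero", 0.0)
                               + trng.normal(0, spec.noise_sd * 0.2)),
                )
                alpha = float(
                    np.clip(
                        base.attenuation_slope + eff.get("attenuation", 0.0)
                        + trng.normal(0, spec.noise_sd * 0.1),
                        0.0,
                        2.0,
                    )
                )
                pspec = replace(
                    base,
                    attenuation_slope=alpha,
                    seed=int(trng.integers(2**31)),
                )
                mask = _disc_mask(pspec, radius_mm)
                frame = simulate_rf(pspec, region_mask=mask, region_params=tum)
                # ring width 5 mm on the anisotropic frame grid via physical distance
                masks = _frame_masks(mask, pspec, ring_mm=5.0)
                truth = {
                    "label": label,
                    "radius_mm": radius_mm,
                    "attenuation": alpha,
                    "tumor_density": tum.density,
                    "tumor_radius_scale": tum.radius_scale,
                }
                yield pid, tp, label, frame, masks, truth


def _disc_mask(spec: PhantomSpec, radius_mm: float) -> np.ndarray:
    """Boolean disc on the frame grid, centered pre-focally."""
    z = np.arange(spec.n_axial) * spec.axial_pitch_m * 1e3  # mm
    x = (np.arange(spec.n_lines) - spec.n_lines / 2) * spec.line_pitch_m * 1e3
    zc = spec.focus_depth_cm * 10.0 * 0.6  # 60% of focus depth
    return ((z[:, None] - zc) ** 2 + x[None, :] ** 2) <= radius_mm**2


def _frame_masks(tumor: np.ndarray, spec: PhantomSpec, ring_mm: float) -> RegionMasks:
    """Peri-tumoral ring on the (anisotropic) frame grid by physical distance."""
    from scipy.ndimage import distance_transform_edt

    samp = (spec.axial_pitch_m * 1e3, spec.line_pitch_m * 1e3)
    dist = distance_transform_edt(~tumor, sampling=samp)
    ring = (dist > 0) & (dist <= ring_mm)
    return RegionMasks(tumor=tumor, peri_tumor=ring, ring_width_mm=ring_mm)


# ---------------------------------------------------------------------------
# Feature-level cohort (desk-scale classifier calibration)
# ---------------------------------------------------------------------------

def simulate_feature_cohort(
    n_per_group: int = 15,
    effect_sd: float = 0.0,
    n_informative: int = 12,
    n_replicates: int = 3,
    replicate_noise_sd: float = 0.05,
    n_unstable: int = 20,
    seed: int = 0,
):
    """Draw the assembled 174-column feature table directly from group-shifted
    normals, bypassing RF synthesis.

    Each feature j for patient i at timepoint t is
    ``x = b_j + u_i + delta_j(t) * label + noise`` with patient random effect
    ``u_i`` and per-feature baseline ``b_j``; ``delta_j`` equals ``effect_sd``
    (in units of the noise SD) on ``n_informative`` features and 0 elsewhere,
    so ``effect_sd=0`` makes the groups exchangeable (the null condition) and
    large ``effect_sd`` makes them separable by construction.

    Returns ``(table, replicates)``: the patient x timepoint feature table
    (label column included) and baseline perturbation replicates for the ICC
    stability stage, where the last ``n_unstable`` features are re-drawn per
    replicate (unstable, ICC ~ 0) and the rest only jitter slightly (ICC ~ 1).
    """
    from .features import feature_schema

    cols = [c.name for c in feature_schema()]
    n_feat = len(cols)
    rng = np.random.default_rng(seed)
    base = rng.normal(0, 1, n_feat)
    informative = rng.choice(n_feat - n_unstable, size=n_informative, replace=False)
    delta = np.zeros(n_feat)
    delta[informative] = effect_sd * rng.choice([-1.0, 1.0], n_informative)

    rows, index, labels = [], [], []
    rep_rows, rep_index = [], []
    for label in (0, 1):
        for pi in range(n_per_group):
            pid = f"g{label}p{pi:02d}"
            u = rng.normal(0, 0.3, n_feat)
            for ti, tp in enumerate(TIMEPOINTS):
                x = base + u + delta * label * (1.0 if ti == 0 else 1.0 + 0.3 * ti)
                x = x + rng.normal(0, 1.0, n_feat)
                rows.append(x)
                index.append((pid, tp))
                labels.append(label)
                if ti == 0:
                    for r in range(n_replicates):
                        xr = x + rng.normal(0, replicate_noise_sd, n_feat)
                        if n_unstable:
                            xr[-n_unstable:] = rng.normal(0, 1.0, n_unstable)
                        rep_rows.append(xr)
                        rep_index.append((pid, r))

    import pandas as pd

    table = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["patient", "timepoint"]),
        columns=cols,
    )
    table["label"] = labels
    reps = pd.DataFrame(
        rep_rows,
        index=pd.MultiIndex.from_tuples(rep_index, names=["patient", "replicate"]),
        columns=cols,
    )
    return table, reps
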