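"""Reference-frequency attenuation-coefficient estimation.

The frequency-dependent loss of ultrasound in tissue tilts the local power
spectrum of the backscattered RF downward with depth. Writing the localized
power spectrum at lateral kernel x_l and depth z as

    S(f, z) = |P(f)|^2 B(f) exp(-4 alpha f z) G(z)^2,

with alpha in Np/cm/MHz, the frequency derivative of ln S is
``-4 alpha z + d/df ln(|P|^2 B)``; the depth-independent pulse/backscatter
term and every frequency-independent gain (TGC, focal gain) cancel when two
depths are differenced:

    alpha(z_k) = -[d(z_k) - d(z_r)] / (4 (z_k - z_r)),   d(z) = d/df ln S(f, z)

Each d(z) is the ordinary-least-squares slope of ln power vs frequency over
the usable band (within 20 dB of the spectral peak). All reference depths
z_r != z_k in the same lateral kernel enter a least-squares solve, and the
result is converted to dB/cm/MHz and constrained to the [-2, 0] physical
range (negative-slope sign convention: the magnitude is the attenuation
slope). Analysis is restricted to the pre-focal zone plus a short post-focal
margin, where the single-focus beam approximation holds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from .rf_core import RFFrame, RegionMasks
from .speckle import paint_windows

DB_PER_NEPER = 8.685889638065035


@dataclass
class AttenuationSpec:
    """Estimation geometry and constraints (all lengths physical)."""

    lateral_kernel_mm: float = 10.0
    lateral_step_mm: float = 0.2
    axial_window_mm: float = 3.0
    axial_overlap: float = 0.95
    bounds_db: tuple[float, float] = (-2.0, 0.0)
    postfocal_limit_cm: float = 0.8
    usable_band_drop_db: float = 20.0

    def __post_init__(self) -> None:
        if self.bounds_db[0] >= self.bounds_db[1]:
            raise ValueError("bounds must satisfy lo < hi")
        if not self.lateral_kernel_mm > self.lateral_step_mm > 0:
            raise ValueError("need kernel > step > 0")


@dataclass
class SpectralProfile:
    """Averaged local power spectra for one lateral kernel."""

    power: np.ndarray  # [n_depths x n_freqs]
    freqs_mhz: np.ndarray
    depths_cm: np.ndarray
    lateral_center: int  # line index of the kernel center
    usable_band: tuple[float, float]  # MHz
    window_var_mhz2: float = 0.0  # spectral variance of the taper's |W(f)|^2


def _usable_band(mean_spec: np.ndarray, freqs: np.ndarray, band, drop_db: float):
    """Contiguous frequency region within `drop_db` of the in-band peak."""
    sel = (freqs >= band[0]) & (freqs <= band[1])
    power = np.where(sel, mean_spec, 0.0)
    peak = power.max()
    ok = power >= peak * 10 ** (-drop_db / 10.0)
    ipk = int(np.argmax(power))
    lo = ipk
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = ipk
    while hi < len(ok) - 1 and ok[hi + 1]:
        hi += 1
    return freqs[lo], freqs[hi]


def local_spectra(
    frame: RFFrame,
    spec: AttenuationSpec | None = None,
    masks: RegionMasks | None = None,
) -> list[SpectralProfile]:
    """Windowed power spectra per lateral kernel across the analysis region.

    The analysis region is the pre-focal zone plus ``postfocal_limit_cm``
    beyond the focus, intersected (if masks are given) with the axial/lateral
    extent of the tumor + peri-tumor region. Spectra are Hann-windowed
    periodograms averaged over the kernel's lines.
    """
    spec = spec or AttenuationSpec()
    frame = frame.without_tgc()
    dz_m = frame.axial_pitch
    win = max(8, int(round(spec.axial_window_mm * 1e-3 / dz_m)))
    step = max(1, int(round((1.0 - spec.axial_overlap) * win)))
    klines = max(3, int(round(spec.lateral_kernel_mm * 1e-3 / frame.line_pitch)))
    kstep = max(1, int(round(spec.lateral_step_mm * 1e-3 / frame.line_pitch)))

    z_max_m = frame.focus_depth + spec.postfocal_limit_cm * 1e-2
    ax_hi = min(frame.n_axial, int(z_max_m / dz_m))
    # skip the first window: the shallowest samples carry edge transients
    # (incomplete pulse support) that flatten their spectra
    ax_lo, lat_lo, lat_hi = win, 0, frame.n_lines
    if masks is not None:
        rows = np.flatnonzero(masks.union.any(axis=1))
        cols = np.flatnonzero(masks.union.any(axis=0))
        ax_lo, ax_hi = max(ax_lo, rows[0]), min(ax_hi, rows[-1] + 1)
        lat_lo, lat_hi = cols[0], cols[-1] + 1
    if ax_hi - ax_lo < win:
        raise ValueError("analysis region too small for one axial window")
    # narrow regions: shrink the kernel to the available width (>= 3 lines)
    klines = min(klines, lat_hi - lat_lo)
    if klines < 3:
        raise ValueError("analysis region too narrow for a lateral kernel")

    nfft = int(2 ** np.ceil(np.log2(win * 2)))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / frame.sampling_rate) / 1e6
    taper = get_window("hann", win)[:, None]
    win_var = _taper_spectral_variance(taper[:, 0], frame.sampling_rate)

    starts = np.arange(ax_lo, ax_hi - win + 1, step)
    depths_cm = (starts + win / 2) * dz_m * 1e2
    profiles = []
    half = klines // 2
    for lc in range(lat_lo + half, lat_hi - (klines - half) + 1, kstep):
        seg = frame.samples[:, lc - half : lc - half + klines]
        power = np.empty((len(starts), len(freqs)))
        for i, s0 in enumerate(starts):
            block = seg[s0 : s0 + win] * taper
            spec_block = np.abs(np.fft.rfft(block, nfft, axis=0)) ** 2
            power[i] = spec_block.mean(axis=1)
        band = _usable_band(
            power.mean(axis=0), freqs, frame.transducer_band, spec.usable_band_drop_db
        )
        profiles.append(
            SpectralProfile(
                power=power,
                freqs_mhz=freqs,
                depths_cm=depths_cm,
                lateral_center=lc,
                usable_band=band,
                window_var_mhz2=win_var,
            )
        )
    if not profiles:
        raise ValueError("analysis region too narrow for one lateral kernel")
    return profiles


def _taper_spectral_variance(taper: np.ndarray, fs: float) -> float:
    """Spectral variance (MHz^2) of the taper's |W(f)|^2 smoothing kernel.

    The expected windowed periodogram is the true spectrum convolved with
    |W(f)|^2; its variance quantifies the broadening that attenuates
    frequency-slope differences.
    """
    nfft = int(2 ** np.ceil(np.log2(taper.size * 16)))
    W2 = np.abs(np.fft.fft(taper, nfft)) ** 2
    f = np.fft.fftfreq(nfft, d=1.0 / fs) / 1e6
    return float((W2 * f**2).sum() / W2.sum())


def _broadening_factor(prof: "SpectralProfile", fsel: np.ndarray) -> float:
    """Estimate sigma^2 / (sigma^2 + sigma_W^2) from the spectrum's own
    log-curvature: a quadratic fit of ln S gives the broadened Gaussian
    variance; subtracting the known window variance recovers the true one.
    Falls back to 1 (no correction) when the curvature is unusable.
    """
    f = prof.freqs_mhz[fsel]
    if f.size < 5 or prof.window_var_mhz2 <= 0:
        return 1.0
    ln_mean = np.log(np.maximum(prof.power.mean(axis=0)[fsel], 1e-300))
    c = np.polyfit(f, ln_mean, 2)[0]
    if c >= -1e-9:
        return 1.0
    var_meas = -1.0 / (2.0 * c)  # broadened power-Gaussian variance
    var_true = var_meas - prof.window_var_mhz2
    if var_true <= 0.2 * var_meas:
        return 1.0
    return float(var_true / var_meas)


def estimate_attenuation(
    profiles: list[SpectralProfile],
    spec: AttenuationSpec | None = None,
    frame_shape: tuple[int, int] | None = None,
    axial_pitch_m: float | None = None,
) -> np.ndarray | dict:
    """Solve the reference-depth least squares for every (z_k, x_l).

    Returns a dict with ``values`` [n_depths x n_kernels] in dB/cm/MHz
    (clipped to the physical bounds), plus the depth/lateral coordinates.
    If ``frame_shape`` and ``axial_pitch_m`` are given, also paints the
    estimates onto the full frame grid under key ``map``.
    """
    spec = spec or AttenuationSpec()
    n_lat = len(profiles)
    n_z = len(profiles[0].depths_cm)
    if n_z < 2:
        raise ValueError("need at least two axial depths per kernel")
    values = np.full((n_z, n_lat), np.nan)
    win_cm = spec.axial_window_mm / 10.0
    for j, prof in enumerate(profiles):
        fsel = (prof.freqs_mhz >= prof.usable_band[0]) & (
            prof.freqs_mhz <= prof.usable_band[1]
        )
        f = prof.freqs_mhz[fsel]
        if f.size < 3:
            continue
        lnp = np.log(np.maximum(prof.power[:, fsel], 1e-300))
        # OLS slope of ln power vs f (MHz) at every depth, vectorized
        fc = f - f.mean()
        slopes = lnp @ fc / (fc @ fc)  # d(z_k), units 1/MHz (Np scale)
        # windowed spectra are the true spectrum convolved with |W(f)|^2,
        # which shrinks slope differences by sigma^2/(sigma^2 + sigma_W^2);
        # undo the known broadening before differencing
        slopes = slopes / _broadening_factor(prof, fsel)
        z = prof.depths_cm
        for k in range(n_z):
            dz = z[k] - z
            dd = slopes[k] - slopes
            keep = np.abs(dz) >= win_cm  # exclude near-degenerate pairs
            if not keep.any():
                continue
            a = 4.0 * dz[keep]
            # alpha_Np solves min ||a * alpha + dd|| => attenuation magnitude
            alpha_np = -(a @ dd[keep]) / (a @ a)
            alpha_db = -alpha_np * DB_PER_NEPER  # negative-slope convention
            values[k, j] = np.clip(alpha_db, *spec.bounds_db)
    result = {
        "values": values,
        "depths_cm": profiles[0].depths_cm,
        "lateral_centers": np.array([p.lateral_center for p in profiles]),
    }
    if frame_shape is not None and axial_pitch_m is not None:
        centers_ax = np.round(profiles[0].depths_cm * 1e-2 / axial_pitch_m).astype(int)
        full = paint_windows(
            frame_shape, centers_ax, result["lateral_centers"], values
        )
        # blank everything outside the analyzed axial extent
        full[: max(0, centers_ax[0] - 1), :] = np.nan
        full[min(frame_shape[0], centers_ax[-1] + 1) :, :] = np.nan
        result["map"] = full
    return result


def attenuation_map(
    frame: RFFrame,
    spec: AttenuationSpec | None = None,
    masks: RegionMasks | None = None,
) -> np.ndarray:
    """Convenience: local spectra + least squares, painted on the frame grid."""
    spec = spec or AttenuationSpec()
    profiles = local_spectra(frame, spec, masks)
    res = estimate_attenuation(
        profiles, spec, frame_shape=frame.samples.shape, axial_pitch_m=frame.axial_pitch
    )
    full = res["map"]
    if masks is not None:
        # estimates outside the peri-tumor boundary are rejected
        full = np.where(masks.union, full, np.nan)
    return full
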