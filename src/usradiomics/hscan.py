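"""H-scan ultrasound frequency imaging.

H-scan analysis is a matched-filter decomposition of the RF spectrum: the RF
signal is convolved with a bank of frequency-shifted Gaussian band-pass
filters (default 256 centers spanning 3-8 MHz, each with 50% relative
bandwidth), and every pixel is assigned the center frequency of the filter
with the largest envelope response. Because smaller sub-resolution scatterers
backscatter relatively more high-frequency energy, the peak frequency is a
proxy for local scatterer size.

Depth-dependent attenuation would masquerade as a scatterer-size gradient, so
the RF is attenuation-compensated first using the estimated attenuation map
(``attenuation_correct``), inverting the exp(-2 alpha f z) amplitude loss
blockwise in depth.

Implementation notes: filters are applied as zero-phase band-pass transfer
functions in the frequency domain, each normalized to unit peak gain so a
narrowband signal maps exactly to its own frequency; the per-filter response
magnitude is the analytic-signal envelope of the filtered RF. Ties break
toward the lower center frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .rf_core import RFFrame

DB_PER_NEPER = 8.685889638065035


@dataclass
class FilterBank:
    """Gaussian matched-filter bank over the transducer band."""

    centers_mhz: np.ndarray
    relative_bandwidth: float = 0.5

    def __post_init__(self) -> None:
        self.centers_mhz = np.asarray(self.centers_mhz, dtype=np.float64)
        if self.centers_mhz.size < 2 or np.any(np.diff(self.centers_mhz) <= 0):
            raise ValueError("centers must be strictly increasing, length >= 2")

    def __len__(self) -> int:
        return self.centers_mhz.size


def build_filter_bank(
    n: int = 256, band: tuple[float, float] = (3.0, 8.0), rel_bw: float = 0.5
) -> FilterBank:
    """Uniformly spaced Gaussian passbands spanning the band endpoints inclusive.

    The Gaussian sigma_f is set so that the full width at half maximum of the
    (amplitude) passband equals ``rel_bw * fc``.
    """
    if rel_bw <= 0:
        raise ValueError("relative bandwidth must be positive")
    if n < 2:
        raise ValueError("bank needs at least two filters")
    centers = np.linspace(band[0], band[1], n)
    return FilterBank(centers_mhz=centers, relative_bandwidth=rel_bw)


def filter_sigma_f(bank: FilterBank) -> np.ndarray:
    """Per-filter Gaussian sigma (MHz): FWHM = rel_bw * fc = 2.355 sigma."""
    return bank.relative_bandwidth * bank.centers_mhz / (2.0 * np.sqrt(2 * np.log(2)))


def attenuation_correct(frame: RFFrame, alpha_map: np.ndarray | float) -> RFFrame:
    """Invert the depth-progressive spectral tilt using the local |alpha|.

    ``alpha_map`` is a full-frame-grid attenuation map in dB/cm/MHz (negative
    convention) or a scalar; NaNs are filled with the finite median. The
    correction multiplies each depth block's spectrum by exp(+2 |alpha| f z),
    the inverse of the two-way amplitude loss.
    """
    if np.isscalar(alpha_map):
        alpha_mag = abs(float(alpha_map))
    else:
        vals = np.asarray(alpha_map, dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size == 0:
            raise ValueError("attenuation map holds no finite values")
        alpha_mag = abs(float(np.median(finite)))
    if alpha_mag == 0.0:
        return frame

    x = frame.samples
    n_ax = x.shape[0]
    fs = frame.sampling_rate
    block = max(8, int(round(0.5e-3 / frame.axial_pitch)))
    alpha_np = alpha_mag / DB_PER_NEPER
    out = np.empty_like(x)
    nfft = int(2 ** np.ceil(np.log2(max(2 * block, 64))))
    freqs_mhz = np.fft.rfftfreq(nfft, d=1.0 / fs) / 1e6
    f_hi = frame.transducer_band[1]
    pad = block // 2
    for start in range(0, n_ax, block):
        stop = min(start + block, n_ax)
        z_cm = (start + stop) / 2 * frame.axial_pitch * 1e2
        gain = np.exp(2.0 * alpha_np * np.minimum(freqs_mhz, f_hi) * z_cm)
        lo = max(0, start - pad)
        hi = min(n_ax, stop + pad)
        seg = x[lo:hi]
        spec = np.fft.rfft(seg, nfft, axis=0)
        corr = np.fft.irfft(spec * gain[:, None], nfft, axis=0)[: hi - lo]
        out[start:stop] = corr[start - lo : stop - lo]
    return replace(frame, samples=out)


def hscan_map(frame: RFFrame, bank: FilterBank | None = None) -> np.ndarray:
    """Per-pixel peak filter center frequency (MHz) of the matched-filter bank.

    Every value lies within [min(centers), max(centers)]; ties break toward
    the lower frequency. Raises on an all-zero frame (argmax undefined).
    """
    bank = bank or build_filter_bank()
    x = frame.samples
    if not np.any(x):
        raise ValueError("all-zero frame: matched-filter argmax is undefined")
    n_ax = x.shape[0]
    nfft = int(2 ** np.ceil(np.log2(2 * n_ax)))
    freqs_mhz = np.fft.rfftfreq(nfft, d=1.0 / frame.sampling_rate) / 1e6
    X = np.fft.rfft(x, nfft, axis=0)
    sigmas = filter_sigma_f(bank)

    best = np.full(x.shape, -np.inf)
    arg = np.zeros(x.shape, dtype=np.int32)
    for i, (fc, sf) in enumerate(zip(bank.centers_mhz, sigmas)):
        # unit peak gain: a pure tone at fc maps exactly to fc (an energy
        # normalization would bias the argmax low by ~sigma_f^2 / 2 fc)
        h = np.exp(-0.5 * ((freqs_mhz - fc) / sf) ** 2)
        # analytic signal of the filtered RF: scale positive freqs by 2
        resp = np.fft.ifft(
            np.concatenate([X * h[:, None] * 2.0, np.zeros((nfft // 2 - 1, x.shape[1]))]),
            nfft,
            axis=0,
        )[:n_ax]
        mag = np.abs(resp)
        better = mag > best  # strict: ties keep the earlier (lower) center
        best[better] = mag[better]
        arg[better] = i
    return bank.centers_mhz[arg]
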