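"""RF data model, envelope extraction, B-scan formation, region masks, and container I/O.

The carrier object is :class:`RFFrame`: a beamformed radiofrequency (RF)
acquisition stored as a real-valued ``[axial_samples x lines]`` grid with the
geometry needed to interpret it (axial sampling rate, line pitch, sound speed,
transducer band, focus depth). All downstream quantitative-ultrasound maps —
speckle statistics, attenuation, H-scan frequency, texture — are computed from
this object or from the envelope/B-scan images derived from it.

Conventions
-----------
* Axial index 0 is the transducer face; depths are metres internally.
* The envelope is the per-scan-line magnitude of the analytic signal
  ``|r(z) + i H[r(z)]|`` (axial Hilbert transform; the lateral direction is
  untouched).
* B-scans are ``20 log10(a / max a)`` clipped to ``[-dynamic_range, 0]`` dB.
* Time gain compensation (TGC), when present, is a strictly positive per-depth
  gain on linear scale; it is frequency independent and treated as constant
  within any axial analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from scipy.signal import hilbert

SOUND_SPEED_DEFAULT = 1540.0  # m/s, soft-tissue convention


@dataclass
class RFFrame:
    """One beamformed RF acquisition with geometry metadata.

    Parameters
    ----------
    samples : ndarray, shape (axial_samples, lines)
        Real-valued RF samples.
    sampling_rate : float
        Axial sampling rate in Hz.
    line_pitch : float
        Lateral spacing between scan lines in metres.
    sound_speed : float
        Speed of sound in m/s used for depth conversion.
    transducer_band : tuple of float
        (f_lo, f_hi) in MHz.
    focus_depth : float
        Transmit focus depth in metres.
    tgc_profile : ndarray or None
        Per-depth linear-scale gain, strictly positive when present.
    """

    samples: np.ndarray
    sampling_rate: float
    line_pitch: float
    sound_speed: float = SOUND_SPEED_DEFAULT
    transducer_band: tuple[float, float] = (3.0, 8.0)
    focus_depth: float = 0.02
    tgc_profile: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2D [axial x lines] grid")
        if self.samples.shape[1] < 9:
            raise ValueError("frame needs at least 9 scan lines")
        f_hi_hz = self.transducer_band[1] * 1e6
        if self.sampling_rate <= 2.0 * f_hi_hz:
            raise ValueError(
                f"sampling_rate {self.sampling_rate:g} Hz violates Nyquist for "
                f"band up to {self.transducer_band[1]} MHz"
            )
        if self.tgc_profile is not None:
            self.tgc_profile = np.asarray(self.tgc_profile, dtype=np.float64)
            if self.tgc_profile.shape != (self.samples.shape[0],):
                raise ValueError("tgc_profile must have one gain per axial sample")
            if np.any(self.tgc_profile <= 0):
                raise ValueError("tgc_profile must be strictly positive")

    @property
    def n_axial(self) -> int:
        return self.samples.shape[0]

    @property
    def n_lines(self) -> int:
        return self.samples.shape[1]

    @property
    def axial_pitch(self) -> float:
        """Axial sample spacing in metres (two-way travel accounted)."""
        return self.sound_speed / (2.0 * self.sampling_rate)

    def depths(self) -> np.ndarray:
        """Depth of every axial sample in metres."""
        return np.arange(self.n_axial) * self.axial_pitch

    def without_tgc(self) -> "RFFrame":
        """Divide out the TGC profile (identity if absent)."""
        if self.tgc_profile is None:
            return self
        comp = self.samples / self.tgc_profile[:, None]
        return replace(self, samples=comp, tgc_profile=None)


@dataclass
class EnvelopeImage:
    """Non-negative RF envelope with geometry inherited from the source frame."""

    amplitude: np.ndarray
    axial_pitch: float
    line_pitch: float
    focus_depth: float = 0.02

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=np.float64)
        if np.any(self.amplitude < 0):
            raise ValueError("envelope amplitudes must be non-negative")


@dataclass
class BScanImage:
    """Log-compressed envelope in dB relative to the frame maximum."""

    intensity: np.ndarray
    dynamic_range: float = 60.0
    axial_pitch: float = 0.0
    line_pitch: float = 0.0


@dataclass
class RegionMasks:
    """Tumor mask plus the disjoint peri-tumoral ring on the image grid."""

    tumor: np.ndarray
    peri_tumor: np.ndarray
    ring_width_mm: float = 5.0

    def __post_init__(self) -> None:
        self.tumor = np.asarray(self.tumor, dtype=bool)
        self.peri_tumor = np.asarray(self.peri_tumor, dtype=bool)
        if self.tumor.shape != self.peri_tumor.shape:
            raise ValueError("tumor and peri_tumor masks must share a grid")
        if np.any(self.tumor & self.peri_tumor):
            raise ValueError("tumor and peri-tumor masks must be disjoint")

    @property
    def union(self) -> np.ndarray:
        return self.tumor | self.peri_tumor


def compute_envelope(frame: RFFrame) -> EnvelopeImage:
    """Extract the RF envelope as the per-line analytic-signal magnitude.

    NaN samples indicate corrupt input and raise; an all-zero frame yields a
    valid all-zero envelope.
    """
    if not np.all(np.isfinite(frame.samples)):
        raise ValueError("RF frame contains non-finite samples (corrupt input)")
    analytic = hilbert(frame.samples, axis=0)
    return EnvelopeImage(
        amplitude=np.abs(analytic),
        axial_pitch=frame.axial_pitch,
        line_pitch=frame.line_pitch,
        focus_depth=frame.focus_depth,
    )


def form_bscan(env: EnvelopeImage, dynamic_range: float = 60.0) -> BScanImage:
    """Log-compress an envelope into a B-scan in dB relative to its maximum."""
    peak = env.amplitude.max()
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero envelope")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(env.amplitude / peak)
    db = np.clip(db, -dynamic_range, 0.0)
    return BScanImage(
        intensity=db,
        dynamic_range=dynamic_range,
        axial_pitch=env.axial_pitch,
        line_pitch=env.line_pitch,
    )


def build_region_masks(
    tumor_mask: np.ndarray, ring_width_mm: float, pixel_size_mm: float
) -> RegionMasks:
    """Grow a peri-tumoral ring of ``ring_width_mm`` around a tumor mask.

    The ring is the morphological dilation of the tumor by the ring width minus
    the tumor itself; it is clipped at the image boundary (no wraparound).
    Ring widths follow the clinical delineation practice of 3–10 mm.
    """
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    if not tumor_mask.any():
        raise ValueError("tumor mask is empty")
    if not 3.0 <= ring_width_mm <= 10.0:
        raise ValueError("ring_width_mm must lie in [3, 10] mm")
    from scipy.ndimage import distance_transform_edt

    # Euclidean distance (in pixels) from every background pixel to the tumor;
    # the ring is everything within ring_width of the boundary.
    dist = distance_transform_edt(~tumor_mask)
    ring = (dist > 0) & (dist * pixel_size_mm <= ring_width_mm)
    return RegionMasks(tumor=tumor_mask, peri_tumor=ring, ring_width_mm=ring_width_mm)


# ---------------------------------------------------------------------------
# Container I/O: HDF5 with dataset `rf` and geometry attributes
# ---------------------------------------------------------------------------

def save_frame(path, frame: RFFrame, masks: RegionMasks | None = None) -> None:
    """Write an RF frame (and optionally its masks) to the HDF5 container."""
    with h5py.File(path, "w") as h5:
        ds = h5.create_dataset("rf", data=frame.samples)
        ds.attrs["sampling_rate_hz"] = frame.sampling_rate
        ds.attrs["line_pitch_m"] = frame.line_pitch
        ds.attrs["sound_speed_mps"] = frame.sound_speed
        ds.attrs["focus_depth_m"] = frame.focus_depth
        ds.attrs["band_mhz"] = np.asarray(frame.transducer_band)
        if frame.tgc_profile is not None:
            h5.create_dataset("tgc", data=frame.tgc_profile)
        if masks is not None:
            h5.create_dataset("tumor", data=masks.tumor)
            h5.create_dataset("peri_tumor", data=masks.peri_tumor)
            h5["tumor"].attrs["ring_width_mm"] = masks.ring_width_mm


def load_frame(path) -> tuple[RFFrame, RegionMasks | None]:
    """Read an RF frame (and masks, if stored) from the HDF5 container."""
    with h5py.File(path, "r") as h5:
        ds = h5["rf"]
        frame = RFFrame(
            samples=ds[()],
            sampling_rate=float(ds.attrs["sampling_rate_hz"]),
            line_pitch=float(ds.attrs["line_pitch_m"]),
            sound_speed=float(ds.attrs["sound_speed_mps"]),
            focus_depth=float(ds.attrs["focus_depth_m"]),
            transducer_band=tuple(np.asarray(ds.attrs["band_mhz"], dtype=float)),
            tgc_profile=h5["tgc"][()] if "tgc" in h5 else None,
        )
        masks = None
        if "tumor" in h5:
            masks = RegionMasks(
                tumor=h5["tumor"][()],
                peri_tumor=h5["peri_tumor"][()],
                ring_width_mm=float(h5["tumor"].attrs.get("ring_width_mm", 5.0)),
            )
    return frame, masks


def save_map(path, name: str, values: np.ndarray, **attrs) -> None:
    """Store a parametric map under ``maps/<name>`` in an existing container."""
    with h5py.File(path, "a") as h5:
        key = f"maps/{name}"
        if key in h5:
            del h5[key]
        ds = h5.create_dataset(key, data=values)
        for k, v in attrs.items():
            ds.attrs[k] = v
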