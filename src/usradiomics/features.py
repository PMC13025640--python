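"""Assembly of parametric maps into the per-patient feature table.

One patient-timepoint acquisition yields 87 parametric maps:

===========================  =====  ==========
source                       count  domain
===========================  =====  ==========
B-scan intensity                 1  amplitude
Nakagami m, Omega                2  amplitude
Burr b, lambda                   2  amplitude
attenuation (ACE)                1  frequency
H-scan peak frequency            1  frequency
B-scan textures                 40  amplitude
H-scan textures                 40  frequency
===========================  =====  ==========

Each map contributes its mean over the tumor region and over the peri-tumoral
ring, giving 174 features per row (42 frequency-domain maps -> 84 frequency
features, 45 amplitude-domain maps -> 90). Longitudinal features are strictly
within-patient baseline-relative changes ``(x_t - x_pre) / |x_pre|`` — no
cross-patient statistic ever enters a feature value.
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import shift as nd_shift
from scipy.ndimage import zoom

from .attenuation import AttenuationSpec, attenuation_map
from .hscan import attenuation_correct, build_filter_bank, hscan_map
from .rf_core import RFFrame, RegionMasks, compute_envelope, form_bscan
from .speckle import SpeckleWindowSpec, speckle_maps
from .texture import FEATURE_MANIFEST, TextureSpec, texture_maps

MIN_REGION_PIXELS = 10

MapInfo = namedtuple("MapInfo", "name domain")
Column = namedtuple("Column", "name map_name region domain")


def map_manifest() -> list[MapInfo]:
    """The fixed 87-map roster with its amplitude/frequency domain tags."""
    maps = [
        MapInfo("bscan", "amplitude"),
        MapInfo("nak_m", "amplitude"),
        MapInfo("nak_omega", "amplitude"),
        MapInfo("burr_b", "amplitude"),
        MapInfo("burr_lambda", "amplitude"),
        MapInfo("ace", "frequency"),
        MapInfo("hscan_freq", "frequency"),
    ]
    maps += [MapInfo(f"tex/bscan/{f}", "amplitude") for f in FEATURE_MANIFEST]
    maps += [MapInfo(f"tex/hscan/{f}", "frequency") for f in FEATURE_MANIFEST]
    assert len(maps) == 87
    return maps


def feature_schema() -> list[Column]:
    """The 174-column schema: every map crossed with {tumor, peri_tumor}."""
    cols = []
    for m in map_manifest():
        for region in ("tumor", "peri_tumor"):
            cols.append(Column(f"{m.name}|{region}", m.name, region, m.domain))
    assert len(cols) == 174
    return cols


def to_isotropic(
    arr: np.ndarray, axial_pitch_m: float, lateral_pitch_m: float, order: int = 1
) -> np.ndarray:
    """Resample a frame-grid array to an isotropic grid at the lateral pitch."""
    factor = axial_pitch_m / lateral_pitch_m
    if np.isnan(arr).any():
        order = 0  # nearest keeps NaN structure intact
    return zoom(arr, (factor, 1.0), order=order, mode="nearest", grid_mode=True)


def masks_to_isotropic(masks: RegionMasks, axial_pitch_m, lateral_pitch_m) -> RegionMasks:
    t = to_isotropic(masks.tumor.astype(float), axial_pitch_m, lateral_pitch_m, 0) > 0.5
    p = to_isotropic(masks.peri_tumor.astype(float), axial_pitch_m, lateral_pitch_m, 0) > 0.5
    return RegionMasks(tumor=t, peri_tumor=p & ~t, ring_width_mm=masks.ring_width_mm)


def assemble_maps(
    frame: RFFrame,
    masks: RegionMasks,
    speckle_spec: SpeckleWindowSpec | None = None,
    atten_spec: AttenuationSpec | None = None,
    texture_spec: TextureSpec | None = None,
    n_filters: int = 256,
) -> tuple[dict[str, np.ndarray], RegionMasks]:
    """Run every map stage on one frame; returns 87 isotropic-grid maps.

    ``masks`` are on the frame grid; the returned masks are on the common
    isotropic analysis grid that every map is resampled to.
    """
    ap, lp = frame.axial_pitch, frame.line_pitch
    maps: dict[str, np.ndarray] = {}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"map stage '{name}' failed: {exc}") from exc

    env = _stage("envelope", lambda: compute_envelope(frame))
    bscan = _stage("bscan", lambda: form_bscan(env))
    maps["bscan"] = to_isotropic(bscan.intensity, ap, lp)

    spk = _stage("speckle", lambda: speckle_maps(env, speckle_spec))
    for k, v in spk.items():
        maps[k] = to_isotropic(v, ap, lp)

    ace = _stage("ace", lambda: attenuation_map(frame, atten_spec, masks))
    maps["ace"] = to_isotropic(ace, ap, lp)

    corrected = _stage("attenuation_correct", lambda: attenuation_correct(frame, ace))
    hmap = _stage("hscan", lambda: hscan_map(corrected, build_filter_bank(n=n_filters)))
    maps["hscan_freq"] = to_isotropic(hmap, ap, lp)

    masks_iso = masks_to_isotropic(masks, ap, lp)
    tex_b = _stage(
        "texture/bscan", lambda: texture_maps(maps["bscan"], masks_iso, texture_spec)
    )
    for k, v in tex_b.items():
        maps[f"tex/bscan/{k}"] = v
    tex_h = _stage(
        "texture/hscan", lambda: texture_maps(maps["hscan_freq"], masks_iso, texture_spec)
    )
    for k, v in tex_h.items():
        maps[f"tex/hscan/{k}"] = v

    expected = {m.name for m in map_manifest()}
    missing = expected - maps.keys()
    if missing:
        raise RuntimeError(f"map assembly incomplete, missing {sorted(missing)}")
    return maps, masks_iso


def regionize(maps: dict[str, np.ndarray], masks: RegionMasks) -> pd.Series:
    """Regional means of every map over tumor and peri-tumoral pixels.

    Regions with fewer than 10 valid (finite) map pixels yield a missing
    value with a warning.
    """
    values = {}
    for col in feature_schema():
        arr = maps[col.map_name]
        region = masks.tumor if col.region == "tumor" else masks.peri_tumor
        vals = arr[region]
        vals = vals[np.isfinite(vals)]
        if vals.size < MIN_REGION_PIXELS:
            warnings.warn(
                f"{col.name}: only {vals.size} valid pixels, emitting NaN",
                stacklevel=2,
            )
            values[col.name] = np.nan
        else:
            values[col.name] = float(vals.mean())
    return pd.Series(values)


def perturbation_replicates(
    maps: dict[str, np.ndarray],
    masks: RegionMasks,
    pixel_mm: float,
    n_perturbations: int = 4,
    max_shift_mm: float = 1.0,
    rng=None,
) -> pd.DataFrame:
    """Re-extract regional features under small rigid mask shifts (<= 1 mm).

    Used by the ICC stability filter: each replicate is the 174-feature row
    obtained after shifting both masks by a random sub-millimetre offset.
    Replicate 0 is the unshifted extraction.
    """
    rng = np.random.default_rng(rng)
    rows = [regionize(maps, masks)]
    max_px = max(1, int(round(max_shift_mm / pixel_mm)))
    for _ in range(n_perturbations - 1):
        dz, dx = rng.integers(-max_px, max_px + 1, size=2)
        t = np.roll(masks.tumor, (dz, dx), axis=(0, 1))
        p = np.roll(masks.peri_tumor, (dz, dx), axis=(0, 1))
        rows.append(regionize(maps, RegionMasks(t, p & ~t, masks.ring_width_mm)))
    df = pd.DataFrame(rows).reset_index(drop=True)
    df.index.name = "replicate"
    return df


def longitudinal_features(
    table: pd.DataFrame, baseline: str = "pre"
) -> pd.DataFrame:
    """Within-patient baseline-relative changes for every follow-up row.

    For each patient and follow-up timepoint t the change is
    ``(x_t - x_pre) / |x_pre|``; the |.| keeps the sign meaningful for
    negative-valued features such as the attenuation slope. Baselines below
    machine tolerance yield missing values with a warning. Raises if any
    patient lacks a baseline row.
    """
    if not isinstance(table.index, pd.MultiIndex):
        raise ValueError("table must be indexed by (patient, timepoint)")
    feat_cols = [c for c in table.columns if c != "label"]
    out_rows, out_index = [], []
    for pid, sub in table.groupby(level="patient", sort=False):
        sub = sub.droplevel("patient")
        if baseline not in sub.index:
            raise ValueError(f"patient {pid} has no baseline ({baseline}) row")
        x0 = sub.loc[baseline, feat_cols].to_numpy(dtype=float)
        denom = np.abs(x0)
        tiny = denom < np.sqrt(np.finfo(float).eps)
        if tiny.any():
            warnings.warn(
                f"patient {pid}: {int(tiny.sum())} near-zero baselines -> NaN change",
                stacklevel=2,
            )
        for tp in sub.index:
            if tp == baseline:
                continue
            xt = sub.loc[tp, feat_cols].to_numpy(dtype=float)
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = (xt - x0) / denom
            rel[tiny] = np.nan
            row = pd.Series(rel, index=feat_cols)
            if "label" in table.columns:
                row["label"] = sub.loc[tp, "label"]
            out_rows.append(row)
            out_index.append((pid, tp))
    return pd.DataFrame(
        out_rows,
        index=pd.MultiIndex.from_tuples(out_index, names=["patient", "timepoint"]),
    )
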