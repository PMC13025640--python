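"""Denoising, quantization, and sliding-window texture parametric maps.

Forty texture (radiomic) features are computed per source image from four
gray-level matrix families:

* GLCM — co-occurrence of pixel pairs at distance 1 along 0, 45, 135 and 270
  degrees, averaged with inverse-distance weights (1 for the axis-aligned
  offsets, 1/sqrt(2) for the diagonals) and symmetrized;
* GLRLM — run lengths of equal gray level along the same four directions,
  averaged with the same weights;
* GLSZM — sizes of 8-connected equal-gray-level zones (direction free);
* NGTDM — per-level absolute deviation from the 3x3 neighborhood mean
  (direction free; Amadasun-King formulation).

Maps are built with a sliding window (default 9 x 9 pixels on the
isotropically resampled grid, 80% overlap). Pixel intensities inside each
window are quantized to 64 levels between the window's own minimum and
maximum — a window-local operation, so every feature is invariant to affine
intensity rescaling of the image and no cross-image statistics enter.
Windows with zero dynamic range take their analytic degenerate values (e.g.
GLCM contrast 0, homogeneity 1, energy 1) and are flagged.

Images are denoised with Perona-Malik anisotropic diffusion before feature
extraction; the diffusion is spatially local and confined to one image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import label as cc_label
from scipy.ndimage import uniform_filter

from .rf_core import RegionMasks

SQ2 = np.sqrt(2.0)
# offsets (dz, dx) for 0, 45, 135, 270 degrees with inverse-distance weights;
# 270 duplicates 90-degree co-occurrence under symmetry and is kept as such.
DIRECTIONS = [((0, 1), 1.0), ((-1, 1), 1.0 / SQ2), ((-1, -1), 1.0 / SQ2), ((1, 0), 1.0)]

GLCM_FEATURES = [
    "glcm_CON", "glcm_COR", "glcm_DIS", "glcm_ENT", "glcm_ENE", "glcm_HOM",
    "glcm_VAR", "glcm_SA", "glcm_SE", "glcm_DE", "glcm_CS", "glcm_CP",
    "glcm_MP",
]
GLRLM_FEATURES = [
    "glrlm_SRE", "glrlm_LRE", "glrlm_GLN", "glrlm_RLN", "glrlm_RP",
    "glrlm_LGRE", "glrlm_HGRE", "glrlm_SRLGE", "glrlm_SRHGE", "glrlm_LRLGE",
    "glrlm_LRHGE", "glrlm_GLV", "glrlm_RLV",
]
GLSZM_FEATURES = [
    "glszm_SAE", "glszm_LAE", "glszm_LGZE", "glszm_HGZE", "glszm_SZLGE",
    "glszm_SZHGE", "glszm_LZLGE", "glszm_LZHGE", "glszm_ZSV",
]
NGTDM_FEATURES = ["ngtdm_CRS", "ngtdm_CON", "ngtdm_BUS", "ngtdm_COM", "ngtdm_STR"]

FEATURE_MANIFEST = GLCM_FEATURES + GLRLM_FEATURES + GLSZM_FEATURES + NGTDM_FEATURES
assert len(FEATURE_MANIFEST) == 40


@dataclass
class TextureSpec:
    """Texture map construction parameters (isotropic-grid pixels)."""

    window: int = 9
    overlap: float = 0.80
    levels: int = 64
    diffusion_iterations: int = 10
    diffusion_kappa: float = 20.0
    diffusion_step: float = 0.15

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("need at least 2 quantization levels")
        if self.window < 3:
            raise ValueError("window must be at least 3 pixels")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must lie in [0, 1)")

    @property
    def step(self) -> int:
        return max(1, round((1.0 - self.overlap) * self.window))


def denoise(image: np.ndarray, spec: TextureSpec | None = None) -> np.ndarray:
    """Perona-Malik anisotropic diffusion (exponential conduction)."""
    spec = spec or TextureSpec()
    u = np.asarray(image, dtype=np.float64).copy()
    if not np.all(np.isfinite(u)):
        raise ValueError("image must be finite")
    k = spec.diffusion_kappa
    dt = spec.diffusion_step
    for _ in range(spec.diffusion_iterations):
        dn = np.zeros_like(u)
        ds = np.zeros_like(u)
        de = np.zeros_like(u)
        dw = np.zeros_like(u)
        dn[1:, :] = u[:-1, :] - u[1:, :]
        ds[:-1, :] = u[1:, :] - u[:-1, :]
        de[:, :-1] = u[:, 1:] - u[:, :-1]
        dw[:, 1:] = u[:, :-1] - u[:, 1:]
        u = u + dt * sum(g * np.exp(-((g / k) ** 2)) for g in (dn, ds, de, dw))
    return u


def quantize_window(window: np.ndarray, levels: int = 64) -> np.ndarray:
    """Equal-width quantization between the window's own min and max.

    Returns integer levels in [1, levels]; a constant window maps to level 1.
    """
    w = np.asarray(window, dtype=np.float64)
    if w.size == 0:
        raise ValueError("empty window")
    lo, hi = w.min(), w.max()
    if hi <= lo:
        return np.ones(w.shape, dtype=np.int32)
    q = np.floor((w - lo) / (hi - lo) * levels).astype(np.int32) + 1
    return np.minimum(q, levels)


# ---------------------------------------------------------------------------
# Matrix builders
# ---------------------------------------------------------------------------

def glcm_matrix(q: np.ndarray, levels: int) -> np.ndarray:
    """Direction-averaged, symmetrized, normalized co-occurrence matrix."""
    P = np.zeros((levels, levels))
    for (dz, dx), w in DIRECTIONS:
        a, b = _offset_pairs(q, dz, dx)
        np.add.at(P, (a - 1, b - 1), w)
        np.add.at(P, (b - 1, a - 1), w)  # symmetrize
    total = P.sum()
    return P / total if total > 0 else P


def _offset_pairs(q: np.ndarray, dz: int, dx: int):
    nz, nx = q.shape
    z0, z1 = max(0, -dz), min(nz, nz - dz)
    x0, x1 = max(0, -dx), min(nx, nx - dx)
    a = q[z0:z1, x0:x1]
    b = q[z0 + dz : z1 + dz, x0 + dx : x1 + dx]
    return a.ravel(), b.ravel()


def glrlm_matrix(q: np.ndarray, levels: int) -> np.ndarray:
    """Direction-averaged run-length matrix R[gray, run_length-1]."""
    nz, nx = q.shape
    max_run = max(nz, nx)
    R = np.zeros((levels, max_run))
    for (dz, dx), w in DIRECTIONS:
        for line in _direction_lines(q, dz, dx):
            for g, run in _runs(line):
                R[g - 1, run - 1] += w
    return R


def _direction_lines(q: np.ndarray, dz: int, dx: int):
    """Traverse the image along the (dz, dx) direction, yielding 1D lines."""
    if (dz, dx) == (0, 1):
        yield from q
    elif (dz, dx) == (1, 0):
        yield from q.T
    elif (dz, dx) == (-1, 1):  # anti-diagonals
        fl = np.flipud(q)
        for o in range(-fl.shape[0] + 1, fl.shape[1]):
            yield np.diagonal(fl, offset=o)
    elif (dz, dx) == (-1, -1):  # main diagonals (run content equals (1,1))
        for o in range(-q.shape[0] + 1, q.shape[1]):
            yield np.diagonal(q, offset=o)
    else:  # pragma: no cover
        raise ValueError("unsupported direction")


def _runs(line: np.ndarray):
    if line.size == 0:
        return
    change = np.flatnonzero(np.diff(line)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [line.size]])
    for s, e in zip(starts, ends):
        yield int(line[s]), int(e - s)


def glszm_matrix(q: np.ndarray, levels: int) -> np.ndarray:
    """Size-zone matrix Z[gray, zone_size-1] using 8-connected zones."""
    Z = np.zeros((levels, q.size))
    structure = np.ones((3, 3), dtype=int)
    for g in np.unique(q):
        lab, n = cc_label(q == g, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            Z[g - 1, s - 1] += 1
    return Z


def ngtdm_table(q: np.ndarray, levels: int):
    """Amadasun-King s_i (summed neighborhood deviation) and p_i per level.

    Uses the full 3x3 neighborhood; border pixels (incomplete neighborhood)
    are excluded from the counted set, as in the original formulation.
    """
    qf = q.astype(np.float64)
    nb_mean = (uniform_filter(qf, 3) * 9.0 - qf) / 8.0
    inner = np.zeros(q.shape, dtype=bool)
    inner[1:-1, 1:-1] = True
    s = np.zeros(levels)
    counts = np.zeros(levels)
    dev = np.abs(qf - nb_mean)
    for g in range(1, levels + 1):
        sel = inner & (q == g)
        counts[g - 1] = sel.sum()
        s[g - 1] = dev[sel].sum()
    n = counts.sum()
    p = counts / n if n > 0 else counts
    return s, p, counts


# ---------------------------------------------------------------------------
# Feature formulas
# ---------------------------------------------------------------------------

def _glcm_features(P: np.ndarray) -> dict:
    levels = P.shape[0]
    i = np.arange(1, levels + 1)[:, None]
    j = np.arange(1, levels + 1)[None, :]
    out = {}
    out["glcm_CON"] = float(((i - j) ** 2 * P).sum())
    out["glcm_DIS"] = float((np.abs(i - j) * P).sum())
    out["glcm_HOM"] = float((P / (1.0 + (i - j) ** 2)).sum())
    out["glcm_ENE"] = float((P**2).sum())
    nz = P[P > 0]
    out["glcm_ENT"] = float(-(nz * np.log(nz)).sum()) if nz.size else 0.0
    px = P.sum(axis=1)
    mu = float((np.arange(1, levels + 1) * px).sum())
    var = float(((np.arange(1, levels + 1) - mu) ** 2 * px).sum())
    out["glcm_VAR"] = var
    if var > 0:
        out["glcm_COR"] = float((((i - mu) * (j - mu) * P).sum()) / var)
    else:
        out["glcm_COR"] = 0.0  # degenerate: undefined correlation
    # sum/difference distributions
    ks = np.arange(2, 2 * levels + 1)
    p_sum = np.array([P[(i + j) == k].sum() for k in ks])
    out["glcm_SA"] = float((ks * p_sum).sum())
    nzs = p_sum[p_sum > 0]
    out["glcm_SE"] = float(-(nzs * np.log(nzs)).sum()) if nzs.size else 0.0
    kd = np.arange(0, levels)
    p_diff = np.array([P[np.abs(i - j) == k].sum() for k in kd])
    nzd = p_diff[p_diff > 0]
    out["glcm_DE"] = float(-(nzd * np.log(nzd)).sum()) if nzd.size else 0.0
    out["glcm_CS"] = float(((i + j - 2 * mu) ** 3 * P).sum())
    out["glcm_CP"] = float(((i + j - 2 * mu) ** 4 * P).sum())
    out["glcm_MP"] = float(P.max())
    return out


def _weighted_var(weights: np.ndarray, x: np.ndarray) -> float:
    tot = weights.sum()
    if tot <= 0:
        return 0.0
    mu = (weights * x).sum() / tot
    return float((weights * (x - mu) ** 2).sum() / tot)


def _glrlm_features(R: np.ndarray, n_pixels: int) -> dict:
    Nr = R.sum()
    out = {}
    if Nr <= 0:
        return {k: 0.0 for k in GLRLM_FEATURES}
    g = np.arange(1, R.shape[0] + 1)[:, None].astype(float)
    l = np.arange(1, R.shape[1] + 1)[None, :].astype(float)
    out["glrlm_SRE"] = float((R / l**2).sum() / Nr)
    out["glrlm_LRE"] = float((R * l**2).sum() / Nr)
    out["glrlm_GLN"] = float((R.sum(axis=1) ** 2).sum() / Nr)
    out["glrlm_RLN"] = float((R.sum(axis=0) ** 2).sum() / Nr)
    out["glrlm_RP"] = float(Nr / (n_pixels * sum(w for _, w in DIRECTIONS)))
    out["glrlm_LGRE"] = float((R / g**2).sum() / Nr)
    out["glrlm_HGRE"] = float((R * g**2).sum() / Nr)
    out["glrlm_SRLGE"] = float((R / (g**2 * l**2)).sum() / Nr)
    out["glrlm_SRHGE"] = float((R * g**2 / l**2).sum() / Nr)
    out["glrlm_LRLGE"] = float((R * l**2 / g**2).sum() / Nr)
    out["glrlm_LRHGE"] = float((R * g**2 * l**2).sum() / Nr)
    out["glrlm_GLV"] = _weighted_var(R.sum(axis=1), g.ravel())
    out["glrlm_RLV"] = _weighted_var(R.sum(axis=0), l.ravel())
    return out


def _glszm_features(Z: np.ndarray) -> dict:
    Nz = Z.sum()
    out = {}
    if Nz <= 0:
        return {k: 0.0 for k in GLSZM_FEATURES}
    g = np.arange(1, Z.shape[0] + 1)[:, None].astype(float)
    s = np.arange(1, Z.shape[1] + 1)[None, :].astype(float)
    out["glszm_SAE"] = float((Z / s**2).sum() / Nz)
    out["glszm_LAE"] = float((Z * s**2).sum() / Nz)
    out["glszm_LGZE"] = float((Z / g**2).sum() / Nz)
    out["glszm_HGZE"] = float((Z * g**2).sum() / Nz)
    out["glszm_SZLGE"] = float((Z / (g**2 * s**2)).sum() / Nz)
    out["glszm_SZHGE"] = float((Z * g**2 / s**2).sum() / Nz)
    out["glszm_LZLGE"] = float((Z * s**2 / g**2).sum() / Nz)
    out["glszm_LZHGE"] = float((Z * g**2 * s**2).sum() / Nz)
    out["glszm_ZSV"] = _weighted_var(Z.sum(axis=0), s.ravel())
    return out


def _ngtdm_features(s: np.ndarray, p: np.ndarray, counts: np.ndarray) -> dict:
    eps = 1e-12
    out = {}
    present = p > 0
    Ng = int(present.sum())
    n = counts.sum()
    gi = np.arange(1, len(p) + 1).astype(float)
    denom = float((p * s).sum())
    # degenerate (perfectly smooth) windows: coarseness limit is infinite; 0 is emitted
    out["ngtdm_CRS"] = float(1.0 / (denom + eps)) if denom > 0 else 0.0
    if Ng > 1 and n > 0:
        pi_ = p[present]
        gi_ = gi[present]
        si_ = s[present]
        diff2 = (pi_[:, None] * pi_[None, :] * (gi_[:, None] - gi_[None, :]) ** 2)
        out["ngtdm_CON"] = float(
            diff2.sum() / (Ng * (Ng - 1)) * (s.sum() / n)
        )
        psum = np.abs(gi_[:, None] * pi_[:, None] - gi_[None, :] * pi_[None, :])
        out["ngtdm_BUS"] = float(denom / (psum.sum() + eps))
        com = (
            np.abs(gi_[:, None] - gi_[None, :])
            / (pi_[:, None] + pi_[None, :])
            * (pi_[:, None] * si_[:, None] + pi_[None, :] * si_[None, :])
        )
        out["ngtdm_COM"] = float(com.sum() / n)
        strength = (
            (pi_[:, None] + pi_[None, :]) * (gi_[:, None] - gi_[None, :]) ** 2
        )
        out["ngtdm_STR"] = float(strength.sum() / (s.sum() + eps))
    else:
        out["ngtdm_CON"] = 0.0
        out["ngtdm_BUS"] = 0.0
        out["ngtdm_COM"] = 0.0
        out["ngtdm_STR"] = 0.0
    return out


def texture_features(qwindow: np.ndarray, levels: int = 64) -> tuple[dict, bool]:
    """All 40 texture features of a quantized window, plus a degenerate flag.

    The degenerate flag marks constant windows, where variance-normalized
    features take their analytic limits (contrast 0, homogeneity 1, energy 1,
    correlation emitted as 0).
    """
    q = np.asarray(qwindow)
    if q.shape[0] < 3 or q.shape[1] < 3:
        raise ValueError("window must be at least 3 x 3")
    degenerate = bool(q.min() == q.max())
    feats = {}
    feats.update(_glcm_features(glcm_matrix(q, levels)))
    feats.update(_glrlm_features(glrlm_matrix(q, levels), q.size))
    feats.update(_glszm_features(glszm_matrix(q, levels)))
    feats.update(_ngtdm_features(*ngtdm_table(q, levels)))
    return {k: feats[k] for k in FEATURE_MANIFEST}, degenerate


def texture_maps(
    image: np.ndarray,
    masks: RegionMasks | None = None,
    spec: TextureSpec | None = None,
    denoise_first: bool = True,
) -> dict[str, np.ndarray]:
    """Sliding-window texture parametric maps of an isotropic-grid image.

    Returns ``{feature_name: full-grid array}`` with each window's features
    painted over its step cell; window centers outside tumor + peri-tumor
    (when masks are given) are skipped and left NaN.
    """
    spec = spec or TextureSpec()
    img = np.asarray(image, dtype=np.float64)
    if img.shape[0] < spec.window or img.shape[1] < spec.window:
        raise ValueError("image smaller than the texture window")
    if denoise_first:
        img = denoise(img, spec)
    w, st = spec.window, spec.step
    centers_z = np.arange(w // 2, img.shape[0] - (w - w // 2) + 1, st)
    centers_x = np.arange(w // 2, img.shape[1] - (w - w // 2) + 1, st)
    win_vals = {k: np.full((len(centers_z), len(centers_x)), np.nan) for k in FEATURE_MANIFEST}
    any_center = False
    for iz, cz in enumerate(centers_z):
        for ix, cx in enumerate(centers_x):
            if masks is not None and not masks.union[cz, cx]:
                continue
            any_center = True
            block = img[cz - w // 2 : cz - w // 2 + w, cx - w // 2 : cx - w // 2 + w]
            q = quantize_window(block, spec.levels)
            feats, _ = texture_features(q, spec.levels)
            for k, v in feats.items():
                win_vals[k][iz, ix] = v
    if masks is not None and not any_center:
        raise ValueError("no valid window centers inside the region masks")
    from .speckle import paint_windows

    out = {}
    for k, vals in win_vals.items():
        full = paint_windows(img.shape, centers_z, centers_x, vals)
        if masks is not None:
            full = np.where(masks.union, full, np.nan)
        out[k] = full
    return out
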