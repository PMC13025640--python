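"""Independent brute-force texture-feature oracle (naive per-pixel loops).

Shared by the unit tests and the acceptance suite; deliberately written with
plain Python loops and no code shared with the package implementation.
"""

import itertools
import math

import numpy as np

SQ2 = math.sqrt(2.0)
OFFSETS = [((0, 1), 1.0), ((-1, 1), 1.0 / SQ2), ((-1, -1), 1.0 / SQ2), ((1, 0), 1.0)]


# ---------------------------------------------------------------------------
# Brute-force oracle: naive per-pixel loops, no shared code with the package
# ---------------------------------------------------------------------------

def brute_glcm(q, levels):
    P = [[0.0] * levels for _ in range(levels)]
    nz, nx = q.shape
    for (dz, dx), w in OFFSETS:
        for i in range(nz):
            for j in range(nx):
                i2, j2 = i + dz, j + dx
                if 0 <= i2 < nz and 0 <= j2 < nx:
                    P[q[i, j] - 1][q[i2, j2] - 1] += w
                    P[q[i2, j2] - 1][q[i, j] - 1] += w
    total = sum(map(sum, P))
    return np.array(P) / total if total else np.array(P)


def brute_glcm_features(P):
    L = P.shape[0]
    con = dis = hom = ene = ent = 0.0
    mp = 0.0
    px = P.sum(axis=1)
    mu = sum((g + 1) * px[g] for g in range(L))
    var = sum((g + 1 - mu) ** 2 * px[g] for g in range(L))
    cor = cs = cp = 0.0
    for i in range(L):
        for j in range(L):
            p = P[i, j]
            con += (i - j) ** 2 * p
            dis += abs(i - j) * p
            hom += p / (1 + (i - j) ** 2)
            ene += p * p
            if p > 0:
                ent -= p * math.log(p)
            mp = max(mp, p)
            if var > 0:
                cor += (i + 1 - mu) * (j + 1 - mu) * p / var
            cs += (i + j + 2 - 2 * mu) ** 3 * p
            cp += (i + j + 2 - 2 * mu) ** 4 * p
    p_sum = {}
    p_diff = {}
    for i in range(L):
        for j in range(L):
            p_sum[i + j + 2] = p_sum.get(i + j + 2, 0) + P[i, j]
            p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0) + P[i, j]
    sa = sum(k * v for k, v in p_sum.items())
    se = -sum(v * math.log(v) for v in p_sum.values() if v > 0)
    de = -sum(v * math.log(v) for v in p_diff.values() if v > 0)
    return {
        "glcm_CON": con, "glcm_COR": cor, "glcm_DIS": dis, "glcm_ENT": ent,
        "glcm_ENE": ene, "glcm_HOM": hom, "glcm_VAR": var, "glcm_SA": sa,
        "glcm_SE": se, "glcm_DE": de, "glcm_CS": cs, "glcm_CP": cp,
        "glcm_MP": mp,
    }


def brute_runs(q, dz, dx):
    """All maximal runs along direction (dz, dx) by walking each line."""
    nz, nx = q.shape
    runs = []
    starts = []
    for i in range(nz):
        for j in range(nx):
            ip, jp = i - dz, j - dx
            if not (0 <= ip < nz and 0 <= jp < nx):
                starts.append((i, j))
    for i0, j0 in starts:
        line = []
        i, j = i0, j0
        while 0 <= i < nz and 0 <= j < nx:
            line.append(q[i, j])
            i, j = i + dz, j + dx
        k = 0
        while k < len(line):
            k2 = k
            while k2 + 1 < len(line) and line[k2 + 1] == line[k]:
                k2 += 1
            runs.append((line[k], k2 - k + 1))
            k = k2 + 1
    return runs


def brute_glrlm_features(q, levels):
    n = q.size
    max_run = max(q.shape)
    R = np.zeros((levels, max_run))
    for (dz, dx), w in OFFSETS:
        for g, r in brute_runs(q, dz, dx):
            R[g - 1, r - 1] += w
    Nr = R.sum()
    g = np.arange(1, levels + 1)[:, None].astype(float)
    l = np.arange(1, max_run + 1)[None, :].astype(float)
    rg = R.sum(axis=1)
    rl = R.sum(axis=0)
    mu_g = (rg * g.ravel()).sum() / Nr
    mu_l = (rl * l.ravel()).sum() / Nr
    wtot = sum(w for _, w in OFFSETS)
    return {
        "glrlm_SRE": (R / l**2).sum() / Nr,
        "glrlm_LRE": (R * l**2).sum() / Nr,
        "glrlm_GLN": (rg**2).sum() / Nr,
        "glrlm_RLN": (rl**2).sum() / Nr,
        "glrlm_RP": Nr / (n * wtot),
        "glrlm_LGRE": (R / g**2).sum() / Nr,
        "glrlm_HGRE": (R * g**2).sum() / Nr,
        "glrlm_SRLGE": (R / (g**2 * l**2)).sum() / Nr,
        "glrlm_SRHGE": (R * g**2 / l**2).sum() / Nr,
        "glrlm_LRLGE": (R * l**2 / g**2).sum() / Nr,
        "glrlm_LRHGE": (R * g**2 * l**2).sum() / Nr,
        "glrlm_GLV": (rg * (g.ravel() - mu_g) ** 2).sum() / Nr,
        "glrlm_RLV": (rl * (l.ravel() - mu_l) ** 2).sum() / Nr,
    }


def brute_zones(q):
    """8-connected equal-level zones by flood fill."""
    nz, nx = q.shape
    seen = np.zeros(q.shape, bool)
    zones = []
    for i in range(nz):
        for j in range(nx):
            if seen[i, j]:
                continue
            g = q[i, j]
            stack = [(i, j)]
            seen[i, j] = True
            size = 0
            while stack:
                a, b = stack.pop()
                size += 1
                for da, db in itertools.product((-1, 0, 1), repeat=2):
                    if da == db == 0:
                        continue
                    a2, b2 = a + da, b + db
                    if (0 <= a2 < nz and 0 <= b2 < nx and not seen[a2, b2]
                            and q[a2, b2] == g):
                        seen[a2, b2] = True
                        stack.append((a2, b2))
            zones.append((g, size))
    return zones


def brute_glszm_features(q, levels):
    zones = brute_zones(q)
    Nz = len(zones)
    ss = [s for _, s in zones]
    mu_s = sum(ss) / Nz
    out = {
        "glszm_SAE": sum(1.0 / s**2 for _, s in zones) / Nz,
        "glszm_LAE": sum(s**2 for _, s in zones) / Nz,
        "glszm_LGZE": sum(1.0 / g**2 for g, _ in zones) / Nz,
        "glszm_HGZE": sum(g**2 for g, _ in zones) / Nz,
        "glszm_SZLGE": sum(1.0 / (g**2 * s**2) for g, s in zones) / Nz,
        "glszm_SZHGE": sum(g**2 / s**2 for g, s in zones) / Nz,
        "glszm_LZLGE": sum(s**2 / g**2 for g, s in zones) / Nz,
        "glszm_LZHGE": sum(g**2 * s**2 for g, s in zones) / Nz,
        "glszm_ZSV": sum((s - mu_s) ** 2 for s in ss) / Nz,
    }
    return out


def brute_ngtdm_features(q, levels):
    nz, nx = q.shape
    s = [0.0] * levels
    counts = [0] * levels
    for i in range(1, nz - 1):
        for j in range(1, nx - 1):
            nb = [q[i + di, j + dj] for di in (-1, 0, 1) for dj in (-1, 0, 1)
                  if not (di == 0 and dj == 0)]
            g = q[i, j]
            s[g - 1] += abs(g - sum(nb) / 8.0)
            counts[g - 1] += 1
    n = sum(counts)
    p = [c / n for c in counts]
    eps = 1e-12
    denom = sum(pi * si for pi, si in zip(p, s))
    present = [g for g in range(levels) if p[g] > 0]
    Ng = len(present)
    crs = 1.0 / (denom + eps) if denom > 0 else 0.0
    if Ng > 1:
        con = sum(
            p[a] * p[b] * (a - b) ** 2 for a in present for b in present
        ) / (Ng * (Ng - 1)) * (sum(s) / n)
        bus = denom / (
            sum(abs((a + 1) * p[a] - (b + 1) * p[b]) for a in present for b in present)
            + eps
        )
        com = sum(
            abs(a - b) / (p[a] + p[b]) * (p[a] * s[a] + p[b] * s[b])
            for a in present for b in present
        ) / n
        stren = sum(
            (p[a] + p[b]) * (a - b) ** 2 for a in present for b in present
        ) / (sum(s) + eps)
    else:
        con = bus = com = stren = 0.0
    return {"ngtdm_CRS": crs, "ngtdm_CON": con, "ngtdm_BUS": bus,
            "ngtdm_COM": com, "ngtdm_STR": stren}


def brute_all_features(q, levels):
    out = {}
    out.update(brute_glcm_features(brute_glcm(q, levels)))
    out.update(brute_glrlm_features(q, levels))
    out.update(brute_glszm_features(q, levels))
    out.update(brute_ngtdm_features(q, levels))
    return out


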