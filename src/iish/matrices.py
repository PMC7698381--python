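"""Gray-level texture matrix accumulators over a masked, discretized volume.

All accumulators operate on an integer level volume (values 1..n_levels) and
a boolean mask; only voxels inside the mask contribute, and neighborhoods are
the 26-connected 3D neighborhood (13 unique direction offsets, pooled into a
single matrix before statistics are taken).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

# 13 unique offsets of the 26-neighborhood (the other 13 are their negatives)
OFFSETS_3D = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


def _shift_pairs(levels: np.ndarray, mask: np.ndarray, off: tuple[int, int, int]):
    """Index slices selecting voxel pairs (p, p+off) with both ends in bounds."""
    src = tuple(slice(max(-o, 0), levels.shape[a] - max(o, 0)) for a, o in enumerate(off))
    dst = tuple(slice(max(o, 0), levels.shape[a] + min(o, 0)) for a, o in enumerate(off))
    valid = mask[src] & mask[dst]
    return levels[src][valid], levels[dst][valid]


def glcm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence counts pooled over the 26-neighborhood."""
    G = np.zeros((n_levels, n_levels), dtype=np.int64)
    for off in OFFSETS_3D:
        a, b = _shift_pairs(levels, mask, off)
        if len(a):
            np.add.at(G, (a - 1, b - 1), 1)
            np.add.at(G, (b - 1, a - 1), 1)
    return G


def glrlm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Run-length counts pooled over the 13 directions; column j = run length j+1."""
    shape = levels.shape
    max_len = int(np.ceil(np.sqrt(sum(s**2 for s in shape)))) + 1
    R = np.zeros((n_levels, max_len), dtype=np.int64)
    coords = np.column_stack(np.nonzero(mask))
    for off in OFFSETS_3D:
        off_arr = np.array(off)
        prev = coords - off_arr
        inb = np.all((prev >= 0) & (prev < shape), axis=1)
        prev_ok = np.zeros(len(coords), dtype=bool)
        pi = prev[inb]
        prev_ok[inb] = mask[pi[:, 0], pi[:, 1], pi[:, 2]] & (
            levels[pi[:, 0], pi[:, 1], pi[:, 2]]
            == levels[coords[inb, 0], coords[inb, 1], coords[inb, 2]]
        )
        starts = coords[~prev_ok]
        if len(starts) == 0:
            continue
        run_level = levels[starts[:, 0], starts[:, 1], starts[:, 2]]
        length = np.ones(len(starts), dtype=np.int64)
        pos = starts.copy()
        alive = np.ones(len(starts), dtype=bool)
        while alive.any():
            pos[alive] += off_arr
            p = pos[alive]
            ok = np.all((p >= 0) & (p < shape), axis=1)
            cont = np.zeros(len(p), dtype=bool)
            q = p[ok]
            cont[ok] = mask[q[:, 0], q[:, 1], q[:, 2]] & (
                levels[q[:, 0], q[:, 1], q[:, 2]] == run_level[alive][ok]
            )
            idx = np.nonzero(alive)[0]
            length[idx[cont]] += 1
            alive[idx[~cont]] = False
        np.add.at(R, (run_level - 1, length - 1), 1)
    return R[:, : R.sum(axis=0).nonzero()[0].max() + 1] if R.any() else R[:, :1]


def glszm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone counts: 26-connected components per gray level; column j = size j+1."""
    structure = np.ones((3, 3, 3), dtype=bool)
    sizes_per_level: list[tuple[int, np.ndarray]] = []
    max_size = 1
    for g in range(1, n_levels + 1):
        lab, nz = ndimage.label(mask & (levels == g), structure=structure)
        if nz == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        sizes_per_level.append((g, sizes))
        max_size = max(max_size, int(sizes.max()))
    Z = np.zeros((n_levels, max_size), dtype=np.int64)
    for g, sizes in sizes_per_level:
        np.add.at(Z, (g - 1, sizes - 1), 1)
    return Z


def ngtdm_table(levels: np.ndarray, mask: np.ndarray, n_levels: int):
    """Per-level occupancy n_i and absolute-difference sums s_i (IBSI NGTDM)."""
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    m = mask.astype(float)
    nsum = ndimage.correlate(levels * m, kernel, mode="constant")
    ncnt = ndimage.correlate(m, kernel, mode="constant")
    valid = mask & (ncnt > 0)
    g = levels[valid]
    diff = np.abs(g - nsum[valid] / ncnt[valid])
    n_i = np.bincount(g - 1, minlength=n_levels).astype(float)
    s_i = np.bincount(g - 1, weights=diff, minlength=n_levels)
    return n_i, s_i


def ngldm_matrix(
    levels: np.ndarray, mask: np.ndarray, n_levels: int, alpha: int = 0
) -> np.ndarray:
    """Dependence counts: column j = (1 + #neighbors with |level diff| <= alpha) = j+1."""
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in OFFSETS_3D:
        src = tuple(slice(max(-o, 0), levels.shape[a] - max(o, 0)) for a, o in enumerate(off))
        dst = tuple(slice(max(o, 0), levels.shape[a] + min(o, 0)) for a, o in enumerate(off))
        both = mask[src] & mask[dst]
        close = both & (np.abs(levels[src] - levels[dst]) <= alpha)
        inc_src = np.zeros(levels.shape, dtype=np.int64)
        inc_dst = np.zeros(levels.shape, dtype=np.int64)
        inc_src[src] = close
        inc_dst[dst] = close
        dep += inc_src + inc_dst
    counts = dep[mask] + 1  # dependence includes the center voxel
    g = levels[mask]
    D = np.zeros((n_levels, int(counts.max())), dtype=np.int64)
    np.add.at(D, (g - 1, counts - 1), 1)
    return D


# ---------------------------------------------------------------------------
# feature statistics per family
# ---------------------------------------------------------------------------

def _marginals(P: np.ndarray):
    p = P / P.sum()
    i = np.arange(1, P.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, P.shape[1] + 1, dtype=float)[None, :]
    return p, i, j


def glcm_features(G: np.ndarray) -> dict[str, float]:
    p, i, j = _marginals(G)
    nz = p > 0
    energy = float((p**2).sum())
    entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    contrast = float((p * (i - j) ** 2).sum())
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mi = float((np.arange(1, len(pi) + 1) * pi).sum())
    mj = float((np.arange(1, len(pj) + 1) * pj).sum())
    si = float(np.sqrt(((np.arange(1, len(pi) + 1) - mi) ** 2 * pi).sum()))
    sj = float(np.sqrt(((np.arange(1, len(pj) + 1) - mj) ** 2 * pj).sum()))
    if si * sj > 0:
        correlation = float((p * (i - mi) * (j - mj)).sum() / (si * sj))
    else:
        correlation = 1.0
    return {
        "energy": energy,
        "entropy": entropy,
        "homogeneity": homogeneity,
        "contrast": contrast,
        "correlation": correlation,
    }


def _run_zone_features(P: np.ndarray, n_voxels: int, prefix_small: str) -> dict[str, float]:
    """Shared 13-feature set for GLRLM (runs) and GLSZM (zones)."""
    N = float(P.sum())
    p, i, j = _marginals(P)
    row = P.sum(axis=1).astype(float)  # per gray level
    col = P.sum(axis=0).astype(float)  # per run length / zone size
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    small = float((p / j**2).sum())
    large = float((p * j**2).sum())
    return {
        f"S{prefix_small}E": small,
        f"L{prefix_small}E": large,
        "GLN": float((row**2).sum() / N),
        "N2": float((col**2).sum() / N),
        "PCT": N / float(n_voxels),
        "LGLE": float((p / i**2).sum()),
        "HGLE": float((p * i**2).sum()),
        "SLGLE": float((p / (i**2 * j**2)).sum()),
        "SHGLE": float((p * i**2 / j**2).sum()),
        "LLGLE": float((p * j**2 / i**2).sum()),
        "LHGLE": float((p * i**2 * j**2).sum()),
        "GLV": float((p * (i - mu_i) ** 2).sum()),
        "V2": float((p * (j - mu_j) ** 2).sum()),
    }


def glrlm_features(R: np.ndarray, n_voxels: int) -> dict[str, float]:
    f = _run_zone_features(R, n_voxels, "R")
    return {
        "SRE": f["SRE"], "LRE": f["LRE"], "GLN": f["GLN"], "RLN": f["N2"],
        "RP": f["PCT"], "LGLRE": f["LGLE"], "HGLRE": f["HGLE"],
        "SRLGLE": f["SLGLE"], "SRHGLE": f["SHGLE"], "LRLGLE": f["LLGLE"],
        "LRHGLE": f["LHGLE"], "GLV": f["GLV"], "RLV": f["V2"],
    }


def glszm_features(Z: np.ndarray, n_voxels: int) -> dict[str, float]:
    f = _run_zone_features(Z, n_voxels, "A")
    return {
        "SAE": f["SAE"], "LAE": f["LAE"], "GLN": f["GLN"], "SZN": f["N2"],
        "ZP": f["PCT"], "LGLZE": f["LGLE"], "HGLZE": f["HGLE"],
        "SALGLE": f["SLGLE"], "SAHGLE": f["SHGLE"], "LALGLE": f["LLGLE"],
        "LAHGLE": f["LHGLE"], "GLV": f["GLV"], "ZV": f["V2"],
    }


def ngtdm_features(n_i: np.ndarray, s_i: np.ndarray) -> dict[str, float]:
    n = n_i.sum()
    p = n_i / n
    levels = np.arange(1, len(n_i) + 1, dtype=float)
    present = p > 0
    n_gp = int(present.sum())
    ps = float((p * s_i).sum())
    coarseness = 1.0 / ps if ps > 0 else 1e6
    pi_, pj_ = p[present][:, None], p[present][None, :]
    ii, jj = levels[present][:, None], levels[present][None, :]
    si_, sj_ = s_i[present][:, None], s_i[present][None, :]
    if n_gp > 1:
        contrast = float((pi_ * pj_ * (ii - jj) ** 2).sum() / (n_gp * (n_gp - 1))) * float(
            s_i.sum() / n
        )
    else:
        contrast = 0.0
    denom = float(np.abs(ii * pi_ - jj * pj_).sum())
    busyness = ps / denom if denom > 0 else 0.0
    complexity = float((np.abs(ii - jj) * (pi_ * si_ + pj_ * sj_) / (pi_ + pj_)).sum() / n)
    s_sum = float(s_i.sum())
    strength = float(((pi_ + pj_) * (ii - jj) ** 2).sum() / s_sum) if s_sum > 0 else 0.0
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


def ngldm_features(D: np.ndarray) -> dict[str, float]:
    N = float(D.sum())
    p, i, j = _marginals(D)
    row = D.sum(axis=1).astype(float)
    col = D.sum(axis=0).astype(float)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    nz = p > 0
    return {
        "SDE": float((p / j**2).sum()),
        "LDE": float((p * j**2).sum()),
        "GLN": float((row**2).sum() / N),
        "DCN": float((col**2).sum() / N),
        "DCNN": float((col**2).sum() / N**2),
        "GLV": float((p * (i - mu_i) ** 2).sum()),
        "DCV": float((p * (j - mu_j) ** 2).sum()),
        "DCE": float(-(p[nz] * np.log2(p[nz])).sum()),
        "DCEnergy": float((p**2).sum()),
        "LGLE": float((p / i**2).sum()),
        "HGLE": float((p * i**2).sum()),
        "SDLGLE": float((p / (i**2 * j**2)).sum()),
        "SDHGLE": float((p * i**2 / j**2).sum()),
        "LDLGLE": float((p * j**2 / i**2).sum()),
        "LDHGLE": float((p * i**2 * j**2).sum()),
    }
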