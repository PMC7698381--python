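"""Per-voxel Haralick texture maps over a sliding in-plane patch.

The pipeline mirrors the clinical protocol: CT intensities are min-max
rescaled to 0-255 (by default over the union of the patient's lesion voxels,
a tumor-focused window), discretized into 32 gray levels, and for every voxel
inside a lesion a gray-level co-occurrence matrix (GLCM) is accumulated from
an 11x11x1 patch centered on it.  Four Haralick statistics are derived from
the normalized GLCM:

    energy      = sum p^2
    entropy     = -sum p log2 p          (0*log 0 := 0)
    homogeneity = sum p / (1 + |i - j|)
    contrast    = sum p (i - j)^2

Co-occurrence pairs are pooled over the four in-plane directions at distance
1 into a single symmetric GLCM per voxel, and both voxels of a pair must lie
inside the lesion mask (no contamination from surrounding tissue or air).  A
patch that yields no valid pair falls back to the degenerate single-cell
convention (energy 1, entropy 0, homogeneity 1, contrast 0).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .errors import ValidationError
from .io import CTVolume, LesionMask, LesionSet

MAP_NAMES = ("energy", "entropy", "homogeneity", "contrast")

# four in-plane offsets at distance 1, in (x, y); negatives come from symmetry
INPLANE_OFFSETS = ((1, 0), (0, 1), (1, 1), (1, -1))


@dataclass
class TexturePatchConfig:
    rescale_range: tuple[float, float] = (0.0, 255.0)
    n_levels: int = 32
    patch_size: tuple[int, int, int] = (11, 11, 1)
    glcm_distance: int = 1
    offsets: tuple[tuple[int, int], ...] = INPLANE_OFFSETS
    symmetric: bool = True
    rescale_scope: str = "lesions"  # "lesions" | "image"

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValidationError("n_levels must be >= 2")
        if any(s % 2 == 0 for s in self.patch_size):
            raise ValidationError(f"patch dimensions must be odd, got {self.patch_size}")

    def to_dict(self) -> dict:
        return {
            "rescale_range": list(self.rescale_range),
            "n_levels": self.n_levels,
            "patch_size": list(self.patch_size),
            "glcm_distance": self.glcm_distance,
            "offsets": [list(o) for o in self.offsets],
            "symmetric": self.symmetric,
            "rescale_scope": self.rescale_scope,
        }


@dataclass
class TextureMapSet:
    """Four co-registered per-voxel texture maps defined on the lesion voxels.

    Each map is a full-grid float array holding NaN outside the lesion mask.
    """

    maps: dict[str, np.ndarray]
    mask: np.ndarray
    lesion_id: str
    region: str
    config: TexturePatchConfig = field(default_factory=TexturePatchConfig)

    def descriptor_matrix(self) -> np.ndarray:
        """(n_voxels, 4) matrix of [energy, entropy, homogeneity, contrast]."""
        idx = np.nonzero(self.mask)
        return np.column_stack([self.maps[name][idx] for name in MAP_NAMES])

    def voxel_coords(self) -> np.ndarray:
        return np.column_stack(np.nonzero(self.mask))


def rescale_discretize(
    volume: CTVolume,
    lesions: LesionSet,
    config: TexturePatchConfig | None = None,
) -> np.ndarray:
    """Min-max rescale to 0-255 then bin uniformly into integer levels 1..n.

    The reference range is taken over the union of lesion voxels
    (``rescale_scope="lesions"``, the default) or the whole image.  A
    degenerate range (max == min) maps every voxel to level 1 with a warning.
    """
    config = config or TexturePatchConfig()
    union = lesions.union_mask()
    if not union.any():
        raise ValidationError("union of lesion masks is empty")
    ref = volume.voxels[union] if config.rescale_scope == "lesions" else volume.voxels
    vmin, vmax = float(ref.min()), float(ref.max())
    if vmax <= vmin:
        warnings.warn("degenerate intensity range; all voxels mapped to level 1")
        return np.ones(volume.shape, dtype=np.int32)
    lo, hi = config.rescale_range
    scaled = (volume.voxels.astype(np.float64) - vmin) / (vmax - vmin)
    scaled = np.clip(scaled, 0.0, 1.0) * (hi - lo) + lo
    frac = (scaled - lo) / (hi - lo)
    levels = np.minimum(config.n_levels, np.floor(frac * config.n_levels).astype(np.int32) + 1)
    return levels


@njit(cache=True)
def _haralick_kernel(disc, mask, coords, hx, hy, offsets, n_levels):  # pragma: no cover
    n = coords.shape[0]
    out = np.empty((n, 4))
    nx, ny, nz = disc.shape
    glcm = np.empty((n_levels, n_levels))
    for v in range(n):
        cx, cy, cz = coords[v, 0], coords[v, 1], coords[v, 2]
        glcm[:, :] = 0.0
        total = 0.0
        for dx in range(-hx, hx + 1):
            px = cx + dx
            if px < 0 or px >= nx:
                continue
            for dy in range(-hy, hy + 1):
                py = cy + dy
                if py < 0 or py >= ny:
                    continue
                if not mask[px, py, cz]:
                    continue
                a = disc[px, py, cz] - 1
                for o in range(offsets.shape[0]):
                    qdx = dx + offsets[o, 0]
                    qdy = dy + offsets[o, 1]
                    if qdx < -hx or qdx > hx or qdy < -hy or qdy > hy:
                        continue
                    qx = cx + qdx
                    qy = cy + qdy
                    if qx < 0 or qx >= nx or qy < 0 or qy >= ny:
                        continue
                    if not mask[qx, qy, cz]:
                        continue
                    b = disc[qx, qy, cz] - 1
                    glcm[a, b] += 1.0
                    glcm[b, a] += 1.0
                    total += 2.0
        if total == 0.0:
            out[v, 0] = 1.0  # energy
            out[v, 1] = 0.0  # entropy
            out[v, 2] = 1.0  # homogeneity
            out[v, 3] = 0.0  # contrast
            continue
        energy = 0.0
        entropy = 0.0
        homog = 0.0
        contrast = 0.0
        for i in range(n_levels):
            for j in range(n_levels):
                c = glcm[i, j]
                if c == 0.0:
                    continue
                p = c / total
                energy += p * p
                entropy -= p * np.log2(p)
                homog += p / (1.0 + abs(i - j))
                contrast += p * (i - j) * (i - j)
        out[v, 0] = energy
        out[v, 1] = entropy
        out[v, 2] = homog
        out[v, 3] = contrast
    return out


def haralick_maps(
    disc_volume: np.ndarray,
    lesion: LesionMask,
    config: TexturePatchConfig | None = None,
) -> TextureMapSet:
    """Compute the four per-voxel Haralick maps for one lesion."""
    config = config or TexturePatchConfig()
    disc_volume = np.ascontiguousarray(disc_volume, dtype=np.int32)
    if disc_volume.shape != lesion.mask.shape:
        raise ValidationError(
            f"discretized volume shape {disc_volume.shape} != mask shape {lesion.mask.shape}"
        )
    if not lesion.mask.any():
        raise ValidationError(f"lesion {lesion.lesion_id!r}: empty mask")
    coords = np.column_stack(np.nonzero(lesion.mask)).astype(np.int64)
    hx = config.patch_size[0] // 2
    hy = config.patch_size[1] // 2
    d = config.glcm_distance
    offsets = np.array([(ox * d, oy * d) for ox, oy in config.offsets], dtype=np.int64)
    stats = _haralick_kernel(
        disc_volume,
        np.ascontiguousarray(lesion.mask),
        coords,
        hx,
        hy,
        offsets,
        config.n_levels,
    )
    maps = {}
    for k, name in enumerate(MAP_NAMES):
        arr = np.full(disc_volume.shape, np.nan)
        arr[tuple(coords.T)] = stats[:, k]
        maps[name] = arr
    return TextureMapSet(
        maps=maps, mask=lesion.mask.copy(), lesion_id=lesion.lesion_id,
        region=lesion.region, config=config,
    )


def texture_maps_for_patient(
    volume: CTVolume,
    lesions: LesionSet,
    config: TexturePatchConfig | None = None,
) -> list[TextureMapSet]:
    """Rescale/discretize once per patient, then map every lesion."""
    config = config or TexturePatchConfig()
    disc = rescale_discretize(volume, lesions, config)
    return [haralick_maps(disc, lesion, config) for lesion in lesions]


def save_texture_maps(
    tms: TextureMapSet, volume: CTVolume, out_dir: str | Path
) -> None:
    """Export one NIfTI per statistic plus a sidecar JSON with the config."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = np.eye(4)
    aff[:3, :3] = np.diag(volume.spacing)
    aff[:3, 3] = volume.origin
    for name, arr in tms.maps.items():
        nib.save(
            nib.Nifti1Image(arr.astype(np.float32), aff),
            str(out / f"{tms.lesion_id}_{name}.nii.gz"),
        )
    sidecar = {"lesion_id": tms.lesion_id, "config": tms.config.to_dict()}
    (out / f"{tms.lesion_id}_texture_config.json").write_text(json.dumps(sidecar, indent=2))
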