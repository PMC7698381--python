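"""The 75 average-heterogeneity radiomic features per patient.

Features are computed over the pooled voxel set of all lesions ("across all
disease sites"), which makes the burden-sensitive non-uniformity features
(GLN, SZN, DCN) grow with total tumor volume, in line with their reported
behavior.  Family sizes are fixed by the manifest: first-order (4), GLCM (5),
GLRLM (13), GLSZM (13), NGTDM (5), NGLDM (15), Sobel statistics (4) and Gabor
statistics at orientations {0, 45, 90, 135} degrees, wavelength 2 px,
bandwidth sqrt(2) (16) — 75 in total.  Shape features are deliberately
excluded: they describe single tumors, not cross-site heterogeneity.

Intensities are min-max rescaled to 0-255 over the lesion union before
anything else, so every feature is invariant to a constant intensity shift.
The matrix families use the same 32-level discretization as the per-voxel
texture maps; Sobel and Gabor are applied slice-wise (2D) to the rescaled
volume and summarized by {mean, std, skewness, kurtosis} of the response
magnitudes over lesion voxels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from . import matrices
from .errors import ValidationError
from .io import CTVolume, LesionSet
from .texture import TexturePatchConfig, rescale_discretize

GABOR_ANGLES = (0, 45, 90, 135)
GABOR_WAVELENGTH = 2.0
GABOR_BANDWIDTH = math.sqrt(2.0)
FILTER_STATS = ("mean", "std", "skewness", "kurtosis")

_FIRSTORDER = ("mean", "variance", "skewness", "kurtosis")
_GLCM = ("energy", "entropy", "homogeneity", "contrast", "correlation")
_GLRLM = (
    "SRE", "LRE", "GLN", "RLN", "RP", "LGLRE", "HGLRE",
    "SRLGLE", "SRHGLE", "LRLGLE", "LRHGLE", "GLV", "RLV",
)
_GLSZM = (
    "SAE", "LAE", "GLN", "SZN", "ZP", "LGLZE", "HGLZE",
    "SALGLE", "SAHGLE", "LALGLE", "LAHGLE", "GLV", "ZV",
)
_NGTDM = ("coarseness", "contrast", "busyness", "complexity", "strength")
_NGLDM = (
    "SDE", "LDE", "GLN", "DCN", "DCNN", "GLV", "DCV", "DCE", "DCEnergy",
    "LGLE", "HGLE", "SDLGLE", "SDHGLE", "LDLGLE", "LDHGLE",
)

MANIFEST_VERSION = "1.0"


@dataclass
class DiscretizationConfig:
    n_levels: int = 32
    rescale_scope: str = "lesions"
    aggregation: str = "pooled_voxels"  # or "volume_weighted"

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValidationError("n_levels must be >= 2")


@dataclass
class FeatureVector:
    values: dict[str, float]
    patient_id: str = ""
    config: DiscretizationConfig = field(default_factory=DiscretizationConfig)

    def __post_init__(self) -> None:
        manifest = [name for name, _ in feature_manifest()]
        if list(self.values.keys()) != manifest:
            raise ValidationError("feature vector does not match the 75-feature manifest")
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValidationError(f"non-finite features: {bad}")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return self.values[resolve_feature_alias(name)]

    def to_series(self):
        import pandas as pd

        return pd.Series(self.values, name=self.patient_id)


def feature_manifest() -> list[tuple[str, str]]:
    """Deterministic ordered list of (feature name, family tag); 75 entries."""
    out: list[tuple[str, str]] = []
    out += [(f"firstorder.{n}", "firstorder") for n in _FIRSTORDER]
    out += [(f"glcm.{n}", "glcm") for n in _GLCM]
    out += [(f"glrlm.{n}", "glrlm") for n in _GLRLM]
    out += [(f"glszm.{n}", "glszm") for n in _GLSZM]
    out += [(f"ngtdm.{n}", "ngtdm") for n in _NGTDM]
    out += [(f"ngldm.{n}", "ngldm") for n in _NGLDM]
    out += [(f"sobel.{s}", "sobel") for s in FILTER_STATS]
    for ang in GABOR_ANGLES:
        out += [(f"gabor({ang},2).{s}", "gabor") for s in FILTER_STATS]
    return out


_ALIASES = {
    "GLN": "glszm.GLN",
    "SZN": "glszm.SZN",
    "DCN": "ngldm.DCN",
    "coarseness": "ngtdm.coarseness",
}


def resolve_feature_alias(name: str) -> str:
    """Map flagship shorthand and cosmetic spellings onto manifest names."""
    if name in _ALIASES:
        return _ALIASES[name]
    norm = name.replace("\N{DEGREE SIGN}", "").replace(" ", "")
    low = norm.lower()
    if low.startswith("sobel") or low.startswith("gabor"):
        if low.startswith("gabor(") and "." not in low:
            low += ".mean"  # bare filter term defaults to its mean statistic
        return low
    return name


def _stat_block(x: np.ndarray) -> dict[str, float]:
    x = np.asarray(x, dtype=float)
    sd = float(x.std())
    if sd == 0:
        return {"mean": float(x.mean()), "std": 0.0, "skewness": 0.0, "kurtosis": 0.0}
    return {
        "mean": float(x.mean()),
        "std": sd,
        "skewness": float(stats.skew(x)),
        "kurtosis": float(stats.kurtosis(x, fisher=False)),
    }


def _rescaled_volume(ct: CTVolume, lesions: LesionSet, scope: str) -> np.ndarray:
    union = lesions.union_mask()
    ref = ct.voxels[union] if scope == "lesions" else ct.voxels
    vmin, vmax = float(ref.min()), float(ref.max())
    if vmax <= vmin:
        return np.zeros(ct.shape)
    return np.clip((ct.voxels - vmin) / (vmax - vmin), 0.0, 1.0) * 255.0


def _filter_responses(rescaled: np.ndarray, mask: np.ndarray) -> dict[str, np.ndarray]:
    """Slice-wise Sobel and Gabor magnitude responses sampled at mask voxels."""
    from skimage.filters import gabor

    xs, ys, zs = np.nonzero(mask)
    zvals = np.unique(zs)
    out: dict[str, list[np.ndarray]] = {"sobel": []}
    for ang in GABOR_ANGLES:
        out[f"gabor({ang},2)"] = []
    for z in zvals:
        sl = rescaled[:, :, z]
        m = mask[:, :, z]
        gx = ndimage.sobel(sl, axis=0)
        gy = ndimage.sobel(sl, axis=1)
        out["sobel"].append(np.hypot(gx, gy)[m])
        for ang in GABOR_ANGLES:
            real, imag = gabor(
                sl,
                frequency=1.0 / GABOR_WAVELENGTH,
                theta=math.radians(ang),
                bandwidth=GABOR_BANDWIDTH,
            )
            out[f"gabor({ang},2)"].append(np.hypot(real, imag)[m])
    return {k: np.concatenate(v) for k, v in out.items()}


def _bbox(mask: np.ndarray, margin: int = 2) -> tuple[slice, slice, slice]:
    idx = np.nonzero(mask)
    return tuple(
        slice(max(int(i.min()) - margin, 0), min(int(i.max()) + margin + 1, mask.shape[a]))
        for a, i in enumerate(idx)
    )


def _features_for_mask(
    levels: np.ndarray, rescaled: np.ndarray, mask: np.ndarray, n_levels: int
) -> dict[str, float]:
    box = _bbox(mask)
    levels, rescaled, mask = levels[box], rescaled[box], mask[box]
    n_vox = int(mask.sum())
    vals: dict[str, float] = {}
    fo = _stat_block(rescaled[mask])
    fo["variance"] = fo.pop("std") ** 2
    for n in _FIRSTORDER:
        vals[f"firstorder.{n}"] = fo[n]
    G = matrices.glcm_matrix(levels, mask, n_levels)
    if G.sum() == 0:  # isolated voxels only: degenerate single-cell convention
        gf = {"energy": 1.0, "entropy": 0.0, "homogeneity": 1.0, "contrast": 0.0,
              "correlation": 1.0}
    else:
        gf = matrices.glcm_features(G)
    for n in _GLCM:
        vals[f"glcm.{n}"] = gf[n]
    rf = matrices.glrlm_features(matrices.glrlm_matrix(levels, mask, n_levels), n_vox)
    for n in _GLRLM:
        vals[f"glrlm.{n}"] = rf[n]
    zf = matrices.glszm_features(matrices.glszm_matrix(levels, mask, n_levels), n_vox)
    for n in _GLSZM:
        vals[f"glszm.{n}"] = zf[n]
    n_i, s_i = matrices.ngtdm_table(levels, mask, n_levels)
    tf = matrices.ngtdm_features(n_i, s_i)
    for n in _NGTDM:
        vals[f"ngtdm.{n}"] = tf[n]
    df = matrices.ngldm_features(matrices.ngldm_matrix(levels, mask, n_levels))
    for n in _NGLDM:
        vals[f"ngldm.{n}"] = df[n]
    resp = _filter_responses(rescaled, mask)
    for fam, r in resp.items():
        sb = _stat_block(r)
        for s in FILTER_STATS:
            vals[f"{fam}.{s}"] = sb[s]
    return vals


def extract_features(
    ct: CTVolume,
    lesions: LesionSet,
    config: DiscretizationConfig | None = None,
) -> FeatureVector:
    """Compute the 75-feature vector for one patient."""
    config = config or DiscretizationConfig()
    union = lesions.union_mask()
    if not union.any():
        raise ValidationError("union of lesion masks is empty")
    tex_cfg = TexturePatchConfig(n_levels=config.n_levels, rescale_scope=config.rescale_scope)
    levels = rescale_discretize(ct, lesions, tex_cfg)
    rescaled = _rescaled_volume(ct, lesions, config.rescale_scope)

    if config.aggregation == "pooled_voxels":
        vals = _features_for_mask(levels, rescaled, union, config.n_levels)
    elif config.aggregation == "volume_weighted":
        per = [
            (m.n_voxels, _features_for_mask(levels, rescaled, m.mask, config.n_levels))
            for m in lesions
        ]
        w = np.array([n for n, _ in per], dtype=float)
        w /= w.sum()
        vals = {
            k: float(sum(wi * d[k] for wi, (_, d) in zip(w, per)))
            for k in per[0][1]
        }
    else:
        raise ValidationError(f"unknown aggregation {config.aggregation!r}")

    ordered = {name: vals[name] for name, _ in feature_manifest()}
    return FeatureVector(values=ordered, patient_id=lesions.patient_id, config=config)
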