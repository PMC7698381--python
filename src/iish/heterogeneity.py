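"""Subregion extraction and the cluster-dissimilarity (cluDiss) statistic.

Each lesion is partitioned into texturally homogeneous subregions by kernel
K-means on a 7-channel voxel descriptor (the four Haralick map values plus
spatially weighted coordinates), with the cluster count k in 1..5 selected by
an Akaike information criterion.  Subregions from all lesions are pooled per
patient; their pairwise Euclidean descriptor distances are summarized into a
group dissimilarity matrix (GDM) — a 2D histogram over dissimilarity level x
group size — whose fourth central moment is cluDiss:

    cluDiss = 1/(K*M) * sum_i sum_j (i + j - muD - muA)^4 * G(i, j)

with bin indices i (dissimilarity level, min-max discretized per patient into
K = 10 levels) and j (group size, the absolute count of partner subregions at
that level, clamped at M = 10), and muD/muA the count-weighted mean levels.
G enters as raw counts, so the statistic grows with the number of lesions and
subregions as well as with their textural distinctness.  Dissimilarities are
min-max normalized per patient before binning (texture-descriptor scale is
arbitrary) but group sizes are binned on their absolute count: normalizing
sizes per patient would erase precisely the dependence on the number of
disease sites that the statistic exists to capture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError
from .io import CTVolume, LesionSet
from .texture import MAP_NAMES, TextureMapSet, TexturePatchConfig, texture_maps_for_patient


@dataclass
class ClusteringConfig:
    max_clusters: int = 5
    spatial_weight: float = 0.1
    n_restarts: int = 10
    max_iter: int = 50
    sample_cap: int = 1000       # voxels entering the exact kernel matrix
    bandwidth_sample: int = 2000  # voxels used for the median-distance bandwidth
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_clusters < 1:
            raise ValidationError("max_clusters must be >= 1")
        if self.spatial_weight < 0:
            raise ValidationError("spatial_weight must be >= 0")


@dataclass
class SubRegion:
    voxel_indices: np.ndarray      # (n, 3) voxel coordinates
    lesion_id: str
    region: str
    descriptor: np.ndarray         # mean [energy, entropy, homogeneity, contrast]

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_indices.shape[0])


@dataclass
class DissimilarityMatrix:
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)

    @property
    def n(self) -> int:
        return self.d.shape[0]


@dataclass
class GroupDissimilarityMatrix:
    G: np.ndarray                  # (K, M) raw integer counts
    K: int = 10
    M: int = 10
    mu_D: float = 0.0
    mu_A: float = 0.0
    d_range: tuple[float, float] = (0.0, 0.0)
    size_range: tuple[float, float] = (0.0, 0.0)

    @property
    def total(self) -> int:
        return int(self.G.sum())


@dataclass
class CluDissResult:
    value: float
    region_scope: str = "all"
    n_subregions: int = 0
    n_lesions: int = 0
    evaluable: bool = True
    gdm: GroupDissimilarityMatrix | None = None


@dataclass
class ConventionalMeasures:
    ttv_cc: float
    n_sites: int


# ---------------------------------------------------------------------------
# kernel K-means with AIC model selection
# ---------------------------------------------------------------------------

def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _voxel_descriptors(tms: TextureMapSet, spatial_weight: float) -> np.ndarray:
    """7-channel z-scored descriptor: 4 texture maps + weighted coordinates."""
    tex = tms.descriptor_matrix()
    xyz = tms.voxel_coords().astype(float)
    X = _zscore(np.column_stack([tex, xyz]))
    X[:, 4:] *= spatial_weight
    return X


def _rbf_bandwidth(X: np.ndarray, rng: np.random.Generator, cap: int) -> float:
    idx = rng.choice(X.shape[0], size=min(cap, X.shape[0]), replace=False)
    if len(idx) < 2:
        return 1.0
    med = float(np.median(pdist(X[idx])))
    return med if med > 0 else 1.0


def _kernel_kmeans_labels(
    K: np.ndarray, k: int, rng: np.random.Generator, n_restarts: int, max_iter: int
) -> np.ndarray:
    """Hard kernel K-means on a precomputed kernel matrix; best of restarts."""
    n = K.shape[0]
    diag = np.diag(K)
    best_obj, best_labels = np.inf, None
    for _ in range(n_restarts):
        # k-means++-style seeding in kernel-induced distance
        centers = [int(rng.integers(n))]
        d2 = diag - 2 * K[:, centers[0]] + diag[centers[0]]
        for _ in range(1, k):
            d2c = np.maximum(d2, 0)
            probs = d2c / d2c.sum() if d2c.sum() > 0 else np.full(n, 1.0 / n)
            c = int(rng.choice(n, p=probs))
            centers.append(c)
            d2 = np.minimum(d2, diag - 2 * K[:, c] + diag[c])
        dist = np.stack([diag - 2 * K[:, c] + diag[c] for c in centers], axis=1)
        labels = np.argmin(dist, axis=1)
        for _ in range(max_iter):
            Z = np.zeros((n, k))
            Z[np.arange(n), labels] = 1.0
            m = Z.sum(axis=0)
            empty = m == 0
            if empty.any():
                # reseed empty clusters at random points
                for c in np.flatnonzero(empty):
                    labels[int(rng.integers(n))] = c
                continue
            S = K @ Z                                   # S[x, c] = sum_{y in c} K(x, y)
            quad = (Z * S).sum(axis=0) / m**2           # mean within-cluster kernel
            dist = diag[:, None] - 2 * S / m + quad[None, :]
            new_labels = np.argmin(dist, axis=1)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
        obj = float(dist[np.arange(n), labels].sum())
        if obj < best_obj:
            best_obj, best_labels = obj, labels.copy()
    return best_labels


def _assign_to_clusters(
    X_all: np.ndarray, X_sub: np.ndarray, labels_sub: np.ndarray, gamma: float, k: int
) -> np.ndarray:
    """Kernel distance of every voxel to each subsample cluster."""
    from sklearn.metrics.pairwise import rbf_kernel

    dist = np.empty((X_all.shape[0], k))
    for c in range(k):
        members = X_sub[labels_sub == c]
        Kxc = rbf_kernel(X_all, members, gamma=gamma)
        Kcc = rbf_kernel(members, members, gamma=gamma)
        dist[:, c] = 1.0 - 2 * Kxc.mean(axis=1) + Kcc.mean()
    return np.argmin(dist, axis=1)


def _aic(X: np.ndarray, labels: np.ndarray, k: int) -> float:
    """AIC of the diagonal-covariance Gaussian mixture implied by a partition.

    Weights, means and per-cluster per-channel variances are the M-step
    estimates from the hard labels, but the likelihood is the soft mixture
    likelihood, so splitting overlapping mass yields almost no gain and k is
    not inflated on homogeneous data (a hard-assignment "classification
    likelihood" would inflate it, and spherical components would reward
    splitting merely because the z-scored descriptor is anisotropic).
    """
    from scipy.special import logsumexp

    n, d = X.shape
    floor = np.maximum(1e-8, 1e-3 * X.var(axis=0))
    log_terms = []
    n_comp = 0
    for c in range(k):
        members = X[labels == c]
        if len(members) == 0:
            continue
        n_comp += 1
        mu = members.mean(axis=0)
        var = np.maximum(((members - mu) ** 2).mean(axis=0), floor)
        sq = ((X - mu) ** 2 / var).sum(axis=1)
        log_terms.append(
            np.log(len(members) / n)
            - 0.5 * np.log(2 * np.pi * var).sum()
            - 0.5 * sq
        )
    loglik = float(logsumexp(np.stack(log_terms, axis=0), axis=0).sum())
    n_params = (n_comp - 1) + 2 * n_comp * d  # weights + means + diagonal variances
    return -2.0 * loglik + 2.0 * n_params


def segment_lesion(
    tms: TextureMapSet, config: ClusteringConfig | None = None
) -> tuple[list[SubRegion], int]:
    """Partition one lesion into AIC-selected kernel K-means subregions."""
    from sklearn.metrics.pairwise import rbf_kernel

    config = config or ClusteringConfig()
    if not tms.mask.any():
        raise ValidationError(f"lesion {tms.lesion_id!r}: no texture voxels")
    X = _voxel_descriptors(tms, config.spatial_weight)
    coords = tms.voxel_coords()
    tex = tms.descriptor_matrix()
    n = X.shape[0]
    rng = np.random.default_rng(config.seed)

    kmax = min(config.max_clusters, n)
    if kmax == 1 or n < 3:
        labels = np.zeros(n, dtype=int)
        best_k = 1
    else:
        sigma = _rbf_bandwidth(X, rng, config.bandwidth_sample)
        gamma = 1.0 / (2.0 * sigma**2)
        sub_idx = (
            np.arange(n)
            if n <= config.sample_cap
            else np.sort(rng.choice(n, size=config.sample_cap, replace=False))
        )
        Ksub = rbf_kernel(X[sub_idx], X[sub_idx], gamma=gamma)
        best_aic, best_k, labels = np.inf, 1, np.zeros(n, dtype=int)
        for k in range(1, kmax + 1):
            if k == 1:
                lab_all = np.zeros(n, dtype=int)
            else:
                lab_sub = _kernel_kmeans_labels(
                    Ksub, k, rng, config.n_restarts, config.max_iter
                )
                if len(sub_idx) == n:
                    lab_all = lab_sub
                else:
                    lab_all = _assign_to_clusters(X, X[sub_idx], lab_sub, gamma, k)
            aic = _aic(X, lab_all, k)
            if aic < best_aic:
                best_aic, best_k, labels = aic, k, lab_all

    subregions = []
    for c in range(best_k):
        members = labels == c
        if not members.any():
            continue
        subregions.append(
            SubRegion(
                voxel_indices=coords[members],
                lesion_id=tms.lesion_id,
                region=tms.region,
                descriptor=tex[members].mean(axis=0),
            )
        )
    return subregions, best_k


def segment_subregions(
    maps_per_lesion: list[TextureMapSet], config: ClusteringConfig | None = None
) -> list[SubRegion]:
    """Cluster each lesion independently and pool subregions patient-wide."""
    if not maps_per_lesion:
        raise ValidationError("no lesions with texture maps")
    config = config or ClusteringConfig()
    out: list[SubRegion] = []
    for i, tms in enumerate(maps_per_lesion):
        # derive a per-lesion stream so lesion order, not identity, fixes it
        cfg = ClusteringConfig(**{**config.__dict__, "seed": (config.seed + i) % 2**31})
        subs, _ = segment_lesion(tms, cfg)
        out.extend(subs)
    return out


# ---------------------------------------------------------------------------
# dissimilarity matrix, GDM, cluDiss
# ---------------------------------------------------------------------------

def dissimilarity_matrix(subregions: list[SubRegion]) -> DissimilarityMatrix:
    if not subregions:
        raise ValidationError("no subregions")
    desc = np.vstack([s.descriptor for s in subregions])
    return DissimilarityMatrix(d=squareform(pdist(desc)) if len(subregions) > 1 else np.zeros((1, 1)))


def _bin_levels(values: np.ndarray, n_bins: int) -> tuple[np.ndarray, tuple[float, float]]:
    """Min-max normalize then assign 1-based equal-width levels (max clamped)."""
    vmin, vmax = float(values.min()), float(values.max())
    if vmax <= vmin:
        return np.ones(len(values), dtype=int), (vmin, vmax)
    frac = (values - vmin) / (vmax - vmin)
    return np.minimum(n_bins, np.floor(frac * n_bins).astype(int) + 1), (vmin, vmax)


def build_gdm(D: DissimilarityMatrix, K: int = 10, M: int = 10) -> GroupDissimilarityMatrix:
    """2D histogram over (dissimilarity level, group size level).

    For each subregion s and dissimilarity level l, the group size c(s, l)
    counts the other subregions whose distance to s falls in level l; every
    non-empty (s, l) entry contributes one count to G at
    (i = l, j = min(c(s, l), M)).
    """
    n = D.n
    if n < 2:
        return GroupDissimilarityMatrix(G=np.zeros((K, M), dtype=int), K=K, M=M)
    iu, ju = np.triu_indices(n, k=1)
    levels_flat, d_range = _bin_levels(D.d[iu, ju], K)
    level_mat = np.zeros((n, n), dtype=int)
    level_mat[iu, ju] = levels_flat
    level_mat[ju, iu] = levels_flat

    G = np.zeros((K, M), dtype=int)
    max_size = 0
    for s in range(n):
        partner_levels = np.delete(level_mat[s], s)
        counts = np.bincount(partner_levels, minlength=K + 1)
        for lev in range(1, K + 1):
            if counts[lev] > 0:
                G[lev - 1, min(int(counts[lev]), M) - 1] += 1
                max_size = max(max_size, int(counts[lev]))

    # count-weighted mean levels (the G-normalized means of i and j)
    i_idx = np.arange(1, K + 1, dtype=float)[:, None]
    j_idx = np.arange(1, M + 1, dtype=float)[None, :]
    P = G / G.sum()
    mu_D = float((i_idx * P).sum())
    mu_A = float((j_idx * P).sum())
    return GroupDissimilarityMatrix(
        G=G, K=K, M=M, mu_D=mu_D, mu_A=mu_A, d_range=d_range, size_range=(1.0, float(max_size))
    )


def cludiss(gdm: GroupDissimilarityMatrix, region_scope: str = "all") -> CluDissResult:
    """Fourth central moment of the GDM over its raw-count-weighted bin indices."""
    G = gdm.G
    total = G.sum()
    if total == 0:
        return CluDissResult(value=0.0, region_scope=region_scope, gdm=gdm)
    i = np.arange(1, gdm.K + 1, dtype=float)[:, None]
    j = np.arange(1, gdm.M + 1, dtype=float)[None, :]
    dev = i + j - gdm.mu_D - gdm.mu_A
    value = float((dev**4 * G).sum() / (gdm.K * gdm.M))
    return CluDissResult(value=value, region_scope=region_scope, gdm=gdm)


def cludiss_for_patient(
    volume: CTVolume,
    lesions: LesionSet,
    clustering_config: ClusteringConfig | None = None,
    texture_config: TexturePatchConfig | None = None,
    scope: str = "all",
    K: int = 10,
    M: int = 10,
) -> CluDissResult:
    """Full chain: texture maps -> subregions -> distances -> GDM -> cluDiss.

    Lesions are filtered to ``scope`` (all / pelvis / abdomen); fewer than two
    in-scope lesions yields a not-evaluable result (the protocol requires at
    least two tumor sites), not an exception.
    """
    kept = lesions.filter_region(scope)
    if len(kept) < 2:
        return CluDissResult(
            value=0.0, region_scope=scope, n_lesions=len(kept), evaluable=False
        )
    scoped = LesionSet(patient_id=lesions.patient_id, lesions=kept, scanner=lesions.scanner)
    maps = texture_maps_for_patient(volume, scoped, texture_config)
    subs = segment_subregions(maps, clustering_config)
    if len(subs) < 2:
        return CluDissResult(
            value=0.0, region_scope=scope, n_subregions=len(subs), n_lesions=len(kept)
        )
    gdm = build_gdm(dissimilarity_matrix(subs), K=K, M=M)
    result = cludiss(gdm, region_scope=scope)
    result.n_subregions = len(subs)
    result.n_lesions = len(kept)
    return result


def conventional_measures(lesions: LesionSet, spacing: tuple[float, float, float]) -> ConventionalMeasures:
    """Total tumor volume in cc and number of distinct anatomic sites."""
    if len(lesions) == 0:
        raise ValidationError("empty lesion set")
    voxel_cc = float(np.prod(spacing)) / 1000.0
    ttv = sum(m.n_voxels for m in lesions) * voxel_cc
    return ConventionalMeasures(ttv_cc=ttv, n_sites=len({m.site_label for m in lesions}))
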