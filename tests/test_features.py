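import numpy as np
import pytest
from scipy.stats import spearmanr

from iish import (
    CTVolume,
    DiscretizationConfig,
    LesionMask,
    LesionSet,
    ValidationError,
    extract_features,
    feature_manifest,
)
from iish import matrices
from iish.features import resolve_feature_alias
from iish.phantom import make_multisite_patient

NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


# ---------------------------------------------------------------------------
# independent brute-force accumulators (explicit nested loops throughout)
# ---------------------------------------------------------------------------

def bf_glcm(levels, mask, n_levels):
    G = np.zeros((n_levels, n_levels), int)
    nx, ny, nz = levels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                for dx, dy, dz in NEIGHBORS_26:
                    q = (x + dx, y + dy, z + dz)
                    if not all(0 <= q[a] < levels.shape[a] for a in range(3)):
                        continue
                    if mask[q]:
                        G[levels[x, y, z] - 1, levels[q] - 1] += 1
    return G


def bf_glrlm(levels, mask, n_levels):
    from iish.matrices import OFFSETS_3D

    runs = []
    nx, ny, nz = levels.shape

    def inb(p):
        return all(0 <= p[a] < levels.shape[a] for a in range(3))

    for off in OFFSETS_3D:
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    p = (x, y, z)
                    if not mask[p]:
                        continue
                    prev = (x - off[0], y - off[1], z - off[2])
                    if inb(prev) and mask[prev] and levels[prev] == levels[p]:
                        continue  # not a run start
                    length = 1
                    q = (x + off[0], y + off[1], z + off[2])
                    while inb(q) and mask[q] and levels[q] == levels[p]:
                        length += 1
                        q = (q[0] + off[0], q[1] + off[1], q[2] + off[2])
                    runs.append((levels[p], length))
    max_len = max(l for _, l in runs)
    R = np.zeros((n_levels, max_len), int)
    for g, l in runs:
        R[g - 1, l - 1] += 1
    return R


def bf_glszm(levels, mask, n_levels):
    seen = np.zeros(levels.shape, bool)
    zones = []
    nx, ny, nz = levels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z] or seen[x, y, z]:
                    continue
                g = levels[x, y, z]
                stack, size = [(x, y, z)], 0
                seen[x, y, z] = True
                while stack:
                    p = stack.pop()
                    size += 1
                    for dx, dy, dz in NEIGHBORS_26:
                        q = (p[0] + dx, p[1] + dy, p[2] + dz)
                        if (
                            all(0 <= q[a] < levels.shape[a] for a in range(3))
                            and mask[q]
                            and not seen[q]
                            and levels[q] == g
                        ):
                            seen[q] = True
                            stack.append(q)
                zones.append((g, size))
    max_size = max(s for _, s in zones)
    Z = np.zeros((n_levels, max_size), int)
    for g, s in zones:
        Z[g - 1, s - 1] += 1
    return Z


def bf_ngtdm(levels, mask, n_levels):
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    nx, ny, nz = levels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                neigh = [
                    levels[x + dx, y + dy, z + dz]
                    for dx, dy, dz in NEIGHBORS_26
                    if all(
                        0 <= (x + dx, y + dy, z + dz)[a] < levels.shape[a] for a in range(3)
                    )
                    and mask[x + dx, y + dy, z + dz]
                ]
                if not neigh:
                    continue
                g = levels[x, y, z]
                n_i[g - 1] += 1
                s_i[g - 1] += abs(g - np.mean(neigh))
    return n_i, s_i


def bf_ngldm(levels, mask, n_levels, alpha=0):
    entries = []
    nx, ny, nz = levels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                dep = 1
                for dx, dy, dz in NEIGHBORS_26:
                    q = (x + dx, y + dy, z + dz)
                    if (
                        all(0 <= q[a] < levels.shape[a] for a in range(3))
                        and mask[q]
                        and abs(int(levels[q]) - int(levels[x, y, z])) <= alpha
                    ):
                        dep += 1
                entries.append((levels[x, y, z], dep))
    max_dep = max(d for _, d in entries)
    D = np.zeros((n_levels, max_dep), int)
    for g, d in entries:
        D[g - 1, d - 1] += 1
    return D


class TestManifest:
    def test_manifest_counts_and_families(self):
        manifest = feature_manifest()
        assert len(manifest) == 75
        fams = [f for _, f in manifest]
        expected = {
            "firstorder": 4, "glcm": 5, "glrlm": 13, "glszm": 13,
            "ngtdm": 5, "ngldm": 15, "sobel": 4, "gabor": 16,
        }
        assert {f: fams.count(f) for f in expected} == expected
        names = [n for n, _ in manifest]
        for key in ("GLN", "DCN", "SZN", "coarseness"):
            assert any(key in n for n in names)

    def test_alias_resolution(self):
        assert resolve_feature_alias("GLN") == "glszm.GLN"
        assert resolve_feature_alias("DCN") == "ngldm.DCN"
        assert resolve_feature_alias("Sobel.mean") == "sobel.mean"
        assert resolve_feature_alias("Gabor(90\N{DEGREE SIGN},2).mean") == "gabor(90,2).mean"
        assert resolve_feature_alias("Gabor(135,2)") == "gabor(135,2).mean"


class TestMatrixOracles:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_accumulators_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        levels = rng.integers(1, 5, size=(8, 8, 2)).astype(np.int32)
        mask = rng.random((8, 8, 2)) < 0.85
        mask[4, 4, 0] = True
        np.testing.assert_array_equal(
            matrices.glcm_matrix(levels, mask, 4), bf_glcm(levels, mask, 4)
        )
        R = matrices.glrlm_matrix(levels, mask, 4)
        Rb = bf_glrlm(levels, mask, 4)
        np.testing.assert_array_equal(R[:, : Rb.shape[1]], Rb)
        assert R[:, Rb.shape[1]:].sum() == 0
        Z = matrices.glszm_matrix(levels, mask, 4)
        Zb = bf_glszm(levels, mask, 4)
        np.testing.assert_array_equal(Z[:, : Zb.shape[1]], Zb)
        n_i, s_i = matrices.ngtdm_table(levels, mask, 4)
        n_b, s_b = bf_ngtdm(levels, mask, 4)
        np.testing.assert_array_equal(n_i, n_b)
        np.testing.assert_allclose(s_i, s_b, atol=1e-10)
        D = matrices.ngldm_matrix(levels, mask, 4)
        Db = bf_ngldm(levels, mask, 4)
        np.testing.assert_array_equal(D[:, : Db.shape[1]], Db)

    def test_two_level_slab_hand_enumeration(self):
        # 4x4 image, left half level 1, right half level 2 (one slice):
        # GLSZM: one zone per level -> GLN = 1; both zones size 8 -> SZN = 2
        # NGLDM (alpha=0, 8-neighborhood): per level, dependence counts
        # {4,6,6,4} down each column -> column sums 8 at j=4 and j=6 -> DCN = 8
        levels = np.ones((4, 4, 1), dtype=np.int32)
        levels[:, 2:, :] = 2
        mask = np.ones(levels.shape, bool)
        zf = matrices.glszm_features(matrices.glszm_matrix(levels, mask, 2), 16)
        assert zf["GLN"] == pytest.approx(1.0)
        assert zf["SZN"] == pytest.approx(2.0)
        df = matrices.ngldm_features(matrices.ngldm_matrix(levels, mask, 2))
        assert df["DCN"] == pytest.approx(8.0)
        assert df["GLN"] == pytest.approx(8.0)


class TestExtraction:
    def test_vector_length_and_finiteness(self, small_phantom_patient):
        volume, lesions, _ = small_phantom_patient
        fv = extract_features(volume, lesions)
        assert len(fv) == 75
        assert all(np.isfinite(v) for v in fv.values.values())

    def test_single_zone_constant_image_gln_is_one(self):
        vox = np.full((12, 12, 4), 70.0)
        mask = np.zeros(vox.shape, bool)
        mask[3:9, 3:9, 1:3] = True
        ct = CTVolume(vox, (1, 1, 1), patient_id="c")
        les = LesionSet("c", [LesionMask(mask, "l", "s", "pelvis")])
        with pytest.warns(UserWarning):
            fv = extract_features(ct, les)
        assert fv["glszm.GLN"] == pytest.approx(1.0)

    def test_shift_invariance(self, small_phantom_patient):
        volume, lesions, _ = small_phantom_patient
        fv = extract_features(volume, lesions)
        shifted = CTVolume(
            volume.voxels + 137.0, volume.spacing, patient_id=volume.patient_id
        )
        fv2 = extract_features(shifted, lesions)
        # invariance is exact in exact arithmetic; float32 voxel storage leaves
        # ~1e-7 relative noise in the rescaled intensities
        for name in fv.values:
            assert fv.values[name] == pytest.approx(fv2.values[name], rel=1e-4, abs=1e-6), name

    def test_volume_weighted_aggregation_runs(self, small_phantom_patient):
        volume, lesions, _ = small_phantom_patient
        fv = extract_features(
            volume, lesions, DiscretizationConfig(aggregation="volume_weighted")
        )
        assert len(fv) == 75

    def test_empty_lesion_set_rejected(self):
        with pytest.raises(ValidationError):
            LesionSet("p", [])


def test_dcn_gln_strongly_correlated_on_phantoms():
    # burden-sensitive non-uniformity features should co-vary across patients
    gln, dcn = [], []
    rng = np.random.default_rng(0)
    for s in range(50):
        n = int(rng.integers(2, 9))  # the cohort's lesion-count range
        volume, lesions, _ = make_multisite_patient(
            n, n_classes=min(n, 3), seed=7000 + s, radii=(5, 5, 2), shape=(96, 96, 24)
        )
        fv = extract_features(volume, lesions)
        gln.append(fv["GLN"])
        dcn.append(fv["DCN"])
    assert spearmanr(gln, dcn).statistic > 0.9
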