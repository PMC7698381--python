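"""Synthetic multi-lesion CT patients and cohorts with known ground truth.

Lesions are ellipsoids filled with Gaussian-random-field texture: white noise
smoothed at a class-specific correlation length, then scaled to a class mean
and standard deviation.  Texture realism is deliberately minimal — the point
is controllable descriptor separation between texture classes, not anatomy.
A cohort couples the per-patient number of distinct texture classes (the
ground-truth heterogeneity knob) to platinum resistance through a logistic
link and to progression-free survival through a log-linear hazard, emulating
the structure of a multi-site ovarian-cancer cohort (multi-lesion disease,
imbalanced resistance labels with unknowns, censored PFS).

All randomness flows from a single cohort seed; patient i uses the stream
``SeedSequence([cohort_seed, i])`` so any subset regenerates reproducibly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ValidationError
from .io import CTVolume, LesionMask, LesionSet, save_patient

# palette of texture classes with distinct local-contrast/smoothness profiles
TEXTURE_PALETTE = [
    {"mean": 100.0, "sd": 3.0, "corr_len": 1.5},
    {"mean": 150.0, "sd": 25.0, "corr_len": 0.0},
    {"mean": 80.0, "sd": 12.0, "corr_len": 0.8},
    {"mean": 170.0, "sd": 6.0, "corr_len": 0.3},
    {"mean": 120.0, "sd": 18.0, "corr_len": 1.2},
    {"mean": 60.0, "sd": 9.0, "corr_len": 0.0},
    {"mean": 190.0, "sd": 15.0, "corr_len": 0.5},
    {"mean": 105.0, "sd": 22.0, "corr_len": 2.0},
]

SITE_POOL = [
    ("ovary_left", "pelvis"),
    ("ovary_right", "pelvis"),
    ("pelvic_node", "pelvis"),
    ("omentum", "abdomen"),
    ("liver_surface", "abdomen"),
    ("paracolic_gutter", "abdomen"),
    ("mesentery", "abdomen"),
    ("diaphragm", "abdomen"),
]


@dataclass
class TextureClass:
    id: int
    mean: float
    sd: float
    corr_len: float

    def __post_init__(self) -> None:
        if self.sd < 0 or self.corr_len < 0:
            raise ValidationError("texture class sd and corr_len must be >= 0")


@dataclass
class LesionSpec:
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    site_label: str
    region: str
    classes: tuple[int, ...] = (0,)  # texture class id per sub-lobe


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (96, 96, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    lesions: list[LesionSpec] = field(default_factory=list)
    texture_classes: list[TextureClass] = field(
        default_factory=lambda: [TextureClass(i, **p) for i, p in enumerate(TEXTURE_PALETTE)]
    )
    background_mean: float = 30.0
    background_sd: float = 5.0
    seed: int = 0
    patient_id: str = "phantom"


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def _texture_field(shape, cls: TextureClass, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if cls.corr_len > 0:
        noise = ndimage.gaussian_filter(noise, sigma=cls.corr_len)
        sd = noise.std()
        if sd > 0:
            noise = noise / sd
    return cls.mean + cls.sd * noise


def make_patient(spec: PhantomSpec) -> tuple[CTVolume, LesionSet, np.ndarray]:
    """Render one phantom patient; returns ground-truth class labels too.

    The truth volume holds ``class_id + 1`` inside lesions and 0 outside, so
    clustering-recovery tests can score voxel-label agreement.
    """
    if not spec.lesions:
        raise ValidationError("phantom spec declares no lesions")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed]))
    classes = {c.id: c for c in spec.texture_classes}

    volume = spec.background_mean + spec.background_sd * rng.standard_normal(spec.shape)
    truth = np.zeros(spec.shape, dtype=np.int32)
    fields: dict[int, np.ndarray] = {}
    occupied = np.zeros(spec.shape, dtype=bool)
    lesion_masks: list[LesionMask] = []

    for li, les in enumerate(spec.lesions):
        mask = _ellipsoid_mask(spec.shape, les.center, les.radii)
        if not mask.any():
            raise ValidationError(f"lesion {li} rasterizes to zero voxels")
        if (mask & occupied).any():
            raise ValidationError(f"lesion {li} overlaps a previous lesion")
        occupied |= mask
        # split the ellipsoid into equal slabs along x, one per sub-lobe
        n_lobes = len(les.classes)
        xs = np.nonzero(mask.any(axis=(1, 2)))[0]
        bounds = np.linspace(xs.min(), xs.max() + 1, n_lobes + 1)
        xcoord = np.arange(spec.shape[0])[:, None, None]
        for lobe, cid in enumerate(les.classes):
            if cid not in classes:
                raise ValidationError(f"unknown texture class id {cid}")
            if cid not in fields:
                fields[cid] = _texture_field(spec.shape, classes[cid], rng)
            lobe_mask = mask & (xcoord >= bounds[lobe]) & (xcoord < bounds[lobe + 1])
            volume[lobe_mask] = fields[cid][lobe_mask]
            truth[lobe_mask] = cid + 1
        lesion_masks.append(
            LesionMask(
                mask=mask,
                lesion_id=f"les{li:02d}",
                site_label=les.site_label,
                region=les.region,
            )
        )

    ct = CTVolume(
        voxels=volume.astype(np.float32),
        spacing=spec.spacing,
        patient_id=spec.patient_id,
    )
    return ct, LesionSet(patient_id=spec.patient_id, lesions=lesion_masks), truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults emulate the clinical cohort the method targets: 75 patients,
    multi-site disease (2-8 lesions), ~19% missing platinum labels, ~23%
    resistance prevalence at the logistic intercept, PFS with median ~15
    months and ~30% censoring.
    """

    n_patients: int = 75
    lesion_count_range: tuple[int, int] = (2, 8)
    n_classes_range: tuple[int, int] = (1, 4)
    shape: tuple[int, int, int] = (96, 96, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    radii_range: tuple[float, float] = (5.0, 9.0)
    radii_z_range: tuple[float, float] = (2.0, 4.0)
    logit_intercept: float = -1.2
    logit_slope: float = 1.0
    baseline_median_pfs: float = 15.0
    hazard_slope: float = 0.35
    censor_rate: float = 0.3
    unknown_platinum_rate: float = 14.0 / 75.0
    nonge_scanner_rate: float = 14.0 / 75.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < 1 / (1 + math.exp(-self.logit_intercept)) < 1:
            raise ValidationError("logistic intercept gives degenerate probability")
        if self.baseline_median_pfs <= 0:
            raise ValidationError("baseline hazard must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ValidationError("censor_rate must be in [0, 1)")


def _place_lesions(
    spec: CohortSpec, n_lesions: int, n_classes: int, rng: np.random.Generator
) -> list[LesionSpec]:
    """Rejection-sample non-overlapping ellipsoids; each lesion gets a class."""
    placed: list[tuple[np.ndarray, np.ndarray]] = []
    lesions: list[LesionSpec] = []
    class_ids = [i % n_classes for i in range(n_lesions)]
    sites = [SITE_POOL[i % len(SITE_POOL)] for i in range(n_lesions)]
    for li in range(n_lesions):
        for attempt in range(200):
            radii = np.array(
                [
                    rng.uniform(*spec.radii_range),
                    rng.uniform(*spec.radii_range),
                    rng.uniform(*spec.radii_z_range),
                ]
            )
            lo = radii + 1
            hi = np.array(spec.shape) - radii - 1
            if np.any(hi <= lo):
                continue
            center = rng.uniform(lo, hi)
            ok = all(
                np.linalg.norm((center - c) / (radii + r + 1.0)) > 1.0
                for c, r in placed
            )
            if ok:
                placed.append((center, radii))
                site, region = sites[li]
                lesions.append(
                    LesionSpec(
                        center=tuple(center),
                        radii=tuple(radii),
                        site_label=f"{site}_{li}",
                        region=region,
                        classes=(class_ids[li],),
                    )
                )
                break
        else:
            raise ValidationError(
                "infeasible lesion packing; reduce lesion count/radii or enlarge grid"
            )
    return lesions


def generate_cohort(spec: CohortSpec):
    """Yield (PhantomSpec, clinical row dict, truth row dict) per patient."""
    for i in range(spec.n_patients):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, i]))
        pid = f"P{i:03d}"
        n_lesions = int(rng.integers(spec.lesion_count_range[0], spec.lesion_count_range[1] + 1))
        n_classes = int(rng.integers(spec.n_classes_range[0], spec.n_classes_range[1] + 1))
        n_classes = min(n_classes, n_lesions, len(TEXTURE_PALETTE))
        lesions = _place_lesions(spec, n_lesions, n_classes, rng)
        pspec = PhantomSpec(
            shape=spec.shape,
            spacing=spec.spacing,
            lesions=lesions,
            seed=int(rng.integers(2**31)),
            patient_id=pid,
        )

        mid_classes = (spec.n_classes_range[0] + spec.n_classes_range[1]) / 2.0
        logit = spec.logit_intercept + spec.logit_slope * (n_classes - mid_classes)
        p_resist = 1.0 / (1.0 + math.exp(-logit))
        resistant = bool(rng.random() < p_resist)
        unknown = bool(rng.random() < spec.unknown_platinum_rate)

        rate = math.log(2.0) / spec.baseline_median_pfs
        hazard = rate * math.exp(spec.hazard_slope * (n_classes - mid_classes))
        t_event = float(rng.exponential(1.0 / hazard))
        censored = bool(rng.random() < spec.censor_rate)
        pfs = float(rng.uniform(0, t_event)) if censored else t_event

        age = float(np.clip(rng.normal(59.0, 9.0), 35.0, 85.0))
        clinical = {
            "patient_id": pid,
            "age": round(age, 1),
            "stage": "IV" if rng.random() < 0.25 else "III",
            "resection": ["complete", "optimal", "suboptimal"][
                int(rng.choice(3, p=[0.30, 0.45, 0.25]))
            ],
            "cnb": round(float(rng.beta(5.5, 4.5)), 3),
            "platinum_status": "unknown"
            if unknown
            else ("resistant" if resistant else "sensitive"),
            "pfs_months": round(pfs, 2),
            "pfs_event": not censored,
            "scanner": "nonGE" if rng.random() < spec.nonge_scanner_rate else "GE",
        }
        truth = {
            "patient_id": pid,
            "n_lesions": n_lesions,
            "n_texture_classes": n_classes,
            "resistant_true": resistant,
            "p_resist": p_resist,
            "hazard": hazard,
        }
        yield pspec, clinical, truth


def make_multisite_patient(
    n_lesions: int,
    n_classes: int | None = None,
    seed: int = 0,
    radii: tuple[float, float, float] = (7.0, 7.0, 2.8),
    shape: tuple[int, int, int] = (96, 96, 32),
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0),
) -> tuple[CTVolume, LesionSet, np.ndarray]:
    """Controlled-experiment patient: lesions on a grid, one texture class each.

    With ``n_classes=None`` every lesion gets its own texture class (fully
    heterogeneous); with ``n_classes=1`` all lesions share one class
    (homogeneous).  Lesion centers sit on a fixed 3x3x2 grid, so up to 18
    non-overlapping lesions fit the default grid.
    """
    if n_classes is None:
        n_classes = n_lesions
    slots = [
        (18 + 30 * (i % 3), 18 + 30 * ((i // 3) % 3), 8 + 16 * (i // 9))
        for i in range(n_lesions)
    ]
    if n_lesions > 18:
        raise ValidationError("at most 18 grid slots available")
    lesions = []
    for i in range(n_lesions):
        site, region = SITE_POOL[i % len(SITE_POOL)]
        lesions.append(
            LesionSpec(
                center=slots[i],
                radii=radii,
                site_label=f"{site}_{i}",
                region=region,
                classes=(i % min(n_classes, len(TEXTURE_PALETTE)),),
            )
        )
    return make_patient(
        PhantomSpec(shape=shape, spacing=spacing, lesions=lesions, seed=seed)
    )


def make_cohort(spec: CohortSpec, out_dir: str | Path):
    """Write a cohort directory exactly as the I/O layer expects.

    Produces one NIfTI volume + one mask per lesion per patient, plus
    ``lesions.csv``, ``clinical.csv`` and ``truth.csv``.  Returns the three
    tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lesion_rows, clin_rows, truth_rows = [], [], []
    for pspec, clinical, truth in generate_cohort(spec):
        volume, lesset, _ = make_patient(pspec)
        lesion_rows.append(save_patient(volume, lesset, out))
        clin_rows.append(clinical)
        truth_rows.append(truth)
    lesion_df = pd.concat(lesion_rows, ignore_index=True)
    clin_df = pd.DataFrame(clin_rows)
    truth_df = pd.DataFrame(truth_rows)
    lesion_df.to_csv(out / "lesions.csv", index=False)
    clin_df.to_csv(out / "clinical.csv", index=False)
    truth_df.to_csv(out / "truth.csv", index=False)
    return lesion_df, clin_df, truth_df
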