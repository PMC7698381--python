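"""Volume, mask and table input/output with geometric and schema validation.

Volumes and masks are exchanged as NIfTI files (one file per lesion mask, so
that lesion identity and anatomic-site labels survive independently of voxel
values); a labelmap importer is provided as a convenience.  Tabular metadata
travels as CSV.  All geometry checks compare shape exactly, spacing to
1e-4 mm and origin to 1e-3 mm; voxel indices are 0-based.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import GeometryError, SchemaError, ValidationError

SPACING_TOL_MM = 1e-4
ORIGIN_TOL_MM = 1e-3

REGIONS = ("pelvis", "abdomen")
STAGES = ("III", "IV")
RESECTIONS = ("complete", "optimal", "suboptimal")
PLATINUM = ("sensitive", "resistant", "unknown")

LESION_TABLE_COLUMNS = ("patient_id", "lesion_id", "mask_path", "site_label", "region")
CLINICAL_TABLE_COLUMNS = (
    "patient_id",
    "age",
    "stage",
    "resection",
    "cnb",
    "platinum_status",
    "pfs_months",
    "pfs_event",
    "scanner",
)


@dataclass
class CTVolume:
    """A calibrated 3D intensity grid (Hounsfield units or phantom intensity)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValidationError("volume must be a non-empty 3D grid")
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("volume contains non-finite values")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class LesionMask:
    """A binary VOI on the same lattice as its parent volume."""

    mask: np.ndarray
    lesion_id: str
    site_label: str
    region: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValidationError(f"mask {self.lesion_id!r} must be 3D")
        if not self.mask.any():
            raise ValidationError(f"mask {self.lesion_id!r} has no foreground voxel")
        if self.region not in REGIONS:
            raise SchemaError(
                f"lesion {self.lesion_id!r}: unknown region {self.region!r}; "
                f"expected one of {REGIONS}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class LesionSet:
    """All delineated lesions of one patient plus scanner provenance."""

    patient_id: str
    lesions: list[LesionMask]
    scanner: str = "GE"

    def __post_init__(self) -> None:
        if len(self.lesions) < 1:
            raise ValidationError(f"patient {self.patient_id!r}: at least one lesion required")
        ids = [m.lesion_id for m in self.lesions]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"patient {self.patient_id!r}: duplicate lesion ids {ids}")

    def __len__(self) -> int:
        return len(self.lesions)

    def __iter__(self):
        return iter(self.lesions)

    def filter_region(self, region: str) -> list[LesionMask]:
        if region == "all":
            return list(self.lesions)
        return [m for m in self.lesions if m.region == region]

    def union_mask(self) -> np.ndarray:
        out = np.zeros_like(self.lesions[0].mask, dtype=bool)
        for m in self.lesions:
            out |= m.mask
        return out


@dataclass
class ClinicalRecord:
    patient_id: str
    age: float
    stage: str
    resection: str
    cnb: float
    platinum_status: str
    pfs_months: float
    pfs_event: bool
    scanner: str = "GE"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise SchemaError(f"{self.patient_id}: unknown stage {self.stage!r}")
        if self.resection not in RESECTIONS:
            raise SchemaError(f"{self.patient_id}: unknown resection {self.resection!r}")
        if self.platinum_status not in PLATINUM:
            raise SchemaError(
                f"{self.patient_id}: unknown platinum status {self.platinum_status!r}"
            )
        if not 0.0 <= self.cnb <= 1.0:
            raise ValidationError(f"{self.patient_id}: cnb {self.cnb} outside [0, 1]")
        if self.pfs_months < 0:
            raise ValidationError(f"{self.patient_id}: negative pfs_months {self.pfs_months}")

    @property
    def has_platinum_label(self) -> bool:
        return self.platinum_status != "unknown"


def _affine(spacing: Sequence[float], origin: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def _geometry_of(img: nib.Nifti1Image) -> tuple[tuple, tuple]:
    aff = img.affine
    spacing = tuple(float(s) for s in np.sqrt((aff[:3, :3] ** 2).sum(axis=0)))
    origin = tuple(float(o) for o in aff[:3, 3])
    return spacing, origin


def save_volume(volume: CTVolume, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(
        np.asarray(volume.voxels, dtype=np.float32), _affine(volume.spacing, volume.origin)
    )
    nib.save(img, str(path))


def save_mask(mask: LesionMask, volume: CTVolume, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(
        mask.mask.astype(np.uint8), _affine(volume.spacing, volume.origin)
    )
    nib.save(img, str(path))


def load_volume(path: str | os.PathLike, patient_id: str = "") -> CTVolume:
    img = nib.load(str(path))
    spacing, origin = _geometry_of(img)
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    return CTVolume(voxels=data, spacing=spacing, origin=origin, patient_id=patient_id)


def _check_grid(volume: CTVolume, path: str, img: nib.Nifti1Image) -> None:
    if tuple(img.shape[:3]) != tuple(volume.shape):
        raise GeometryError(
            f"mask {path!r}: shape {tuple(img.shape[:3])} != volume shape {volume.shape}"
        )
    spacing, origin = _geometry_of(img)
    if max(abs(a - b) for a, b in zip(spacing, volume.spacing)) > SPACING_TOL_MM:
        raise GeometryError(f"mask {path!r}: spacing {spacing} != volume spacing {volume.spacing}")
    if max(abs(a - b) for a, b in zip(origin, volume.origin)) > ORIGIN_TOL_MM:
        raise GeometryError(f"mask {path!r}: origin {origin} != volume origin {volume.origin}")


def load_patient(
    volume_path: str | os.PathLike,
    lesion_rows: pd.DataFrame,
    base_dir: str | os.PathLike | None = None,
    scanner: str = "GE",
) -> tuple[CTVolume, LesionSet]:
    """Load one patient's volume and validated lesion set.

    ``lesion_rows`` are the rows of the lesion table belonging to this
    patient (columns ``patient_id, lesion_id, mask_path, site_label, region``).
    Mask paths are resolved relative to ``base_dir`` (defaults to the volume's
    directory).
    """
    missing = [c for c in LESION_TABLE_COLUMNS if c not in lesion_rows.columns]
    if missing:
        raise SchemaError(f"lesion table missing columns {missing}")
    if len(lesion_rows) == 0:
        raise SchemaError("no lesion rows supplied")
    pids = set(lesion_rows["patient_id"].astype(str))
    if len(pids) != 1:
        raise SchemaError(f"lesion rows span multiple patients: {sorted(pids)}")
    patient_id = pids.pop()
    base = Path(base_dir) if base_dir is not None else Path(volume_path).parent

    volume = load_volume(volume_path, patient_id=patient_id)
    lesions = []
    for row in lesion_rows.itertuples(index=False):
        mask_path = Path(row.mask_path)
        if not mask_path.is_absolute():
            mask_path = base / mask_path
        img = nib.load(str(mask_path))
        _check_grid(volume, str(mask_path), img)
        lesions.append(
            LesionMask(
                mask=np.asarray(img.get_fdata()) > 0.5,
                lesion_id=str(row.lesion_id),
                site_label=str(row.site_label),
                region=str(row.region),
            )
        )
    return volume, LesionSet(patient_id=patient_id, lesions=lesions, scanner=scanner)


def save_patient(
    volume: CTVolume,
    lesions: LesionSet,
    out_dir: str | os.PathLike,
) -> pd.DataFrame:
    """Write ``<pid>_ct.nii.gz`` + one mask file per lesion; return lesion rows."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pid = lesions.patient_id
    save_volume(volume, out / f"{pid}_ct.nii.gz")
    rows = []
    for m in lesions:
        fname = f"{pid}_{m.lesion_id}_mask.nii.gz"
        save_mask(m, volume, out / fname)
        rows.append(
            {
                "patient_id": pid,
                "lesion_id": m.lesion_id,
                "mask_path": fname,
                "site_label": m.site_label,
                "region": m.region,
            }
        )
    return pd.DataFrame(rows, columns=list(LESION_TABLE_COLUMNS))


def import_labelmap(
    labelmap: np.ndarray,
    site_labels: dict[int, str],
    regions: dict[int, str],
) -> list[LesionMask]:
    """Split an integer labelmap into one binary :class:`LesionMask` per label."""
    labelmap = np.asarray(labelmap)
    masks = []
    for value in sorted(int(v) for v in np.unique(labelmap) if v != 0):
        if value not in site_labels or value not in regions:
            raise SchemaError(f"labelmap value {value} has no site/region entry")
        masks.append(
            LesionMask(
                mask=labelmap == value,
                lesion_id=f"lesion{value}",
                site_label=site_labels[value],
                region=regions[value],
            )
        )
    return masks


def load_dicom_series(series_dir: str | os.PathLike, patient_id: str = "") -> CTVolume:
    """Assemble an axial DICOM series into a single volume (slices sorted by z)."""
    import pydicom

    paths = sorted(Path(series_dir).glob("*.dcm"))
    if not paths:
        raise SchemaError(f"no DICOM files in {series_dir!r}")
    slices = [pydicom.dcmread(str(p)) for p in paths]
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    px = [float(v) for v in slices[0].PixelSpacing]
    zs = [float(ds.ImagePositionPatient[2]) for ds in slices]
    dz = float(np.median(np.diff(zs))) if len(zs) > 1 else float(
        getattr(slices[0], "SliceThickness", 1.0)
    )
    arrs = []
    for ds in slices:
        a = ds.pixel_array.astype(np.float32)
        a = a * float(getattr(ds, "RescaleSlope", 1.0)) + float(
            getattr(ds, "RescaleIntercept", 0.0)
        )
        arrs.append(a.T)  # (x, y) indexing to match NIfTI convention
    vol = np.stack(arrs, axis=-1)
    origin = tuple(float(v) for v in slices[0].ImagePositionPatient)
    return CTVolume(
        voxels=vol, spacing=(px[1], px[0], abs(dz)), origin=origin, patient_id=patient_id
    )


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("1", "true", "t", "yes"):
        return True
    if s in ("0", "false", "f", "no"):
        return False
    raise SchemaError(f"cannot parse boolean value {v!r}")


def load_clinical_table(path: str | os.PathLike) -> list[ClinicalRecord]:
    """Read the clinical CSV into validated records.

    Rows with ``platinum_status == "unknown"`` are retained but flagged
    (``has_platinum_label`` is False); resistance-classification callers must
    exclude them.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise SchemaError(f"cannot parse clinical table {path!r}: {exc}") from exc
    missing = [c for c in CLINICAL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"clinical table missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        try:
            age = float(row.age)
            cnb = float(row.cnb)
            pfs = float(row.pfs_months)
        except (TypeError, ValueError) as exc:
            raise SchemaError(
                f"{row.patient_id}: non-numeric age/cnb/pfs_months"
            ) from exc
        records.append(
            ClinicalRecord(
                patient_id=str(row.patient_id),
                age=age,
                stage=str(row.stage),
                resection=str(row.resection),
                cnb=cnb,
                platinum_status=str(row.platinum_status),
                pfs_months=pfs,
                pfs_event=_parse_bool(row.pfs_event),
                scanner=str(row.scanner),
            )
        )
    return records


def clinical_to_frame(records: Iterable[ClinicalRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])
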