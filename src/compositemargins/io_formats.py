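"""File formats: NIfTI masks, DICOM RT structure sets, cohort manifests, reports.

The cohort manifest is a JSON file tying each patient's planning structure
source and per-fraction sources together with the rigid translations from
both registration protocols. Shift sign convention: translations map the
fraction (CBCT) frame into the planning frame, i.e. they are *added* to
fraction coordinates; a manifest-level ``shift_convention`` of
``"pct_to_cbct"`` flips the sign for sources that record the opposite
direction.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom
from pydantic import BaseModel, Field, ValidationError, field_validator
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.sequence import Sequence as DcmSequence
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import ManifestError, UnsupportedOrientationError
from .margin_engine import round_margin_mm
from .mask_geometry import (
    ContourSet,
    ContourSlice,
    StructureMask,
    VoxelGrid,
)

logger = logging.getLogger(__name__)

RTSTRUCT_SOP_CLASS_UID = "1.2.840.10008.5.1.4.1.1.481.3"

__all__ = [
    "read_mask_volume",
    "write_mask_volume",
    "read_rtstruct",
    "write_rtstruct",
    "CohortManifest",
    "PatientEntry",
    "FractionEntry",
    "GridSpec",
    "load_manifest",
    "write_manifest",
    "write_report",
    "write_synthetic_cohort",
]


# ---------------------------------------------------------------------------
# NIfTI masks


def write_mask_volume(mask: StructureMask, path: str | Path) -> None:
    """Write a binary mask as NIfTI with a diagonal affine (spacing + origin)."""
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = mask.grid.spacing
    affine[:3, 3] = mask.grid.origin
    img = nib.Nifti1Image(mask.occupancy.astype(np.uint8), affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_mask_volume(path: str | Path, label: str = "") -> StructureMask:
    """Read a NIfTI mask; values are binarized at > 0 (with a warning if the
    volume was not already binary). Non-axis-aligned affines are refused —
    this reader never resamples silently."""
    img = nib.load(str(path))
    affine = np.asarray(img.affine, dtype=float)
    rot = affine[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6) or np.any(
        np.diag(rot) <= 0
    ):
        raise UnsupportedOrientationError(
            f"{path}: affine is not a positive diagonal (axis-aligned, "
            "un-flipped) matrix; resampling is out of scope"
        )
    spacing = tuple(float(v) for v in np.diag(rot))
    origin = tuple(float(v) for v in affine[:3, 3])
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0, 1))):
        warnings.warn(
            f"{path}: volume is not binary; binarizing at > 0", stacklevel=2
        )
    occ = data > 0
    grid = VoxelGrid(origin=origin, spacing=spacing, dims=occ.shape)
    return StructureMask(grid=grid, occupancy=occ, label=label or Path(path).stem)


# ---------------------------------------------------------------------------
# DICOM RT Structure Set


def read_rtstruct(
    path: str | Path, label_map: Mapping[str, str] | None = None
) -> dict[str, ContourSet]:
    """Read planar contours from a DICOM RT Structure Set.

    Returns one :class:`ContourSet` per mapped ROI, vertices in patient mm.
    ``label_map`` maps ROI names in the file to canonical structure labels;
    unmapped ROIs are skipped with a warning. With no map, every ROI is kept
    under its own name.
    """
    ds = pydicom.dcmread(str(path))
    if "StructureSetROISequence" not in ds or "ROIContourSequence" not in ds:
        raise ValueError(f"{path}: not an RT Structure Set (missing ROI sequences)")
    roi_names = {
        int(item.ROINumber): str(item.ROIName) for item in ds.StructureSetROISequence
    }
    out: dict[str, ContourSet] = {}
    if not ds.ROIContourSequence:
        warnings.warn(f"{path}: structure set contains zero ROIs", stacklevel=2)
    for roi in ds.ROIContourSequence:
        name = roi_names.get(int(roi.ReferencedROINumber), "")
        if label_map is not None:
            if name not in label_map:
                warnings.warn(
                    f"{path}: ROI {name!r} not in label map; skipped", stacklevel=2
                )
                continue
            label = label_map[name]
        else:
            label = name
        slices: dict[float, list[np.ndarray]] = {}
        for contour in getattr(roi, "ContourSequence", []):
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            z = float(np.round(pts[:, 2].mean(), 6))
            slices.setdefault(z, []).append(pts[:, :2])
        contour_slices = tuple(
            ContourSlice(z=z, polygons=tuple(polys))
            for z, polys in sorted(slices.items())
        )
        out[label] = ContourSet(label=label, slices=contour_slices)
    return out


def write_rtstruct(
    structures: Mapping[str, ContourSet],
    path: str | Path,
    patient_id: str = "ANON",
) -> None:
    """Write contour sets as a minimal, self-consistent RT Structure Set.

    Synthetic output: it carries the contour geometry and ROI naming needed
    by :func:`read_rtstruct` and common viewers, not a full clinical export
    (no referenced image series).
    """
    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = RTSTRUCT_SOP_CLASS_UID
    file_meta.MediaStorageSOPInstanceUID = generate_uid()
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = file_meta
    ds.SOPClassUID = RTSTRUCT_SOP_CLASS_UID
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.PatientID = patient_id
    ds.PatientName = patient_id
    ds.StructureSetLabel = "compositemargins"
    ds.FrameOfReferenceUID = generate_uid()

    ds.StructureSetROISequence = DcmSequence()
    ds.ROIContourSequence = DcmSequence()
    for number, (label, cs) in enumerate(sorted(structures.items()), start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = label
        roi.ReferencedFrameOfReferenceUID = ds.FrameOfReferenceUID
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        ds.StructureSetROISequence.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ContourSequence = DcmSequence()
        for sl in cs.slices:
            for poly in sl.polygons:
                c = Dataset()
                c.ContourGeometricType = "CLOSED_PLANAR"
                c.NumberOfContourPoints = len(poly)
                data = np.column_stack(
                    [poly, np.full(len(poly), sl.z)]
                ).ravel()
                c.ContourData = [f"{v:.6f}" for v in data]
                rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)

    pydicom.dcmwrite(str(path), ds, enforce_file_format=True)


# ---------------------------------------------------------------------------
# cohort manifest


class GridSpec(BaseModel):
    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]

    @field_validator("spacing")
    @classmethod
    def _positive_spacing(cls, v):
        if any(s <= 0 for s in v):
            raise ValueError("spacing components must be > 0")
        return v

    def to_grid(self) -> VoxelGrid:
        return VoxelGrid(origin=self.origin, spacing=self.spacing, dims=self.dims)


class FractionEntry(BaseModel):
    path: str
    fraction_index: int = Field(ge=1)
    bone_shift_mm: tuple[float, float, float]
    soft_tissue_shift_mm: tuple[float, float, float]


class PatientEntry(BaseModel):
    """One patient's sources.

    For ``format == "rtstruct"`` the planning and fraction paths are DICOM
    files; for ``"nifti"`` they are directories holding one
    ``<label>.nii.gz`` per structure.
    """

    id: str
    planning_path: str
    format: Literal["rtstruct", "nifti"]
    fractions: list[FractionEntry]

    @field_validator("fractions")
    @classmethod
    def _unique_fraction_indices(cls, v):
        idx = [f.fraction_index for f in v]
        if len(set(idx)) != len(idx):
            raise ValueError(f"fraction indices not unique: {idx}")
        return v


class CohortManifest(BaseModel):
    grid: GridSpec
    label_map: dict[str, str] = Field(default_factory=dict)
    shift_convention: Literal["cbct_to_pct", "pct_to_cbct"] = "cbct_to_pct"
    patients: list[PatientEntry]

    @field_validator("patients")
    @classmethod
    def _unique_patient_ids(cls, v):
        ids = [p.id for p in v]
        if len(set(ids)) != len(ids):
            raise ValueError(f"patient ids not unique: {ids}")
        return v

    def shift_sign(self) -> float:
        return 1.0 if self.shift_convention == "cbct_to_pct" else -1.0


def load_manifest(path: str | Path) -> CohortManifest:
    """Load and validate a cohort manifest; every referenced path must resolve
    relative to the manifest's directory."""
    path = Path(path)
    try:
        manifest = CohortManifest.model_validate_json(path.read_text())
    except ValidationError as exc:
        raise ManifestError(f"{path}: {exc}") from exc
    base = path.parent
    for patient in manifest.patients:
        for ref in [patient.planning_path] + [f.path for f in patient.fractions]:
            if not (base / ref).exists():
                raise ManifestError(
                    f"{path}: patient {patient.id!r} references missing file {ref!r}"
                )
    return manifest


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(manifest.model_dump(), indent=2, sort_keys=True) + "\n"
    )


# ---------------------------------------------------------------------------
# reports


_MM_COLUMNS = ("m95_mm", "mean_mm", "sd_mm", "margin_mm", "m95_mm_mean", "m95_mm_sd")


def _rounded(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if col in _MM_COLUMNS:
            out[col] = out[col].map(
                lambda v: round_margin_mm(v) if pd.notna(v) else v
            )
    return out


def write_report(report, out_dir: str | Path) -> dict[str, Path]:
    """Write a study report as CSV tables (margins rounded to 0.1 mm) plus a
    full-precision JSON document. Deterministic: fixed column order, sorted
    rows and keys, so identical studies produce byte-identical files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    population = pd.DataFrame(
        [
            {
                "structure": s.structure_label,
                "protocol": s.protocol,
                "n": s.n_patients,
                "mean_mm": s.mean_mm,
                "sd_mm": s.sd_mm,
                "margin_mm": s.margin_mm,
            }
            for s in report.population
        ]
    )
    tables = {
        "per_patient": report.per_patient,
        "population_margins": population,
        "cohort_summary": report.summary,
        "protocol_tests": report.protocol_tests,
        "normality": report.normality,
        "recipe_margins": report.recipe_margins,
    }
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        _rounded(df).to_csv(p, index=False, float_format="%.6g", lineterminator="\n")
        paths[name] = p

    doc = {
        "n_fractions": report.n_fractions,
        "seed": report.seed,
        "non_convergent": list(report.non_convergent),
        "population_margins": population.to_dict(orient="records"),
        "per_patient": report.per_patient.to_dict(orient="records"),
        "sweeps": {
            "|".join(key): list(map(list, sweep.increments))
            for key, sweep in sorted(report.sweeps.items())
        },
    }
    p = out_dir / "report.json"
    p.write_text(json.dumps(doc, indent=2, sort_keys=True, allow_nan=True) + "\n")
    paths["report"] = p
    return paths


# ---------------------------------------------------------------------------
# synthetic cohort export (manifest + NIfTI masks, real-data-path compatible)


def write_synthetic_cohort(
    out_dir: str | Path,
    n_patients: int,
    spec,
    model,
    n_fractions: int = 5,
) -> Path:
    """Materialize a synthetic cohort as NIfTI masks plus a JSON manifest.

    Fraction masks are written in the planning frame as already-displaced
    anatomy; the manifest carries the registration translations for both
    protocols, exactly as the real-data path expects. Returns the manifest
    path.
    """
    from .mask_geometry import rasterize
    from .synthetic_cohort import generate_phantom, simulate_fractions

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    planning = generate_phantom(spec)
    patients: list[PatientEntry] = []
    seeds = np.random.SeedSequence(model.seed).spawn(n_patients)
    for i in range(n_patients):
        pid = f"SYN{i + 1:03d}"
        pdir = out_dir / pid
        pdir.mkdir(exist_ok=True)
        plan_dir = pdir / "planning"
        plan_dir.mkdir(exist_ok=True)
        for label, cs in planning.items():
            write_mask_volume(rasterize(cs, spec.grid), plan_dir / f"{label}.nii.gz")
        rng = np.random.default_rng(seeds[i])
        fractions = simulate_fractions(planning, model, n_fractions, rng)
        entries: list[FractionEntry] = []
        for f in range(1, n_fractions + 1):
            fdir = pdir / f"fraction{f}"
            fdir.mkdir(exist_ok=True)
            bone_shift = soft_shift = None
            for protocol in ("bone", "soft_tissue"):
                for label, fs_list in fractions[protocol].items():
                    fs = next(x for x in fs_list if x.fraction_index == f)
                    if protocol == "bone":
                        bone_shift = fs.shift.translation
                        write_mask_volume(
                            rasterize(fs.contours, spec.grid),
                            fdir / f"{label}.nii.gz",
                        )
                    else:
                        soft_shift = fs.shift.translation
            entries.append(
                FractionEntry(
                    path=str(fdir.relative_to(out_dir)),
                    fraction_index=f,
                    bone_shift_mm=bone_shift,
                    soft_tissue_shift_mm=soft_shift,
                )
            )
        patients.append(
            PatientEntry(
                id=pid,
                planning_path=str(plan_dir.relative_to(out_dir)),
                format="nifti",
                fractions=entries,
            )
        )
    manifest = CohortManifest(
        grid=GridSpec(
            origin=spec.grid.origin, spacing=spec.grid.spacing, dims=spec.grid.dims
        ),
        label_map={label: label for label in planning},
        patients=patients,
    )
    manifest_path = out_dir / "cohort.json"
    write_manifest(manifest, manifest_path)
    return manifest_path


# ---------------------------------------------------------------------------
# manifest-driven derivation (the real-data path)


def _load_patient_structures(
    base: Path, source: str, fmt: str, manifest: CohortManifest, grid: VoxelGrid
) -> dict[str, StructureMask]:
    from .mask_geometry import rasterize

    path = base / source
    if fmt == "rtstruct":
        contours = read_rtstruct(path, label_map=manifest.label_map or None)
        return {label: rasterize(cs, grid) for label, cs in contours.items()}
    labels = manifest.label_map.values() if manifest.label_map else None
    masks: dict[str, StructureMask] = {}
    for f in sorted(path.glob("*.nii*")):
        label = f.name.split(".nii")[0]
        if labels is not None and label not in labels:
            continue
        mask = read_mask_volume(f, label=label)
        # NIfTI affines are float32; compare with tolerance, then adopt the
        # manifest grid so downstream exact grid checks hold
        if mask.grid.dims != grid.dims or not (
            np.allclose(mask.grid.origin, grid.origin, atol=1e-3)
            and np.allclose(mask.grid.spacing, grid.spacing, atol=1e-3)
        ):
            raise ManifestError(f"{f}: mask grid differs from the manifest grid")
        masks[label] = StructureMask(grid=grid, occupancy=mask.occupancy, label=label)
    return masks


def derive_from_manifest(
    manifest_path: str | Path,
    protocols: Sequence[str] = ("bone", "soft_tissue"),
    threshold: float = 95.0,
    margins: Sequence[float] | None = None,
):
    """Run the composite-volume margin analysis on an on-disk cohort.

    Fraction structures are shifted into the planning frame by the manifest's
    registration translations (nearest-voxel for mask sources, continuous
    for contour sources), unioned into one composite per structure and
    protocol, and swept against the planning CTV. Returns a
    :class:`~compositemargins.synthetic_cohort.StudyReport`.
    """
    from .cohort_stats import summarize_cohort
    from .margin_engine import (
        DEFAULT_MARGINS_MM,
        composite_ratio,
        derive_patient_margin,
        population_margin,
    )
    from .mask_geometry import CompositeStructure, StructureMask, shift_mask
    from .synthetic_cohort import StudyReport, _normality_table, _protocol_tests

    manifest_path = Path(manifest_path)
    manifest = load_manifest(manifest_path)
    base = manifest_path.parent
    grid = manifest.grid.to_grid()
    sign = manifest.shift_sign()
    if margins is None:
        margins = DEFAULT_MARGINS_MM

    rows: list[dict[str, object]] = []
    sweeps: dict[tuple[str, str, str], object] = {}
    records: dict[tuple[str, str], list] = {}
    failures: list[str] = []
    for patient in manifest.patients:
        planning = _load_patient_structures(
            base, patient.planning_path, patient.format, manifest, grid
        )
        fraction_masks: dict[int, dict[str, StructureMask]] = {
            e.fraction_index: _load_patient_structures(
                base, e.path, patient.format, manifest, grid
            )
            for e in patient.fractions
        }
        for protocol in protocols:
            for label, plan_mask in planning.items():
                union = np.zeros(grid.dims, dtype=bool)
                for e in patient.fractions:
                    if label not in fraction_masks[e.fraction_index]:
                        continue
                    t = (
                        e.bone_shift_mm
                        if protocol == "bone"
                        else e.soft_tissue_shift_mm
                    )
                    shifted = shift_mask(
                        fraction_masks[e.fraction_index][label],
                        tuple(sign * v for v in t),
                    )
                    union |= shifted.occupancy
                composite = CompositeStructure(
                    mask=StructureMask(grid=grid, occupancy=union, label=label),
                    n_fractions=len(patient.fractions),
                    protocol=protocol,
                )
                from .errors import NonConvergenceError

                try:
                    record, sweep = derive_patient_margin(
                        patient.id, plan_mask, composite,
                        threshold=threshold, margins=margins,
                    )
                except NonConvergenceError:
                    failures.append(f"{patient.id}/{label}/{protocol}")
                    continue
                sweeps[(patient.id, label, protocol)] = sweep
                records.setdefault((label, protocol), []).append(record)
                overlap5 = next(
                    (o for m, o in sweep.increments if abs(m - 5.0) < 1e-9),
                    float("nan"),
                )
                rows.append(
                    {
                        "patient_id": patient.id,
                        "structure": label,
                        "protocol": protocol,
                        "pct_volume_cm3": plan_mask.volume_cm3,
                        "composite_volume_cm3": composite.mask.volume_cm3,
                        "composite_ratio": composite_ratio(composite, plan_mask),
                        "overlap_at_5mm_pct": overlap5,
                        "m95_mm": record.m95,
                    }
                )

    per_patient = pd.DataFrame(rows)
    if not per_patient.empty:
        per_patient = per_patient.sort_values(
            ["structure", "protocol", "patient_id"], ignore_index=True
        )
    population = tuple(
        population_margin(recs)
        for (label, protocol), recs in sorted(records.items())
        if len(recs) >= 2
    )
    protocol_tests = (
        _protocol_tests(sweeps, margins)
        if set(protocols) == {"bone", "soft_tissue"} and sweeps
        else pd.DataFrame()
    )
    return StudyReport(
        per_patient=per_patient,
        population=population,
        summary=summarize_cohort(per_patient) if not per_patient.empty else per_patient,
        protocol_tests=protocol_tests,
        normality=_normality_table(records),
        recipe_margins=pd.DataFrame(),
        sweeps=sweeps,
        non_convergent=tuple(failures),
        n_fractions=max((len(p.fractions) for p in manifest.patients), default=0),
        seed=None,
    )
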