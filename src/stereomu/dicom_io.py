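"""DICOM-RT input and report output.

Reads the four objects an MU check needs — the CT series, RT Plan, RT
Structure Set and RT Dose — into plain in-memory containers, and writes the
per-beam comparison report.

Conventions: DICOM patient coordinates (LPS, millimetres) throughout;
gantry / couch angles as stored in the plan (IEC 61217). Head-first supine
is the primary tested configuration; other orientations are handled through
the image orientation cosines.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import pydicom
from matplotlib.path import Path as MplPath

from .exceptions import DicomError

log = logging.getLogger(__name__)

_CT_SOP = "1.2.840.10008.5.1.4.1.1.2"


# --------------------------------------------------------------------------
# In-memory containers
# --------------------------------------------------------------------------

@dataclass
class CTVolume:
    """A CT voxel grid in Hounsfield units with its spatial frame.

    ``hu`` is indexed ``[slice, row, column]``. ``origin`` is the patient
    (LPS) position of the centre of voxel (0, 0, 0). ``spacing`` is
    (column, row, slice) spacing in mm; ``col_dir`` / ``row_dir`` /
    ``slice_dir`` are the unit patient-frame directions along which the
    column, row and slice indices increase.
    """

    hu: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray  # (dc, dr, dk)
    col_dir: np.ndarray
    row_dir: np.ndarray
    slice_dir: np.ndarray
    patient_position: str = "HFS"
    frame_of_reference_uid: str = ""

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=np.float32)
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        for name in ("col_dir", "row_dir", "slice_dir"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v / np.linalg.norm(v))
        if np.any(self.spacing <= 0):
            raise DicomError(f"voxel spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.hu)):
            raise DicomError("CT volume contains non-finite HU values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape  # (nk, nr, nc)

    @property
    def affine(self) -> np.ndarray:
        """3x3 matrix with columns = world step per (column, row, slice) index."""
        return np.column_stack(
            [
                self.col_dir * self.spacing[0],
                self.row_dir * self.spacing[1],
                self.slice_dir * self.spacing[2],
            ]
        )

    def world_to_index(self, points) -> np.ndarray:
        """Continuous (c, r, k) indices of LPS point(s)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        idx = np.linalg.solve(self.affine, (p - self.origin).T).T
        return idx[0] if np.ndim(points) == 1 else idx

    def index_to_world(self, idx) -> np.ndarray:
        i = np.atleast_2d(np.asarray(idx, dtype=float))
        w = (self.affine @ i.T).T + self.origin
        return w[0] if np.ndim(idx) == 1 else w

    def hu_at(self, c, r, k):
        """HU at integer voxel indices (arrays allowed)."""
        return self.hu[k, r, c]


@dataclass
class DoseGrid:
    """An RT Dose grid (Gy) with its frame and plan linkage."""

    values: np.ndarray  # [frame, row, col], Gy
    origin: np.ndarray
    spacing: np.ndarray  # (dc, dr, dk)
    col_dir: np.ndarray
    row_dir: np.ndarray
    slice_dir: np.ndarray
    summation_type: str = "PLAN"
    beam_number: Optional[int] = None

    def sample(self, point) -> float:
        """Trilinear interpolation of the dose at an LPS point (Gy)."""
        M = np.column_stack(
            [
                self.col_dir * self.spacing[0],
                self.row_dir * self.spacing[1],
                self.slice_dir * self.spacing[2],
            ]
        )
        c, r, k = np.linalg.solve(M, np.asarray(point, dtype=float) - self.origin)
        nk, nr, nc = self.values.shape
        if not (-0.5 <= c <= nc - 0.5 and -0.5 <= r <= nr - 0.5 and -0.5 <= k <= nk - 0.5):
            raise DicomError("dose sample point outside the dose grid")
        out = 0.0
        c0, r0, k0 = (int(np.floor(v)) for v in (c, r, k))
        for dc in (0, 1):
            for dr in (0, 1):
                for dk in (0, 1):
                    ci = min(max(c0 + dc, 0), nc - 1)
                    ri = min(max(r0 + dr, 0), nr - 1)
                    ki = min(max(k0 + dk, 0), nk - 1)
                    wc = 1 - abs(c - (c0 + dc))
                    wr = 1 - abs(r - (r0 + dr))
                    wk = 1 - abs(k - (k0 + dk))
                    w = max(wc, 0) * max(wr, 0) * max(wk, 0)
                    out += w * float(self.values[ki, ri, ci])
        return out


_EXTERNAL_NAMES = {"body", "external", "skin"}


@dataclass
class StructureSet:
    """Named planar contours in the patient frame.

    ``contours`` maps ROI name to a list of closed planar contours, each an
    (N, 3) array of LPS points. ``types`` maps ROI name to its RT ROI
    interpreted type (may be empty strings).
    """

    contours: dict[str, list[np.ndarray]]
    types: dict[str, str] = field(default_factory=dict)

    @property
    def external_name(self) -> str:
        """The external/BODY structure used for depth calculation."""
        for name, t in self.types.items():
            if t.upper() == "EXTERNAL":
                return name
        for name in self.contours:
            if name.lower() in _EXTERNAL_NAMES:
                return name
        raise DicomError(
            "no external structure: need RTROIInterpretedType EXTERNAL or a "
            "ROI named BODY/External/SKIN"
        )

    def body_slices(self) -> list[tuple[float, float, list[np.ndarray]]]:
        """External contour grouped per slice as (z_low, z_high, [xy polygons]).

        Each planar contour occupies a z band of one slice thickness
        (estimated from the contour z positions) centred on its plane.
        """
        polys = self.contours[self.external_name]
        by_z: dict[float, list[np.ndarray]] = {}
        for p in polys:
            z = float(np.round(np.mean(p[:, 2]), 6))
            by_z.setdefault(z, []).append(np.asarray(p[:, :2], dtype=float))
        zs = np.array(sorted(by_z))
        if len(zs) > 1:
            h = float(np.median(np.diff(zs)))
        else:
            h = 1.0
        return [(z - h / 2.0, z + h / 2.0, by_z[z]) for z in zs]

    def body_mask(self, ct: CTVolume) -> np.ndarray:
        """Even-odd rasterization of the external contour on the CT grid.

        Voxel centres decide membership; multiple contours on one slice
        toggle (so holes subtract).
        """
        nk, nr, nc = ct.shape
        mask = np.zeros((nk, nr, nc), dtype=bool)
        # voxel-centre world coordinates per slice, via the affine
        cc, rr = np.meshgrid(np.arange(nc), np.arange(nr))
        flat_idx = np.column_stack([cc.ravel(), rr.ravel()])
        slice_z = np.array(
            [ct.index_to_world(np.array([0.0, 0.0, float(k)]))[2] for k in range(nk)]
        )
        for zlo, zhi, polys in self.body_slices():
            zc = 0.5 * (zlo + zhi)
            k = int(np.argmin(np.abs(slice_z - zc)))
            if abs(slice_z[k] - zc) > (zhi - zlo):
                continue
            pts_idx = np.column_stack(
                [flat_idx, np.full(len(flat_idx), float(k))]
            )
            world = ct.index_to_world(pts_idx)[:, :2]
            inside = np.zeros(len(world), dtype=bool)
            for poly in polys:
                inside ^= MplPath(poly, closed=True).contains_points(world)
            mask[k] |= inside.reshape(nr, nc)
        return mask


@dataclass
class ConeBeam:
    """One plan beam delivered through a conical applicator."""

    beam_id: str
    beam_number: int
    cone_mm: float
    isocenter: np.ndarray  # LPS mm
    couch_deg: float
    gantry_start_deg: float
    gantry_stop_deg: float
    rotation_direction: str  # 'NONE' | 'CW' | 'CC'
    plan_mu: float
    dose_gy: float
    dose_source: str = "beam_dose"

    def __post_init__(self) -> None:
        self.isocenter = np.asarray(self.isocenter, dtype=float)
        if self.dose_gy <= 0:
            raise DicomError(f"beam {self.beam_id}: isocenter dose must be positive")
        if self.rotation_direction == "NONE" and not np.isclose(
            self.gantry_start_deg % 360.0, self.gantry_stop_deg % 360.0
        ):
            raise DicomError(
                f"beam {self.beam_id}: static beam with start != stop angle"
            )

    @property
    def is_arc(self) -> bool:
        return self.rotation_direction != "NONE"


@dataclass
class PlanBundle:
    """A complete exported study: CT + structures + beams (+ dose grids)."""

    ct: CTVolume
    structures: StructureSet
    beams: list[ConeBeam]
    dose_grids: dict[int, DoseGrid] = field(default_factory=dict)
    patient_id: str = ""
    plan_label: str = ""
    _mask: Optional[np.ndarray] = field(default=None, repr=False)

    def body_mask(self) -> np.ndarray:
        if self._mask is None:
            self._mask = self.structures.body_mask(self.ct)
        return self._mask


# --------------------------------------------------------------------------
# Readers
# --------------------------------------------------------------------------

def read_ct_series(directory) -> CTVolume:
    """Read one coherent CT series from a directory of DICOM files.

    Slices are sorted by position along the slice normal regardless of file
    naming; rescale slope/intercept are applied so values are HU.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if getattr(ds, "SOPClassUID", "") == _CT_SOP or getattr(ds, "Modality", "") == "CT":
            slices.append(ds)
    if not slices:
        raise DicomError(f"no CT slices found in {directory}")
    series = {ds.SeriesInstanceUID for ds in slices}
    if len(series) != 1:
        raise DicomError(f"directory mixes {len(series)} CT series")

    first = slices[0]
    iop = np.asarray(first.ImageOrientationPatient, dtype=float)
    col_dir, row_dir = iop[:3], iop[3:]
    normal = np.cross(col_dir, row_dir)
    slices.sort(key=lambda ds: float(np.dot(np.asarray(ds.ImagePositionPatient, float), normal)))

    positions = np.array([np.asarray(ds.ImagePositionPatient, float) for ds in slices])
    if len(slices) > 1:
        gaps = np.diff(positions @ normal)
        dk = float(np.mean(gaps))
        if np.any(np.abs(gaps - dk) > 0.01):
            raise DicomError("non-uniform slice spacing beyond 0.01 mm tolerance")
    else:
        dk = float(getattr(first, "SliceThickness", 1.0))

    planes = []
    for ds in slices:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise DicomError(f"CT slice {ds.SOPInstanceUID} missing rescale tags")
        planes.append(
            ds.pixel_array.astype(np.float32) * float(ds.RescaleSlope)
            + float(ds.RescaleIntercept)
        )
    hu = np.stack(planes, axis=0)
    ps = np.asarray(first.PixelSpacing, dtype=float)  # (row, col)
    return CTVolume(
        hu=hu,
        origin=positions[0],
        spacing=np.array([ps[1], ps[0], dk]),
        col_dir=col_dir,
        row_dir=row_dir,
        slice_dir=normal,
        patient_position=str(getattr(first, "PatientPosition", "HFS")),
        frame_of_reference_uid=str(getattr(first, "FrameOfReferenceUID", "")),
    )


def read_struct(path) -> StructureSet:
    """Read an RT Structure Set into named contour lists."""
    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", "") != "RTSTRUCT":
        raise DicomError(f"{path} is not an RT Structure Set")
    names = {}
    for roi in ds.StructureSetROISequence:
        names[int(roi.ROINumber)] = str(roi.ROIName)
    types: dict[str, str] = {}
    for obs in getattr(ds, "RTROIObservationsSequence", []):
        num = int(obs.ReferencedROINumber)
        if num in names:
            types[names[num]] = str(getattr(obs, "RTROIInterpretedType", ""))
    contours: dict[str, list[np.ndarray]] = {}
    for rc in getattr(ds, "ROIContourSequence", []):
        name = names.get(int(rc.ReferencedROINumber))
        if name is None:
            continue
        items = []
        for c in getattr(rc, "ContourSequence", []):
            pts = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
            items.append(pts)
        contours[name] = items
    return StructureSet(contours=contours, types=types)


_CONE_RE = re.compile(r"(\d+(?:\.\d+)?)")


def _cone_diameter_from_beam(beam) -> float:
    seq = getattr(beam, "ApplicatorSequence", None)
    if not seq:
        raise DicomError(f"beam {getattr(beam, 'BeamName', '?')}: no cone applicator")
    app = seq[0]
    for attr in ("ApplicatorID", "ApplicatorDescription"):
        text = str(getattr(app, attr, ""))
        m = _CONE_RE.search(text)
        if m:
            return float(m.group(1))
    raise DicomError(
        f"beam {getattr(beam, 'BeamName', '?')}: cannot parse cone diameter "
        "from applicator"
    )


def read_dose(path) -> DoseGrid:
    """Read an RT Dose grid (per-beam or plan summation)."""
    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", "") != "RTDOSE":
        raise DicomError(f"{path} is not an RT Dose object")
    iop = np.asarray(ds.ImageOrientationPatient, dtype=float)
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dk = float(offsets[1] - offsets[0]) if len(offsets) > 1 else 1.0
    ps = np.asarray(ds.PixelSpacing, dtype=float)
    beam_number = None
    summation = str(getattr(ds, "DoseSummationType", "PLAN"))
    try:
        rps = ds.ReferencedRTPlanSequence[0]
        rfg = rps.ReferencedFractionGroupSequence[0]
        beam_number = int(rfg.ReferencedBeamSequence[0].ReferencedBeamNumber)
    except (AttributeError, IndexError):
        pass
    return DoseGrid(
        values=ds.pixel_array.astype(np.float64) * float(ds.DoseGridScaling),
        origin=np.asarray(ds.ImagePositionPatient, dtype=float),
        spacing=np.array([ps[1], ps[0], dk]),
        col_dir=iop[:3],
        row_dir=iop[3:],
        slice_dir=np.cross(iop[:3], iop[3:]),
        summation_type=summation,
        beam_number=beam_number,
    )


def read_plan(rtplan_path, rtdose_paths=(), rtstruct_path=None):
    """Read RT Plan (+ optional RT Dose / RT Structure Set).

    Returns ``(beams, structures, dose_grids)`` where ``structures`` is None
    when no structure set path is given and ``dose_grids`` maps referenced
    beam number to :class:`DoseGrid`.

    The per-beam isocenter dose D is resolved in this order: the plan's
    referenced BeamDose; trilinear sampling of a per-beam (BEAM summation)
    dose grid at the isocenter; apportioning a plan-total grid sample by
    beam MU weight.
    """
    plan = pydicom.dcmread(rtplan_path)
    if getattr(plan, "Modality", "") != "RTPLAN":
        raise DicomError(f"{rtplan_path} is not an RT Plan")

    structures = read_struct(rtstruct_path) if rtstruct_path is not None else None
    dose_grids: dict[int, DoseGrid] = {}
    plan_grid: Optional[DoseGrid] = None
    for p in rtdose_paths:
        g = read_dose(p)
        if g.summation_type == "BEAM" and g.beam_number is not None:
            dose_grids[g.beam_number] = g
        else:
            plan_grid = g

    refs = {}
    try:
        fg = plan.FractionGroupSequence[0]
        for rb in fg.ReferencedBeamSequence:
            refs[int(rb.ReferencedBeamNumber)] = rb
    except (AttributeError, IndexError):
        raise DicomError("plan has no fraction group with referenced beams")

    mu_by_number = {
        n: float(getattr(rb, "BeamMeterset", 0.0)) for n, rb in refs.items()
    }
    total_mu = sum(mu_by_number.values())

    beams: list[ConeBeam] = []
    for beam in plan.BeamSequence:
        if str(getattr(beam, "TreatmentDeliveryType", "TREATMENT")) != "TREATMENT":
            continue
        number = int(beam.BeamNumber)
        cone_mm = _cone_diameter_from_beam(beam)
        cps = beam.ControlPointSequence
        cp0 = cps[0]
        gantry_start = float(cp0.GantryAngle)
        rotation = str(getattr(cp0, "GantryRotationDirection", "NONE") or "NONE")
        couch = float(getattr(cp0, "PatientSupportAngle", 0.0))
        iso = np.asarray(cp0.IsocenterPosition, dtype=float)
        gantry_stop = gantry_start
        if len(cps) > 1 and "GantryAngle" in cps[-1]:
            gantry_stop = float(cps[-1].GantryAngle)
        if rotation == "NONE":
            gantry_stop = gantry_start

        rb = refs.get(number)
        if rb is None:
            raise DicomError(f"beam {number}: not referenced by the fraction group")
        mu = float(getattr(rb, "BeamMeterset", 0.0))

        dose, source = None, None
        if getattr(rb, "BeamDose", None) is not None:
            dose, source = float(rb.BeamDose), "beam_dose"
        elif number in dose_grids:
            dose, source = dose_grids[number].sample(iso), "beam_grid"
        elif plan_grid is not None and total_mu > 0:
            dose = plan_grid.sample(iso) * mu / total_mu
            source = "plan_grid_mu_weighted"
        if dose is None or dose <= 0:
            raise DicomError(f"beam {number}: no resolvable per-beam isocenter dose")
        log.info("beam %s: isocenter dose %.4f Gy from %s", number, dose, source)

        beams.append(
            ConeBeam(
                beam_id=str(getattr(beam, "BeamName", number)),
                beam_number=number,
                cone_mm=cone_mm,
                isocenter=iso,
                couch_deg=couch,
                gantry_start_deg=gantry_start,
                gantry_stop_deg=gantry_stop,
                rotation_direction=rotation,
                plan_mu=mu,
                dose_gy=dose,
                dose_source=source,
            )
        )
    if not beams:
        raise DicomError("plan contains no treatment beams")
    return beams, structures, dose_grids


def read_study(directory) -> PlanBundle:
    """Read a whole exported study (CT + RTPLAN + RTSTRUCT + RTDOSE) from a
    directory tree, matching objects by modality."""
    directory = Path(directory)
    plan_path = struct_path = None
    dose_paths: list[Path] = []
    ct_files = []
    for f in sorted(directory.rglob("*")):
        if not f.is_file():
            continue
        try:
            ds = pydicom.dcmread(f, stop_before_pixels=True)
        except Exception:
            continue
        modality = getattr(ds, "Modality", "")
        if modality == "CT":
            ct_files.append(f)
        elif modality == "RTPLAN":
            plan_path = f
        elif modality == "RTSTRUCT":
            struct_path = f
        elif modality == "RTDOSE":
            dose_paths.append(f)
    if not ct_files:
        raise DicomError(f"no CT series under {directory}")
    if plan_path is None or struct_path is None:
        raise DicomError(f"missing RT Plan or RT Structure Set under {directory}")

    ct = read_ct_series(ct_files[0].parent)
    beams, structures, dose_grids = read_plan(plan_path, dose_paths, struct_path)

    plan_ds = pydicom.dcmread(plan_path, stop_before_pixels=True)
    frame = str(getattr(plan_ds, "FrameOfReferenceUID", ""))
    if frame and ct.frame_of_reference_uid and frame != ct.frame_of_reference_uid:
        raise DicomError("RT Plan and CT use different frames of reference")
    return PlanBundle(
        ct=ct,
        structures=structures,
        beams=beams,
        dose_grids=dose_grids,
        patient_id=str(getattr(plan_ds, "PatientID", "")),
        plan_label=str(getattr(plan_ds, "RTPlanLabel", "")),
    )


# --------------------------------------------------------------------------
# Report writer
# --------------------------------------------------------------------------

REPORT_COLUMNS = [
    "beam_id",
    "cone_mm",
    "type",
    "plan_mu",
    "mu_nhc",
    "diff_nhc_pct",
    "mu_whc",
    "diff_whc_pct",
    "depth_mm",
    "eff_depth_mm",
]


def write_report(results, csv_path, txt_path=None, action_nhc=2.0, action_whc=5.0):
    """Write the per-beam MU comparison as CSV (+ optional text summary).

    ``results`` is a non-empty sequence of MUResult-like objects. Beams whose
    |Diff_NHC| exceeds ``action_nhc`` (homogeneous-equivalence level, %) or
    whose |Diff_WHC| exceeds ``action_whc`` (clinical tolerance, %) are
    flagged; flags are advisory. Returns the report DataFrame.
    """
    results = list(results)
    if not results:
        raise ValueError("results must be non-empty")
    rows = []
    for r in results:
        rows.append(
            {
                "beam_id": r.beam_id,
                "cone_mm": r.cone_mm,
                "type": "arc" if r.is_arc else "static",
                "plan_mu": r.plan_mu,
                "mu_nhc": r.mu_nhc,
                "diff_nhc_pct": r.diff_nhc_pct,
                "mu_whc": r.mu_whc,
                "diff_whc_pct": r.diff_whc_pct,
                "depth_mm": float(np.mean(r.depths_mm)),
                "eff_depth_mm": float(np.mean(r.eff_depths_mm)),
            }
        )
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    df.to_csv(csv_path, index=False, float_format="%.6g")

    if txt_path is not None:
        lines = ["Independent MU check report", "=" * 60]
        for row in rows:
            flags = []
            if abs(row["diff_nhc_pct"]) > action_nhc:
                flags.append(f"NHC>{action_nhc:g}%")
            if abs(row["diff_whc_pct"]) > action_whc:
                flags.append(f"WHC>{action_whc:g}%")
            lines.append(
                f"beam {row['beam_id']:<12} cone {row['cone_mm']:>5.1f} mm "
                f"{row['type']:<6} planMU {row['plan_mu']:9.2f}  "
                f"MU_NHC {row['mu_nhc']:9.2f} ({row['diff_nhc_pct']:+6.2f}%)  "
                f"MU_WHC {row['mu_whc']:9.2f} ({row['diff_whc_pct']:+6.2f}%)"
                + ("  ** " + ", ".join(flags) if flags else "")
            )
        lines.append("-" * 60)
        lines.append(
            "Diff_NHC mean +/- SD: "
            f"{df.diff_nhc_pct.mean():+.2f}% +/- {df.diff_nhc_pct.std(ddof=0):.2f}%"
        )
        lines.append(
            "Diff_WHC mean +/- SD: "
            f"{df.diff_whc_pct.mean():+.2f}% +/- {df.diff_whc_pct.std(ddof=0):.2f}%"
        )
        Path(txt_path).write_text("\n".join(lines) + "\n")
    return df
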