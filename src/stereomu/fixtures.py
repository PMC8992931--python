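"""Synthetic commissioning data and DICOM phantom studies.

Everything the calculator consumes can be generated here without any
external data: an analytic beam-data archive (TMR/OF tables with a
closed-form shape chosen for invertibility rather than radiological
realism) and DICOM studies of simple phantoms — a homogeneous cylinder, a
thorax-like phantom with a low-density (lung/cedarwood-like) and a
high-density (bone-like) insert plus a couch slab, and an ellipsoidal head
with a high-density shell.

Each generated study embeds a known answer: the per-beam isocenter dose is
computed *forward* from a chosen MU through the same dose model the
calculator inverts (without heterogeneity correction, mimicking a planning
system that assumes water), so the full pipeline has a known-answer
inverse.

Boundary voxels of the CT get partial-volume HU from 3x3 in-plane
supersampling, emulating the partial-volume averaging of a real scanner.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .beam_model import (
    AbsoluteCalibration,
    BeamDataArchive,
    ConeRecord,
    CTCalibrationCurve,
    TMRTable,
    equivalent_square,
    fit_correction_curve,
    of_at_tmrmax,
    resample_and_normalize_tmr,
)
from .dicom_io import ConeBeam, CTVolume, PlanBundle, StructureSet
from .exceptions import ConfigurationError, InputError
from .geometry import body_entry_parameter, ray_for_angles, segment_arc

_FIXED_DATE = "20220101"
_FIXED_TIME = "000000"

#: HU -> RED calibration used by all fixtures.
FIXTURE_CT_CURVE = CTCalibrationCurve(
    hu=np.array([-1000.0, 0.0, 1000.0, 3000.0]),
    red=np.array([0.0, 1.0, 1.6, 2.5]),
)


def hu_for_red(red: float) -> float:
    """HU that the fixture calibration curve maps to the requested RED."""
    return FIXTURE_CT_CURVE.hu_for_red(red)


# --------------------------------------------------------------------------
# Analytic beam data
# --------------------------------------------------------------------------

@dataclass
class SyntheticBeamSpec:
    """Parameters of the analytic beam model.

    TMR(d) = (d/dmax)^2 below dmax and exp(-mu*(d-dmax)) beyond it — peaked
    at 1 exactly at dmax and exactly invertible. ``mu_per_mm`` is the
    exponential attenuation coefficient; 0.004/mm gives the ~0.4 %/mm
    falloff typical of a 6 MV FFF beam at depth.
    """

    energy: str = "6FFF"
    dmax_mm: float = 15.0
    mu_per_mm: float = 0.004
    cone_diameters_mm: tuple[float, ...] = (4.0, 5.0, 7.5, 10.0, 12.5, 15.0, 17.5)
    sad_mm: float = 1000.0
    dr_ref_gy_per_mu: float = 0.01
    machine: str = "SyntheticTB"

    def __post_init__(self) -> None:
        if self.mu_per_mm <= 0:
            raise InputError("attenuation coefficient must be positive")
        if self.dmax_mm <= 0:
            raise InputError("dmax must be positive")

    def tmr(self, depth_mm):
        d = np.asarray(depth_mm, dtype=float)
        v = np.where(
            d < self.dmax_mm,
            (d / self.dmax_mm) ** 2,
            np.exp(-self.mu_per_mm * (d - self.dmax_mm)),
        )
        return np.maximum(v, 1e-4)

    def output_factor(self, cone_mm: float) -> float:
        # monotone in cone size, saturating below 1
        return 0.88 - 0.30 * math.exp(-0.12 * cone_mm)


def make_archive(spec: SyntheticBeamSpec | None = None) -> BeamDataArchive:
    """Build a fully analytic :class:`BeamDataArchive` from a spec."""
    spec = spec or SyntheticBeamSpec()
    depths = np.arange(0.0, 201.0, 1.0)
    cones: dict[float, ConeRecord] = {}
    for diam in spec.cone_diameters_mm:
        table = resample_and_normalize_tmr(
            depths, spec.tmr(depths), dmax=spec.dmax_mm, cone_id=diam
        )
        cones[diam] = ConeRecord(
            diameter_mm=diam, tmr=table, of=spec.output_factor(diam)
        )
    # a plausible correction-factor curve sampled at the cones' equivalent squares
    s = np.array([equivalent_square(d) for d in spec.cone_diameters_mm])
    k = 0.95 * np.exp(0.002 * s) + 0.10 * np.exp(-0.4 * s)
    fit = fit_correction_curve(np.column_stack([s, k]))
    return BeamDataArchive(
        machine=spec.machine,
        energy=spec.energy,
        cones=cones,
        output_geometry_ssd_mm=950.0,
        output_geometry_depth_mm=50.0,
        calibration=AbsoluteCalibration(
            dr_ref_gy_per_mu=spec.dr_ref_gy_per_mu,
            depth_mm=spec.dmax_mm,
            ssd_mm=spec.sad_mm - spec.dmax_mm,
            sad_mm=spec.sad_mm,
        ),
        ct_curve=CTCalibrationCurve(
            hu=FIXTURE_CT_CURVE.hu.copy(), red=FIXTURE_CT_CURVE.red.copy()
        ),
        correction_fit=fit,
    )


# --------------------------------------------------------------------------
# Phantoms
# --------------------------------------------------------------------------

@dataclass
class Insert:
    """A density insert inside the phantom body.

    Shapes: ``cylinder`` (axis along z; ``radius``, optional ``half_length``
    to truncate), ``sphere`` (``radius``), ``shell`` (ellipsoidal shell of
    ``thickness`` just inside the body surface).
    """

    shape: str
    hu: float
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius: float = 0.0
    half_length: Optional[float] = None
    thickness: float = 0.0

    @property
    def red(self) -> float:
        return FIXTURE_CT_CURVE.red_at(self.hu)


@dataclass
class CouchSlab:
    """A flat couch-like slab posterior to the body (outside the contour)."""

    y_top_mm: float
    thickness_mm: float
    width_mm: float
    hu: float


@dataclass
class PhantomSpec:
    """Geometric description of a synthetic phantom.

    ``semiaxes`` are (x, y, z) half-sizes in mm: for a cylinder the x/y pair
    is the elliptical cross-section and z the half-length; for an ellipsoid
    all three are semi-axes. Body material is water (HU 0); surroundings are
    air (HU -1000).
    """

    body_shape: str = "cylinder"  # 'cylinder' | 'ellipsoid'
    semiaxes: tuple[float, float, float] = (80.0, 80.0, 60.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    inserts: list[Insert] = field(default_factory=list)
    couch: Optional[CouchSlab] = None
    spacing_mm: float = 2.0
    margin_mm: float = 10.0
    name: str = "phantom"

    def __post_init__(self) -> None:
        if self.body_shape not in ("cylinder", "ellipsoid"):
            raise ConfigurationError(f"unknown body shape {self.body_shape!r}")
        if min(self.semiaxes) <= 0 or self.spacing_mm <= 0:
            raise ConfigurationError("semiaxes and spacing must be positive")
        for ins in self.inserts:
            off = np.asarray(ins.center) - np.asarray(self.center)
            frac = np.sum((off / np.asarray(self.semiaxes)) ** 2)
            if frac > 1.0:
                raise ConfigurationError(f"insert centre {ins.center} outside body")
            if not (FIXTURE_CT_CURVE.hu[0] <= ins.hu <= FIXTURE_CT_CURVE.hu[-1]):
                raise ConfigurationError(f"insert HU {ins.hu} outside calibration range")


def make_head_phantom(
    skull_thickness_mm: float = 6.0,
    semiaxes: tuple[float, float, float] = (70.0, 80.0, 70.0),
    shell_red: float = 1.6,
    spacing_mm: float = 2.0,
) -> PhantomSpec:
    """Ellipsoidal head: water interior inside a uniform high-RED shell.

    Supports tangential-vs-normal incidence experiments: a beam grazing the
    shell traverses much more bone-like path than a normally incident one.
    """
    if skull_thickness_mm < 0:
        raise InputError("shell thickness must be non-negative")
    if skull_thickness_mm >= min(semiaxes):
        raise InputError("shell thicker than the head radius")
    inserts = []
    if skull_thickness_mm > 0:
        inserts.append(
            Insert(
                shape="shell",
                hu=hu_for_red(shell_red),
                thickness=skull_thickness_mm,
            )
        )
    return PhantomSpec(
        body_shape="ellipsoid",
        semiaxes=semiaxes,
        inserts=inserts,
        spacing_mm=spacing_mm,
        name="head",
    )


_SUPERSAMPLE = 3  # in-plane subsamples per voxel edge (partial-volume HU)


def build_phantom(spec: PhantomSpec) -> tuple[CTVolume, StructureSet]:
    """Rasterize a phantom spec into a CT volume and its external contour."""
    dx = dy = dz = spec.spacing_mm
    cx, cy, cz = spec.center
    sx, sy, sz = spec.semiaxes

    x_ext = sx + spec.margin_mm
    y_lo = -(sy + spec.margin_mm)
    y_hi = sy + spec.margin_mm
    if spec.couch is not None:
        y_hi = max(y_hi, spec.couch.y_top_mm + spec.couch.thickness_mm + spec.margin_mm)
    ni = int(math.ceil(x_ext / dx))
    j_lo = -int(math.ceil(-y_lo / dy))
    j_hi = int(math.ceil(y_hi / dy))
    nk = int(math.floor(sz / dz + 1e-9)) + 1  # one margin slice each side

    xs = cx + dx * np.arange(-ni, ni + 1)
    ys = cy + dy * np.arange(j_lo, j_hi + 1)
    zs = cz + dz * np.arange(-nk, nk + 1)

    sub = (np.arange(_SUPERSAMPLE) - (_SUPERSAMPLE - 1) / 2.0) / _SUPERSAMPLE
    xs_sub = (xs[:, None] + dx * sub[None, :]).ravel()
    ys_sub = (ys[:, None] + dy * sub[None, :]).ravel()
    XS, YS = np.meshgrid(xs_sub, ys_sub)  # (nys, nxs)

    def downsample(f):
        nyy, nxx = len(ys), len(xs)
        return f.reshape(nyy, _SUPERSAMPLE, nxx, _SUPERSAMPLE).mean(axis=(1, 3))

    def body_fraction(z: float) -> np.ndarray:
        if spec.body_shape == "cylinder":
            if abs(z - cz) > sz + 1e-9:
                return np.zeros((len(ys), len(xs)))
            scale = 1.0
        else:
            t = 1.0 - ((z - cz) / sz) ** 2
            if t <= 0:
                return np.zeros((len(ys), len(xs)))
            scale = math.sqrt(t)
        f = ((XS - cx) / (sx * scale)) ** 2 + ((YS - cy) / (sy * scale)) ** 2 <= 1.0
        return downsample(f.astype(float))

    def insert_fraction(ins: Insert, z: float) -> np.ndarray:
        zero = np.zeros((len(ys), len(xs)))
        icx, icy, icz = ins.center
        if ins.shape == "cylinder":
            hl = ins.half_length if ins.half_length is not None else sz
            if abs(z - icz) > hl + 1e-9:
                return zero
            f = (XS - icx) ** 2 + (YS - icy) ** 2 <= ins.radius**2
            return downsample(f.astype(float))
        if ins.shape == "sphere":
            r2 = ins.radius**2 - (z - icz) ** 2
            if r2 <= 0:
                return zero
            f = (XS - icx) ** 2 + (YS - icy) ** 2 <= r2
            return downsample(f.astype(float))
        if ins.shape == "shell":
            # ellipsoidal shell hugging the body surface
            def ell(ax, ay, az):
                t = 1.0 - ((z - cz) / az) ** 2
                if t <= 0:
                    return np.zeros_like(XS, dtype=float)
                s = math.sqrt(t)
                return (
                    ((XS - cx) / (ax * s)) ** 2 + ((YS - cy) / (ay * s)) ** 2 <= 1.0
                ).astype(float)

            outer = ell(sx, sy, sz)
            inner = ell(sx - ins.thickness, sy - ins.thickness, sz - ins.thickness)
            return downsample(np.clip(outer - inner, 0.0, 1.0))
        raise ConfigurationError(f"unknown insert shape {ins.shape!r}")

    planes = []
    contours: list[np.ndarray] = []
    phi = np.linspace(0.0, 2.0 * math.pi, 181)[:-1]
    for z in zs:
        fb = body_fraction(z)
        hu = -1000.0 * (1.0 - fb)  # air outside, water inside
        for ins in spec.inserts:
            hu += ins.hu * insert_fraction(ins, z)
        if spec.couch is not None:
            c = spec.couch
            fc = downsample(
                (
                    (YS >= c.y_top_mm)
                    & (YS <= c.y_top_mm + c.thickness_mm)
                    & (np.abs(XS - cx) <= c.width_mm / 2.0)
                ).astype(float)
            )
            hu += (c.hu + 1000.0) * fc
        planes.append(np.rint(hu).astype(np.int16))

        # external contour of this slice
        if spec.body_shape == "cylinder":
            scale = 1.0 if abs(z - cz) <= sz + 1e-9 else 0.0
        else:
            t = 1.0 - ((z - cz) / sz) ** 2
            scale = math.sqrt(t) if t > 0 else 0.0
        if scale > 0:
            poly = np.column_stack(
                [
                    cx + sx * scale * np.cos(phi),
                    cy + sy * scale * np.sin(phi),
                    np.full_like(phi, z),
                ]
            )
            contours.append(poly)

    hu_vol = np.stack(planes, axis=0).astype(np.float32)
    ct = CTVolume(
        hu=hu_vol,
        origin=np.array([xs[0], ys[0], zs[0]]),
        spacing=np.array([dx, dy, dz]),
        col_dir=np.array([1.0, 0.0, 0.0]),
        row_dir=np.array([0.0, 1.0, 0.0]),
        slice_dir=np.array([0.0, 0.0, 1.0]),
    )
    sset = StructureSet(contours={"BODY": contours}, types={"BODY": "EXTERNAL"})
    return ct, sset


# --------------------------------------------------------------------------
# Beams and forward dose
# --------------------------------------------------------------------------

@dataclass
class BeamSpec:
    """A beam to embed in a generated study, with its known MU."""

    beam_id: str
    cone_mm: float
    mu: float
    gantry_start_deg: float
    gantry_stop_deg: Optional[float] = None
    rotation_direction: str = "NONE"
    couch_deg: float = 0.0
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)


def forward_dose(
    beam: BeamSpec,
    sset: StructureSet,
    archive: BeamDataArchive,
    resolution_deg: float = 1.0,
) -> float:
    """Isocenter dose (Gy) that ``beam.mu`` delivers under the water model.

    Uses the archive's own tables with the geometric depth (no heterogeneity
    correction) — the same model a cone planning system without density
    correction applies — so the calculator's MU_NHC inverts it exactly.
    """
    stop = beam.gantry_stop_deg if beam.gantry_stop_deg is not None else beam.gantry_start_deg
    angles = segment_arc(
        beam.gantry_start_deg, stop, beam.rotation_direction, resolution_deg
    )
    slices = sset.body_slices()
    sad = archive.calibration.sad_mm
    table = archive.cone(beam.cone_mm).tmr
    tmrs = []
    for g in angles:
        ray = ray_for_angles(np.asarray(beam.isocenter, float), g, beam.couch_deg, sad)
        t = body_entry_parameter(ray, slices)
        tmrs.append(table.lookup((1.0 - t) * sad))
    mean_tmr = float(np.mean(tmrs))
    return (
        beam.mu
        * archive.calibration.dr_ref_gy_per_mu
        * of_at_tmrmax(archive, beam.cone_mm)
        * mean_tmr
    )


# --------------------------------------------------------------------------
# DICOM writing
# --------------------------------------------------------------------------

def _uid(seed: int, *tags) -> str:
    return generate_uid(entropy_srcs=["stereomu", str(seed)] + [str(t) for t in tags])


def _fmt(values, ndigits=6):
    return [round(float(v), ndigits) for v in np.atleast_1d(values)]


def _base_dataset(sop_class: str, sop_uid: str, modality: str, seed: int) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = sop_uid
    ds.Modality = modality
    ds.PatientName = "Phantom^Synthetic"
    ds.PatientID = "STEREOMU-FIXTURE"
    ds.PatientBirthDate = ""
    ds.PatientSex = "O"
    ds.StudyDate = _FIXED_DATE
    ds.StudyTime = _FIXED_TIME
    ds.SeriesDate = _FIXED_DATE
    ds.InstanceCreationDate = _FIXED_DATE
    ds.InstanceCreationTime = _FIXED_TIME
    ds.Manufacturer = "stereomu synthetic fixtures"
    ds.ReferringPhysicianName = ""
    ds.AccessionNumber = ""
    ds.StudyID = "1"
    ds.StudyInstanceUID = _uid(seed, "study")
    ds.FrameOfReferenceUID = _uid(seed, "frame")
    ds.PositionReferenceIndicator = ""
    return ds


def write_ct_series(ct: CTVolume, directory, seed: int = 0) -> list[Path]:
    """Write the CT volume as one DICOM file per slice."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nk, nr, nc = ct.shape
    series_uid = _uid(seed, "ct-series")
    paths = []
    for k in range(nk):
        sop_uid = _uid(seed, "ct", k)
        ds = _base_dataset("1.2.840.10008.5.1.4.1.1.2", sop_uid, "CT", seed)
        ds.SeriesInstanceUID = series_uid
        ds.SeriesNumber = 1
        ds.InstanceNumber = k + 1
        ds.PatientPosition = ct.patient_position
        ds.ImageOrientationPatient = _fmt(np.concatenate([ct.col_dir, ct.row_dir]))
        ipp = ct.index_to_world(np.array([0.0, 0.0, float(k)]))
        ds.ImagePositionPatient = _fmt(ipp)
        ds.SliceThickness = round(float(ct.spacing[2]), 6)
        ds.PixelSpacing = [round(float(ct.spacing[1]), 6), round(float(ct.spacing[0]), 6)]
        ds.Rows = nr
        ds.Columns = nc
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1
        ds.RescaleIntercept = 0
        ds.RescaleType = "HU"
        ds.KVP = 120
        ds.PixelData = np.ascontiguousarray(
            np.rint(ct.hu[k]).astype("<i2")
        ).tobytes()
        path = directory / f"ct_{k:03d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def write_rtstruct(sset: StructureSet, ct: CTVolume, path, seed: int = 0) -> Path:
    path = Path(path)
    sop_uid = _uid(seed, "rtstruct")
    ds = _base_dataset("1.2.840.10008.5.1.4.1.1.481.3", sop_uid, "RTSTRUCT", seed)
    ds.SeriesInstanceUID = _uid(seed, "rtstruct-series")
    ds.SeriesNumber = 2
    ds.StructureSetLabel = "Synthetic"
    ds.StructureSetDate = _FIXED_DATE
    ds.StructureSetTime = _FIXED_TIME

    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    ds.RTROIObservationsSequence = []
    for num, (name, contours) in enumerate(sset.contours.items(), start=1):
        roi = Dataset()
        roi.ROINumber = num
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = ds.FrameOfReferenceUID
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        ds.StructureSetROISequence.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = num
        rc.ContourSequence = []
        for poly in contours:
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = len(poly)
            c.ContourData = _fmt(np.asarray(poly).ravel())
            rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)

        obs = Dataset()
        obs.ObservationNumber = num
        obs.ReferencedROINumber = num
        obs.RTROIInterpretedType = sset.types.get(name, "")
        obs.ROIInterpreter = ""
        ds.RTROIObservationsSequence.append(obs)
    ds.save_as(path, enforce_file_format=True)
    return path


def write_rtplan(
    beams: list[ConeBeam],
    path,
    seed: int = 0,
    sad_mm: float = 1000.0,
    energy: str = "6FFF",
) -> Path:
    path = Path(path)
    sop_uid = _uid(seed, "rtplan")
    ds = _base_dataset("1.2.840.10008.5.1.4.1.1.481.5", sop_uid, "RTPLAN", seed)
    ds.SeriesInstanceUID = _uid(seed, "rtplan-series")
    ds.SeriesNumber = 3
    ds.RTPlanLabel = "SyntheticPlan"
    ds.RTPlanDate = _FIXED_DATE
    ds.RTPlanTime = _FIXED_TIME
    ds.RTPlanGeometry = "PATIENT"

    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = 1
    fg.NumberOfBeams = len(beams)
    fg.NumberOfBrachyApplicationSetups = 0
    fg.ReferencedBeamSequence = []
    ds.FractionGroupSequence = [fg]

    ds.BeamSequence = []
    for beam in beams:
        rb = Dataset()
        rb.ReferencedBeamNumber = beam.beam_number
        rb.BeamMeterset = round(float(beam.plan_mu), 8)
        rb.BeamDose = round(float(beam.dose_gy), 10)
        rb.BeamDoseSpecificationPoint = _fmt(beam.isocenter)
        fg.ReferencedBeamSequence.append(rb)

        b = Dataset()
        b.BeamNumber = beam.beam_number
        b.BeamName = beam.beam_id
        b.BeamType = "STATIC" if beam.rotation_direction == "NONE" else "DYNAMIC"
        b.RadiationType = "PHOTON"
        b.TreatmentMachineName = "SyntheticTB"
        b.TreatmentDeliveryType = "TREATMENT"
        b.SourceAxisDistance = round(float(sad_mm), 6)
        b.FinalCumulativeMetersetWeight = 1.0
        b.NumberOfWedges = 0
        b.NumberOfCompensators = 0
        b.NumberOfBoli = 0
        b.NumberOfBlocks = 0

        app = Dataset()
        app.ApplicatorID = f"{beam.cone_mm:g}mm"
        app.ApplicatorType = "STEREOTACTIC"
        b.ApplicatorSequence = [app]

        cp0 = Dataset()
        cp0.ControlPointIndex = 0
        cp0.NominalBeamEnergy = 6
        cp0.GantryAngle = round(float(beam.gantry_start_deg), 6)
        cp0.GantryRotationDirection = beam.rotation_direction
        cp0.PatientSupportAngle = round(float(beam.couch_deg), 6)
        cp0.PatientSupportRotationDirection = "NONE"
        cp0.BeamLimitingDeviceAngle = 0
        cp0.BeamLimitingDeviceRotationDirection = "NONE"
        cp0.IsocenterPosition = _fmt(beam.isocenter)
        cp0.CumulativeMetersetWeight = 0.0

        cp1 = Dataset()
        cp1.ControlPointIndex = 1
        cp1.GantryAngle = round(float(beam.gantry_stop_deg), 6)
        cp1.GantryRotationDirection = "NONE"
        cp1.CumulativeMetersetWeight = 1.0

        b.ControlPointSequence = [cp0, cp1]
        b.NumberOfControlPoints = 2
        ds.BeamSequence.append(b)
    ds.save_as(path, enforce_file_format=True)
    return path


def write_rtdose_for_beam(
    beam: ConeBeam,
    plan_sop_uid: str,
    path,
    seed: int = 0,
    grid_half_extent_mm: float = 20.0,
    grid_spacing_mm: float = 2.0,
) -> Path:
    """Write a small per-beam (BEAM summation) dose grid, uniform at the
    beam's isocenter dose — enough to exercise the grid-sampling fallback."""
    path = Path(path)
    sop_uid = _uid(seed, "rtdose", beam.beam_number)
    ds = _base_dataset("1.2.840.10008.5.1.4.1.1.481.2", sop_uid, "RTDOSE", seed)
    ds.SeriesInstanceUID = _uid(seed, "rtdose-series")
    ds.SeriesNumber = 4
    ds.InstanceNumber = beam.beam_number

    n = int(2 * grid_half_extent_mm / grid_spacing_mm) + 1
    scale = float(beam.dose_gy) / 1.0e6
    values = np.full((n, n, n), 1.0e6, dtype="<u4")
    origin = np.asarray(beam.isocenter, float) - grid_half_extent_mm

    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.ImagePositionPatient = _fmt(origin)
    ds.PixelSpacing = [round(grid_spacing_mm, 6)] * 2
    ds.GridFrameOffsetVector = _fmt(grid_spacing_mm * np.arange(n))
    ds.NumberOfFrames = n
    ds.FrameIncrementPointer = pydicom.tag.Tag(0x3004, 0x000C)
    ds.Rows = n
    ds.Columns = n
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "BEAM"
    ds.DoseGridScaling = scale

    rp = Dataset()
    rp.ReferencedSOPClassUID = "1.2.840.10008.5.1.4.1.1.481.5"
    rp.ReferencedSOPInstanceUID = plan_sop_uid
    rfg = Dataset()
    rfg.ReferencedFractionGroupNumber = 1
    rbeam = Dataset()
    rbeam.ReferencedBeamNumber = beam.beam_number
    rfg.ReferencedBeamSequence = [rbeam]
    rp.ReferencedFractionGroupSequence = [rfg]
    ds.ReferencedRTPlanSequence = [rp]

    ds.PixelData = np.ascontiguousarray(values).tobytes()
    ds.save_as(path, enforce_file_format=True)
    return path


# --------------------------------------------------------------------------
# Studies
# --------------------------------------------------------------------------

def make_study(
    phantom: PhantomSpec,
    beams: list[BeamSpec],
    archive: BeamDataArchive,
    out_dir,
    seed: int = 0,
    resolution_deg: float = 1.0,
    write_dose_grids: bool = True,
) -> PlanBundle:
    """Generate a phantom study on disk and return the in-memory bundle.

    Writes a CT series, RT Structure Set (EXTERNAL contour), RT Plan with
    cone applicator beams, and per-beam RT Dose grids. The per-beam
    isocenter dose is forward-computed from each beam's chosen MU (see
    :func:`forward_dose`), giving the pipeline a known-answer inverse.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ct, sset = build_phantom(phantom)

    cone_beams = []
    for i, spec in enumerate(beams, start=1):
        archive.cone(spec.cone_mm)  # raises LookupError if unknown
        dose = forward_dose(spec, sset, archive, resolution_deg)
        stop = spec.gantry_stop_deg if spec.gantry_stop_deg is not None else spec.gantry_start_deg
        cone_beams.append(
            ConeBeam(
                beam_id=spec.beam_id,
                beam_number=i,
                cone_mm=spec.cone_mm,
                isocenter=np.asarray(spec.isocenter, float),
                couch_deg=spec.couch_deg,
                gantry_start_deg=spec.gantry_start_deg,
                gantry_stop_deg=stop,
                rotation_direction=spec.rotation_direction,
                plan_mu=spec.mu,
                dose_gy=dose,
            )
        )

    write_ct_series(ct, out_dir / "ct", seed=seed)
    write_rtstruct(sset, ct, out_dir / "rtstruct.dcm", seed=seed)
    plan_path = write_rtplan(
        cone_beams, out_dir / "rtplan.dcm", seed=seed, sad_mm=archive.calibration.sad_mm
    )
    if write_dose_grids:
        plan_uid = _uid(seed, "rtplan")
        for beam in cone_beams:
            write_rtdose_for_beam(
                beam, plan_uid, out_dir / f"rtdose_beam{beam.beam_number}.dcm", seed=seed
            )
    return PlanBundle(ct=ct, structures=sset, beams=cone_beams)


# -- the named validation scenarios ----------------------------------------

def homogeneous_phantom(spacing_mm: float = 2.0) -> PhantomSpec:
    """Homogeneous water cylinder (radius 80 mm, half-length 60 mm)."""
    return PhantomSpec(
        body_shape="cylinder",
        semiaxes=(80.0, 80.0, 60.0),
        spacing_mm=spacing_mm,
        name="homogeneous",
    )


def homogeneous_beams() -> list[BeamSpec]:
    """Three static fields and three arcs on the homogeneous cylinder."""
    return [
        BeamSpec("S-g90", 10.0, 150.0, 90.0),
        BeamSpec("S-g180", 5.0, 175.0, 180.0),
        BeamSpec("S-g45-c30", 17.5, 180.0, 45.0, couch_deg=30.0),
        BeamSpec("A-0-180", 10.0, 200.0, 0.0, 180.0, "CW"),
        BeamSpec("A-180-0", 5.0, 220.0, 180.0, 0.0, "CC"),
        BeamSpec("A-350-10", 17.5, 120.0, 350.0, 10.0, "CW"),
    ]


def thorax_phantom(spacing_mm: float = 2.0) -> PhantomSpec:
    """Thorax-like elliptical phantom with lung and bone inserts + couch.

    A low-density cylinder (RED ~ 0.45, cedarwood-like) sits in each lung
    position; a high-density cylinder (RED ~ 1.3, bone-like) sits in the
    vertebra position; a thin low-density couch slab lies posterior to the
    body.
    """
    lung_hu = hu_for_red(0.45)
    bone_hu = hu_for_red(1.3)
    return PhantomSpec(
        body_shape="cylinder",
        semiaxes=(100.0, 75.0, 30.0),
        inserts=[
            Insert("cylinder", hu=lung_hu, center=(45.0, 0.0, 0.0), radius=15.0),
            Insert("cylinder", hu=lung_hu, center=(-45.0, 0.0, 0.0), radius=15.0),
            Insert("cylinder", hu=bone_hu, center=(0.0, 55.0, 0.0), radius=12.0),
        ],
        couch=CouchSlab(y_top_mm=80.0, thickness_mm=10.0, width_mm=220.0, hu=-750.0),
        spacing_mm=spacing_mm,
        name="thorax",
    )


def thorax_beams(cone_mm: float = 10.0) -> list[BeamSpec]:
    """The three heterogeneity-validation fields: lateral through the
    low-density insert, posterior through the bone insert, and the
    0 -> 180 deg clockwise arc crossing both."""
    return [
        BeamSpec("S-90-lung", cone_mm, 200.0, 90.0),
        BeamSpec("S-180-bone", cone_mm, 200.0, 180.0),
        BeamSpec("A-0-180", cone_mm, 250.0, 0.0, 180.0, "CW"),
    ]


_SCENARIOS = {
    "homogeneous": (homogeneous_phantom, homogeneous_beams),
    "thorax": (thorax_phantom, thorax_beams),
    "head": (make_head_phantom, None),
}


def make_scenario(
    name: str, out_dir, seed: int = 0, spacing_mm: float = 2.0
) -> PlanBundle:
    """Write a named validation scenario (study + archive JSON) to disk."""
    if name not in _SCENARIOS:
        raise ConfigurationError(
            f"unknown scenario {name!r}; choose from {sorted(_SCENARIOS)}"
        )
    out_dir = Path(out_dir)
    archive = make_archive(SyntheticBeamSpec())
    phantom_fn, beams_fn = _SCENARIOS[name]
    if name == "head":
        phantom = phantom_fn(spacing_mm=spacing_mm)
        beams = [
            BeamSpec("S-0-normal", 10.0, 150.0, 0.0),
            BeamSpec("A-0-180", 10.0, 200.0, 0.0, 180.0, "CW"),
        ]
    else:
        phantom = phantom_fn(spacing_mm=spacing_mm)
        beams = beams_fn()
    bundle = make_study(phantom, beams, archive, out_dir, seed=seed)
    archive.save(out_dir / "archive.json")
    return bundle
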