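"""Beam geometry: source placement, arc segmentation, depth along the CAX.

The MU formalism used here is one-dimensional: every quantity is evaluated
along the central axis (CAX), the straight line from the radiation source to
the isocenter. Two depths are needed per incident angle:

* the *geometric depth* ``d`` — distance from the point where the CAX first
  pierces the external (body) contour to the isocenter, used when the
  patient is assumed water-equivalent; and
* the *effective depth* ``deff`` (equivalent path length, EPL) — the
  RED-weighted path, sum over traversed CT voxels of RED(HU_i) * x_i where
  x_i is the exact intersection length of the ray with voxel i.

Voxel intersection lengths come from an exact boundary-crossing (Siddon
style) traversal, not fixed-step sampling. The body surface is intersected
with the external-contour polygon stack directly, which resolves the entry
point below voxel resolution.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from matplotlib.path import Path as MplPath

from .dicom_io import CTVolume, StructureSet
from .beam_model import CTCalibrationCurve
from .exceptions import GeometryError, InputError

_EPS = 1e-12


# --------------------------------------------------------------------------
# Rays and angles
# --------------------------------------------------------------------------

@dataclass
class BeamRay:
    """A source -> isocenter ray in the patient (LPS) frame."""

    source: np.ndarray
    isocenter: np.ndarray
    direction: np.ndarray  # unit, source -> isocenter
    gantry_deg: float
    couch_deg: float
    sad_mm: float


def ray_for_angles(isocenter, gantry_deg: float, couch_deg: float, sad_mm: float = 1000.0) -> BeamRay:
    """Place the source at distance SAD from the isocenter per IEC 61217.

    For a head-first supine patient: gantry 0 deg puts the source anterior
    (LPS offset (0, -SAD, 0)), gantry 90 deg on the patient's left
    ((+SAD, 0, 0)); a couch rotation turns the gantry plane about the
    patient's vertical (anterior-posterior) axis.
    """
    if sad_mm <= 0:
        raise InputError("SAD must be positive")
    iso = np.asarray(isocenter, dtype=float)
    g = math.radians(gantry_deg)
    c = math.radians(couch_deg)
    offset = np.array(
        [
            math.sin(g) * math.cos(c),
            -math.cos(g),
            -math.sin(g) * math.sin(c),
        ]
    )
    source = iso + sad_mm * offset
    return BeamRay(
        source=source,
        isocenter=iso,
        direction=-offset,
        gantry_deg=float(gantry_deg),
        couch_deg=float(couch_deg),
        sad_mm=float(sad_mm),
    )


def segment_arc(
    gantry_start_deg: float,
    gantry_stop_deg: float,
    rotation_direction: str = "CW",
    resolution_deg: float = 1.0,
) -> np.ndarray:
    """Incident gantry angles of an arc, both endpoints included.

    Angles are normalized to [0, 360); CW means increasing IEC gantry angle,
    wrapping through 360 -> 0 as needed. A static beam (direction 'NONE' or
    start == stop) yields exactly one angle.
    """
    if resolution_deg <= 0:
        raise InputError("arc resolution must be positive")
    start = float(gantry_start_deg) % 360.0
    stop = float(gantry_stop_deg) % 360.0
    if rotation_direction == "NONE" or math.isclose(start, stop):
        return np.array([start])
    if rotation_direction == "CW":
        span = (stop - start) % 360.0
        sign = 1.0
    elif rotation_direction == "CC":
        span = (start - stop) % 360.0
        sign = -1.0
    else:
        raise InputError(f"unknown rotation direction {rotation_direction!r}")
    n = int(math.floor(span / resolution_deg + 1e-9))
    angles = (start + sign * resolution_deg * np.arange(n + 1)) % 360.0
    if not math.isclose((angles[-1] - stop) % 360.0, 0.0, abs_tol=1e-9):
        angles = np.append(angles, stop)
    return angles


# --------------------------------------------------------------------------
# Voxel traversal (Siddon)
# --------------------------------------------------------------------------

def traverse(ct: CTVolume, p0, p1, t_lo: float = 0.0, t_hi: float = 1.0):
    """Exact voxel traversal of the segment p0 -> p1 through the CT grid.

    Returns ``(t_edges, idx, lengths)``: sorted boundary parameters within
    the part of [t_lo, t_hi] inside the volume, the (c, r, k) integer index
    of the voxel between consecutive edges, and the segment length in mm
    inside each voxel.
    """
    a0 = ct.world_to_index(np.asarray(p0, float))
    a1 = ct.world_to_index(np.asarray(p1, float))
    d = a1 - a0
    nk, nr, nc = ct.shape
    dims = np.array([nc, nr, nk], dtype=float)

    tmin, tmax = float(t_lo), float(t_hi)
    for ax in range(3):
        if abs(d[ax]) < _EPS:
            if not (-0.5 <= a0[ax] <= dims[ax] - 0.5):
                return np.empty(0), np.empty((0, 3), int), np.empty(0)
        else:
            ta = (-0.5 - a0[ax]) / d[ax]
            tb = (dims[ax] - 0.5 - a0[ax]) / d[ax]
            tmin = max(tmin, min(ta, tb))
            tmax = min(tmax, max(ta, tb))
    if tmin >= tmax:
        return np.empty(0), np.empty((0, 3), int), np.empty(0)

    ts = [np.array([tmin, tmax])]
    for ax in range(3):
        if abs(d[ax]) < _EPS:
            continue
        v0 = a0[ax] + tmin * d[ax]
        v1 = a0[ax] + tmax * d[ax]
        lo, hi = min(v0, v1), max(v0, v1)
        m_lo = math.ceil(lo - 0.5)
        m_hi = math.floor(hi - 0.5)
        if m_hi < m_lo:
            continue
        planes = np.arange(m_lo, m_hi + 1) + 0.5
        t = (planes - a0[ax]) / d[ax]
        ts.append(t[(t > tmin) & (t < tmax)])
    t_edges = np.unique(np.concatenate(ts))
    mids = a0[None, :] + 0.5 * (t_edges[:-1] + t_edges[1:])[:, None] * d[None, :]
    idx = np.floor(mids + 0.5).astype(int)
    idx = np.clip(idx, 0, (dims - 1).astype(int))
    length = float(np.linalg.norm(np.asarray(p1, float) - np.asarray(p0, float)))
    lengths = np.diff(t_edges) * length
    return t_edges, idx, lengths


# --------------------------------------------------------------------------
# Body surface intersection
# --------------------------------------------------------------------------

def _point_in_polys(point_xy, polys) -> bool:
    inside = False
    for poly in polys:
        inside ^= bool(
            MplPath(poly, closed=True).contains_point(tuple(point_xy))
        )
    return inside


def _inside_body(point, body_slices) -> bool:
    z = point[2]
    best = None
    for zlo, zhi, polys in body_slices:
        zc = 0.5 * (zlo + zhi)
        d = abs(z - zc)
        if best is None or d < best[0]:
            best = (d, zlo, zhi, polys)
    if best is None:
        return False
    d, zlo, zhi, polys = best
    if not (zlo - 1e-9 <= z <= zhi + 1e-9):
        return False
    return _point_in_polys(point[:2], polys)


def body_entry_parameter(ray: BeamRay, body_slices) -> float:
    """Parameter t in [0, 1] where the CAX first enters the body.

    The body is the stack of external-contour polygons, each extruded over
    one slice thickness; the crossing is located exactly by intersecting the
    2-D ray projection with the polygon edges (sub-voxel resolution).
    Raises if the ray misses the body or the isocenter lies outside it.
    """
    p0 = ray.source
    d3 = ray.isocenter - p0
    cands = [0.0, 1.0]
    for zlo, zhi, polys in body_slices:
        if abs(d3[2]) < _EPS:
            if not (zlo <= p0[2] <= zhi):
                continue
            ta, tb = 0.0, 1.0
        else:
            t1 = (zlo - p0[2]) / d3[2]
            t2 = (zhi - p0[2]) / d3[2]
            ta, tb = min(t1, t2), max(t1, t2)
            ta, tb = max(ta, 0.0), min(tb, 1.0)
            if ta >= tb:
                continue
        cands.extend((ta, tb))
        dxy = d3[:2]
        for poly in polys:
            a = poly
            b = np.roll(poly, -1, axis=0)
            e = b - a
            denom = dxy[0] * e[:, 1] - dxy[1] * e[:, 0]
            ok = np.abs(denom) > _EPS
            if not np.any(ok):
                continue
            ap = a - p0[:2]
            t = (ap[:, 0] * e[:, 1] - ap[:, 1] * e[:, 0]) / np.where(ok, denom, 1.0)
            u = (ap[:, 0] * dxy[1] - ap[:, 1] * dxy[0]) / np.where(ok, denom, 1.0)
            # tolerant u-window so a ray through a shared vertex is kept
            # (duplicate candidates collapse in the sorted walk)
            hit = ok & (u >= -1e-9) & (u <= 1.0 + 1e-9) & (t > ta) & (t < tb)
            cands.extend(t[hit].tolist())

    t_edges = np.unique(np.asarray(cands))
    entry = None
    last_inside = False
    for i in range(len(t_edges) - 1):
        tm = 0.5 * (t_edges[i] + t_edges[i + 1])
        inside = _inside_body(p0 + tm * d3, body_slices)
        if inside and entry is None:
            entry = t_edges[i]
        last_inside = inside
    if not last_inside and not _inside_body(ray.isocenter, body_slices):
        raise GeometryError("isocenter is outside the external contour")
    if entry is None:
        raise GeometryError("ray does not intersect the external contour")
    return float(entry)


# --------------------------------------------------------------------------
# Depths
# --------------------------------------------------------------------------

@dataclass
class DepthResult:
    """Geometric and effective depth of one incident angle."""

    d_mm: float
    deff_mm: float
    entry_point: np.ndarray
    voxel_count: int
    in_body_path_mm: float


def geometric_depth(ray: BeamRay, body) -> float:
    """Distance (mm) from the proximal body-surface crossing to the isocenter.

    ``body`` is either a :class:`StructureSet` (exact contour intersection)
    or a ``(mask, ct)`` pair (first in-mask voxel along the traversal).
    """
    length = float(np.linalg.norm(ray.isocenter - ray.source))
    if isinstance(body, StructureSet):
        t = body_entry_parameter(ray, body.body_slices())
        return (1.0 - t) * length
    mask, ct = body
    _, idx, lengths = traverse(ct, ray.source, ray.isocenter)
    if len(idx) == 0:
        raise GeometryError("ray does not intersect the CT volume")
    inside = mask[idx[:, 2], idx[:, 1], idx[:, 0]]
    if not inside[-1]:
        raise GeometryError("isocenter is outside the body mask")
    hits = np.flatnonzero(inside)
    if len(hits) == 0:
        raise GeometryError("ray does not intersect the body mask")
    t_entry = 1.0 - lengths[hits[0]:].sum() / length
    return (1.0 - t_entry) * length


def effective_depth(
    ray: BeamRay,
    ct: CTVolume,
    curve: CTCalibrationCurve,
    body=None,
    include_couch: bool = True,
    entry_t: Optional[float] = None,
) -> float:
    """Equivalent path length (mm): sum of RED(HU_i) * x_i along the CAX.

    With ``include_couch`` on, accumulation starts at the proximal CT volume
    face, so couch structures upstream of the skin contribute through their
    HU (air contributes ~0). With it off, accumulation starts at the exact
    body-surface entry point, which excludes anything upstream of the skin.
    """
    if entry_t is None and not include_couch:
        if body is None:
            raise InputError("need the body (StructureSet) when include_couch is off")
        entry_t = body_entry_parameter(ray, body.body_slices())
    t_lo = 0.0 if include_couch else float(entry_t)
    t_edges, idx, lengths = traverse(ct, ray.source, ray.isocenter, t_lo=t_lo)
    if len(idx) == 0 or t_edges[-1] < 1.0 - 1e-9:
        raise GeometryError("insufficient CT coverage: ray exits the volume before the isocenter")
    if entry_t is not None and t_edges[0] > entry_t + 1e-9:
        raise GeometryError("insufficient CT coverage: body surface outside the scan")
    red = curve.red_at(ct.hu[idx[:, 2], idx[:, 1], idx[:, 0]])
    return float(np.sum(red * lengths))


def compute_depths(
    ray: BeamRay,
    ct: CTVolume,
    curve: CTCalibrationCurve,
    structures: StructureSet,
    include_couch: bool = True,
    mask: Optional[np.ndarray] = None,
) -> DepthResult:
    """Geometric and effective depth for one ray, sharing the traversal."""
    length = float(np.linalg.norm(ray.isocenter - ray.source))
    entry_t = body_entry_parameter(ray, structures.body_slices())
    d = (1.0 - entry_t) * length

    t_lo = 0.0 if include_couch else entry_t
    t_edges, idx, lengths = traverse(ct, ray.source, ray.isocenter, t_lo=t_lo)
    if len(idx) == 0 or t_edges[-1] < 1.0 - 1e-9:
        raise GeometryError("insufficient CT coverage: ray exits the volume before the isocenter")
    if t_edges[0] > entry_t + 1e-9:
        raise GeometryError("insufficient CT coverage: body surface outside the scan")
    red = curve.red_at(ct.hu[idx[:, 2], idx[:, 1], idx[:, 0]])
    deff = float(np.sum(red * lengths))

    in_body = float("nan")
    if mask is not None:
        sel = mask[idx[:, 2], idx[:, 1], idx[:, 0]]
        in_body = float(np.sum(lengths[sel]))
    return DepthResult(
        d_mm=d,
        deff_mm=deff,
        entry_point=ray.source + entry_t * (ray.isocenter - ray.source),
        voxel_count=int(len(idx)),
        in_body_path_mm=in_body,
    )
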