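"""Commissioning beam data and small-field dosimetry primitives.

This module houses everything a medical physicist feeds the calculator at
commissioning time: per-cone tissue-maximum-ratio (TMR) tables, output
factors (OF), the absolute calibration (reference dose rate DRref), the
CT-number -> relative-electron-density (RED) calibration curve, and the
two-term exponential fit used to interpolate/extrapolate small-field output
correction factors over equivalent square field size.

All of it is bundled into a :class:`BeamDataArchive` — one archive per
machine + energy — which serializes to a documented JSON container.

Units: millimetres for all lengths, degrees for angles, Gy/MU for DRref.
"""
from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .exceptions import ConfigurationError, FitError, InputError

log = logging.getLogger(__name__)

ARCHIVE_FORMAT_VERSION = 1

#: Phantom-scatter ratio used in the TMR <-> PDD conversion. For the very
#: small circular fields handled here the phantom scatter factor is taken as
#: depth-independent, so the ratio is unity; kept as a named constant so the
#: assumption is explicit and revisitable.
PHANTOM_SCATTER_RATIO = 1.0


def equivalent_square(cone_diameter_mm: float) -> float:
    """Side length (mm) of the square field with the same area as a circle.

    For a circular field of FWHM diameter ``D`` (radius ``r = D/2``) the
    equal-area square has side ``s = r * sqrt(pi)``; e.g. the 4 mm cone maps
    to a 3.54 mm square.
    """
    if cone_diameter_mm <= 0:
        raise InputError(f"cone diameter must be positive, got {cone_diameter_mm}")
    return 0.5 * cone_diameter_mm * math.sqrt(math.pi)


# --------------------------------------------------------------------------
# TMR
# --------------------------------------------------------------------------

@dataclass
class TMRTable:
    """Depth-indexed tissue-maximum ratios for one cone.

    ``values[depths == dmax] == 1`` after normalization. The grid is expected
    at 1 mm spacing (see :func:`resample_and_normalize_tmr`). Lookups below
    the first tabulated depth clamp to the first value (surface proximity the
    1D model cannot represent); lookups beyond the last tabulated depth are
    log-linearly extrapolated from the last two grid points, since TMR decays
    near-exponentially at depth.
    """

    cone_id: float
    depths: np.ndarray
    values: np.ndarray
    dmax: float

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.depths.ndim != 1 or self.depths.shape != self.values.shape:
            raise InputError("depths and values must be 1-D arrays of equal length")
        if self.depths.size < 2:
            raise InputError("TMR table needs at least two points")
        if not np.all(np.diff(self.depths) > 0):
            raise InputError("TMR depths must be strictly increasing")
        if not np.all(self.values > 0):
            raise InputError("TMR values must be positive")
        if not (self.depths[0] <= self.dmax <= self.depths[-1]):
            raise InputError(
                f"dmax={self.dmax} outside tabulated range "
                f"[{self.depths[0]}, {self.depths[-1]}]"
            )

    def lookup(self, depth):
        """Linear interpolation on the grid; see class docstring for tails."""
        d = np.asarray(depth, dtype=float)
        if np.any(d < 0):
            raise InputError("depth must be non-negative")
        out = np.interp(d, self.depths, self.values)
        beyond = d > self.depths[-1]
        if np.any(beyond):
            # log-linear continuation from the last two nodes
            slope = (math.log(self.values[-1]) - math.log(self.values[-2])) / (
                self.depths[-1] - self.depths[-2]
            )
            out = np.where(
                beyond, self.values[-1] * np.exp(slope * (d - self.depths[-1])), out
            )
        if np.any(d < self.depths[0]):
            log.warning(
                "TMR lookup below first tabulated depth (%.1f mm); clamping",
                self.depths[0],
            )
        return float(out) if np.isscalar(depth) or np.ndim(depth) == 0 else out


def resample_and_normalize_tmr(
    raw_depths,
    raw_values,
    dmax: float,
    cone_id: float = 0.0,
    smooth_window: Optional[int] = None,
) -> TMRTable:
    """Resample a measured TMR curve to a 1 mm grid and normalize at dmax.

    Values are linearly interpolated onto an integer-millimetre grid spanning
    the measured range, optionally smoothed with a centred moving average of
    odd width ``smooth_window``, then divided by the (smoothed) value at
    ``dmax`` so that TMR(dmax) = 1.
    """
    raw_depths = np.asarray(raw_depths, dtype=float)
    raw_values = np.asarray(raw_values, dtype=float)
    if raw_depths.ndim != 1 or raw_depths.shape != raw_values.shape:
        raise InputError("raw depths/values must be matching 1-D arrays")
    if not np.all(np.diff(raw_depths) > 0):
        raise InputError("raw depths must be strictly increasing")
    if not (raw_depths[0] <= dmax <= raw_depths[-1]):
        raise InputError(f"dmax={dmax} outside the measured depth range")

    lo = math.ceil(raw_depths[0] - 1e-9)
    hi = math.floor(raw_depths[-1] + 1e-9)
    grid = np.arange(lo, hi + 1, 1.0)
    vals = np.interp(grid, raw_depths, raw_values)

    if smooth_window is not None:
        w = int(smooth_window)
        if w < 1 or w % 2 == 0:
            raise InputError("smooth_window must be a positive odd integer")
        if w > 1:
            pad = w // 2
            padded = np.pad(vals, pad, mode="edge")
            vals = np.convolve(padded, np.ones(w) / w, mode="valid")

    norm = np.interp(dmax, grid, vals)
    if norm <= 0:
        raise InputError("TMR value at dmax must be positive")
    vals = vals / norm
    return TMRTable(cone_id=cone_id, depths=grid, values=vals, dmax=float(dmax))


def tmr_lookup(table: TMRTable, depth) -> float:
    """Functional alias for :meth:`TMRTable.lookup`."""
    return table.lookup(depth)


def tmr_to_pdd(table: TMRTable, ssd_mm: float, depth_mm) -> float:
    """Percentage depth dose derived from TMR.

    PDD(d, SSD, S) = 100 * TMR(d, S) * ((SSD + dmax) / (SSD + d))^2, with the
    phantom-scatter ratio taken as unity for small cone fields.
    """
    if ssd_mm <= 0:
        raise InputError("SSD must be positive")
    d = np.asarray(depth_mm, dtype=float)
    pdd = (
        100.0
        * table.lookup(depth_mm)
        * ((ssd_mm + table.dmax) / (ssd_mm + d)) ** 2
        * PHANTOM_SCATTER_RATIO
    )
    return float(pdd) if np.ndim(depth_mm) == 0 else pdd


# --------------------------------------------------------------------------
# Output factors and the correction-factor fit
# --------------------------------------------------------------------------

@dataclass
class OutputFactorTable:
    """Output factors (reading ratio vs. the 10x10 cm^2 reference field).

    ``cones`` maps nominal cone diameter (mm) to OF. The measurement geometry
    (SSD and depth of the water-tank readings) is recorded because the
    conversion to OF at TMR-max depends on it.
    """

    cones: dict[float, float]
    ssd_mm: float = 950.0
    depth_mm: float = 50.0

    def __post_init__(self) -> None:
        if not self.cones:
            raise ConfigurationError("output factor table has no cones")
        for c, of in self.cones.items():
            if not (0.0 < of < 1.0):
                raise ConfigurationError(
                    f"output factor for cone {c} mm must lie in (0, 1), got {of}"
                )


_TWO_TERM_INITS = (
    # fixed multi-start seed list for the two-term exponential fit
    (1.0, 0.001, 0.01, -0.1),
    (0.9, 0.005, 0.1, -0.3),
    (1.05, -0.001, -0.05, -0.2),
    (0.5, 0.01, 0.5, -0.05),
    (1.0, 0.0, 0.001, -0.01),
    (0.2, 0.05, 0.8, -0.005),
    (1.1, -0.005, 0.2, -0.5),
)


def _two_term_exp(s, a, b, c, d):
    return a * np.exp(b * s) + c * np.exp(d * s)


@dataclass
class CorrectionFactorFit:
    """Two-term exponential fit k(s) = a*e^(b*s) + c*e^(d*s).

    Models the field-output correction factor as a function of equivalent
    square field size s (mm); supports extrapolation below the smallest
    fitted s (needed for the 4 mm cone, whose 3.54 mm equivalent square lies
    below tabulated correction-factor data).
    """

    a: float
    b: float
    c: float
    d: float
    r_squared: float = float("nan")

    def __call__(self, s):
        s = np.asarray(s, dtype=float)
        k = _two_term_exp(s, self.a, self.b, self.c, self.d)
        return float(k) if k.ndim == 0 else k


def fit_correction_curve(points) -> CorrectionFactorFit:
    """Least-squares fit of correction-factor points to a two-term exponential.

    ``points`` is a sequence of (s_mm, k) pairs; at least 5 points with
    distinct positive s are required (4 parameters). A fixed list of starting
    quadruples is tried; the fit with the lowest residual wins (ties broken
    by start index).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InputError("points must be a sequence of (s, k) pairs")
    s, k = pts[:, 0], pts[:, 1]
    if len(s) < 5:
        raise FitError(f"need at least 5 points to fit 4 parameters, got {len(s)}")
    if np.any(s <= 0):
        raise InputError("s values must be positive")
    if len(np.unique(s)) != len(s):
        raise InputError("s values must be distinct")

    best = None
    for i, p0 in enumerate(_TWO_TERM_INITS):
        try:
            with np.errstate(over="ignore", invalid="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(_two_term_exp, s, k, p0=p0, maxfev=20000)
        except (RuntimeError, OverflowError):
            continue
        resid = k - _two_term_exp(s, *popt)
        ssr = float(resid @ resid)
        if not np.isfinite(ssr):
            continue
        if best is None or ssr < best[0]:
            best = (ssr, i, popt)
    if best is None:
        raise FitError(
            "two-term exponential fit did not converge from any of the "
            f"{len(_TWO_TERM_INITS)} starting points"
        )
    ssr, _, popt = best
    sst = float(np.sum((k - k.mean()) ** 2))
    r2 = 1.0 if sst == 0.0 and ssr < 1e-12 else (1.0 - ssr / sst if sst > 0 else 0.0)
    fit = CorrectionFactorFit(*(float(p) for p in popt), r_squared=r2)
    check = fit(s)
    if not np.all(np.isfinite(check)) or np.any(check <= 0):
        raise FitError("fitted curve is not finite and positive over the data range")
    return fit


# --------------------------------------------------------------------------
# Calibration, CT curve, archive
# --------------------------------------------------------------------------

@dataclass
class AbsoluteCalibration:
    """Absolute dosimetry calibration of the reference field.

    ``dr_ref_gy_per_mu`` is the reference dose rate DRref: absolute dose in
    water per MU for the reference field at the calibration depth.
    """

    dr_ref_gy_per_mu: float
    depth_mm: float
    ssd_mm: float
    sad_mm: float = 1000.0
    ref_field_size_mm: float = 100.0

    def __post_init__(self) -> None:
        if self.dr_ref_gy_per_mu <= 0:
            raise ConfigurationError("calibration: DRref must be positive")
        if self.sad_mm <= 0:
            raise ConfigurationError("calibration: SAD must be positive")


@dataclass
class CTCalibrationCurve:
    """Piecewise-linear HU -> relative electron density calibration.

    Outside the tabulated HU range the RED is clamped to the end values.
    Water (HU ~ 0) must map to RED ~ 1.
    """

    hu: np.ndarray
    red: np.ndarray

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=float)
        self.red = np.asarray(self.red, dtype=float)
        if self.hu.ndim != 1 or self.hu.shape != self.red.shape or self.hu.size < 2:
            raise ConfigurationError("ct_curve: need matching 1-D hu/red arrays (>= 2 points)")
        if not np.all(np.diff(self.hu) > 0):
            raise ConfigurationError("ct_curve: HU breakpoints must be strictly increasing")
        if np.any(np.diff(self.red) < 0) or np.any(self.red < 0):
            raise ConfigurationError("ct_curve: RED must be non-negative and non-decreasing")
        if abs(self.red_at(0.0) - 1.0) > 0.05:
            raise ConfigurationError("ct_curve: HU=0 must map to RED~1 (water)")

    def red_at(self, hu):
        r = np.interp(np.asarray(hu, dtype=float), self.hu, self.red)
        return float(r) if np.ndim(hu) == 0 else r

    def hu_for_red(self, red: float) -> float:
        """Inverse lookup (first HU reaching the requested RED)."""
        return float(np.interp(red, self.red, self.hu))


@dataclass
class ConeRecord:
    """Per-cone entry of the archive: TMR table plus output factor."""

    diameter_mm: float
    tmr: TMRTable
    of: float
    fwhm_mm: Optional[float] = None  # measured-FWHM override for Eq.-square


@dataclass
class BeamDataArchive:
    """All commissioning data for one machine + energy.

    This is the unit of configuration: it is built once from tabular
    commissioning files, serialized to JSON, and loaded by the MU calculator.
    """

    machine: str
    energy: str
    cones: dict[float, ConeRecord]
    output_geometry_ssd_mm: float
    output_geometry_depth_mm: float
    calibration: AbsoluteCalibration
    ct_curve: CTCalibrationCurve
    correction_fit: Optional[CorrectionFactorFit] = None

    def __post_init__(self) -> None:
        if not self.cones:
            raise ConfigurationError("archive must contain at least one cone")

    # -- lookups ------------------------------------------------------------

    def cone_key(self, cone_mm: float) -> float:
        for key in self.cones:
            if abs(key - cone_mm) <= 0.05:
                return key
        raise LookupError(
            f"cone {cone_mm} mm not in archive (have "
            f"{sorted(self.cones)})"
        )

    def cone(self, cone_mm: float) -> ConeRecord:
        return self.cones[self.cone_key(cone_mm)]

    def tmr(self, cone_mm: float, depth) -> float:
        return self.cone(cone_mm).tmr.lookup(depth)

    @property
    def output_factors(self) -> OutputFactorTable:
        return OutputFactorTable(
            cones={d: rec.of for d, rec in self.cones.items()},
            ssd_mm=self.output_geometry_ssd_mm,
            depth_mm=self.output_geometry_depth_mm,
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": ARCHIVE_FORMAT_VERSION,
            "machine": self.machine,
            "energy": self.energy,
            "calibration": {
                "dr_ref_gy_per_mu": self.calibration.dr_ref_gy_per_mu,
                "depth_mm": self.calibration.depth_mm,
                "ssd_mm": self.calibration.ssd_mm,
                "sad_mm": self.calibration.sad_mm,
                "ref_field_size_mm": self.calibration.ref_field_size_mm,
            },
            "ct_curve": {
                "hu": self.ct_curve.hu.tolist(),
                "red": self.ct_curve.red.tolist(),
            },
            "correction_fit": None
            if self.correction_fit is None
            else {
                "a": self.correction_fit.a,
                "b": self.correction_fit.b,
                "c": self.correction_fit.c,
                "d": self.correction_fit.d,
                "r_squared": self.correction_fit.r_squared,
            },
            "cones": [
                {
                    "diameter_mm": d,
                    "fwhm_mm": rec.fwhm_mm,
                    "dmax_mm": rec.tmr.dmax,
                    "of": rec.of,
                    "of_geometry": {
                        "ssd_mm": self.output_geometry_ssd_mm,
                        "depth_mm": self.output_geometry_depth_mm,
                    },
                    "tmr": {
                        "depths": rec.tmr.depths.tolist(),
                        "values": rec.tmr.values.tolist(),
                    },
                }
                for d, rec in sorted(self.cones.items())
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BeamDataArchive":
        if d.get("format_version") != ARCHIVE_FORMAT_VERSION:
            raise ConfigurationError(
                f"unsupported archive format_version {d.get('format_version')!r}"
            )
        cal = AbsoluteCalibration(**d["calibration"])
        curve = CTCalibrationCurve(hu=d["ct_curve"]["hu"], red=d["ct_curve"]["red"])
        fit = None
        if d.get("correction_fit") is not None:
            fit = CorrectionFactorFit(**d["correction_fit"])
        cones: dict[float, ConeRecord] = {}
        geoms = set()
        for c in d["cones"]:
            diam = float(c["diameter_mm"])
            tab = TMRTable(
                cone_id=diam,
                depths=c["tmr"]["depths"],
                values=c["tmr"]["values"],
                dmax=float(c["dmax_mm"]),
            )
            cones[diam] = ConeRecord(
                diameter_mm=diam, tmr=tab, of=float(c["of"]), fwhm_mm=c.get("fwhm_mm")
            )
            geoms.add((c["of_geometry"]["ssd_mm"], c["of_geometry"]["depth_mm"]))
        if len(geoms) != 1:
            raise ConfigurationError("all cones must share one OF measurement geometry")
        (ssd, dep), = geoms
        return cls(
            machine=d["machine"],
            energy=d["energy"],
            cones=cones,
            output_geometry_ssd_mm=float(ssd),
            output_geometry_depth_mm=float(dep),
            calibration=cal,
            ct_curve=curve,
            correction_fit=fit,
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def load(cls, path) -> "BeamDataArchive":
        return cls.from_dict(json.loads(Path(path).read_text()))


def of_at_tmrmax(archive: BeamDataArchive, cone_mm: float) -> float:
    """Output factor renormalized to the depth of maximum dose in TMR geometry.

    OF_TMRmax(S) = OF(S) * PDD(S, SSD, dmax) / PDD(S, SSD, d_meas)
                         * ((SSD + dmax) / SAD)^2

    with SSD and d_meas taken from the OF measurement geometry. This converts
    a fixed-SSD water-tank reading at depth d_meas into the factor needed by
    the isocentric TMR formalism.
    """
    rec = archive.cone(cone_mm)
    ssd = archive.output_geometry_ssd_mm
    d_meas = archive.output_geometry_depth_mm
    sad = archive.calibration.sad_mm
    pdd_dmax = tmr_to_pdd(rec.tmr, ssd, rec.tmr.dmax)
    pdd_meas = tmr_to_pdd(rec.tmr, ssd, d_meas)
    return rec.of * (pdd_dmax / pdd_meas) * ((ssd + rec.tmr.dmax) / sad) ** 2


# --------------------------------------------------------------------------
# Archive build from commissioning files
# --------------------------------------------------------------------------

def _read_two_column_csv(path, cols, what: str) -> pd.DataFrame:
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"{what}: file not found: {p}")
    try:
        df = pd.read_csv(p, sep=None, engine="python")
    except Exception as exc:  # malformed delimited text
        raise ConfigurationError(f"{what}: cannot parse {p}: {exc}") from exc
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{what}: {p} missing column(s) {missing}")
    return df


def build_archive(config: dict) -> BeamDataArchive:
    """Build a validated archive from a configuration mapping.

    Expected keys::

        machine, energy            str labels
        dmax_mm                    depth of maximum dose for this energy
        tmr_csvs                   {cone_mm: path}  columns depth_mm,value
        of_csv                     path, columns cone_mm,of
        of_ssd_mm, of_depth_mm     OF measurement geometry (default 950 / 50)
        ct_csv                     path, columns hu,red
        dr_ref_gy_per_mu           reference dose rate
        cal_depth_mm, cal_ssd_mm   calibration geometry
        sad_mm                     default 1000
        correction_csv             optional, columns s_mm,k
        smooth_window              optional odd moving-average width
    """
    for key in ("machine", "energy", "dmax_mm", "tmr_csvs", "of_csv", "ct_csv"):
        if key not in config:
            raise ConfigurationError(f"config: missing required key '{key}'")
    if "dr_ref_gy_per_mu" not in config or config["dr_ref_gy_per_mu"] is None:
        raise ConfigurationError("config: calibration requires 'dr_ref_gy_per_mu'")

    dmax = float(config["dmax_mm"])
    sad = float(config.get("sad_mm", 1000.0))
    smooth = config.get("smooth_window")

    of_df = _read_two_column_csv(config["of_csv"], ("cone_mm", "of"), "output factors")
    ofs = {float(r.cone_mm): float(r.of) for r in of_df.itertuples()}
    if not ofs:
        raise ConfigurationError("output factors: empty cone list")

    tmr_csvs = {float(k): v for k, v in dict(config["tmr_csvs"]).items()}
    cones: dict[float, ConeRecord] = {}
    for cone_mm, of in sorted(ofs.items()):
        path = None
        for k, v in tmr_csvs.items():
            if abs(k - cone_mm) <= 0.05:
                path = v
        if path is None:
            raise ConfigurationError(f"tmr_csvs: no TMR file for cone {cone_mm} mm")
        df = _read_two_column_csv(path, ("depth_mm", "value"), f"TMR cone {cone_mm}")
        table = resample_and_normalize_tmr(
            df["depth_mm"].to_numpy(),
            df["value"].to_numpy(),
            dmax=dmax,
            cone_id=cone_mm,
            smooth_window=smooth,
        )
        cones[cone_mm] = ConeRecord(diameter_mm=cone_mm, tmr=table, of=of)

    ct_df = _read_two_column_csv(config["ct_csv"], ("hu", "red"), "CT calibration")
    curve = CTCalibrationCurve(hu=ct_df["hu"].to_numpy(), red=ct_df["red"].to_numpy())

    cal = AbsoluteCalibration(
        dr_ref_gy_per_mu=float(config["dr_ref_gy_per_mu"]),
        depth_mm=float(config.get("cal_depth_mm", dmax)),
        ssd_mm=float(config.get("cal_ssd_mm", sad - dmax)),
        sad_mm=sad,
        ref_field_size_mm=float(config.get("ref_field_size_mm", 100.0)),
    )

    fit = None
    if config.get("correction_csv"):
        k_df = _read_two_column_csv(
            config["correction_csv"], ("s_mm", "k"), "correction factors"
        )
        fit = fit_correction_curve(k_df[["s_mm", "k"]].to_numpy())

    return BeamDataArchive(
        machine=str(config["machine"]),
        energy=str(config["energy"]),
        cones=cones,
        output_geometry_ssd_mm=float(config.get("of_ssd_mm", 950.0)),
        output_geometry_depth_mm=float(config.get("of_depth_mm", 50.0)),
        calibration=cal,
        ct_curve=curve,
        correction_fit=fit,
    )
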