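"""Monitor-unit computation at the isocenter.

The dose delivered to the isocenter by a conical field of nominal size S at
depth d is modelled as

    D = MU * DRref * OF_TMRmax(S) * TMR(d, S)

with the off-axis ratio and the inverse-square term both unity at the
isocenter. Inverting gives the MU of a static field,

    MU = D / (DRref * OF_TMRmax(S) * TMR(d, S)),

and for an arc the TMR is replaced by its arithmetic mean over the incident
gantry angles (the arc segmented at 1 deg by default). The heterogeneity
correction substitutes the effective depth deff (equivalent path length)
for d in every TMR lookup; both the uncorrected (NHC) and corrected (WHC)
MU are always computed in one pass since they share the ray geometry.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beam_model import BeamDataArchive, of_at_tmrmax
from .dicom_io import ConeBeam, PlanBundle
from .exceptions import ComputationError, InputError, StereoMUError
from .geometry import compute_depths, ray_for_angles, segment_arc


def percent_diff(mu_calc: float, mu_ref: float) -> float:
    """Signed percent difference 100 * (mu_calc - mu_ref) / mu_ref."""
    if mu_ref <= 0:
        raise InputError("reference MU must be positive")
    return 100.0 * (mu_calc - mu_ref) / mu_ref


def mu_static(dose_gy: float, archive: BeamDataArchive, cone_mm: float, depth_mm: float) -> float:
    """MU of a static field delivering ``dose_gy`` to the isocenter at depth d."""
    if dose_gy <= 0:
        raise InputError("dose must be positive")
    if depth_mm < 0:
        raise InputError("depth must be non-negative")
    tmr = archive.tmr(cone_mm, depth_mm)
    if tmr <= 0:
        raise ComputationError(f"TMR({depth_mm} mm) <= 0 for cone {cone_mm} mm")
    return dose_gy / (
        archive.calibration.dr_ref_gy_per_mu * of_at_tmrmax(archive, cone_mm) * tmr
    )


def dose_from_mu(mu: float, archive: BeamDataArchive, cone_mm: float, depth_mm: float) -> float:
    """Forward dose (Gy) at the isocenter from MU — the inverse of mu_static."""
    return (
        mu
        * archive.calibration.dr_ref_gy_per_mu
        * of_at_tmrmax(archive, cone_mm)
        * archive.tmr(cone_mm, depth_mm)
    )


def average_tmr(depths_mm, archive: BeamDataArchive, cone_mm: float) -> float:
    """Arithmetic mean of TMR(depth_k, S) over the arc's segment angles."""
    depths = np.asarray(depths_mm, dtype=float)
    if depths.size == 0:
        raise InputError("need at least one depth")
    if not np.all(np.isfinite(depths)):
        raise InputError("depths must be finite")
    table = archive.cone(cone_mm).tmr
    return float(np.mean(table.lookup(depths)))


@dataclass
class MUResult:
    """Per-beam MU check outcome with per-angle diagnostics."""

    beam_id: str
    cone_mm: float
    is_arc: bool
    plan_mu: float
    mu_nhc: float
    mu_whc: float
    diff_nhc_pct: float
    diff_whc_pct: float
    angles_deg: np.ndarray
    depths_mm: np.ndarray
    eff_depths_mm: np.ndarray
    tmr_d: np.ndarray
    tmr_deff: np.ndarray
    of_tmrmax: float
    dr_ref_gy_per_mu: float
    headline: str = "WHC"

    @property
    def mu(self) -> float:
        """Headline MU, selected by the heterogeneity flag."""
        return self.mu_whc if self.headline == "WHC" else self.mu_nhc


def mu_for_beam(
    beam: ConeBeam,
    bundle: PlanBundle,
    archive: BeamDataArchive,
    heterogeneity: bool = True,
    include_couch: bool = True,
    resolution_deg: float = 1.0,
) -> MUResult:
    """Compute MU_NHC and MU_WHC for one beam of a plan bundle.

    Static beams use the single incident angle; arcs are segmented at
    ``resolution_deg`` and the TMR averaged over segments. The
    ``heterogeneity`` flag only selects which value is the headline — both
    are always computed. Differences are reported against the plan MU.
    """
    try:
        angles = segment_arc(
            beam.gantry_start_deg,
            beam.gantry_stop_deg,
            beam.rotation_direction,
            resolution_deg,
        )
        sad = archive.calibration.sad_mm
        table = archive.cone(beam.cone_mm).tmr
        ds, deffs = [], []
        for g in angles:
            ray = ray_for_angles(beam.isocenter, g, beam.couch_deg, sad)
            res = compute_depths(
                ray,
                bundle.ct,
                archive.ct_curve,
                bundle.structures,
                include_couch=include_couch,
            )
            ds.append(res.d_mm)
            deffs.append(res.deff_mm)
        ds = np.asarray(ds)
        deffs = np.asarray(deffs)
        tmr_d = np.atleast_1d(table.lookup(ds))
        tmr_deff = np.atleast_1d(table.lookup(deffs))
        mean_tmr_d = float(np.mean(tmr_d))
        mean_tmr_deff = float(np.mean(tmr_deff))
        if mean_tmr_d <= 0 or mean_tmr_deff <= 0:
            raise ComputationError("non-positive mean TMR")

        of_max = of_at_tmrmax(archive, beam.cone_mm)
        dr_ref = archive.calibration.dr_ref_gy_per_mu
        mu_nhc = beam.dose_gy / (dr_ref * of_max * mean_tmr_d)
        mu_whc = beam.dose_gy / (dr_ref * of_max * mean_tmr_deff)
    except (StereoMUError, LookupError) as exc:
        raise ComputationError(f"beam {beam.beam_id}: {exc}") from exc

    return MUResult(
        beam_id=beam.beam_id,
        cone_mm=beam.cone_mm,
        is_arc=beam.is_arc,
        plan_mu=beam.plan_mu,
        mu_nhc=mu_nhc,
        mu_whc=mu_whc,
        diff_nhc_pct=percent_diff(mu_nhc, beam.plan_mu),
        diff_whc_pct=percent_diff(mu_whc, beam.plan_mu),
        angles_deg=angles,
        depths_mm=ds,
        eff_depths_mm=deffs,
        tmr_d=tmr_d,
        tmr_deff=tmr_deff,
        of_tmrmax=of_max,
        dr_ref_gy_per_mu=dr_ref,
        headline="WHC" if heterogeneity else "NHC",
    )


def mu_for_plan(
    bundle: PlanBundle,
    archive: BeamDataArchive,
    heterogeneity: bool = True,
    include_couch: bool = True,
    resolution_deg: float = 1.0,
) -> list[MUResult]:
    """Run the MU check for every beam of the bundle."""
    return [
        mu_for_beam(
            b,
            bundle,
            archive,
            heterogeneity=heterogeneity,
            include_couch=include_couch,
            resolution_deg=resolution_deg,
        )
        for b in bundle.beams
    ]
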