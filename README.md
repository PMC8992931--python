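# stereomu

An independent monitor-unit (MU) calculator for stereotactic radiosurgery
with conical collimators. Given commissioning beam data for one machine and
energy — per-cone tissue-maximum-ratio (TMR) curves, output factors (OF),
the absolute calibration, and a CT-number → relative-electron-density (RED)
calibration — and a DICOM-exported treatment plan (CT series, RT Plan, RT
Structure Set, RT Dose), it recomputes the MU of every static cone field or
arc at the isocenter, with and without CT-based heterogeneity correction,
for comparison against the treatment planning system's value. It is aimed
at medical physicists running secondary MU checks (TG-114 style) on
cone-based SRS plans.

## The model

The dose at the isocenter of a cone field of nominal size *S* at depth *d*
is

    D = MU · DRref · OF_TMRmax(S) · TMR(d, S)

with the off-axis ratio and the inverse-square term both unity at the
isocenter. Inverting gives the MU of a static field; for an arc, the TMR is
replaced by its arithmetic mean over the incident gantry angles, with the
arc segmented at 1° resolution. `OF_TMRmax` converts the fixed-SSD output
factor reading into isocentric TMR geometry via PDD curves derived from the
TMR tables:

    OF_TMRmax(S) = OF(S) · PDD(S, SSD, dmax) / PDD(S, SSD, d_meas) · ((SSD + dmax)/SAD)²

The depth *d* is found by intersecting the source→isocenter ray (IEC 61217
gantry/couch geometry) with the plan's external contour. The heterogeneity
correction replaces *d* by the effective depth (equivalent path length)

    deff = Σᵢ REDᵢ · xᵢ

accumulated by an exact voxel-boundary (Siddon-type) traversal of the CT,
where `xᵢ` is the intersection length of the ray with voxel *i* and `REDᵢ`
comes from the HU calibration curve. Couch attenuation is included by
starting the accumulation at the CT volume face (switchable). Percentage
differences against the plan are `100·(MU_calc − MU_plan)/MU_plan`.

## Worked example

`examples/02_homogeneous_check.py` generates a DICOM study of a homogeneous
water cylinder (radius 80 mm) with three static fields and three arcs whose
isocenter doses were forward-computed from known MU values, then runs the
check:

```
beam S-g90        cone  10.0 mm static planMU    150.00  MU_NHC    150.00 ( +0.00%)  MU_WHC    149.93 ( -0.04%)
beam S-g45-c30    cone  17.5 mm static planMU    180.00  MU_NHC    180.00 ( +0.00%)  MU_WHC    180.34 ( +0.19%)
beam A-0-180      cone  10.0 mm arc    planMU    200.00  MU_NHC    200.00 ( -0.00%)  MU_WHC    200.00 ( -0.00%)
...
Diff_NHC mean +/- SD: -0.00% +/- 0.00%
Diff_WHC mean +/- SD: +0.01% +/- 0.08%
```

`MU_NHC` (no heterogeneity correction) recovers the embedded MU exactly —
the study was built with the same water model — and `MU_WHC` agrees to
within ~0.2%, the residual being the half-voxel surface ambiguity of the
2 mm CT grid. On the thorax-like phantom (`examples/03_thorax_heterogeneity.py`)
the correction pulls the two directions apart as it should:

```
beam          <d> mm   <deff> mm   MU_NHC    MU_WHC   WHC vs NHC
S-90-lung      100.0       83.5    200.00    187.23    -6.38 %
S-180-bone      75.0       84.9    200.00    208.05    +4.03 %
A-0-180         86.1       84.7    250.00    248.67    -0.53 %
```

The lateral beam crosses a low-density insert (shorter effective depth →
fewer MU); the posterior beam crosses a bone-like insert and the couch
(deeper effective depth → more MU); the arc averages over both.

## Command line

```
stereomu beam-config --config commissioning.json --out archive.json
stereomu calc --archive archive.json --study exported_plan/ --out report/
stereomu make-fixtures thorax --out study_thorax --seed 0
```

`calc` writes `report.csv` (fixed schema, one row per beam) and a
human-readable `report.txt`, flagging beams beyond the configurable 2%
(homogeneous-equivalence) and 5% (clinical tolerance) action levels.

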