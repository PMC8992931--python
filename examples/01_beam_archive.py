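"""Build a beam-data archive and inspect the small-field dosimetry factors.

Constructs a fully analytic commissioning data set (TMR tables per cone,
output factors, absolute calibration, CT calibration curve), saves it to
JSON, and prints the derived per-cone quantities the MU formula consumes.
"""
from stereomu import equivalent_square, of_at_tmrmax, tmr_to_pdd
from stereomu.fixtures import SyntheticBeamSpec, make_archive

archive = make_archive(SyntheticBeamSpec(energy="6FFF", dmax_mm=15.0))
archive.save("archive.json")
print(f"archive for {archive.machine} / {archive.energy} -> archive.json")
print(f"DRref = {archive.calibration.dr_ref_gy_per_mu} Gy/MU at "
      f"depth {archive.calibration.depth_mm} mm, SAD {archive.calibration.sad_mm} mm\n")

print("cone    eq.square   OF(950/50)   OF_TMRmax   TMR(80mm)   PDD(80mm,SSD 900)")
for diam, rec in sorted(archive.cones.items()):
    print(
        f"{diam:5.1f} mm  {equivalent_square(diam):6.2f} mm   "
        f"{rec.of:8.4f}   {of_at_tmrmax(archive, diam):9.4f}   "
        f"{rec.tmr.lookup(80.0):8.4f}   {tmr_to_pdd(rec.tmr, 900.0, 80.0):8.2f} %"
    )

# The equivalent square is the side of the square field with the same area
# as the circular cone field (s = r * sqrt(pi)); OF_TMRmax renormalizes the
# fixed-SSD output factor to the depth of maximum dose in isocentric (TMR)
# geometry, which is what the MU formula divides by.
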