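import numpy as np
import pytest
from hypothesis import settings

from stereomu import dicom_io
from stereomu import fixtures as fx

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def archive():
    return fx.make_archive()


@pytest.fixture(scope="session")
def cylinder_study(tmp_path_factory, archive):
    """Homogeneous water cylinder with 3 static + 3 arc beams, on disk."""
    out = tmp_path_factory.mktemp("homog")
    bundle = fx.make_study(
        fx.homogeneous_phantom(), fx.homogeneous_beams(), archive, out, seed=1
    )
    return out, bundle


@pytest.fixture(scope="session")
def cylinder_bundle(cylinder_study):
    """The homogeneous study read back through the DICOM layer."""
    out, _ = cylinder_study
    return dicom_io.read_study(out)


@pytest.fixture(scope="session")
def thorax_study(tmp_path_factory, archive):
    out = tmp_path_factory.mktemp("thorax")
    bundle = fx.make_study(
        fx.thorax_phantom(), fx.thorax_beams(), archive, out, seed=2
    )
    return out, bundle


@pytest.fixture(scope="session")
def thorax_bundle(thorax_study):
    out, _ = thorax_study
    return dicom_io.read_study(out)


@pytest.fixture(scope="session")
def cylinder_phantom_raw():
    """In-memory cylinder CT + contours (no DICOM round trip)."""
    return fx.build_phantom(fx.homogeneous_phantom())


def fine_step_epl(ct, curve, p0, p1, t_lo, step_mm=0.05):
    """Independent EPL oracle: midpoint-rule sampling at a fixed step.

    Looks the HU up at the nearest voxel of each sample point, exactly the
    piecewise-constant density field the exact traversal integrates.
    """
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    length = float(np.linalg.norm(p1 - p0)) * (1.0 - t_lo)
    n = max(int(np.ceil(length / step_mm)), 1)
    ts = t_lo + (1.0 - t_lo) * (np.arange(n) + 0.5) / n
    pts = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
    idx = np.floor(ct.world_to_index(pts) + 0.5).astype(int)
    nk, nr, nc = ct.shape
    ok = (
        (idx[:, 0] >= 0) & (idx[:, 0] < nc)
        & (idx[:, 1] >= 0) & (idx[:, 1] < nr)
        & (idx[:, 2] >= 0) & (idx[:, 2] < nk)
    )
    red = np.zeros(n)
    red[ok] = curve.red_at(ct.hu[idx[ok, 2], idx[ok, 1], idx[ok, 0]])
    return float(np.sum(red) * length / n)


def volume_entry_parameter(ct, p0, p1):
    """Independent slab-method clip of the segment against the volume box."""
    a0 = ct.world_to_index(np.asarray(p0, float))
    a1 = ct.world_to_index(np.asarray(p1, float))
    d = a1 - a0
    nk, nr, nc = ct.shape
    dims = np.array([nc, nr, nk], float)
    t = 0.0
    for ax in range(3):
        if abs(d[ax]) < 1e-12:
            continue
        ta = (-0.5 - a0[ax]) / d[ax]
        tb = (dims[ax] - 0.5 - a0[ax]) / d[ax]
        t = max(t, min(ta, tb))
    return t
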